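# Custom reconstruction protocol: eigen-flat-field (dynamic) flat fielding,
# automatic axis finding + stitching, Fourier de-striping, TIE-Hom phase
# retrieval with delta/beta = 100, filtered back projection.
input: {container: hdf5}
output: {dir: recon_custom}
slices: {start: 1, stop: 2}
stages:
  - {stage: flat, method: dynamic, n_components: 2}
  - {stage: geometry, axis: auto}
  - {stage: ring, method: raven, placement: pre_phase, u0: 0.05}
  - {stage: phase, method: paganin, delta_beta_ratio: 100.0, delta_ref: 1.0e-7}
  - {stage: recon, algorithm: fbp, filter: shepp_logan}
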