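# Synthetic offset-axis ("half acquisition") scan of a soft-tissue-like
# ellipse phantom at the 40 keV / 2.2 m / 3.05 um geometry, with detector
# gain stripes, beam drift and Poisson noise.
simulate:
  geometry:
    energy: 40.0            # keV
    pixel_size: 3.05e-6     # m
    distance: 2.2           # m sample-to-detector
    n_angles: 400
    scan_mode: full_turn_360_offset
  detector: {width: 128, height: 4}
  axis_offset: 30.0         # px from detector centre
  phantom:
    - {semi_axis_a: 1.83e-4, semi_axis_b: 1.83e-4, delta_value: 1.0e-7, beta_value: 1.0e-9}
    - {center_x: 7.6e-5, center_y: 3.7e-5, semi_axis_a: 4.3e-5, semi_axis_b: 7.3e-5,
       rotation: 40.0, delta_value: 5.0e-8, beta_value: 5.0e-10}
    - {center_x: -9.2e-5, center_y: -4.6e-5, semi_axis_a: 3.1e-5, semi_axis_b: 3.1e-5,
       delta_value: -4.0e-8, beta_value: 0.0}
  corruption:
    photon_count: 1.0e5
    dark_level: 10.0
    stripe_columns: 12
    stripe_gain: 1.06
    drift_components: 2
    drift_amplitude: 0.03
  flats: {before: 16, after: 16, darks: 2}
  output: {path: scan.h5, container: hdf5}
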