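# Methods

This note records the models, conventions, numerical choices and known
limitations of `pbirecon`, in the spirit of a beamline processing manual.

## Optical model and conventions

The sample is a thin object with refractive index *n* = 1 − δ + iβ under
a monochromatic, fully coherent plane wave.  Its transmittance is

    u(x, y) = exp(−(2π/λ) B) · exp(−i (2π/λ) D),
    D = ∫ δ dz,   B = ∫ β dz,

so the transmittance *phase* is −(2π/λ)D (negative for δ > 0).  Free
space is the paraxial (Fresnel) transfer function
`exp(−iπ λ d |f|²)` applied in the discrete Fourier domain with **f in
cycles per metre** throughout the package.  The Paganin filter is
correspondingly `H = 1/(1 + π λ d r |f|²)`; implementations that use
angular frequency |k| = 2π|f| differ by 4π² in the coefficient —
the convention is fixed here once so all filters and the simulator agree.

Images are 0-based with pixel-centre coordinates; the rotation axis is a
float column index; angles are degrees externally (beamline logs use
degrees) and radians internally.  Lengths are metres, energies keV
(λ = hc/E with hc = 1.23984193·10⁻⁹ keV·m).  All processing is float64;
slices are written as 32-bit float TIFF so physical units survive.

## Simulator

The phantom is a list of additive ellipses with δ- and β-increments, so
its Radon transform has the exact closed form
`2ab·v·sqrt(ρ² − (s−s₀)²)/ρ²` per ellipse.  The forward model evaluates
these chord integrals directly on the detector grid (also at offset
detector coordinates for half-acquisition scans — exact, no
interpolation, which keeps the center-of-rotation ground truth good to
machine precision), propagates with the Fresnel kernel (periodic
boundaries; optional symmetric padding suppresses wrap-around), and
corrupts frames as

    Poisson( photon_count · gain_map · beam(t) · transmission ) + dark_level,

with `beam(t) = 1 + Σ_k w_k(t) E_k` a low-rank drift: a few smooth
spatial modes (tilt, curvature polynomials) times slow sinusoidal
temporal weights.  The drift is low-rank *by construction* so that
PCA-based dynamic flat fielding has a well-posed target; real beam
instability is only approximately low-rank.  Not modelled: partial
coherence, polychromaticity, detector PSF, scattering — passing tests
therefore certify the inversion chain, not detector physics.

Default study conditions (frozen in `pbirecon.benchmarks`): 40 keV,
d = 2.2 m, 3.05 µm pixels; soft-tissue-like δ ≈ 10⁻⁷ with δ/β of
100–200; 10⁵–10⁶ photons per pixel; 3–4 % beam drift on two modes;
*severe* fixed-pattern stripes (6 % gain error on ~10 % of columns,
emulating scintillator bright spots — mild stripes produce rings too
faint for de-striping to pay for its smoothing at desk scale).

## Flat fielding

Conventional: `N = (P − D̄)/(F̄ − D̄)`, denominator clamped at
10⁻⁶ × max(F̄ − D̄), output clipped to [0, 10] so the downstream log
never sees ≤ 0.  Flats before and after the scan are pooled by default.

Dynamic: the dark-subtracted, mean-centred flats are decomposed by SVD;
the top components ("eigen flat fields", unit L2 norm) span the drift
subspace.  Each projection's residual `P − D̄ − (F̄ − D̄)` is fitted by
linear least squares onto the components and the projection divided by
the synthesised flat.  Weights are estimated **per projection** (not per
sinogram row): drift is a property of a moment in time, i.e. of a frame.
Least squares replaces the total-variation weighting of the original
dynamic-flat-field method: closed-form, testable, and exact whenever the
frame is itself a combination of the mean flat and the modes.

The estimation region matters.  Whole-frame fitting absorbs object
structure into the drift weights and measurably biases the normalisation
(in simulation the end-to-end δ correlation drops by ~0.13), so the
pipeline default is an automatically detected **air mask**: pixels whose
median normalised intensity over the scan stays above 0.95, falling back
to the whole frame when almost no air is visible.  The low-level
`dynamic_flat_field` keeps the whole frame as its default and accepts an
explicit mask.  With constant flats every singular value is ~0, the
basis is empty and the dynamic path reproduces the conventional result
bit-for-bit.

## Axis finding and stitching

A projection at θ+180° is the horizontal mirror of the one at θ about
the axis column, so the axis is `(W−1)/2 + s/2` where *s* is the shift
maximising the normalised cross-correlation with the mirrored opposite
view.  Two details proved load-bearing: (i) the NCC is evaluated on the
**overlap window** of each candidate shift (features outside it have no
mirror counterpart in an offset-axis scan — a global FFT correlation
locks onto the object instead of its mirror); (ii) for full 360° scans
the NCC curves of up to eight θ/θ+180° pairs are averaged, and the axis
is always located on *conventionally* flat-fielded frames (per-frame
drift fitting can leave a stationary background that biases the mirror
correlation).  Integer peak + parabolic refinement gives sub-0.1-px
accuracy on simulated data; a peak correlation below 0.2 attaches a
low-confidence warning that pipelines surface in the run report.

Stitching folds rows θ and θ+180 about the axis: output width
`W′ = round(2a + 1)` (axis in the right half; the left half is handled
by mirroring), overlap `v = 2W − W′` blended with a linear ramp (cosine
and hard-cut alternatives are selectable); at the overlap edges the
output equals the single contributing view exactly.  Fractional axes are
sampled with linear interpolation; a sub-pixel uncovered margin at the
far edges is filled with the nearest covered value.  An axis at the
detector centre has no extra field of view to gain and raises a
degenerate-overlap error pointing at the 180° scan mode.

## Ring removal

Stripes that are constant in angle live in the lowest angular-frequency
rows of the 2-D sinogram spectrum, where they are broadband along the
detector frequency.  The Raven-type filter multiplies those rows
(|m| < `n_angular_lines`, default 2; the classic filter uses only m = 0)
by a Butterworth low-pass `1/(1 + (u/u0)^(2·order))` with defaults
u0 = 0.05 cycles/px and order 4.  H(0) = 1 preserves the sinogram mean;
filtering symmetric ±m rows keeps the inverse transform real to machine
precision.  The exact "modified" parameterisation used in beamline
practice is not published; this three-parameter form is a documented
surrogate, and the cutoff is a per-dataset tuning knob exactly as it is
in practice.  The column-normalisation filter (divide each column by its
angular mean over a moving-average trend) is the simple representative
of the statistical de-striper family.  Both filters are ~idempotent and
may be placed before and/or after phase retrieval.

`ring_energy` quantifies rings as the mean over integer radii of the
within-circle pixel variance, minus the same statistic of a reference
image (ground truth or an identically filtered clean reconstruction) so
genuine angular structure does not count.  It is a diagnostic for tests
and reports, not a processing stage.

## Phase retrieval

Paganin/TIE-Hom as in the overview; the filtered intensity is clamped at
10⁻⁸ before the log; symmetric padding (default 128 px) suppresses the
cyclic wrap of the filter.  μ comes from `mu` directly or from
`delta_ref / delta_beta_ratio`.  The retrieval returns both the
projected thickness t and the pseudo-absorption −μt; for reconstruction
the pipeline converts to line integrals of δ (t · δ_ref), so FBP yields
a δ map for a homogeneous object.

CTF: `φ = 𝓕⁻¹[ 𝓕(I/I₀ − 1) · R/(R² + ε) ]` with `R = 2 sin χ`,
`χ = π λ d |f|²`.  The DC component is unobservable and set to zero
(recovered phases are compared mean-free).  The projected-CTF
(quasiparticle) variant clamps the response at χ = π/2 by default —
a monotone surrogate for the unpublished projected response, clearly a
stand-in and labelled as such.  ε trades noise amplification near the
sine zeros against low-frequency fidelity; the clean-simulation
benchmarks use ε = 10⁻¹⁰, the pipeline default is a conservative 10⁻³.
CTF phase output is converted to δ line integrals via
`D = −φ λ/(2π)` (transmittance-phase sign convention).

The `compare_retrievals` report operationalises the known TIE-Hom
resolution loss: on a weak pure-phase edge the Paganin 10–90 % rise
distance exceeds the CTF one.  Note that TIE-Hom retrieves a *pure*
phase edge only in its large-δ/β limit — at moderate ratios the
homogeneity assumption band-passes the step away entirely.

## Reconstruction

One projector pair serves both algorithms: pixel-driven forward
splatting (each pixel's value × pixel size shared linearly between the
two nearest detector bins) and its exact transpose, linear-interpolation
back projection — the adjoint identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to
machine precision, which makes the SIRT update
`x ← x + C Aᵀ R (b − A x)` (inverse row/column-sum weighting,
optional non-negativity clamp) provably non-expansive.  SIRT reports the
per-iteration residual and aborts if it grows three iterations running.

FBP filters each zero-padded row (next power of two ≥ 2W) with the
**band-limited ramp**: the DFT of the discrete kernel (¼ at 0,
−1/(πn)² at odd n), which tends to 2|f| but avoids the DC deficit of
sampling |f| directly (the naive ramp reconstructs a disk 2.3 % low; the
kernel is exact to 0.02 %).  Apodisation windows: none (Ram-Lak),
sinc (Shepp-Logan, default), Hann.  Output scaling
`π/(2 n_angles) / pixel_size` makes a sinogram of line integrals in
[q·m] reconstruct q itself.  Pixels outside the inscribed circle are
zeroed (`circle=False` disables this).

## Pipeline

The YAML parameter file lists stages in execution order; parsing rejects
unknown stages/keys and order violations, then expands defaults.  The
expanded spec and a structured report (per-stage parameters, timings,
warnings including low-confidence axis estimates and dynamic-flat
fallbacks, slice statistics) are written next to the output slices, so
every run is replayable from its own output directory.  Batch mode
applies one protocol per dataset independently; one failure marks that
dataset in the summary and the rest proceed.  Identical spec + dataset
give bit-identical slices (no stage is stochastic).

## Benchmark problem sizes

The benchmark scenarios run at desk scale, chosen so discretisation
effects settle while the whole suite stays in the seconds-to-minutes
range on one CPU: Radon oracle at 512², FBP inversion at 256²/360
angles, phase retrieval at 256 px, flat fielding at 60 projections / 32
flats, stitching at 128-px detectors, SIRT at 128²/60 angles/200
iterations, and the protocol comparison on a 400-angle half-acquisition
scan.  Every random element (noise, stripe positions, drift phases)
derives from a single seed.

## Known limitations

* The projected-CTF response and the "modified" Raven parameterisation
  are documented surrogates for unpublished beamline implementations.
* TIE-Hom accuracy is only tested for homogeneous phantoms; multi-material
  samples violate its core assumption by design.
* The stitcher assumes the second half-turn angles are exactly
  θ + 180°; rotation-stage drift within a scan is not corrected.
* Whole-frame dynamic-flat fitting is biased when the object fills the
  field of view and little air is visible; the automatic air mask then
  falls back to the whole frame and the conventional method may be
  preferable.
* The simulator's monochromatic, fully coherent, PSF-free detector model
  flatters phase retrieval relative to real beamlines.
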