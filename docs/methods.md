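# Methods

This note documents the models, estimators, and numerical choices behind
`optospread`, and what the synthetic benchmarks do and do not demonstrate.

## Light-profile recovery from photobleaching

**Model.** Under constant illumination, photobleaching is first-order in the
local light intensity: a nucleus's fluorescence decays as
F → F₀·exp(−k·I(r)·T), i.e. ΔF/F₀ = f(r) = −1 + exp(−k·I(r)·T), where I(r)
is relative intensity, T the illumination time (dose = intensity × time,
mW·min) and k a fluorophore constant fitted from center-region ΔF/F₀ at
several doses (`fit_bleach_constant`, least squares on f = −1 + e^(−k·dose),
separate fits per fluorophore/wavelength). Inversion gives
I(r) ∝ −ln(f(r) + 1); the unknown global constant is absorbed by
max-normalizing the gridded field.

**Baseline F₀** is the mean fluorescence of ROIs more than 700 µm from the
laser center — Euclidean 3-D distance for blue light, lateral distance only
for orange light, whose central bleaching is near-complete through the full
cortical depth. If no ROI is that far out, the caller must supply F₀
explicitly. ROIs with f ≤ −0.99 (near-complete bleach, the log diverges)
are excluded from inversion and counted in the field metadata.

**Gridding.** Per-ROI intensities are averaged into 25 µm voxels; empty
voxels are filled by inverse-distance interpolation from up to 6 nearest
filled voxels; negative values (f > 0, pure noise) are clipped at zero.

**Half-max summaries.** The estimators assume only that attenuation is
monotone in depth and in lateral distance, plus local shape information:

* The on-axis axial profile averages voxel columns within a radius of
  ~1.6× the beam's lateral σ. For a separable field the lateral factor
  cancels in depth ratios, and this radius approximately maximizes the
  signal-to-noise of the ratio estimate; it mirrors the practice of using
  wider central-averaging regions for wider beams.
* Profiles are regularized by antitonic (monotone-decreasing) regression
  before the crossing search. Without it, "first bin below half" is biased
  early by bin noise; with it, crossings inside the flat pools the fit
  produces are interpolated at pool centers, not pool edges.
* The surface (z = 0) reference is extrapolated by a log-linear fit of the
  profile's shoulder (planes between 35% and 95% of the maximum): the top
  grid plane is the one most distorted by binning/interpolation edge
  effects, so it is not read directly. The range self-scales with the
  decay length.
* The half-level crossing is located by a local fit over the contiguous run
  of planes within ±50% of the half level: ln(I) linear in z for the axial
  profile (exact for exponential attenuation) and ln(I) linear in r² for
  the lateral profile (exact for a Gaussian beam). With fewer than four
  usable planes this falls back to plain linear interpolation. On
  noiseless grids all of this reduces to the plain crossing (e.g.
  I(z) = e^(−z/433 µm) yields 300.1 µm = 433·ln 2).
* The lateral profile at the 200 µm reference depth pools planes within
  ±50 µm (profile shape is depth-invariant for a separable field) and
  anchors the on-axis value at its innermost radial bin.

These choices were validated by parameter recovery on synthetic volumes
(20,000 nuclei, ~95% center bleaching, 10% multiplicative ROI noise) across
many seeds: blue (433 µm axial, 114.7 µm lateral σ) recovers 305 ± 11 µm
half-max depth and 138 ± 4 µm lateral half-width; orange (1221 µm, 400 µm,
in 2.5 mm volumes) recovers 818 ± 19 µm against an 846 µm target — the
small deficit traces to residual bleaching of the "far" baseline ROIs,
which the real assay shares.

## Spike-waveform classification

Width = trough-to-peak interval of the mean waveform (largest-amplitude
channel for multi-site probes; optional 10× cubic-spline upsampling for
sub-sample timing). Labels: FS below 0.35 ms, pyramidal above 0.45 ms, the
closed band [0.35, 0.45] ms excluded — both thresholds strict. Waveforms
whose maximum precedes their minimum, or with no recovery peak, are
rejected as non-spike-like.

## Inactivation metrics

* **Relative spike rate.** Unit form: stimulus-window rate / baseline rate
  (500 ms before onset); units with zero baseline are excluded from
  unit-level ratios but retained in population sums. Population form: mean
  stimulus rate / mean baseline rate — algebraically the baseline-weighted
  mean of unit ratios, reporting the fraction of total spiking output. The
  stimulus window excludes the terminal intensity ramp by default.
* **PSTH.** Per-unit trial-pooled bin rates (1 ms default), then mean over
  units.
* **Spatial profile / half-max radius.** Units binned by lateral distance
  (0.25 mm bins from zero); per-bin population relative rate with bootstrap
  s.e.m. over that bin's units; empty bins kept as NaN. The half-max radius
  is the smallest r at which the reduction d(r) = 1 − R(r) falls to half
  its value at the innermost populated bin, by linear interpolation between
  bin centers; its CI resamples neurons with replacement (2000 times, 90%
  central percentile interval), recomputing the binned profile and crossing
  per resample. Bin-center interpolation slightly coarsens the estimate
  (e.g. the σ = 0.68 mm, 90%-reduction benchmark: continuum truth 0.80 mm,
  binned estimate ~0.83 mm).
* **Onset latency.** Reference = baseline − 0.9 × (baseline − mean
  stimulus-window rate); onset = first post-onset time the population PSTH
  falls to the reference (linear interpolation in the crossing bin).
  Optional denoising for finite-trial PSTHs: Gaussian pre-smoothing
  (σ ≈ 2 ms), monotone regularization of the early stimulus epoch, or
  `method="expfit"`, which locates the same reference crossing on an
  exponential decay fitted to the first 120 ms. The exponential variant has
  ~2× smaller sampling error (±0.8 ms vs ±1.5 ms at 100 units × 100
  trials) and is what the studies use; it assumes a single-exponential
  onset, exact for the generator and a good description of ChR-assisted
  suppression. For an 8 ms decay toward 10% of baseline over a 1.3 s
  stimulus the rule's noiseless value is τ·ln 10 ≈ 18.4 ms.
* **Earliest change.** First 10 ms bin (1 ms for FS excitation) whose
  across-unit rates differ from per-unit baselines by paired two-tailed
  t-test at α = 0.05; no multiple-testing correction (matching field
  practice for this readout), so the per-bin false-positive rate is ≈ α.
* **Rebound index.** (rate in the 500 ms after offset − baseline) /
  baseline, averaged over units with nonzero baseline; negative values mean
  persistent suppression.
* **Intensity conversion.** intensity = power/(2π r²) with r = 1 mm for
  the 2 mm (4σ) beam, exactly as conventionally reported; a `convention="pi"`
  flag gives the geometric disc-area alternative (2× larger) for
  sensitivity checks. The 2π convention is implemented as printed rather
  than second-guessed.
* **Paradoxical scan.** Conditions ordered by intensity; per level the
  FS and pyramidal population relative rates; the paradoxical regime is the
  maximal initial range over which FS is non-increasing while pyramidal
  decreases, and the FS-minimum intensity is reported. Levels missing a
  class are dropped.

## Inhibition-stabilized network

τ_E dr_E/dt = −r_E + [w_EE r_E − w_EI r_I + h_E + s_E]₊ and symmetrically
for I, with unit-gain rectified-linear transfer — the simplest model
exhibiting ISN behavior. Opsin drive s = gain × light enters the target
population; a 40 Hz option multiplies the drive by a unit-mean sinusoid.
Fixed points are found by damped iteration (relaxation 0.1, tolerance
1e−10, error after 10⁵ iterations), with stability from the Jacobian of the
active linear branch. In the fully active branch
∂r_I/∂h_I = (1 − w_EE)/det with det = (1 − w_EE)(1 + w_II) + w_EI·w_IE:
negative exactly when w_EE > 1. Dynamics integrate by explicit Euler with
dt = τ_min/20 (dt ≤ τ_min/10 enforced). The spatial mode places an E and I
population per node of a 1-D lateral grid with Gaussian coupling kernels
row-normalized so row sums equal the scalar weights; zero-width kernels
reduce exactly to independent per-node circuits. Default parameters
(w_EE = 2, w_EI = 2.5, w_IE = 3, w_II = 2, h = (1, 0)) give the hand-solved
fixed point r_E = r_I = 2/3 and the paradoxical response r_I → 0.5667 under
+0.45 drive to I. The model is not fitted to recordings and the I
population is not committed to a specific interneuron subtype.

## Synthetic-data generators

The generators produce data with the statistical structure the estimators
assume, at the study's stated conditions; their defaults are the
benchmark conditions, not tuning knobs.

* **Nuclei volumes:** uniform positions; lognormal baseline fluorescence
  with CV 0.2 (a modest nucleus-to-nucleus expression variability; real
  variability is unreported). Bleaching applies the exponential dose model
  exactly, then unit-mean lognormal multiplicative noise (CV 0.10 in the
  benchmarks).
* **Spiking:** pyramidal rates relax exponentially (τ = 8 ms default)
  toward baseline × (1 − c·exp(−r²/2σ²)) with c = 0.9, σ = 0.68 mm;
  post-offset rates are baseline × (1 + rebound·e^(−t/τ_reb)); FS units
  mirror the profile multiplicatively with gain 2. Baselines are 8 Hz
  (pyramidal) and 15 Hz (FS), gamma-distributed across units with CV 0.5
  by convention (per-cell-type rate distributions are not otherwise
  constrained); the recovery studies use fixed baselines as their stated
  condition. Spikes are inhomogeneous Poisson by thinning against the
  trajectory maximum, with a 1 ms absolute refractory period imposed by
  deletion (truncates rates ~1% at 10 Hz). The reported power is treated
  as time-averaged; the 40 Hz sinusoid is resolved only by the ISN-driven
  backend, which replaces the parametric trajectories with simulated
  network rates.
* **Not emulated:** raw voltage traces and spike-sorting errors, cortical
  layer structure, correlated (non-Poisson) spiking, opsin photocurrent
  kinetics, heat, hemodynamics, and the long low-intensity tail of light
  that photobleaching itself cannot measure. Passing benchmarks therefore
  demonstrates estimator correctness and calibration under the assumed
  forward models, not robustness to these real-data features.

## Problem sizes and determinism

The benchmark studies use 20,000 nuclei per volume; 100 units × 100 trials
for onset; 26 distances × 20 units × 50 trials for the spatial spread;
2000 bootstrap resamples for CIs and 1000 for per-bin s.e.m. — sizes chosen
to match the studies they emulate while keeping any run in seconds. All
randomness flows from a single seed through `numpy` `SeedSequence` spawning;
identical seeds give byte-identical datasets and results.
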