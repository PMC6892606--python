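"""End-to-end parameter-recovery studies.

Each function simulates one of the package's benchmark experiments through
the full noisy forward model and measures the headline quantity with the
same estimators a real dataset would go through.  The analysis drivers in
``analysis/`` and the acceptance script are thin wrappers around these.

Study conditions (defaults):

* light profile, blue  — 20,000 nuclei in 1.2 x 1.2 x 1.0 mm, axial
  e-folding 433 µm, lateral sigma 114.7 µm, ~95% center-surface bleaching,
  10% multiplicative ROI noise.
* light profile, orange — 20,000 nuclei in 2.5 x 2.5 x 2.5 mm, axial
  e-folding 1221 µm, lateral sigma 400 µm; far-field baseline by lateral
  distance (central bleaching is near-complete over the full depth).
* onset — 100 pyramidal units, 8 Hz baseline, rate decaying with an 8 ms
  time constant toward 10% of baseline during a 1.3 s stimulus, 100 trials.
* spatial spread — units every 0.1 mm out to 2.5 mm, 20 per distance,
  50 trials, 90% center reduction with lateral sigma 0.68 mm.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import inactmetrics, isnmodel, lightmap, synthgen, unitclass
from .core import PhotostimProtocol

__all__ = [
    "light_profile_study", "onset_latency_study", "spatial_spread_study",
    "paradoxical_study",
]

#: dose (mW·min) giving ~95% bleaching at the surface center
CENTER_BLEACH_FRACTION = 0.95
REFERENCE_DOSE_MW_MIN = 200.0


def light_profile_study(
    *,
    axial_um: float = 433.0,
    lateral_sigma_um: float = 114.7,
    volume_dims: tuple[float, float, float] = (1200.0, 1200.0, 1000.0),
    n_nuclei: int = 20000,
    noise_cv: float = 0.10,
    distance_mode: str = "3d",
    seed: int = 1,
    voxel_um: float = 25.0,
    axis_radius_um: Optional[float] = None,
    return_field: bool = False,
) -> dict:
    """Simulate a photobleaching volume and recover its light profile.

    Nuclei are placed uniformly, bleached by F -> F * exp(-k I T) under the
    separable field exp(-z/axial) * Gaussian(lateral_sigma), with k*T set for
    ~95% bleaching at the surface center, then pushed through the full
    ΔF/F0 -> inversion -> half-max summary chain.  The on-axis averaging
    radius defaults to 1.6x the lateral sigma (the ratio-cancelling optimum
    for a separable field; the analysis radius scales with the beam, as the
    per-fluorophore central radii do in practice).
    """
    k_total = -np.log(1.0 - CENTER_BLEACH_FRACTION)
    k_dose = k_total / REFERENCE_DOSE_MW_MIN
    vol = synthgen.make_nuclei_volume(n_nuclei, volume_dims, seed=seed)
    field = lightmap.separable_light_field(axial_um, lateral_sigma_um)
    rois = synthgen.bleach_forward(vol, field, k_dose, REFERENCE_DOSE_MW_MIN,
                                   noise_cv=noise_cv, seed=seed + 10_000)
    dff = lightmap.compute_dff(rois, 700.0, distance_mode=distance_mode)
    recovered = lightmap.invert_intensity(dff, voxel_um=voxel_um)
    if axis_radius_um is None:
        axis_radius_um = 1.6 * lateral_sigma_um
    summary = lightmap.profile_summary(recovered, axis_radius_um=axis_radius_um)
    out = {
        "half_max_depth_um": summary["half_max_depth_um"],
        "lateral_half_width_um": summary["lateral_half_width_um"],
        "n_rois": len(dff),
        "f0": dff.f0,
    }
    if return_field:
        out["field"] = recovered
        out["dff"] = dff
    return out


def onset_latency_study(
    *,
    seed: int = 3,
    n_units: int = 100,
    n_trials: int = 100,
    baseline_rate_hz: float = 8.0,
    onset_tau_ms: float = 8.0,
    center_reduction: float = 0.9,
    stim_duration_s: float = 1.3,
    bin_ms: float = 1.0,
    smooth_sigma_ms: float = 2.0,
    method: str = "expfit",
) -> dict:
    """Onset latency of simulated photoinhibition by the 90%-of-average-
    reduction rule on the population PSTH.

    For a rate decaying exponentially toward (1 - reduction) x baseline with
    the average taken over the whole stimulus, the rule's noiseless crossing
    is near tau * ln 10 (~18.4 ms for tau = 8 ms).
    """
    cfg = synthgen.SuppressionConfig(
        baseline_rate_hz=baseline_rate_hz, center_reduction=center_reduction,
        onset_tau_ms=onset_tau_ms, n_units_per_distance=n_units,
        n_fs_per_distance=0, distances_mm=(0.0,), n_trials=n_trials,
        stim_duration_s=stim_duration_s, baseline_cv=0.0, seed=seed)
    proto = PhotostimProtocol(duration_s=stim_duration_s, ramp_ms=0.0)
    ds = synthgen.simulate_suppression_dataset(cfg, proto)
    psth = inactmetrics.compute_psth(
        ds, bin_ms=bin_ms, window_ms=(-200.0, stim_duration_s * 1000.0 + 100.0))
    onset = inactmetrics.onset_latency(
        psth, stim_window_ms=(0.0, stim_duration_s * 1000.0),
        smooth_sigma_ms=smooth_sigma_ms, method=method)
    return {"onset_latency_ms": onset, "n_units": ds.n_units,
            "n_trials": cfg.n_trials, "psth": psth}


def spatial_spread_study(
    *,
    seed: int = 4,
    center_reduction: float = 0.9,
    lateral_sigma_mm: float = 0.68,
    max_distance_mm: float = 2.5,
    distance_step_mm: float = 0.1,
    n_units_per_distance: int = 20,
    n_trials: int = 50,
    baseline_rate_hz: float = 8.0,
    stim_duration_s: float = 1.3,
    bin_width_mm: float = 0.25,
    n_boot: int = 2000,
    classify: bool = True,
) -> dict:
    """Half-max radius of simulated photoinhibition from the full spatial
    pipeline (Poisson spikes -> classification -> binned population profile
    -> interpolated crossing with unit bootstrap)."""
    distances = tuple(np.round(
        np.arange(0.0, max_distance_mm + distance_step_mm / 2, distance_step_mm), 4))
    cfg = synthgen.SuppressionConfig(
        baseline_rate_hz=baseline_rate_hz, center_reduction=center_reduction,
        lateral_sigma_mm=lateral_sigma_mm,
        n_units_per_distance=n_units_per_distance, n_fs_per_distance=0,
        distances_mm=distances, n_trials=n_trials,
        stim_duration_s=stim_duration_s, baseline_cv=0.0, seed=seed)
    proto = PhotostimProtocol(duration_s=stim_duration_s, ramp_ms=0.0)
    ds = synthgen.simulate_suppression_dataset(cfg, proto)
    if classify:
        unitclass.classify_dataset(ds)
        label = "PYR"
    else:
        label = None
    profile = inactmetrics.spatial_profile(
        ds, label=label if classify else None, bin_width_mm=bin_width_mm,
        seed=seed + 1)
    radius, boot = inactmetrics.half_max_radius(
        profile, n_resamples=n_boot, seed=seed + 2)
    return {"half_max_radius_mm": radius, "bootstrap": boot,
            "profile": profile, "dataset": ds}


def paradoxical_study(
    *,
    seed: int = 7,
    intensities_mw_mm2=None,
    isn_params: Optional[isnmodel.ISNParams] = None,
    n_trials: int = 30,
) -> dict:
    """Intensity sweep through an inhibition-stabilized network.

    Steady-state E/I rates of the ISN drive Poisson spiking per intensity
    level; the scan should locate the FS-rate minimum at the intensity where
    pyramidal activity is (nearly) silenced.
    """
    if intensities_mw_mm2 is None:
        intensities_mw_mm2 = list(np.linspace(0.1, 1.6, 8))
    if isn_params is None:
        isn_params = isnmodel.ISNParams()
    cfg = synthgen.SuppressionConfig(n_trials=n_trials, seed=seed,
                                     stim_duration_s=1.0)
    ds = synthgen.simulate_intensity_sweep_dataset(
        intensities_mw_mm2, isn_params, cfg)
    unitclass.classify_dataset(ds)
    scan = inactmetrics.paradoxical_scan(ds)
    scan["dataset"] = ds
    return scan
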