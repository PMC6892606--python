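"""Synthetic inputs with the statistical structure the analysis assumes.

Two families of generators:

* imaging — nuclei scattered uniformly in a tissue volume, bleached through
  the exponential dose model F -> F * exp(-k * I(r) * T) under a known light
  field, with multiplicative measurement noise; feeds the light-profile
  inversion chain.

* electrophysiology — spiking units whose rate trajectories follow
  distance-, time- and power-dependent suppression with exponential onset
  kinetics, post-offset rebound, and mirrored fast-spiking (FS) activation;
  spikes are drawn as inhomogeneous Poisson processes by thinning, with a
  1 ms absolute refractory period imposed by deletion.  Waveforms are
  synthesized so FS widths fall below 0.35 ms and pyramidal widths above
  0.45 ms.

Coordinate convention for volumes: x, y centered on the laser axis
(x, y in [-Lx/2, Lx/2] etc.), z from 0 at the surface, positive downward, µm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import PhotostimProtocol, SpikeDataset
from .lightmap import LightField, ROITable, evaluate_field

__all__ = [
    "NucleiVolume", "SuppressionConfig", "make_nuclei_volume", "bleach_forward",
    "sample_inhomogeneous_poisson", "simulate_suppression_dataset",
    "simulate_intensity_sweep_dataset", "make_waveform",
]

WAVEFORM_FS_HZ = 19531.25  # silicon-probe sampling rate


# ---------------------------------------------------------------------------
# Imaging side
# ---------------------------------------------------------------------------

@dataclass
class NucleiVolume:
    """Nuclei positions (µm) and positive baseline fluorescence (a.u.)."""

    positions: np.ndarray            # (n, 3): x, y, z
    baseline_fluorescence: np.ndarray
    volume_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        lx, ly, lz = self.volume_dims
        if len(p):
            if (np.abs(p[:, 0]) > lx / 2 + 1e-9).any() or \
               (np.abs(p[:, 1]) > ly / 2 + 1e-9).any() or \
               (p[:, 2] < -1e-9).any() or (p[:, 2] > lz + 1e-9).any():
                raise ValueError("nuclei positions outside the volume bounds")
            if (np.asarray(self.baseline_fluorescence) <= 0).any():
                raise ValueError("baseline fluorescence must be > 0")

    def __len__(self) -> int:
        return len(self.positions)


def make_nuclei_volume(
    n: int,
    volume_dims: tuple[float, float, float],
    seed: int,
    *,
    mean_fluorescence: float = 1000.0,
    fluorescence_cv: float = 0.2,
) -> NucleiVolume:
    """Uniformly random nuclei with lognormal baseline fluorescence.

    Baseline intensities are lognormal with the requested mean and
    coefficient of variation (default CV 0.2, a modest nucleus-to-nucleus
    expression variability).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lx, ly, lz = volume_dims
    if min(lx, ly, lz) <= 0:
        raise ValueError("volume dimensions must be > 0")
    rng = np.random.default_rng(seed)
    pos = np.column_stack([
        rng.uniform(-lx / 2, lx / 2, size=n),
        rng.uniform(-ly / 2, ly / 2, size=n),
        rng.uniform(0.0, lz, size=n),
    ])
    sigma2 = np.log1p(fluorescence_cv ** 2)
    mu = np.log(mean_fluorescence) - sigma2 / 2
    fluor = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    return NucleiVolume(pos, fluor, tuple(float(v) for v in volume_dims))


def bleach_forward(
    volume: NucleiVolume,
    light_field: Union[LightField, Callable[[np.ndarray], np.ndarray]],
    k_dose: float,
    dose_mw_min: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    wavelength_nm: float = 473.0,
) -> ROITable:
    """Bleach each nucleus by exp(-k * I * T) and add multiplicative noise.

    ``light_field`` maps positions to relative intensity in [0, 1] (gridded
    field or callable).  Noise is lognormal with unit mean and the requested
    coefficient of variation, applied after bleaching.
    """
    if k_dose <= 0:
        raise ValueError("k_dose must be > 0")
    if dose_mw_min < 0:
        raise ValueError("dose must be >= 0")
    rng = np.random.default_rng(seed)
    intensity = evaluate_field(light_field, volume.positions) if len(volume) else \
        np.zeros(0)
    if len(volume) and (intensity.min() < -1e-9 or intensity.max() > 1 + 1e-9):
        raise ValueError("light-field values must lie in [0, 1]")
    bleached = volume.baseline_fluorescence * np.exp(-k_dose * intensity * dose_mw_min)
    if noise_cv > 0 and len(volume):
        s2 = np.log1p(noise_cv ** 2)
        bleached = bleached * rng.lognormal(-s2 / 2, np.sqrt(s2), size=len(volume))
    df = pd.DataFrame({
        "x_um": volume.positions[:, 0],
        "y_um": volume.positions[:, 1],
        "z_um": volume.positions[:, 2],
        "F": bleached,
    })
    return ROITable(df, dose_mw_min=dose_mw_min, wavelength_nm=wavelength_nm)


# ---------------------------------------------------------------------------
# Spiking side
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuppressionConfig:
    """Parametric suppression model for synthetic spike datasets.

    Pyramidal rate at lateral distance r (mm): baseline before the stimulus;
    during the stimulus it relaxes with time constant ``onset_tau_ms`` toward
    baseline * (1 - center_reduction * exp(-r^2 / (2 lateral_sigma^2)));
    after offset it is baseline * (1 + rebound_amplitude * exp(-t/rebound_tau)).
    FS units get a mirrored activation profile scaled by
    ``fs_activation_gain``.  Per-unit baselines are gamma-distributed around
    the class mean with coefficient of variation ``baseline_cv``.
    """

    baseline_rate_hz: float = 8.0
    fs_baseline_rate_hz: float = 15.0
    center_reduction: float = 0.9
    lateral_sigma_mm: float = 0.68
    onset_tau_ms: float = 8.0
    rebound_amplitude: float = 0.3
    rebound_tau_ms: float = 200.0
    fs_activation_gain: float = 2.0
    n_units_per_distance: int = 20
    n_fs_per_distance: int = 3
    distances_mm: Sequence[float] = tuple(np.round(np.arange(0.0, 2.51, 0.25), 3))
    n_trials: int = 50
    stim_duration_s: float = 1.3
    baseline_cv: float = 0.5
    pre_window_s: float = 0.5
    post_window_s: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.center_reduction <= 1.0):
            raise ValueError("center_reduction must lie in [0, 1]")
        if self.baseline_rate_hz < 0 or self.fs_baseline_rate_hz < 0:
            raise ValueError("rates must be >= 0")
        for name in ("onset_tau_ms", "rebound_tau_ms", "lateral_sigma_mm",
                     "stim_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def sample_inhomogeneous_poisson(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    duration_s: float,
    n_trials: int,
    seed: int,
    *,
    t_start_s: float = 0.0,
    refractory_s: float = 0.001,
    rate_bound_hz: Optional[float] = None,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains by thinning.

    ``rate_fn`` maps an array of times (s) to rates (Hz); it must be
    nonnegative and bounded.  The thinning bound defaults to the maximum of
    the rate on a 1 ms grid.  An absolute refractory period is imposed by
    deleting spikes closer than ``refractory_s`` to their predecessor.
    Returns one sorted spike-time array per trial.
    """
    t_end = t_start_s + duration_s
    grid = np.linspace(t_start_s, t_end, max(2, int(duration_s * 1000) + 1))
    rates = np.asarray(rate_fn(grid), dtype=float)
    if (rates < 0).any():
        raise ValueError("negative rate encountered")
    bound = rate_bound_hz if rate_bound_hz is not None else float(rates.max()) * 1.001
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_trials):
        if bound <= 0:
            trains.append(np.empty(0))
            continue
        n = rng.poisson(bound * duration_s)
        t = np.sort(rng.uniform(t_start_s, t_end, size=n))
        r = np.asarray(rate_fn(t), dtype=float)
        if (r < 0).any():
            raise ValueError("negative rate encountered")
        keep = rng.uniform(0, bound, size=n) < r
        t = t[keep]
        if refractory_s > 0 and len(t) > 1:
            out = [t[0]]
            for ti in t[1:]:
                if ti - out[-1] >= refractory_s:
                    out.append(ti)
            t = np.asarray(out)
        trains.append(t)
    return trains


def pyramidal_rate_fn(base_hz: float, distance_mm: float,
                      config: SuppressionConfig) -> Callable:
    """Vectorized pyramidal rate trajectory (time in s, stimulus onset at 0)."""
    target = base_hz * (1.0 - config.center_reduction *
                        np.exp(-distance_mm ** 2 / (2 * config.lateral_sigma_mm ** 2)))
    tau = config.onset_tau_ms / 1000.0
    dur = config.stim_duration_s
    reb_tau = config.rebound_tau_ms / 1000.0

    def fn(t):
        t = np.asarray(t, dtype=float)
        r = np.full_like(t, base_hz)
        stim = (t >= 0) & (t < dur)
        r[stim] = target + (base_hz - target) * np.exp(-t[stim] / tau)
        post = t >= dur
        r[post] = base_hz * (1.0 + config.rebound_amplitude *
                             np.exp(-(t[post] - dur) / reb_tau))
        return r

    return fn


def fs_rate_fn(base_hz: float, distance_mm: float,
               config: SuppressionConfig) -> Callable:
    """FS activation: mirrored lateral profile, multiplicative gain on baseline."""
    target = base_hz * (1.0 + config.fs_activation_gain *
                        np.exp(-distance_mm ** 2 / (2 * config.lateral_sigma_mm ** 2)))
    tau = config.onset_tau_ms / 1000.0
    dur = config.stim_duration_s

    def fn(t):
        t = np.asarray(t, dtype=float)
        r = np.full_like(t, base_hz)
        stim = (t >= 0) & (t < dur)
        r[stim] = target + (base_hz - target) * np.exp(-t[stim] / tau)
        return r

    return fn


def make_waveform(width_ms: float, fs_hz: float = WAVEFORM_FS_HZ,
                  n_samples: int = 64) -> tuple[np.ndarray, float]:
    """Biphasic spike waveform with an exact integer-sample trough-to-peak.

    The requested width is snapped to the sampling grid; returns (waveform,
    realized width in ms).
    """
    dt_ms = 1000.0 / fs_hz
    k = max(2, int(round(width_ms / dt_ms)))
    width = k * dt_ms
    t = np.arange(n_samples, dtype=float)
    i_trough = n_samples // 3
    i_peak = i_trough + k
    if i_peak >= n_samples - 2:
        raise ValueError("waveform window too short for requested width")
    w = (-np.exp(-0.5 * ((t - i_trough) / 1.2) ** 2)
         + 0.45 * np.exp(-0.5 * ((t - i_peak) / (1.0 + 0.8 * k)) ** 2))
    return w, width


def _draw_width_ms(rng: np.random.Generator, label: str) -> float:
    """Class-conditional spike widths, clear of the 0.35–0.45 ms exclusion band."""
    dt_ms = 1000.0 / WAVEFORM_FS_HZ
    if label == "FS":
        k = rng.integers(4, 7)       # 0.205–0.307 ms
    else:
        k = rng.integers(10, 14)     # 0.512–0.666 ms
    return float(k * dt_ms)


def simulate_suppression_dataset(
    config: SuppressionConfig,
    protocol: Optional[PhotostimProtocol] = None,
    *,
    isn_params=None,
) -> SpikeDataset:
    """Generate a suppression-structured spike dataset.

    Parametric backend (default): rate trajectories from
    :func:`pyramidal_rate_fn` / :func:`fs_rate_fn`, treating the reported
    power as time-averaged (the 40 Hz sinusoidal stimulus is not resolved).
    With ``isn_params`` the per-distance modulation is driven by a spatial
    E–I rate-network simulation instead (opsin drive following the beam's
    lateral profile), for emergent-dynamics tests.
    """
    if protocol is None:
        protocol = PhotostimProtocol(duration_s=config.stim_duration_s)
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    modulations = None
    if isn_params is not None:
        modulations = _isn_modulations(config, protocol, isn_params)

    units, waveforms = [], {}
    unit_rate_fns = {}
    uid = 0
    for d in config.distances_mm:
        for j in range(config.n_units_per_distance + config.n_fs_per_distance):
            label = "PYR" if j < config.n_units_per_distance else "FS"
            mean = (config.baseline_rate_hz if label == "PYR"
                    else config.fs_baseline_rate_hz)
            if config.baseline_cv > 0:
                shape = 1.0 / config.baseline_cv ** 2
                base = rng.gamma(shape, mean / shape)
            else:
                base = mean
            width = _draw_width_ms(rng, label)
            wf, width = make_waveform(width)
            unit_id = f"u{uid:04d}"
            units.append({"unit_id": unit_id, "lateral_distance_um": d * 1000.0,
                          "depth_um": float(rng.uniform(100, 900)),
                          "true_label": label, "baseline_rate_hz": base})
            waveforms[unit_id] = wf
            if modulations is not None:
                mod_t, mod = modulations[label][d]
                unit_rate_fns[unit_id] = _modulated_rate_fn(base, mod_t, mod, config)
            elif label == "PYR":
                unit_rate_fns[unit_id] = pyramidal_rate_fn(base, d, config)
            else:
                unit_rate_fns[unit_id] = fs_rate_fn(base, d, config)
            uid += 1

    units_df = pd.DataFrame(units)
    trials_df = pd.DataFrame({
        "trial_id": [f"t{i:04d}" for i in range(config.n_trials)],
        "condition_id": "stim",
    })
    window = (-config.pre_window_s, config.stim_duration_s + config.post_window_s)
    uid_col, tid_col, time_col = [], [], []
    child_seeds = ss.spawn(len(units_df))
    trial_ids = trials_df["trial_id"].to_numpy()
    for (unit_id, fn), child in zip(unit_rate_fns.items(), child_seeds):
        trains = sample_inhomogeneous_poisson(
            fn, window[1] - window[0], config.n_trials,
            seed=child, t_start_s=window[0])
        counts = [len(tr) for tr in trains]
        total = int(np.sum(counts))
        if total:
            uid_col.append(np.full(total, unit_id, dtype=object))
            tid_col.append(np.repeat(trial_ids, counts))
            time_col.append(np.concatenate(trains))
    spikes_df = pd.DataFrame({
        "unit_id": np.concatenate(uid_col) if uid_col else np.empty(0, dtype=object),
        "trial_id": np.concatenate(tid_col) if tid_col else np.empty(0, dtype=object),
        "spike_time_s": np.concatenate(time_col) if time_col else np.empty(0),
    })
    ds = SpikeDataset(units_df, spikes_df, trials_df, {"stim": protocol},
                      waveforms=waveforms, waveform_fs_hz=WAVEFORM_FS_HZ,
                      trial_window_s=window,
                      metadata={"generator": "suppression", "seed": config.seed,
                                "backend": "isn" if isn_params else "parametric"})
    ds.validate()
    return ds


def _modulated_rate_fn(base_hz: float, mod_t: np.ndarray, mod: np.ndarray,
                       config: SuppressionConfig) -> Callable:
    """Rate = baseline x interpolated ISN modulation during the trial window."""
    def fn(t):
        t = np.asarray(t, dtype=float)
        return base_hz * np.interp(t, mod_t, mod, left=1.0, right=mod[-1])
    return fn


def _isn_modulations(config: SuppressionConfig, protocol: PhotostimProtocol,
                     isn_params) -> dict:
    """Per-distance E/I rate modulations from a spatial ISN simulation."""
    from . import isnmodel

    if isn_params.spatial is None:
        raise ValueError("isn backend requires spatial ISN parameters")
    pos_mm = isn_params.spatial.positions_um / 1000.0
    beam_sigma_mm = protocol.beam_diameter_4sigma_um / 4.0 / 1000.0
    light = np.exp(-pos_mm ** 2 / (2 * beam_sigma_mm ** 2))
    base = isnmodel.steady_state(isn_params, 0.0)
    traj = isnmodel.simulate_dynamics(
        isn_params, light, duration_s=config.stim_duration_s)
    t_s = traj.time_ms / 1000.0
    out = {"PYR": {}, "FS": {}}
    for d in config.distances_mm:
        node = int(np.argmin(np.abs(np.abs(pos_mm) - d)))
        be = max(np.atleast_1d(base["r_e"])[node], 1e-9)
        bi = max(np.atleast_1d(base["r_i"])[node], 1e-9)
        out["PYR"][d] = (t_s, traj.r_e[:, node] / be)
        out["FS"][d] = (t_s, traj.r_i[:, node] / bi)
    return out


def simulate_intensity_sweep_dataset(
    intensities_mw_mm2: Sequence[float],
    isn_params,
    config: SuppressionConfig,
    *,
    n_pyr: int = 40,
    n_fs: int = 10,
) -> SpikeDataset:
    """Dataset for paradoxical-effect scans: one condition per light intensity.

    Units sit near the laser center; each intensity level multiplies every
    unit's baseline by the ISN steady-state rate ratio r(I)/r(0) of its
    population, and spikes are drawn as homogeneous Poisson within each
    window (onset kinetics are not the object of this scan).
    """
    from . import isnmodel

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    base = isnmodel.steady_state(isn_params, 0.0)
    ratios = []
    for inten in intensities_mw_mm2:
        st = isnmodel.steady_state(isn_params, inten)
        ratios.append((st["r_e"] / max(base["r_e"], 1e-9),
                       st["r_i"] / max(base["r_i"], 1e-9)))

    units, waveforms = [], {}
    bases = {}
    for i in range(n_pyr + n_fs):
        label = "PYR" if i < n_pyr else "FS"
        mean = config.baseline_rate_hz if label == "PYR" else config.fs_baseline_rate_hz
        shape = 1.0 / max(config.baseline_cv, 1e-6) ** 2
        b = rng.gamma(shape, mean / shape) if config.baseline_cv > 0 else mean
        wf, width = make_waveform(_draw_width_ms(rng, label))
        unit_id = f"u{i:04d}"
        units.append({"unit_id": unit_id, "lateral_distance_um": float(rng.uniform(0, 300)),
                      "depth_um": float(rng.uniform(100, 900)),
                      "true_label": label, "baseline_rate_hz": b})
        waveforms[unit_id] = wf
        bases[unit_id] = (label, b)

    trial_rows, spike_rows, conditions = [], [], {}
    window = (-config.pre_window_s, config.stim_duration_s + config.post_window_s)
    trial_counter = 0
    child = iter(ss.spawn(len(intensities_mw_mm2) * len(units)))
    for level, (inten, (re_ratio, ri_ratio)) in enumerate(
            zip(intensities_mw_mm2, ratios)):
        cid = f"I{level:02d}"
        conditions[cid] = PhotostimProtocol(
            wavelength_nm=594.0, avg_power_mw=float(inten * 2 * np.pi),
            beam_diameter_4sigma_um=2000.0, duration_s=config.stim_duration_s)
        trial_ids = [f"t{trial_counter + k:05d}" for k in range(config.n_trials)]
        trial_counter += config.n_trials
        trial_rows += [(tid, cid) for tid in trial_ids]
        for unit_id, (label, b) in bases.items():
            ratio = re_ratio if label == "PYR" else ri_ratio
            stim_rate = b * ratio

            def fn(t, b=b, sr=stim_rate, dur=config.stim_duration_s):
                t = np.asarray(t, dtype=float)
                r = np.full_like(t, b)
                r[(t >= 0) & (t < dur)] = sr
                return r

            trains = sample_inhomogeneous_poisson(
                fn, window[1] - window[0], config.n_trials,
                seed=next(child), t_start_s=window[0])
            for tid, train in zip(trial_ids, trains):
                for t in train:
                    spike_rows.append((unit_id, tid, t))

    ds = SpikeDataset(
        pd.DataFrame(units),
        pd.DataFrame(spike_rows, columns=["unit_id", "trial_id", "spike_time_s"]),
        pd.DataFrame(trial_rows, columns=["trial_id", "condition_id"]),
        conditions, waveforms=waveforms, waveform_fs_hz=WAVEFORM_FS_HZ,
        trial_window_s=window,
        metadata={"generator": "intensity_sweep", "seed": config.seed,
                  "intensities_mw_mm2": list(map(float, intensities_mw_mm2))})
    ds.validate()
    return ds
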