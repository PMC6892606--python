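"""Shared in-memory containers for spike datasets and photostimulus protocols.

Units convention: distances in µm in files and containers (converted to mm
only for reporting), times in seconds, rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Columns required in the units table.
UNIT_COLUMNS = ("unit_id", "lateral_distance_um", "depth_um")
#: Columns required in the spikes table.
SPIKE_COLUMNS = ("unit_id", "trial_id", "spike_time_s")
#: Columns required in the trials table.
TRIAL_COLUMNS = ("trial_id", "condition_id")


@dataclass(frozen=True)
class PhotostimProtocol:
    """One photostimulus condition.

    The standard stimulus is a 40 Hz near-sinusoidal profile with a linear
    intensity ramp-down over the last 100–200 ms; reported powers are
    time-averaged.
    """

    wavelength_nm: float = 473.0
    avg_power_mw: float = 1.5
    beam_diameter_4sigma_um: float = 400.0
    temporal_profile: str = "sinusoid_40hz"  # or "constant"
    duration_s: float = 1.3
    ramp_ms: float = 100.0
    center_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.avg_power_mw < 0:
            raise ValueError("avg_power_mw must be >= 0")
        if self.beam_diameter_4sigma_um <= 0:
            raise ValueError("beam_diameter_4sigma_um must be > 0")
        if self.temporal_profile not in ("sinusoid_40hz", "constant"):
            raise ValueError(f"unknown temporal_profile {self.temporal_profile!r}")
        if self.ramp_ms / 1000.0 > self.duration_s:
            raise ValueError("ramp must not exceed stimulus duration")

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "avg_power_mw": self.avg_power_mw,
            "beam_diameter_4sigma_um": self.beam_diameter_4sigma_um,
            "temporal_profile": self.temporal_profile,
            "duration_s": self.duration_s,
            "ramp_ms": self.ramp_ms,
            "center_um": list(self.center_um),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhotostimProtocol":
        d = dict(d)
        if "center_um" in d:
            d["center_um"] = tuple(d["center_um"])
        return cls(**d)


@dataclass
class SpikeDataset:
    """Spike times, unit metadata, trials and photostimulus conditions.

    ``units``: one row per recorded unit — ``unit_id``, ``lateral_distance_um``,
    ``depth_um`` and optionally ``label`` (FS/PYR/UNCLASSIFIED), ``width_ms``.
    ``spikes``: one row per spike — ``unit_id``, ``trial_id``, ``spike_time_s``
    (relative to photostimulus onset; negative = pre-stimulus baseline).
    ``trials``: one row per trial — ``trial_id``, ``condition_id``.
    ``conditions``: mapping condition_id -> :class:`PhotostimProtocol`.
    ``waveforms``: optional mapping unit_id -> mean waveform (1-D array),
    sampled at ``waveform_fs_hz``.
    """

    units: pd.DataFrame
    spikes: pd.DataFrame
    trials: pd.DataFrame
    conditions: dict[str, PhotostimProtocol]
    waveforms: Optional[dict] = None
    waveform_fs_hz: float = 19531.25
    trial_window_s: tuple[float, float] = (-0.5, 1.9)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Referential-integrity checks; raises ValueError naming offending rows."""
        for col in UNIT_COLUMNS:
            if col not in self.units.columns:
                raise ValueError(f"units table missing column {col!r}")
        for col in SPIKE_COLUMNS:
            if col not in self.spikes.columns:
                raise ValueError(f"spikes table missing column {col!r}")
        for col in TRIAL_COLUMNS:
            if col not in self.trials.columns:
                raise ValueError(f"trials table missing column {col!r}")
        known_units = set(self.units["unit_id"])
        known_trials = set(self.trials["trial_id"])
        bad = ~self.spikes["unit_id"].isin(known_units)
        if bad.any():
            rows = list(self.spikes.index[bad][:5])
            raise ValueError(f"spikes reference unknown units at rows {rows}")
        bad = ~self.spikes["trial_id"].isin(known_trials)
        if bad.any():
            rows = list(self.spikes.index[bad][:5])
            raise ValueError(f"spikes reference unknown trials at rows {rows}")
        bad = ~self.trials["condition_id"].isin(self.conditions)
        if bad.any():
            rows = list(self.trials.index[bad][:5])
            raise ValueError(f"trials reference unknown conditions at rows {rows}")
        lo, hi = self.trial_window_s
        t = self.spikes["spike_time_s"].to_numpy()
        if len(t) and (t.min() < lo - 1e-9 or t.max() > hi + 1e-9):
            raise ValueError("spike times outside the trial window")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def select_units(self, label: Optional[str] = None,
                     max_distance_um: Optional[float] = None,
                     unit_ids=None) -> np.ndarray:
        """Return unit_ids matching the filter."""
        mask = np.ones(len(self.units), dtype=bool)
        if label is not None:
            if "label" not in self.units.columns:
                raise ValueError("dataset has no class labels; run classification first")
            mask &= (self.units["label"] == label).to_numpy()
        if max_distance_um is not None:
            mask &= (self.units["lateral_distance_um"] <= max_distance_um).to_numpy()
        if unit_ids is not None:
            mask &= self.units["unit_id"].isin(unit_ids).to_numpy()
        return self.units["unit_id"].to_numpy()[mask]

    def spikes_for(self, unit_id) -> pd.DataFrame:
        return self.spikes[self.spikes["unit_id"] == unit_id]

    def condition_for_trials(self) -> pd.Series:
        return self.trials.set_index("trial_id")["condition_id"]
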