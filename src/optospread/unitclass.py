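"""Spike-waveform cell-type classification.

Extracellular units are classified by the trough-to-peak interval of the mean
spike waveform: narrow-spiking units (< 0.35 ms) are putative fast-spiking
(FS) GABAergic neurons, wide-spiking units (> 0.45 ms) putative pyramidal
neurons, and units in the closed intermediate band [0.35, 0.45] ms are
excluded as UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FS_MAX_WIDTH_MS = 0.35
PYR_MIN_WIDTH_MS = 0.45

LABEL_FS = "FS"
LABEL_PYR = "PYR"
LABEL_UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class UnitClassification:
    width_ms: float
    label: str

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("spike width must be > 0")
        if self.label != classify_unit(self.width_ms):
            raise ValueError("label inconsistent with width thresholds")


def trough_to_peak(mean_waveform, sampling_rate_hz: float,
                   *, upsample: bool = False) -> float:
    """Trough-to-peak interval of a mean spike waveform, in ms.

    The trough is the global minimum; the peak is the maximum after the
    trough.  With ``upsample=True`` the waveform is cubic-spline upsampled
    10x around the extrema for sub-sample timing.

    Raises ValueError for non-spike-like waveforms (no post-trough recovery
    peak, or a waveform whose maximum precedes its minimum with no later
    positive deflection).
    """
    w = np.asarray(mean_waveform, dtype=float)
    if w.ndim == 2:
        # multi-site waveform: use the largest-amplitude channel
        w = w[np.argmax(w.max(axis=1) - w.min(axis=1))]
    if w.ndim != 1 or len(w) < 3:
        raise ValueError("waveform must be a 1-D series of >= 3 samples")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be > 0")

    i_trough = int(np.argmin(w))
    i_max = int(np.argmax(w))
    if i_max <= i_trough:
        # covers flat, monotonically decreasing, and time-reversed waveforms
        raise ValueError(
            "not a spike-like waveform: recovery peak does not follow the trough")
    post = w[i_trough + 1:]
    i_peak = i_trough + 1 + int(np.argmax(post))

    if upsample:
        from scipy.interpolate import CubicSpline
        t = np.arange(len(w))
        cs = CubicSpline(t, w)
        fine = np.linspace(0, len(w) - 1, (len(w) - 1) * 10 + 1)
        wf = cs(fine)
        j_trough = int(np.argmin(wf))
        postf = wf[j_trough + 1:]
        if len(postf) == 0:
            raise ValueError("not a spike-like waveform after upsampling")
        j_peak = j_trough + 1 + int(np.argmax(postf))
        width_samples = fine[j_peak] - fine[j_trough]
    else:
        width_samples = i_peak - i_trough
    return float(width_samples / sampling_rate_hz * 1000.0)


def classify_unit(width_ms: float) -> str:
    """FS if width < 0.35 ms, PYR if > 0.45 ms, UNCLASSIFIED otherwise.

    Both thresholds are strict; widths exactly at 0.35 or 0.45 ms fall in the
    excluded band.
    """
    if width_ms <= 0:
        raise ValueError("spike width must be > 0")
    if width_ms < FS_MAX_WIDTH_MS:
        return LABEL_FS
    if width_ms > PYR_MIN_WIDTH_MS:
        return LABEL_PYR
    return LABEL_UNCLASSIFIED


def classify_dataset(dataset, *, upsample: bool = False):
    """Append width_ms and label columns to a dataset's units table.

    Widths are computed from the dataset's mean waveforms; returns the
    modified dataset (in place).
    """
    if dataset.waveforms is None:
        raise ValueError("dataset has no waveforms to classify")
    widths, labels = [], []
    for uid in dataset.units["unit_id"]:
        w = trough_to_peak(dataset.waveforms[uid], dataset.waveform_fs_hz,
                           upsample=upsample)
        widths.append(w)
        labels.append(classify_unit(w))
    dataset.units["width_ms"] = widths
    dataset.units["label"] = labels
    return dataset
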