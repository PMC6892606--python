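"""File formats: CSV spike-dataset bundles, ROI tables, light-field TIFFs,
and YAML/JSON configuration.

CSV dialect: comma-separated, UTF-8, header row, '.' decimal; times in
seconds, distances in µm.  A spike-dataset bundle is a directory holding
``units.csv``, ``spikes.csv``, ``trials.csv``, ``conditions.json``,
optionally ``waveforms.csv``, and ``meta.json``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .core import PhotostimProtocol, SpikeDataset
from .lightmap import LightField, ROITable

__all__ = [
    "write_spike_dataset", "read_spike_dataset",
    "read_roi_table", "write_light_field", "read_light_field",
    "load_config", "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (embedded in outputs)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# spike datasets
# ---------------------------------------------------------------------------

def write_spike_dataset(dataset: SpikeDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.units.to_csv(out / "units.csv", index=False)
    dataset.spikes.to_csv(out / "spikes.csv", index=False)
    dataset.trials.to_csv(out / "trials.csv", index=False)
    with open(out / "conditions.json", "w") as fh:
        json.dump({cid: p.to_dict() for cid, p in dataset.conditions.items()},
                  fh, indent=2)
    if dataset.waveforms is not None:
        rows = []
        for uid, wf in dataset.waveforms.items():
            for i, v in enumerate(np.asarray(wf, dtype=float)):
                rows.append((uid, i, v))
        pd.DataFrame(rows, columns=["unit_id", "sample", "value"]).to_csv(
            out / "waveforms.csv", index=False)
    with open(out / "meta.json", "w") as fh:
        json.dump({
            "waveform_fs_hz": dataset.waveform_fs_hz,
            "trial_window_s": list(dataset.trial_window_s),
            "metadata": dataset.metadata,
        }, fh, indent=2, default=str)
    return out


def read_spike_dataset(path) -> SpikeDataset:
    """Read and validate a spike-dataset bundle directory.

    Raises ValueError on missing columns or dangling references (with row
    numbers).
    """
    p = Path(path)
    units = pd.read_csv(p / "units.csv")
    spikes = pd.read_csv(p / "spikes.csv") if (p / "spikes.csv").exists() else \
        pd.DataFrame(columns=["unit_id", "trial_id", "spike_time_s"])
    trials = pd.read_csv(p / "trials.csv")
    with open(p / "conditions.json") as fh:
        conditions = {cid: PhotostimProtocol.from_dict(d)
                      for cid, d in json.load(fh).items()}
    waveforms = None
    fs = 19531.25
    window = (-0.5, 1.9)
    metadata = {}
    if (p / "meta.json").exists():
        with open(p / "meta.json") as fh:
            meta = json.load(fh)
        fs = meta.get("waveform_fs_hz", fs)
        window = tuple(meta.get("trial_window_s", window))
        metadata = meta.get("metadata", {})
    if (p / "waveforms.csv").exists():
        wdf = pd.read_csv(p / "waveforms.csv")
        waveforms = {uid: g.sort_values("sample")["value"].to_numpy()
                     for uid, g in wdf.groupby("unit_id")}
    ds = SpikeDataset(units, spikes, trials, conditions, waveforms=waveforms,
                      waveform_fs_hz=fs, trial_window_s=window, metadata=metadata)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# ROI tables and light fields
# ---------------------------------------------------------------------------

def read_roi_table(path, *, dose_mw_min: float = 0.0,
                   wavelength_nm: float = 473.0) -> ROITable:
    return ROITable(pd.read_csv(path), dose_mw_min=dose_mw_min,
                    wavelength_nm=wavelength_nm)


def write_light_field(field: LightField, tiff_path) -> Path:
    """Write a light field as a multi-page TIFF (z pages) + JSON sidecar."""
    import tifffile

    tiff_path = Path(tiff_path)
    # values are [x, y, z]; TIFF pages are [z, y, x]
    tifffile.imwrite(tiff_path, np.transpose(field.values, (2, 1, 0)).astype("float32"))
    sidecar = tiff_path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({
            "voxel_um": field.voxel_um,
            "xs_um": field.xs.tolist(),
            "ys_um": field.ys.tolist(),
            "zs_um": field.zs.tolist(),
            "normalization": "max=1",
            "metadata": field.metadata,
        }, fh)
    return tiff_path


def read_light_field(tiff_path) -> LightField:
    import tifffile

    tiff_path = Path(tiff_path)
    with open(tiff_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    vals = np.transpose(np.asarray(tifffile.imread(tiff_path), dtype=float),
                        (2, 1, 0))
    return LightField(vals, np.asarray(meta["xs_um"]), np.asarray(meta["ys_um"]),
                      np.asarray(meta["zs_um"]), meta["voxel_um"],
                      metadata=meta.get("metadata", {}))
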