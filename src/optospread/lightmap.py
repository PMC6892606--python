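"""Recover the 3-D relative light-intensity profile in tissue from photobleaching.

Photobleaching of nuclear-targeted fluorescent proteins acts as an in-situ
dosimeter: under constant illumination the fractional fluorescence change at
position r follows

    f(r) = dF/F0 = -1 + exp(-k * I(r) * T)

where I(r) is the local light intensity, T the illumination duration (dose =
intensity x time, mW*min) and k a fluorophore-specific bleaching constant.
Inverting the exponential gives the relative intensity profile

    I(r) proportional to -ln(f(r) + 1)

up to a global constant, which is absorbed by normalizing the recovered field
to 1 at its maximum.  The chain implemented here is: ROI extraction from an
image stack -> dF/F0 against a far-field baseline F0 -> exponential bleach fit
-> inversion onto a voxel grid -> axial / lateral half-max summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from ._numutil import first_crossing_below, monotone_decreasing

__all__ = [
    "ROITable",
    "BleachFit",
    "LightField",
    "separable_light_field",
    "extract_roi_intensities",
    "compute_dff",
    "fit_bleach_constant",
    "invert_intensity",
    "profile_summary",
    "bootstrap_half_max_depth",
]


@dataclass
class ROITable:
    """Per-nucleus ROI fluorescence with positions relative to the laser center.

    ``data`` columns: x_um, y_um, z_um (z positive downward from the pia), F;
    after :func:`compute_dff` also ``f`` (= dF/F0, negative under bleaching).
    """

    data: pd.DataFrame
    dose_mw_min: float = 0.0
    wavelength_nm: float = 473.0
    f0: Optional[float] = None
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("x_um", "y_um", "z_um", "F"):
            if col not in self.data.columns:
                raise ValueError(f"ROI table missing column {col!r}")
        if (self.data["F"] < 0).any():
            raise ValueError("fluorescence must be >= 0")
        if not np.isfinite(
                self.data[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)).all():
            raise ValueError("ROI coordinates must be finite")
        if self.dose_mw_min < 0:
            raise ValueError("light dose must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def lateral_distance_um(self) -> np.ndarray:
        return np.hypot(self.data["x_um"].to_numpy(), self.data["y_um"].to_numpy())

    @property
    def radial_distance_um(self) -> np.ndarray:
        xyz = self.data[["x_um", "y_um", "z_um"]].to_numpy()
        return np.linalg.norm(xyz, axis=1)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class BleachFit:
    """Exponential bleach-curve fit f = -1 + exp(-k * dose)."""

    k_per_mw_min: float
    rss: float
    n_points: int
    dose_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.k_per_mw_min <= 0:
            raise ValueError("bleach constant k must be > 0")

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return -1.0 + np.exp(-self.k_per_mw_min * np.asarray(dose, dtype=float))


@dataclass
class LightField:
    """Relative light intensity on a regular voxel grid, max-normalized to 1.

    ``values`` is indexed [ix, iy, iz]; ``xs``/``ys``/``zs`` are voxel-center
    coordinates in µm with the laser center at (0, 0) on the surface plane and
    z positive downward.
    """

    values: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray
    voxel_um: float
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-9):
            raise ValueError("light-field values must lie in [0, 1]")
        if v.size and not np.isclose(v.max(), 1.0):
            raise ValueError("nonempty light field must be normalized to max 1")

    def at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at (N, 3) points (x, y, z) in µm; 0 outside."""
        interp = RegularGridInterpolator(
            (self.xs, self.ys, self.zs), self.values,
            bounds_error=False, fill_value=0.0)
        return np.clip(interp(np.atleast_2d(points)), 0.0, None)


def separable_light_field(
    axial_length_um: float,
    lateral_sigma_um: float,
) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic separable field: exp(-z/L) axially x Gaussian laterally.

    Returns a callable mapping (N, 3) µm points to relative intensity in
    [0, 1]; intensity is zero above the surface (z < 0).
    """
    if axial_length_um <= 0 or lateral_sigma_um <= 0:
        raise ValueError("length scales must be > 0")

    def field(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        z = pts[:, 2]
        out = np.exp(-z / axial_length_um) * np.exp(-r2 / (2 * lateral_sigma_um ** 2))
        out[z < 0] = 0.0
        return out

    return field


def evaluate_field(
    light: Union[LightField, Callable[[np.ndarray], np.ndarray]],
    points: np.ndarray,
) -> np.ndarray:
    """Evaluate a gridded or analytic light field at (N, 3) µm points."""
    if isinstance(light, LightField):
        return light.at(points)
    return np.asarray(light(points), dtype=float)


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi_intensities(
    image_stack: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    *,
    origin_um: Optional[tuple[float, float, float]] = None,
    min_distance_um: float = 8.0,
    threshold_rel: float = 0.2,
    roi_radius_um: float = 5.0,
    dose_mw_min: float = 0.0,
    wavelength_nm: float = 473.0,
) -> ROITable:
    """Detect nuclei as local maxima and measure mean ROI fluorescence.

    ``image_stack`` is indexed [z, y, x] (page order of a multi-page TIFF);
    ``voxel_size_um`` gives (dz, dy, dx).  ``origin_um`` is the laser-center
    position in (x, y, z) µm within the stack; defaults to the center of the
    xy field of view at the top plane.  Nuclei are local maxima above
    ``threshold_rel`` of the stack's dynamic range, separated by at least
    ``min_distance_um``; the ROI intensity is the mean over a sphere of
    ``roi_radius_um`` around each maximum.
    """
    from skimage.feature import peak_local_max

    stack = np.asarray(image_stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("image stack must be a nonempty 3-D array")
    if voxel_size_um is None or len(voxel_size_um) != 3:
        raise ValueError("voxel-size metadata (dz, dy, dx) is required")
    dz, dy, dx = (float(v) for v in voxel_size_um)
    if min(dz, dy, dx) <= 0:
        raise ValueError("voxel sizes must be > 0")
    if origin_um is None:
        origin_um = (stack.shape[2] * dx / 2.0, stack.shape[1] * dy / 2.0, 0.0)

    lo, hi = float(stack.min()), float(stack.max())
    if hi <= lo:  # blank stack
        return ROITable(
            pd.DataFrame(columns=["x_um", "y_um", "z_um", "F"]),
            dose_mw_min=dose_mw_min, wavelength_nm=wavelength_nm)
    min_dist_vox = max(1, int(round(min_distance_um / min(dz, dy, dx))))
    peaks = peak_local_max(
        stack, min_distance=min_dist_vox,
        threshold_abs=lo + threshold_rel * (hi - lo), exclude_border=False)

    rows = []
    rz = max(1, int(np.ceil(roi_radius_um / dz)))
    ry = max(1, int(np.ceil(roi_radius_um / dy)))
    rx = max(1, int(np.ceil(roi_radius_um / dx)))
    for pz, py, px in peaks:
        sl = stack[max(0, pz - rz):pz + rz + 1,
                   max(0, py - ry):py + ry + 1,
                   max(0, px - rx):px + rx + 1]
        zz, yy, xx = np.mgrid[max(0, pz - rz):pz + rz + 1,
                              max(0, py - ry):py + ry + 1,
                              max(0, px - rx):px + rx + 1]
        dist2 = ((zz - pz) * dz) ** 2 + ((yy - py) * dy) ** 2 + ((xx - px) * dx) ** 2
        inside = dist2 <= roi_radius_um ** 2
        rows.append({
            "x_um": px * dx - origin_um[0],
            "y_um": py * dy - origin_um[1],
            "z_um": pz * dz + origin_um[2] if origin_um[2] else pz * dz,
            "F": float(sl[inside].mean()),
        })
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "F"])
    return ROITable(df, dose_mw_min=dose_mw_min, wavelength_nm=wavelength_nm)


# ---------------------------------------------------------------------------
# dF/F0 and bleach-constant fitting
# ---------------------------------------------------------------------------

def compute_dff(
    rois: ROITable,
    far_threshold_um: float = 700.0,
    *,
    distance_mode: str = "3d",
    f0: Optional[float] = None,
) -> ROITable:
    """Compute per-ROI f = dF/F0 against a far-field baseline.

    F0 is the mean fluorescence of all ROIs farther than ``far_threshold_um``
    from the laser center.  ``distance_mode`` selects the distance used for
    "far": ``"3d"`` (Euclidean) or ``"lateral"`` (surface-plane distance only;
    used for orange light, where bleaching is near-complete over a deep
    central column).  An explicit ``f0`` overrides the far-ROI average.
    """
    if distance_mode not in ("3d", "lateral"):
        raise ValueError("distance_mode must be '3d' or 'lateral'")
    if f0 is None:
        dist = (rois.radial_distance_um if distance_mode == "3d"
                else rois.lateral_distance_um)
        far = dist > far_threshold_um
        if not far.any():
            raise ValueError(
                f"no ROIs beyond {far_threshold_um} µm from the laser center; "
                "use a larger field of view or pass an explicit f0")
        f0 = float(rois.data.loc[far, "F"].mean())
    if f0 <= 0:
        raise ValueError("baseline fluorescence F0 must be > 0")
    out = rois.data.copy()
    out["f"] = (out["F"] - f0) / f0
    return ROITable(out, dose_mw_min=rois.dose_mw_min,
                    wavelength_nm=rois.wavelength_nm, f0=f0,
                    metadata=dict(rois.metadata))


def fit_bleach_constant(center_dff_by_dose) -> BleachFit:
    """Least-squares fit of f = -1 + exp(-k * dose) to (dose, f) points.

    The input is typically the center-region mean dF/F0 at several light
    doses.  Requires at least two distinct doses and a net bleaching signal
    (some f < 0).
    """
    arr = np.asarray(list(center_dff_by_dose), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (dose, f) pairs")
    dose, f = arr[:, 0], arr[:, 1]
    if len(np.unique(dose)) < 2:
        raise ValueError("need at least 2 distinct doses to fit k")
    if not (f < 0).any():
        raise ValueError("no bleaching signal: all f >= 0")

    # Linearized initial guess: -ln(f+1) = k * dose.
    ok = f > -1
    with np.errstate(divide="ignore"):
        y = -np.log1p(f[ok])
    denom = float(np.dot(dose[ok], dose[ok]))
    k0 = float(np.dot(dose[ok], y)) / denom if denom > 0 else 1e-3
    k0 = max(k0, 1e-12)

    popt, _ = optimize.curve_fit(
        lambda d, k: -1.0 + np.exp(-k * d), dose, f, p0=[k0], maxfev=10000)
    k = float(popt[0])
    resid = f - (-1.0 + np.exp(-k * dose))
    return BleachFit(k_per_mw_min=k, rss=float(np.sum(resid ** 2)),
                     n_points=len(dose), dose_range=(float(dose.min()), float(dose.max())))


# ---------------------------------------------------------------------------
# Inversion onto a voxel grid
# ---------------------------------------------------------------------------

def _grid_axis(vals: np.ndarray, voxel: float) -> np.ndarray:
    lo = np.floor(vals.min() / voxel) * voxel
    hi = np.ceil(vals.max() / voxel) * voxel
    n = max(1, int(round((hi - lo) / voxel)))
    return lo + (np.arange(n) + 0.5) * voxel


def invert_intensity(
    dff_map: ROITable,
    fit: Optional[BleachFit] = None,
    dose_mw_min: Optional[float] = None,
    *,
    voxel_um: float = 25.0,
    exclude_below: float = -0.99,
    n_neighbors: int = 6,
) -> LightField:
    """Invert per-ROI dF/F0 to relative light intensity and grid it.

    Per ROI the unnormalized intensity is -ln(f + 1) (optionally divided by
    k*T when a bleach fit and dose are supplied — the scale cancels under the
    final max-normalization).  ROIs with f <= ``exclude_below`` are excluded
    (near-complete bleach; the log diverges).  ROI values are averaged into
    ``voxel_um`` voxels; empty voxels are filled by inverse-distance
    interpolation from up to ``n_neighbors`` filled voxels; negative values
    (pure noise, f > 0) are clipped to zero and the field is normalized to 1
    at its maximum.
    """
    if "f" not in dff_map.data.columns:
        raise ValueError("ROI table has no 'f' column; run compute_dff first")
    df = dff_map.data
    f = df["f"].to_numpy(dtype=float)
    if np.allclose(f, f[0] if len(f) else 0.0):
        raise ValueError("flat dF/F0 field: normalization undefined")
    keep = f > exclude_below
    n_excluded = int((~keep).sum())
    df = df.loc[keep]
    intensity = -np.log1p(df["f"].to_numpy(dtype=float))
    scale = 1.0
    if fit is not None:
        d = dose_mw_min if dose_mw_min is not None else dff_map.dose_mw_min
        if d and d > 0:
            scale = fit.k_per_mw_min * d
    intensity = intensity / scale

    xs = _grid_axis(df["x_um"].to_numpy(), voxel_um)
    ys = _grid_axis(df["y_um"].to_numpy(), voxel_um)
    zs = _grid_axis(df["z_um"].to_numpy(), voxel_um)
    ix = np.clip(np.searchsorted(xs + voxel_um / 2, df["x_um"]), 0, len(xs) - 1)
    iy = np.clip(np.searchsorted(ys + voxel_um / 2, df["y_um"]), 0, len(ys) - 1)
    iz = np.clip(np.searchsorted(zs + voxel_um / 2, df["z_um"]), 0, len(zs) - 1)

    shape = (len(xs), len(ys), len(zs))
    flat = np.ravel_multi_index((ix, iy, iz), shape)
    sums = np.bincount(flat, weights=intensity, minlength=np.prod(shape))
    counts = np.bincount(flat, minlength=np.prod(shape))
    grid = np.full(np.prod(shape), np.nan)
    filled = counts > 0
    grid[filled] = sums[filled] / counts[filled]

    if not filled.all() and filled.any():
        centers = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"),
                           axis=-1).reshape(-1, 3)
        tree = cKDTree(centers[filled])
        k = min(n_neighbors, int(filled.sum()))
        dist, idx = tree.query(centers[~filled], k=k)
        dist = np.atleast_2d(dist.reshape((~filled).sum(), -1))
        idx = np.atleast_2d(idx.reshape((~filled).sum(), -1))
        w = 1.0 / np.maximum(dist, 1e-9)
        vals = grid[filled][idx]
        grid[~filled] = np.sum(w * vals, axis=1) / np.sum(w, axis=1)

    grid = grid.reshape(shape)
    grid = np.clip(grid, 0.0, None)
    gmax = grid.max()
    if gmax <= 0:
        raise ValueError("recovered intensity is zero everywhere")
    grid /= gmax
    return LightField(grid, xs, ys, zs, voxel_um,
                      metadata={"n_rois": len(df), "n_excluded": n_excluded,
                                "scale": scale * gmax})


# ---------------------------------------------------------------------------
# Spatial summaries
# ---------------------------------------------------------------------------

def _monotone_decreasing(values: np.ndarray) -> np.ndarray:
    """Antitonic fit of a profile (light attenuation in tissue is monotone
    with distance from the source; enforcing this removes the early-crossing
    bias that bin noise would otherwise cause in the half-max search)."""
    return monotone_decreasing(values)


def _first_half_crossing(coord: np.ndarray, values: np.ndarray,
                         reference: float, axis_name: str) -> float:
    """First coordinate at which values fall to reference/2 (pooled linear
    interpolation; see :func:`optospread._numutil.first_crossing_below`)."""
    from ._numutil import banded_crossing
    xform = "sq" if "lateral" in axis_name else "linear"
    try:
        return banded_crossing(coord, values, reference / 2.0, band=0.5,
                               what=axis_name, xform=xform)
    except ValueError as err:
        raise ValueError(
            f"intensity never falls to 50% within the grid along {axis_name}; "
            f"lower bound {coord[-1]:.1f} um") from err


def _surface_reference(zs: np.ndarray, axial: np.ndarray) -> float:
    """On-axis intensity extrapolated to the surface plane z = 0.

    The first grid plane sits half a voxel below the surface and is the one
    most affected by binning/interpolation edge effects, so the surface value
    is estimated by log-linear extrapolation of the profile's upper shoulder
    (planes where the profile lies within [0.35, 0.95] of its maximum — a
    range that self-scales with the decay length) rather than read from the
    top plane directly.
    """
    zs = np.asarray(zs, dtype=float)
    axial = np.asarray(axial, dtype=float)
    top = float(axial.max())
    if top <= 0:
        return float(axial[0])
    sel = (axial >= 0.35 * top) & (axial <= 0.95 * top) & (axial > 0)
    if sel.sum() < 2:
        # profile too coarse for a shoulder fit: fall back to linear
        # extrapolation from the first two planes
        if len(axial) > 1 and zs[0] > 0:
            v = axial[0] + (axial[0] - axial[1]) / (zs[1] - zs[0]) * zs[0]
            return float(max(v, axial[0]))
        return float(axial[0])
    slope, intercept = np.polyfit(zs[sel], np.log(axial[sel]), 1)
    return float(max(np.exp(intercept), axial[0]))


def axial_profile(field: LightField, axis_radius_um: float = 50.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """On-axis intensity vs depth, averaging voxel columns within
    ``axis_radius_um`` of the beam axis."""
    rr = np.hypot(*np.meshgrid(field.xs, field.ys, indexing="ij"))
    near = rr <= max(axis_radius_um, field.voxel_um * 0.75)
    if not near.any():
        raise ValueError("no voxel columns on or near the beam axis")
    prof = field.values[near].mean(axis=0)
    return field.zs, prof


def lateral_profile(field: LightField, depth_um: float,
                    bin_um: Optional[float] = None,
                    slab_halfspan_um: float = 50.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Radially-binned intensity around the plane at ``depth_um``.

    Planes within ``slab_halfspan_um`` of the requested depth are pooled
    (each normalized profile shape is depth-independent for a separable
    field, and pooling suppresses voxel noise).
    """
    sel = np.abs(field.zs - depth_um) <= max(slab_halfspan_um, field.voxel_um * 0.5)
    if not sel.any():
        sel = np.abs(field.zs - depth_um) == np.min(np.abs(field.zs - depth_um))
    slab = field.values[:, :, sel].mean(axis=2)
    rr = np.hypot(*np.meshgrid(field.xs, field.ys, indexing="ij")).ravel()
    vals = slab.ravel()
    bw = bin_um or field.voxel_um
    nb = int(np.ceil(rr.max() / bw))
    idx = np.minimum((rr / bw).astype(int), nb - 1)
    sums = np.bincount(idx, weights=vals, minlength=nb)
    counts = np.bincount(idx, minlength=nb)
    ok = counts > 0
    centers = (np.arange(nb) + 0.5) * bw
    return centers[ok], sums[ok] / counts[ok]


def profile_summary(
    field: LightField,
    *,
    reference_depth_um: float = 200.0,
    axis_radius_um: float = 50.0,
    monotone: bool = True,
) -> dict:
    """Half-max depth and lateral half-width of a recovered light field.

    ``half_max_depth_um`` is the depth at which the on-axis intensity first
    falls to half its surface value (linear interpolation between grid
    planes); the surface value is extrapolated to z = 0 from the first two
    planes.  ``lateral_half_width_um`` is the lateral distance at
    ``reference_depth_um`` where intensity falls to half the on-axis value at
    that depth.  With ``monotone=True`` (default) profiles are antitonically
    regularized before the crossing search (attenuation in tissue is
    monotone; see :func:`_monotone_decreasing`).
    """
    if field.values.size == 0:
        raise ValueError("empty light field")
    zs, axial = axial_profile(field, axis_radius_um)
    if monotone:
        axial = _monotone_decreasing(axial)
    surface = _surface_reference(zs, axial)
    if surface <= 0:
        raise ValueError("on-axis surface intensity is zero")
    half_depth = _first_half_crossing(zs, axial, surface, "depth")

    radii, lat = lateral_profile(field, reference_depth_um)
    if monotone:
        lat = _monotone_decreasing(lat)
    # On-axis anchor from the radial profile itself (its innermost bin, at
    # ~half a voxel off axis) so anchor and profile share the same estimator.
    on_axis = float(lat[0])
    if on_axis <= 0:
        raise ValueError("on-axis intensity at the reference depth is zero")
    half_lateral = _first_half_crossing(radii, lat, on_axis, "lateral distance")
    return {"half_max_depth_um": half_depth,
            "lateral_half_width_um": half_lateral}


def bootstrap_half_max_depth(
    dff_map: ROITable,
    *,
    n_resamples: int = 2000,
    seed: int = 0,
    voxel_um: float = 25.0,
    axis_radius_um: float = 50.0,
) -> dict:
    """Bootstrap (resampling ROIs) the half-max depth of the recovered field.

    Returns point estimate, s.e.m. (s.d. of resampled estimates) and a 90%
    central percentile CI.
    """
    rng = np.random.default_rng(seed)
    base = invert_intensity(dff_map, voxel_um=voxel_um)
    point = profile_summary(base, axis_radius_um=axis_radius_um)["half_max_depth_um"]
    n = len(dff_map)
    stats = []
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        resampled = ROITable(dff_map.data.iloc[idx].reset_index(drop=True),
                             dose_mw_min=dff_map.dose_mw_min,
                             wavelength_nm=dff_map.wavelength_nm, f0=dff_map.f0)
        try:
            fld = invert_intensity(resampled, voxel_um=voxel_um)
            stats.append(profile_summary(
                fld, axis_radius_um=axis_radius_um)["half_max_depth_um"])
        except ValueError:
            continue
    stats = np.asarray(stats)
    lo, hi = np.percentile(stats, [5, 95])
    return {"point": point, "sem": float(stats.std(ddof=1)),
            "ci90": (float(lo), float(hi)), "n_resamples": len(stats)}
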