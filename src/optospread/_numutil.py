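"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np


def monotone_decreasing(values: np.ndarray) -> np.ndarray:
    """Antitonic (monotone non-increasing) least-squares fit of a profile."""
    from scipy.optimize import isotonic_regression

    return isotonic_regression(np.asarray(values, dtype=float),
                               increasing=False).x


def first_crossing_below(coord: np.ndarray, values: np.ndarray, level: float,
                         what: str = "profile") -> float:
    """First coordinate at which ``values`` fall to/below ``level``.

    Linear interpolation between points; runs of equal consecutive values
    (the flat pools an antitonic fit produces) are collapsed to their center
    coordinate first, so a crossing inside a pool is located at the pool's
    center rather than its far edge.

    Raises ValueError if the values never reach the level.
    """
    coord = np.asarray(coord, dtype=float)
    values = np.asarray(values, dtype=float)
    boundaries = np.flatnonzero(np.diff(values) != 0) + 1
    segments = np.split(np.arange(len(values)), boundaries)
    c = np.array([coord[s].mean() for s in segments])
    v = np.array([values[s[0]] for s in segments])
    below = v <= level
    if not below.any():
        raise ValueError(
            f"{what} never falls to the target level within range; "
            f"lower bound {coord[-1]:.4g}")
    i = int(np.argmax(below))
    if i == 0:
        # already at/below the level from the start: the crossing is at the
        # first point, not the (possibly long) first segment's center
        return float(coord[0])
    x0, x1 = c[i - 1], c[i]
    v0, v1 = v[i - 1], v[i]
    return float(x0 + (v0 - level) / (v0 - v1) * (x1 - x0))


def banded_crossing(coord: np.ndarray, values: np.ndarray, level: float,
                    band: float = 0.5, what: str = "profile",
                    xform: str = "linear") -> float:
    """Crossing of ``values`` through ``level`` from a local log-space fit.

    Points whose value lies within ``band * level`` of the level (the
    contiguous run around the crossing) are fitted with a straight line in
    log space — ln(v) against the coordinate (``xform="linear"``, exact for
    an exponential profile) or against the squared coordinate
    (``xform="sq"``, exact for a Gaussian) — and the crossing of the fit is
    returned.  This uses the whole neighborhood of the crossing instead of a
    single pair of points; with fewer than four usable points it falls back
    to :func:`first_crossing_below`.
    """
    coord = np.asarray(coord, dtype=float)
    values = np.asarray(values, dtype=float)
    first = first_crossing_below(coord, values, level, what)
    sel = (np.abs(values - level) <= band * level) & (values > 0)
    if sel.sum() >= 4:
        idx = np.flatnonzero(sel)
        near = idx[np.argmin(np.abs(coord[idx] - first))]
        members = set(idx.tolist())
        lo = hi = near
        while lo - 1 in members:
            lo -= 1
        while hi + 1 in members:
            hi += 1
        run = np.arange(lo, hi + 1)
        if len(run) >= 4:
            x = coord[run] ** 2 if xform == "sq" else coord[run]
            slope, intercept = np.polyfit(x, np.log(values[run]), 1)
            if slope < 0:
                xc = (np.log(level) - intercept) / slope
                if xform == "sq":
                    xc = np.sqrt(xc) if xc > 0 else -1.0
                if coord[run[0]] <= xc <= coord[run[-1]]:
                    return float(xc)
    return first
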