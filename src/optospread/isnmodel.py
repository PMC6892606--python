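"""Excitatory–inhibitory rate network with rectified-linear transfer.

A minimal inhibition-stabilized network (ISN) model:

    tau_E dr_E/dt = -r_E + [ w_ee r_E - w_ei r_I + h_E + s_E ]_+
    tau_I dr_I/dt = -r_I + [ w_ie r_E - w_ii r_I + h_I + s_I ]_+

with unit-gain rectified-linear transfer [x]_+ = max(x, 0) and opsin drive
s = opsin_gain * light added to the target population.  When the excitatory
subnetwork is unstable alone (w_ee > 1) but the full circuit is stable, extra
drive to I *lowers* the steady-state inhibitory rate — the paradoxical effect:
in the fully active branch dr_I/dh_I = (1 - w_ee) / det with
det = (1 - w_ee)(1 + w_ii) + w_ei * w_ie > 0.

An optional 1-D spatial mode places an E and an I population at each lateral
grid node and couples nodes through Gaussian kernels whose rows are
normalized so that row sums equal the scalar weights; with kernel widths
going to zero the model reduces to independent 2-population circuits per
node.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np

__all__ = ["ISNParams", "SpatialCoupling", "RateTrajectory",
           "steady_state", "simulate_dynamics"]


@dataclass(frozen=True)
class SpatialCoupling:
    """Gaussian lateral coupling on a 1-D grid, widths in µm."""
    grid_spacing_um: float = 100.0
    grid_extent_um: float = 3000.0
    sigma_ee_um: float = 200.0
    sigma_ei_um: float = 200.0
    sigma_ie_um: float = 200.0
    sigma_ii_um: float = 200.0

    def __post_init__(self) -> None:
        if self.grid_spacing_um <= 0 or self.grid_extent_um <= 0:
            raise ValueError("grid spacing and extent must be > 0")
        for s in (self.sigma_ee_um, self.sigma_ei_um,
                  self.sigma_ie_um, self.sigma_ii_um):
            if s < 0:
                raise ValueError("kernel widths must be >= 0")

    @property
    def positions_um(self) -> np.ndarray:
        half = self.grid_extent_um / 2.0
        n = int(np.floor(2 * half / self.grid_spacing_um)) + 1
        return -half + np.arange(n) * self.grid_spacing_um

    def kernel(self, sigma_um: float) -> np.ndarray:
        """Row-normalized Gaussian coupling matrix over grid nodes."""
        x = self.positions_um
        if sigma_um <= 0:
            return np.eye(len(x))
        d2 = (x[:, None] - x[None, :]) ** 2
        k = np.exp(-d2 / (2 * sigma_um ** 2))
        return k / k.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ISNParams:
    """Coupling weights (nonnegative, inhibitory signs applied internally),
    time constants (ms), baseline drives and opsin coupling."""
    w_ee: float = 2.0
    w_ei: float = 2.5
    w_ie: float = 3.0
    w_ii: float = 2.0
    tau_e_ms: float = 20.0
    tau_i_ms: float = 10.0
    h_e: float = 1.0
    h_i: float = 0.0
    opsin_gain: float = 1.0
    target_population: str = "I"
    spatial: Optional[SpatialCoupling] = None
    rate_ceiling: float = 1e6

    def __post_init__(self) -> None:
        for name in ("w_ee", "w_ei", "w_ie", "w_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_e_ms <= 0 or self.tau_i_ms <= 0:
            raise ValueError("time constants must be > 0")
        if self.target_population not in ("E", "I"):
            raise ValueError("target_population must be 'E' or 'I'")


@dataclass
class RateTrajectory:
    """Simulated rate dynamics: time grid (ms) and nonnegative rates.

    ``r_e``/``r_i`` have shape (n_times,) for the 2-population model or
    (n_times, n_nodes) in spatial mode.
    """
    time_ms: np.ndarray
    r_e: np.ndarray
    r_i: np.ndarray
    positions_um: Optional[np.ndarray] = None
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if (np.asarray(self.r_e) < -1e-12).any() or (np.asarray(self.r_i) < -1e-12).any():
            raise ValueError("rates must be nonnegative")


def _drives(params: ISNParams, light) -> tuple[np.ndarray, np.ndarray]:
    """Opsin drive added to (E, I) inputs; scalar or per-node."""
    light = np.asarray(light, dtype=float)
    s = params.opsin_gain * light
    zero = np.zeros_like(s)
    return (s, zero) if params.target_population == "E" else (zero, s)


def _rhs_matrices(params: ISNParams):
    """Return W blocks (with signs) for scalar or spatial mode."""
    if params.spatial is None:
        return (params.w_ee, params.w_ei, params.w_ie, params.w_ii)
    sp = params.spatial
    return (params.w_ee * sp.kernel(sp.sigma_ee_um),
            params.w_ei * sp.kernel(sp.sigma_ei_um),
            params.w_ie * sp.kernel(sp.sigma_ie_um),
            params.w_ii * sp.kernel(sp.sigma_ii_um))


def _net_input(params, wee, wei, wie, wii, r_e, r_i, s_e, s_i):
    if params.spatial is None:
        u_e = wee * r_e - wei * r_i + params.h_e + s_e
        u_i = wie * r_e - wii * r_i + params.h_i + s_i
    else:
        u_e = wee @ r_e - wei @ r_i + params.h_e + s_e
        u_i = wie @ r_e - wii @ r_i + params.h_i + s_i
    return u_e, u_i


def steady_state(params: ISNParams, light: Union[float, np.ndarray] = 0.0,
                 *, tol: float = 1e-10, max_iter: int = 100_000) -> dict:
    """Fixed point of the rectified-linear dynamics under constant light.

    Iterates the dynamics (implicit relaxation step) until max |dr| < tol.
    Returns ``{"r_e", "r_i", "stable", "n_iter"}``; ``stable`` reports whether
    the Jacobian of the active linear branch at the fixed point has all
    eigenvalue real parts negative.

    Raises RuntimeError (naming the parameter set) on non-convergence.
    """
    wee, wei, wie, wii = _rhs_matrices(params)
    s_e, s_i = _drives(params, light)
    n = 1 if params.spatial is None else len(params.spatial.positions_um)
    r_e = np.zeros(n) if n > 1 else 0.0
    r_i = np.zeros(n) if n > 1 else 0.0
    # Relaxation factor < 1 damps oscillatory approach in strongly coupled nets.
    alpha = 0.1
    for it in range(max_iter):
        u_e, u_i = _net_input(params, wee, wei, wie, wii, r_e, r_i, s_e, s_i)
        new_e = r_e + alpha * (np.maximum(u_e, 0.0) - r_e)
        new_i = r_i + alpha * (np.maximum(u_i, 0.0) - r_i)
        delta = max(np.max(np.abs(new_e - r_e)), np.max(np.abs(new_i - r_i)))
        r_e, r_i = new_e, new_i
        if delta < tol * alpha:
            break
        if np.max(np.abs(r_e)) > params.rate_ceiling:
            raise RuntimeError(f"steady_state diverged for params {params}")
    else:
        raise RuntimeError(
            f"steady_state did not converge in {max_iter} iterations for {params}")

    stable = _branch_stable(params, wee, wei, wie, wii, r_e, r_i, s_e, s_i)
    out = {"stable": stable, "n_iter": it + 1}
    if params.spatial is None:
        out["r_e"], out["r_i"] = float(r_e), float(r_i)
    else:
        out["r_e"], out["r_i"] = np.asarray(r_e), np.asarray(r_i)
    return out


def _branch_stable(params, wee, wei, wie, wii, r_e, r_i, s_e, s_i) -> bool:
    """Eigenvalue test of the Jacobian on the active linear branch."""
    u_e, u_i = _net_input(params, wee, wei, wie, wii, r_e, r_i, s_e, s_i)
    d_e = np.atleast_1d(np.asarray(u_e) > 0).astype(float)
    d_i = np.atleast_1d(np.asarray(u_i) > 0).astype(float)
    n = d_e.size
    if params.spatial is None:
        Wee = np.array([[wee]]); Wei = np.array([[wei]])
        Wie = np.array([[wie]]); Wii = np.array([[wii]])
    else:
        Wee, Wei, Wie, Wii = wee, wei, wie, wii
    De, Di = np.diag(d_e), np.diag(d_i)
    I = np.eye(n)
    top = np.hstack([(De @ Wee - I) / params.tau_e_ms, -(De @ Wei) / params.tau_e_ms])
    bot = np.hstack([(Di @ Wie) / params.tau_i_ms, (-(Di @ Wii) - I) / params.tau_i_ms])
    J = np.vstack([top, bot])
    return bool(np.all(np.linalg.eigvals(J).real < 0))


def simulate_dynamics(
    params: ISNParams,
    light: Union[float, np.ndarray, callable] = 0.0,
    *,
    duration_s: float = 1.0,
    dt_ms: Optional[float] = None,
    temporal_profile: str = "constant",
    r0: Optional[tuple] = None,
) -> RateTrajectory:
    """Forward-Euler integration of the rectified-linear E–I dynamics.

    ``light`` is a scalar, a per-node array, or a callable t_ms -> drive.
    ``temporal_profile='sinusoid_40hz'`` multiplies the opsin drive by a
    rectified 40 Hz sinusoid (mean 1, so the time-averaged drive matches the
    constant-profile drive).  With constant drive the trajectory converges to
    the :func:`steady_state` fixed point.

    Raises RuntimeError if rates exceed the configured ceiling (instability).
    """
    tau_min = min(params.tau_e_ms, params.tau_i_ms)
    if dt_ms is None:
        dt_ms = tau_min / 20.0
    if dt_ms > tau_min / 10.0:
        raise ValueError("dt must be <= min(tau)/10")
    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    times = np.arange(n_steps + 1) * dt_ms

    wee, wei, wie, wii = _rhs_matrices(params)
    n = 1 if params.spatial is None else len(params.spatial.positions_um)
    if r0 is None:
        base = steady_state(params, 0.0)
        r_e, r_i = np.atleast_1d(base["r_e"]).astype(float), \
            np.atleast_1d(base["r_i"]).astype(float)
        if params.spatial is None:
            r_e, r_i = float(r_e[0]), float(r_i[0])
    else:
        r_e, r_i = r0

    traj_e = np.empty((n_steps + 1, n)); traj_i = np.empty((n_steps + 1, n))
    traj_e[0], traj_i[0] = r_e, r_i
    for step in range(1, n_steps + 1):
        t = times[step - 1]
        lt = light(t) if callable(light) else light
        s_e, s_i = _drives(params, lt)
        if temporal_profile == "sinusoid_40hz":
            # smooth nonnegative 40 Hz modulation with unit mean
            mod = 1.0 - np.cos(2 * np.pi * 40.0 * t / 1000.0)
            s_e, s_i = s_e * mod, s_i * mod
        u_e, u_i = _net_input(params, wee, wei, wie, wii, r_e, r_i, s_e, s_i)
        r_e = r_e + dt_ms / params.tau_e_ms * (-r_e + np.maximum(u_e, 0.0))
        r_i = r_i + dt_ms / params.tau_i_ms * (-r_i + np.maximum(u_i, 0.0))
        if np.max(np.abs(np.atleast_1d(r_e))) > params.rate_ceiling:
            raise RuntimeError(
                f"rate exceeded ceiling {params.rate_ceiling} at t={t:.1f} ms; "
                "the network is unstable for these parameters")
        traj_e[step], traj_i[step] = r_e, r_i

    if params.spatial is None:
        traj_e, traj_i = traj_e[:, 0], traj_i[:, 0]
        positions = None
    else:
        positions = params.spatial.positions_um
    return RateTrajectory(times, np.maximum(traj_e, 0.0), np.maximum(traj_i, 0.0),
                          positions_um=positions,
                          metadata={"dt_ms": dt_ms, "profile": temporal_profile})
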