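"""Simulation of the coarse-grained ion model and trajectory-based estimators.

The model is the 12-dimensional linear SDE (three independent components)

    dX_i = V_i dt,   dV_i = U_i dt,   dU_i = (-eta1 V_i + Z_i) dt,
    dZ_i = -(eta2 Z_i + eta3 U_i) dt + eta4 dW_i,

integrated with explicit Euler-Maruyama at a caller-supplied timestep
(default 1e-3 ps, the fine-scale timestep the model is parametrized at).
The estimators in this module invert the parametrization: they recover the
stationary second moments, the auxiliary-variable moment, the diffusion
constant (via mean square displacements) and the conditional mean jerk from
a sampled trajectory -- whether that trajectory came from this simulator or
from an external fine-scale code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from . import _kernels
from .errors import NumericalBlowupError, TrajectoryTooShortError
from .params import CGParams, MDMomentStats
from .trajectory import Trajectory

__all__ = [
    "CGState",
    "JerkMap",
    "cg_step",
    "simulate_cg",
    "stationary_std",
    "sample_stationary",
    "estimate_moments",
    "estimate_z2",
    "msd",
    "estimate_D_from_msd_curve",
    "estimate_D_msd",
    "jerk_map",
    "jerk_slope",
    "langevin_moment_check",
]


@dataclass
class CGState:
    """Instantaneous state of one ion: time plus four 3-vectors."""

    t: float
    X: np.ndarray
    V: np.ndarray
    U: np.ndarray
    Z: np.ndarray

    def __post_init__(self):
        for name in ("X", "V", "U", "Z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))

    @classmethod
    def zero(cls) -> "CGState":
        return cls(0.0, np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))

    def is_finite(self) -> bool:
        return bool(
            np.all(np.isfinite(self.X))
            and np.all(np.isfinite(self.V))
            and np.all(np.isfinite(self.U))
            and np.all(np.isfinite(self.Z))
        )


def cg_step(state: CGState, params: CGParams, dt: float, noise: np.ndarray) -> CGState:
    """One explicit Euler-Maruyama step; ``noise`` is a 3-vector of N(0,1) draws.

    All right-hand sides are evaluated at the pre-step state.
    """
    if not state.is_finite():
        raise NumericalBlowupError("numerical blow-up: non-finite state passed to cg_step")
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    noise = np.asarray(noise, dtype=float).reshape(3)
    e1, e2, e3, e4 = params.as_tuple()
    X = state.X + state.V * dt
    V = state.V + state.U * dt
    U = state.U + (-e1 * state.V + state.Z) * dt
    Z = state.Z - (e2 * state.Z + e3 * state.U) * dt + e4 * np.sqrt(dt) * noise
    return CGState(state.t + dt, X, V, U, Z)


def simulate_cg(
    params: CGParams,
    init: CGState | None = None,
    dt: float = 1e-3,
    n_steps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate ``n_steps`` Euler-Maruyama steps; bit-reproducible given a seed.

    Noise is drawn in a single block of shape (n_steps, 3), i.e. per (step,
    component) in fixed order, so the same seed always yields the same path
    and the stream can be shared with the N=1 fictitious-particle model.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if init is None:
        init = CGState.zero()
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, 3))
    e1, e2, e3, e4 = params.as_tuple()
    X, V, U, Z, bad = _kernels.cg_path(
        e1, e2, e3, e4, float(dt), noise, init.X, init.V, init.U, init.Z
    )
    if bad >= 0:
        raise NumericalBlowupError(
            f"numerical blow-up at step {bad} (dt={dt}); reduce the timestep", step=bad
        )
    return Trajectory(dt=float(dt), X=X, V=V, U=U, Z=Z, seed=seed, t0=init.t)


def stationary_std(params: CGParams) -> tuple[float, float, float]:
    """Per-component stationary standard deviations of (V, U, Z).

    The stationary law of (V_i, U_i, Z_i) is a centred Gaussian with diagonal
    covariance (eta4^2, eta1*eta4^2, eta1*eta3*eta4^2) / (2 eta1 eta2 eta3).
    """
    v2 = params.stationary_v2
    return (
        float(np.sqrt(v2)),
        float(np.sqrt(params.eta1 * v2)),
        float(np.sqrt(params.eta1 * params.eta3 * v2)),
    )


def sample_stationary(
    params: CGParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Draw (V, U, Z) from the stationary Gaussian law of the non-position block.

    Cross-covariances vanish at stationarity, so the three vectors are
    independent.  With ``size=None`` returns three 3-vectors; otherwise three
    arrays of shape (size, 3).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sv, su, sz = stationary_std(params)
    shape = (3,) if size is None else (size, 3)
    return (
        sv * rng.standard_normal(shape),
        su * rng.standard_normal(shape),
        sz * rng.standard_normal(shape),
    )


def estimate_moments(traj: Trajectory, burn_in: float = 0.1) -> tuple[float, float]:
    """Time-and-component averages of V^2 and U^2 (single-component moments)."""
    traj.require_steps(1, "moment estimation")
    cut = traj.burned(burn_in)
    return float(np.mean(cut.V**2)), float(np.mean(cut.U**2))


def estimate_z2(traj: Trajectory, eta1: float, burn_in: float = 0.1) -> float:
    """Estimate the auxiliary second moment <Z_i^2> from V and U alone.

    Uses the finite-difference identity
    Z_i(t) ~ (U_i(t+dt) - U_i(t))/dt + eta1 * V_i(t), averaged over steps and
    components.  This is how the auxiliary moment is obtained from fine-scale
    data, where Z is not observable.
    """
    traj.require_steps(1, "z2 estimation")
    cut = traj.burned(burn_in)
    dudt = np.diff(cut.U, axis=0) / cut.dt
    return float(np.mean((dudt + eta1 * cut.V[:-1]) ** 2))


def msd(traj: Trajectory, lags: np.ndarray) -> np.ndarray:
    """Component-averaged, time-origin-averaged MSD at integer step lags."""
    lags = np.asarray(lags, dtype=np.int64)
    if np.any(lags < 1) or np.any(lags >= len(traj)):
        raise ValueError("lags must lie in [1, n_steps]")
    return _kernels.msd_curve(np.ascontiguousarray(traj.X), lags)


def estimate_D_from_msd_curve(t: np.ndarray, msd_values: np.ndarray) -> float:
    """Least-squares slope of an MSD curve divided by 2 (free-diffusion law 2Dt)."""
    t = np.asarray(t, dtype=float)
    msd_values = np.asarray(msd_values, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 points to fit an MSD slope")
    slope = np.polyfit(t, msd_values, 1)[0]
    return float(slope / 2.0)


def estimate_D_msd(
    traj: Trajectory,
    fit_window: tuple[float, float] = (1.0, 5.0),
    n_lags: int = 40,
) -> float:
    """Estimate the diffusion constant from the MSD slope over a time window.

    The window should start late enough for the velocity relaxation
    transients to have decayed (the slowest CG relaxation rates are
    ~12 ps^-1, so the default 1 ps lower edge is conservative).
    """
    t_lo, t_hi = fit_window
    span = traj.n_steps * traj.dt
    if not 0 < t_lo < t_hi:
        raise ValueError(f"invalid fit window {fit_window}")
    if t_hi > span:
        raise TrajectoryTooShortError(
            f"trajectory too short for MSD window: spans {span} ps, window ends {t_hi} ps"
        )
    lags = np.unique(
        np.linspace(t_lo / traj.dt, t_hi / traj.dt, n_lags).round().astype(np.int64)
    )
    if len(lags) < 2:
        raise TrajectoryTooShortError("fewer than 2 usable lags in the MSD window")
    curve = msd(traj, lags)
    return estimate_D_from_msd_curve(lags * traj.dt, curve)


@dataclass
class JerkMap:
    """Binned conditional mean of the jerk (U(t+dt)-U(t))/dt given (V(t), U(t)).

    ``mean_jerk[a, b]`` is the average jerk in velocity bin ``a`` and
    acceleration bin ``b``; cells with ``counts == 0`` hold NaN and are
    excluded from the profiles.  ``J1`` is the slice through the u-bin
    containing zero (jerk at the most likely acceleration); ``J2`` is the
    occupancy-weighted average over u per velocity bin.
    """

    v_bin_edges: np.ndarray
    u_bin_edges: np.ndarray
    mean_jerk: np.ndarray
    counts: np.ndarray
    J1: np.ndarray
    J2: np.ndarray

    @property
    def v_centers(self) -> np.ndarray:
        return 0.5 * (self.v_bin_edges[:-1] + self.v_bin_edges[1:])


def jerk_map(
    traj: Trajectory,
    v_bins: int | np.ndarray = 40,
    u_bins: int | np.ndarray = 40,
    bin_half_width_sigmas: float = 4.0,
) -> JerkMap:
    """Estimate the conditional mean jerk from a trajectory.

    Integer bin arguments request uniform grids spanning +-4 sample standard
    deviations of V and U; explicit edge arrays are used as given.
    """
    traj.require_steps(1, "jerk map")
    v = traj.V[:-1].ravel()
    u = traj.U[:-1].ravel()
    jerk = (np.diff(traj.U, axis=0) / traj.dt).ravel()

    def edges(arg, data):
        if np.ndim(arg) == 0:
            half = bin_half_width_sigmas * np.sqrt(np.mean(data**2))
            if half == 0:
                raise ValueError("degenerate bin grid: data has zero variance")
            return np.linspace(-half, half, int(arg) + 1)
        e = np.asarray(arg, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("degenerate bin grid: edges must be increasing")
        return e

    v_edges = edges(v_bins, v)
    u_edges = edges(u_bins, u)
    sums, _, _, _ = sp_stats.binned_statistic_2d(
        v, u, jerk, statistic="sum", bins=(v_edges, u_edges)
    )
    counts, _, _, _ = sp_stats.binned_statistic_2d(
        v, u, None, statistic="count", bins=(v_edges, u_edges)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
        row_counts = counts.sum(axis=1)
        J2 = np.where(row_counts > 0, sums.sum(axis=1) / row_counts, np.nan)
    u_zero_bin = np.clip(np.searchsorted(u_edges, 0.0) - 1, 0, len(u_edges) - 2)
    J1 = mean[:, u_zero_bin]
    return JerkMap(
        v_bin_edges=v_edges,
        u_bin_edges=u_edges,
        mean_jerk=mean,
        counts=counts.astype(np.int64),
        J1=J1,
        J2=J2,
    )


def jerk_slope(jm: JerkMap, min_count: int = 10) -> tuple[float, float, float]:
    """Occupancy-weighted linear regression of J2(v) on v.

    Returns (slope, intercept, r_squared).  For the CG model the conditional
    mean jerk is exactly -eta1 * v, independent of u.
    """
    w = jm.counts.sum(axis=1).astype(float)
    keep = (w >= min_count) & np.isfinite(jm.J2)
    if keep.sum() < 2:
        raise ValueError("too few occupied velocity bins for a jerk regression")
    v = jm.v_centers[keep]
    y = jm.J2[keep]
    w = w[keep]
    W = np.diag(w)
    A = np.column_stack([v, np.ones_like(v)])
    coef = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
    resid = y - A @ coef
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(coef[0]), float(coef[1]), r2


def langevin_moment_check(stats: MDMomentStats, dt: float) -> float:
    """Second moment of the discretized Langevin acceleration [A^2 ps^-4].

    A Langevin model matched to the same D and <V^2> has one-step
    acceleration second moment

        (<V^2>)^3 / D^2 + 2 (<V^2>)^2 / (D * dt),

    which at fine-scale timesteps is orders of magnitude larger than the
    observed <U^2> -- the quantitative reason the CG model carries an
    auxiliary variable instead of white-noise forcing on the velocity.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return stats.v2**3 / stats.D**2 + 2.0 * stats.v2**2 / (stats.D * dt)
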