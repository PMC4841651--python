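"""Fictitious-particle generalizations of the coarse-grained ion model.

N fictitious particles, each harmonically coupled to the ion, damped and
driven by independent noise, generate non-Markovian velocity dynamics:

    dX_i      = V_i dt
    dV_i      = sum_j alpha_{j,1} (Xt_{j,i} - X_i) dt
    dXt_{j,i} = Vt_{j,i} dt
    dVt_{j,i} = -(alpha_{j,2} Vt_{j,i} + alpha_{j,3} (Xt_{j,i} - X_i)) dt
                + alpha_{j,4} dW_{j,i}

In the variables Ut_j = alpha_{j,1}(Xt_j - X), Zt_j = alpha_{j,1} Vt_j the
system is linear with a (2N+1)-dimensional drift per component, and for N=1
it reduces exactly to the CG model under eta1 = alpha_{1,1},
eta2 = alpha_{1,2}, eta3 = alpha_{1,3}, eta4 = alpha_{1,1} alpha_{1,4}.
The extra parameters for N >= 2 buy freedom to fit the shape of the velocity
autocorrelation function (VACF) while three moment constraints (D, <V^2>,
<U^2>) pin the model to the fine-scale statistics; the fit itself is a
constrained acceptance-rejection random search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.optimize import root

from . import _kernels
from .errors import (
    DegenerateSpectrumError,
    InvalidStatisticsError,
    IonscaleError,
    NumericalBlowupError,
    UnstableModelError,
)
from .params import CGParams
from .trajectory import Trajectory

__all__ = [
    "FictitiousParams",
    "ExtendedDrift",
    "build_extended",
    "stationary_covariance",
    "moments_fp",
    "vacf_fp",
    "diffusion_fp",
    "cg_to_fp",
    "fp_to_cg",
    "simulate_fp",
    "project_to_constraints",
    "VACFFitResult",
    "fit_vacf",
]


@dataclass(frozen=True)
class FictitiousParams:
    """Coefficients of N fictitious particles, one row (a1, a2, a3, a4) each.

    Units: a1 [ps^-2], a2 [ps^-1], a3 [ps^-2], a4 [A ps^-3/2].  All entries
    must be strictly positive; stability of the assembled drift is checked
    separately by :func:`build_extended`.
    """

    alpha: np.ndarray

    def __post_init__(self):
        alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if alpha.ndim != 2 or alpha.shape[1] != 4 or alpha.shape[0] < 1:
            raise InvalidStatisticsError(
                f"alpha must have shape (N, 4) with N >= 1, got {alpha.shape}"
            )
        if not np.all(alpha > 0) or not np.all(np.isfinite(alpha)):
            raise InvalidStatisticsError(
                "invalid parameters: all fictitious-particle coefficients must be positive"
            )
        object.__setattr__(self, "alpha", alpha)

    @property
    def N(self) -> int:
        return self.alpha.shape[0]


@dataclass(frozen=True)
class ExtendedDrift:
    """Extended drift in coordinates (V, Ut_1, Zt_1, ..., Ut_N, Zt_N).

    ``G`` is the (2N+1) x N noise-loading matrix: channel j enters the Zt_j
    row with coefficient alpha_{j,1} alpha_{j,4}.
    """

    B: np.ndarray
    G: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def N(self) -> int:
        return (self.B.shape[0] - 1) // 2

    @property
    def u_indices(self) -> np.ndarray:
        return 1 + 2 * np.arange(self.N)


def build_extended(
    fp: FictitiousParams, degeneracy_rtol: float = 1e-6, check_spectrum: bool = True
) -> ExtendedDrift:
    """Assemble the (2N+1)-dimensional drift and verify stability.

    Raises :class:`UnstableModelError` for a non-negative real part and
    :class:`DegenerateSpectrumError` for (numerically) repeated eigenvalues,
    both assumptions of the eigen-expansion analysis.
    """
    N = fp.N
    dim = 2 * N + 1
    B = np.zeros((dim, dim))
    G = np.zeros((dim, N))
    for j in range(N):
        a1, a2, a3, a4 = fp.alpha[j]
        iu, iz = 1 + 2 * j, 2 + 2 * j
        B[0, iu] = 1.0          # dV = sum_j Ut_j
        B[iu, 0] = -a1          # dUt_j = Zt_j - a1 V
        B[iu, iz] = 1.0
        B[iz, iu] = -a3         # dZt_j = -a2 Zt_j - a3 Ut_j + a1 a4 dW_j
        B[iz, iz] = -a2
        G[iz, j] = a1 * a4
    lam, vec = np.linalg.eig(B)
    order = np.argsort(lam.real)
    lam, vec = lam[order], vec[:, order]
    if check_spectrum:
        if np.any(lam.real >= 0):
            raise UnstableModelError(
                f"extended drift is not stable: eigenvalues {lam}"
            )
        span = np.max(np.abs(lam))
        for i in range(dim):
            for j in range(i + 1, dim):
                if abs(lam[i] - lam[j]) < degeneracy_rtol * span:
                    raise DegenerateSpectrumError(
                        f"degenerate spectrum: {lam[i]} and {lam[j]} coincide"
                    )
    return ExtendedDrift(B=B, G=G, eigenvalues=lam, eigenvectors=vec)


def stationary_covariance(ed: ExtendedDrift) -> np.ndarray:
    """Stationary covariance S of the extended system: B S + S B^T = -G G^T."""
    if np.any(ed.eigenvalues.real >= 0):
        raise UnstableModelError("no stationary covariance: drift is not stable")
    S = solve_continuous_lyapunov(ed.B, -ed.G @ ed.G.T)
    return 0.5 * (S + S.T)


def moments_fp(fp: FictitiousParams) -> tuple[float, float, float]:
    """Diffusion constant, <V^2> and <U^2> of a fictitious-particle model.

    <V^2> is the (V, V) entry of the stationary covariance; <U^2> is the
    stationary second moment of dV/dt = sum_j Ut_j, i.e. the full Ut-block
    covariance sum; D is the Green-Kubo integral in closed form,
    -e1^T B^-1 S e1.
    """
    ed = build_extended(fp, check_spectrum=False)
    if np.any(ed.eigenvalues.real >= 0):
        raise UnstableModelError("moments undefined: drift is not stable")
    S = stationary_covariance(ed)
    v2 = float(S[0, 0])
    iu = ed.u_indices
    u2 = float(S[np.ix_(iu, iu)].sum())
    D = float(-np.linalg.solve(ed.B, S[:, 0])[0])
    return D, v2, u2


def vacf_fp(fp: FictitiousParams, t_grid: np.ndarray) -> np.ndarray:
    """Analytic VACF: C(t) = e1^T exp(B t) S e1 with S the stationary covariance."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be non-negative")
    ed = build_extended(fp, check_spectrum=False)
    if np.any(ed.eigenvalues.real >= 0):
        raise UnstableModelError("VACF undefined: drift is not stable")
    s0 = stationary_covariance(ed)[:, 0]
    lam, P = np.linalg.eig(ed.B)
    w = P[0, :] * np.linalg.solve(P, s0.astype(complex))
    return (w[None, :] * np.exp(np.outer(t_grid, lam))).sum(axis=1).real


def _vacf_expm(fp: FictitiousParams, t_grid: np.ndarray) -> np.ndarray:
    """Matrix-exponential route to the VACF (reference for near-degenerate spectra)."""
    ed = build_extended(fp, check_spectrum=False)
    s0 = stationary_covariance(ed)[:, 0]
    return np.array([(expm(ed.B * t) @ s0)[0] for t in np.asarray(t_grid, float)])


def diffusion_fp(fp: FictitiousParams) -> float:
    """Green-Kubo diffusion constant, closed form: D = -e1^T B^-1 S e1."""
    return moments_fp(fp)[0]


def cg_to_fp(cg: CGParams) -> FictitiousParams:
    """The N=1 fictitious-particle model equivalent to a CG parameter set:
    alpha = (eta1, eta2, eta3, eta4/eta1)."""
    e1, e2, e3, e4 = cg.as_tuple()
    return FictitiousParams(alpha=np.array([[e1, e2, e3, e4 / e1]]))


def fp_to_cg(fp: FictitiousParams) -> CGParams:
    """Inverse of :func:`cg_to_fp`; defined only for N = 1."""
    if fp.N != 1:
        raise IonscaleError(f"fp_to_cg requires N=1, got N={fp.N}")
    a1, a2, a3, a4 = fp.alpha[0]
    return CGParams(eta1=a1, eta2=a2, eta3=a3, eta4=a1 * a4)


def simulate_fp(
    fp: FictitiousParams,
    init: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
    dt: float = 1e-3,
    n_steps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Trajectory, np.ndarray, np.ndarray]:
    """Euler-Maruyama simulation of the fictitious-particle model.

    ``init`` is (X, V, Ut, Zt) with Ut, Zt of shape (N, 3); default zero.
    Noise is drawn in one block of shape (n_steps, N, 3), so for N=1 the
    stream coincides element-for-element with :func:`ionscale.cg.simulate_cg`
    under the same seed and the two models produce identical paths.

    Returns (trajectory, Ut_series, Zt_series); the trajectory's U and Z
    columns hold the per-particle sums (the ion's acceleration and its
    derivative's stochastic part).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    N = fp.N
    if init is None:
        init = (np.zeros(3), np.zeros(3), np.zeros((N, 3)), np.zeros((N, 3)))
    x0, v0, ut0, zt0 = (np.asarray(a, dtype=float) for a in init)
    if ut0.shape != (N, 3) or zt0.shape != (N, 3):
        raise ValueError(f"auxiliary init must have shape ({N}, 3)")
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, N, 3))
    X, V, Ut, Zt, bad = _kernels.fp_path(fp.alpha, float(dt), noise, x0, v0, ut0, zt0)
    if bad >= 0:
        raise NumericalBlowupError(
            f"numerical blow-up at step {bad} (dt={dt})", step=bad
        )
    traj = Trajectory(
        dt=float(dt), X=X, V=V, U=Ut.sum(axis=1), Z=Zt.sum(axis=1), seed=seed
    )
    return traj, Ut, Zt


# ---------------------------------------------------------------------------
# constrained VACF fitting


def _scaled(fp: FictitiousParams, lc: float, lt: float, lk: float) -> FictitiousParams:
    """Apply the three closed-form scaling knobs in log space.

    exp(lt) dilates time: under V'(t) = V(t/tau) the coefficients map as
    a1, a3 ~ tau^-2, a2 ~ tau^-1, a4 ~ tau^-1/2 and the moments as
    v2' = v2, u2' = u2/tau^2, D' = tau*D.  exp(lc) scales every noise
    amplitude a4 jointly (all three moments ~ exp(2*lc)) and exp(lk) scales
    every restoring coefficient a3 jointly (no closed form; resolved by the
    projection root solve).
    """
    tau = np.exp(lt)
    alpha = fp.alpha.copy()
    alpha[:, 0] /= tau**2
    alpha[:, 1] /= tau
    alpha[:, 2] *= np.exp(lk) / tau**2
    alpha[:, 3] *= np.exp(lc) / np.sqrt(tau)
    return FictitiousParams(alpha=alpha)


def project_to_constraints(
    fp: FictitiousParams,
    constraints: tuple[float, float, float],
    tol: float = 1e-10,
) -> FictitiousParams:
    """Rescale a parameter set so its (D, <V^2>, <U^2>) match ``constraints``.

    Solves for three joint scale factors -- a global time dilation, a joint
    noise-amplitude factor and a joint restoring-force factor -- whose action
    on the moments is smooth and, near the identity, invertible.  Raises
    :class:`IonscaleError` if the root solve fails or leaves the stable set.
    """
    D_t, v2_t, u2_t = constraints
    if min(D_t, v2_t, u2_t) <= 0:
        raise ValueError("constraints (D, v2, u2) must be positive")

    def residual(knobs):
        try:
            D, v2, u2 = moments_fp(_scaled(fp, *knobs))
        except (UnstableModelError, InvalidStatisticsError):
            return np.array([10.0, 10.0, 10.0])
        return np.log([D / D_t, v2 / v2_t, u2 / u2_t])

    sol = root(residual, x0=np.zeros(3), method="hybr", tol=1e-12)
    # judge by the residual itself: the solver may flag "no progress" when
    # the start is already (numerically) on the constraint manifold
    for knobs in (sol.x, np.zeros(3)):
        if np.max(np.abs(residual(knobs))) <= tol:
            return _scaled(fp, *knobs)
    raise IonscaleError(
        "constraint projection failed: no nearby parameter scaling matches "
        "the target (D, v2, u2)"
    )


def _default_init(
    constraints: tuple[float, float, float],
    N: int,
    rng: np.random.Generator,
) -> FictitiousParams:
    """Stable constraint-satisfying starting point for the fit.

    Embeds the CG model matched to (D, v2, u2) (with a heuristic auxiliary
    moment) as particle 1 and adds N-1 weakly coupled particles with spread
    frequencies, then projects back onto the constraints.
    """
    D, v2, u2 = constraints
    eta1 = u2 / v2
    z2 = 3.0 * u2**2 / v2  # free choice: sets eta3 = 3*eta1, a stable regime
    eta3 = z2 / u2
    eta2 = (z2 / D) * (v2 / u2) ** 2
    eta4 = np.sqrt(2.0 * eta2 * z2)
    rows = [np.array([eta1, eta2, eta3, eta4 / eta1])]
    for j in range(1, N):
        scale = 0.5 ** j * (1.0 + 0.1 * rng.standard_normal())
        rows.append(
            np.abs(
                np.array(
                    [eta1 * scale, eta2 * (0.7**j), eta3 * scale, 0.05 * eta4 / eta1]
                )
                * (1.0 + 0.05 * rng.standard_normal(4))
            )
        )
    fp = FictitiousParams(alpha=np.vstack(rows))
    return project_to_constraints(fp, constraints)


@dataclass
class VACFFitResult:
    """Outcome of the acceptance-rejection VACF fit."""

    fp: FictitiousParams
    error: float
    error_trace: np.ndarray
    n_accepted: int
    n_iterations: int
    c0: float = field(default=float("nan"))


def _l1_error(t: np.ndarray, model_C: np.ndarray, target_C: np.ndarray) -> float:
    return float(np.trapezoid(np.abs(model_C - target_C), t))


def fit_vacf(
    target_t: np.ndarray,
    target_C: np.ndarray,
    constraints: tuple[float, float, float],
    N: int = 3,
    seed: int | None = None,
    max_iter: int = 3000,
    init_fp: FictitiousParams | None = None,
    sigma0: float = 0.05,
    anneal_after: int = 50,
    sigma_min: float = 1e-3,
) -> VACFFitResult:
    """Constrained acceptance-rejection fit of a fictitious-particle VACF.

    Starting from a stable, constraint-satisfying guess, each iteration
    perturbs all 4N coefficients log-normally (step ``sigma0``, halved after
    ``anneal_after`` consecutive rejections), projects the perturbed set back
    onto the (D, <V^2>, <U^2>) constraints with the closed-form scalings, and
    accepts it iff the trapezoidal L1 distance between the model VACF and the
    target (on the target's own grid) decreases.  The returned error trace is
    therefore non-increasing, and every accepted iterate satisfies the
    constraints to the projection tolerance.
    """
    target_t = np.asarray(target_t, dtype=float)
    target_C = np.asarray(target_C, dtype=float)
    if target_t.ndim != 1 or target_t.shape != target_C.shape:
        raise ValueError("target grid and values must be matching 1-D arrays")
    if np.any(np.diff(target_t) <= 0):
        raise ValueError("target grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    if init_fp is None:
        current = _default_init(constraints, N, rng)
    else:
        if init_fp.N != N:
            raise ValueError(f"init_fp has N={init_fp.N}, expected {N}")
        current = project_to_constraints(init_fp, constraints)
    current_err = _l1_error(target_t, vacf_fp(current, target_t), target_C)
    trace = [current_err]
    sigma = sigma0
    rejections = 0
    accepted = 0
    for _ in range(max_iter):
        proposal = FictitiousParams(
            alpha=current.alpha * np.exp(sigma * rng.standard_normal(current.alpha.shape))
        )
        try:
            proposal = project_to_constraints(proposal, constraints)
            build_extended(proposal)  # reject unstable / degenerate spectra
            err = _l1_error(target_t, vacf_fp(proposal, target_t), target_C)
        except IonscaleError:
            err = np.inf
        if err < current_err:
            current, current_err = proposal, err
            accepted += 1
            rejections = 0
        else:
            rejections += 1
            if rejections >= anneal_after:
                sigma = max(sigma * 0.5, sigma_min)
                rejections = 0
        trace.append(current_err)
    return VACFFitResult(
        fp=current,
        error=current_err,
        error_trace=np.asarray(trace),
        n_accepted=accepted,
        n_iterations=max_iter,
        c0=float(target_C[0]),
    )
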