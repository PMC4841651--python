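"""Brownian dynamics, the nested-region geometry and hybrid CG/BD experiments.

The multiscale scheme tiles space with five nested sup-norm boxes
Omega_1..Omega_5: a fine-scale core Omega_1 (side L), a hand-shaking shell
Omega_2 (width L/(2*omega), over which fine-scale feedback forces are
attenuated with distance), a CG shell Omega_3 (width h1), a CG/BD overlap
shell Omega_4 (width h2) and the unbounded BD exterior Omega_5.  The CG model
is active in Omega_2..Omega_4 and hands over to position-only Brownian
dynamics once the ion enters Omega_5; BD hands back when the ion re-enters
Omega_3, at which point the unobserved (V, U, Z) block is re-initialized
(zero by default, or drawn from the stationary law).  Hysteresis across the
overlap shells prevents switch chatter.

Two validation experiments accompany the machinery: a planar half-space
CG/BD coupling test against the exact image-sum Gaussian density, and the
first-passage ("escape-time") experiment through the full five-region
decomposition against the Brownian mean r^2/(6D).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from . import _kernels
from .cg import CGState, cg_step, sample_stationary, stationary_std
from .errors import IonscaleError
from .params import CGParams

__all__ = [
    "BDParams",
    "RegionDecomposition",
    "HalfspaceDecomposition",
    "HybridParticle",
    "bd_step",
    "analytic_halfspace_density",
    "classify_region",
    "box_distance",
    "attenuated_distance_args",
    "hybrid_step_cg_bd",
    "HalfspaceResult",
    "run_halfspace_experiment",
    "escape_theory",
    "EscapeTheory",
    "EscapeResult",
    "escape_time_experiment",
]


@dataclass(frozen=True)
class BDParams:
    """Brownian-dynamics parameters: diffusion constant and timestep.

    The BD timestep is meant to be orders of magnitude larger than the CG
    one; the default 0.5 ps matches the validation experiments (any larger
    value also works for pure diffusion).
    """

    D: float
    dT: float = 0.5

    def __post_init__(self):
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not self.dT > 0:
            raise ValueError(f"dT must be positive, got {self.dT}")
        if self.dT < 0.1:
            warnings.warn(
                f"BD timestep {self.dT} ps is unusually small; "
                "BD is intended for timesteps >> the CG timestep",
                stacklevel=2,
            )


def bd_step(X: np.ndarray, bd: BDParams, noise: np.ndarray) -> np.ndarray:
    """One BD step: X' = X + sqrt(2 D dT) * noise, per component."""
    X = np.asarray(X, dtype=float)
    noise = np.asarray(noise, dtype=float)
    return X + math.sqrt(2.0 * bd.D * bd.dT) * noise


def analytic_halfspace_density(x1, t: float, D: float, h: float, n_total: float):
    """Exact marginal density (per A) for n_total Brownian walkers released
    in equal halves from +-h at time 0:

        rho(x1) = n_total / sqrt(4 pi D t) * [exp(-(x1-h)^2/4Dt) + exp(-(x1+h)^2/4Dt)] / 2
    """
    if not t > 0:
        raise ValueError(f"t must be positive, got {t}")
    x1 = np.asarray(x1, dtype=float)
    s2 = 4.0 * D * t
    norm = n_total / (2.0 * np.sqrt(np.pi * s2))
    return norm * (np.exp(-((x1 - h) ** 2) / s2) + np.exp(-((x1 + h) ** 2) / s2))


def _halfspace_bin_masses(edges, t, D, h, n_total):
    """Expected walker counts per histogram bin (exact Gaussian integrals)."""
    s = math.sqrt(4.0 * D * t)
    cdf = lambda c: 0.5 * (1.0 + erf((edges - c) / s))
    mass = 0.5 * n_total * (np.diff(cdf(h)) + np.diff(cdf(-h)))
    return mass


@dataclass(frozen=True)
class RegionDecomposition:
    """Nested-box decomposition Omega_1..Omega_5 of R^3.

    Parameters: inner box side ``L`` [A], attenuation parameter ``omega``
    (the hand-shaking shell has width L/(2*omega)), and shell widths ``h1``
    (CG shell) and ``h2`` (CG/BD overlap), which default to L/20 and L/10.
    Inner boxes are closed: boundary points belong to the inner region.
    """

    L: float
    omega: float = 10.0
    h1: float = None
    h2: float = None

    def __post_init__(self):
        if not self.L > 0 or not self.omega > 0:
            raise ValueError("L and omega must be positive")
        if self.h1 is None:
            object.__setattr__(self, "h1", self.L / 20.0)
        if self.h2 is None:
            object.__setattr__(self, "h2", self.L / 10.0)
        if not self.h1 > 0 or not self.h2 > 0:
            raise ValueError("shell widths h1 and h2 must be positive")

    @property
    def half_sides(self) -> tuple[float, float, float, float]:
        """Half-sides of the outer boundaries of Omega_1..Omega_4."""
        r1 = self.L / 2.0
        r2 = r1 + self.L / (2.0 * self.omega)
        r3 = r2 + self.h1
        r4 = r3 + self.h2
        return (r1, r2, r3, r4)

    def shell_volume(self, region: int) -> float:
        """Volume of Omega_region for region 1..4 (Omega_5 is unbounded)."""
        r = (0.0,) + self.half_sides
        if not 1 <= region <= 4:
            raise ValueError("finite volumes exist for regions 1..4 only")
        return (2.0 * r[region]) ** 3 - (2.0 * r[region - 1]) ** 3


@dataclass(frozen=True)
class HalfspaceDecomposition:
    """Planar analogue of the region decomposition used by the half-space test.

    The CG model is active for x1 > -h (switching to BD at x1 <= -h) and BD
    for x1 < h (switching back at x1 >= h); the slab (-h, h) is the overlap.
    """

    h: float = 1.0

    def __post_init__(self):
        if not self.h > 0:
            raise ValueError("h must be positive")


def classify_region(X, dec: RegionDecomposition):
    """Region id in {1..5} of point(s) X (sup-norm nesting, closed inner boxes)."""
    X = np.asarray(X, dtype=float)
    sup = np.max(np.abs(X), axis=-1)
    r1, r2, r3, r4 = dec.half_sides
    region = np.select([sup <= r1, sup <= r2, sup <= r3, sup <= r4], [1, 2, 3, 4], 5)
    return region if region.ndim else int(region)


def box_distance(X, dec: RegionDecomposition):
    """Euclidean distance from X to the closed inner box Omega_1 (0 inside)."""
    X = np.asarray(X, dtype=float)
    excess = np.maximum(np.abs(X) - dec.L / 2.0, 0.0)
    return np.sqrt(np.sum(excess**2, axis=-1))


def attenuated_distance_args(
    r: float, X, dec: RegionDecomposition, cutoff: float | None = None
) -> tuple[float, bool]:
    """Distance-attenuation rule for fine-scale feedback forces.

    When the ion sits outside the fine-scale core, interaction distances are
    inflated by omega * dist(X, Omega_1), which continuously switches the
    feedback force off; once the inflation reaches the interaction cutoff
    (default L/2) the force is identically zero.  Returns the attenuated
    distance and the beyond-cutoff flag.
    """
    if r < 0:
        raise ValueError("distance r must be non-negative")
    if cutoff is None:
        cutoff = dec.L / 2.0
    shift = dec.omega * float(box_distance(X, dec))
    return r + shift, bool(shift >= cutoff)


@dataclass
class HybridParticle:
    """Per-particle bookkeeping for the hybrid stepper.

    ``tag`` is one of "fine", "cg", "bd"; the (V, U, Z) block is carried only
    while a detailed description is active.
    """

    X: np.ndarray
    tag: str = "cg"
    V: np.ndarray | None = None
    U: np.ndarray | None = None
    Z: np.ndarray | None = None
    t: float = 0.0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float).reshape(3)
        if self.tag not in ("fine", "cg", "bd"):
            raise ValueError(f"unknown tag {self.tag!r}")
        if self.tag == "bd":
            self.V = self.U = self.Z = None
        else:
            for name in ("V", "U", "Z"):
                value = getattr(self, name)
                setattr(
                    self,
                    name,
                    np.zeros(3) if value is None else np.asarray(value, float).reshape(3),
                )


def _reinit_aux(p: HybridParticle, cg: CGParams, policy: str, rng) -> None:
    if policy == "zero":
        p.V, p.U, p.Z = np.zeros(3), np.zeros(3), np.zeros(3)
    elif policy == "stationary":
        p.V, p.U, p.Z = sample_stationary(cg, rng=rng)
    else:
        raise ValueError(f"unknown init policy {policy!r}; use 'zero' or 'stationary'")


def hybrid_step_cg_bd(
    p: HybridParticle,
    cg: CGParams,
    bd: BDParams,
    dt: float,
    dec: RegionDecomposition | HalfspaceDecomposition,
    rng: np.random.Generator,
    init_policy: str = "zero",
) -> HybridParticle:
    """Advance one particle by one step of whichever model is active.

    A CG particle takes one Euler-Maruyama step of length ``dt``; a BD
    particle takes one step of length ``bd.dT``.  Switching is detected on
    the post-step position ("until it enters" semantics): CG drops to BD on
    entering the BD-only region, BD returns to CG on entering the CG-only
    region, and the overlap keeps the current description.  The step length
    sqrt(2 D dT) is small compared with the shell widths, so no crossing-time
    interpolation is attempted.
    """
    if p.tag == "fine":
        raise IonscaleError(
            "hybrid_step_cg_bd does not integrate the fine model; "
            "use escape_time_experiment with a fine-model plug-in"
        )
    planar = isinstance(dec, HalfspaceDecomposition)
    if p.tag == "cg":
        state = cg_step(CGState(p.t, p.X, p.V, p.U, p.Z), cg, dt, rng.standard_normal(3))
        p.X, p.V, p.U, p.Z, p.t = state.X, state.V, state.U, state.Z, state.t
        entered_bd = (p.X[0] <= -dec.h) if planar else (classify_region(p.X, dec) == 5)
        if entered_bd:
            p.tag = "bd"
            p.V = p.U = p.Z = None
    else:
        p.X = bd_step(p.X, bd, rng.standard_normal(3))
        p.t += bd.dT
        entered_cg = (p.X[0] >= dec.h) if planar else (classify_region(p.X, dec) <= 3)
        if entered_cg:
            p.tag = "cg"
            _reinit_aux(p, cg, init_policy, rng)
    return p


@dataclass
class HalfspaceResult:
    """Histogram of final x1 positions with the matching analytic expectation."""

    bin_edges: np.ndarray
    counts: np.ndarray
    expected: np.ndarray
    n_particles: int
    t_end: float
    x1: np.ndarray = field(repr=False, default=None)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def run_halfspace_experiment(
    cg: CGParams,
    bd: BDParams,
    h: float = 1.0,
    n_particles: int = 10_000,
    t_end: float = 1_000.0,
    bin_width: float = 2.0,
    seed: int | None = None,
    dt: float = 1e-3,
    init_policy: str = "zero",
) -> HalfspaceResult:
    """Half-space CG/BD coupling test against the exact Brownian density.

    ``n_particles`` walkers (must be even) start in equal halves at
    (+-h, 0, 0); the +h half under the CG description with zero auxiliary
    state, the -h half under BD.  Each is evolved to ``t_end`` with the
    hybrid switching rule and the final x1 marginal is histogrammed in bins
    of ``bin_width`` alongside the exact free-diffusion expectation.

    Only the first coordinate is simulated: the CG components are mutually
    independent and the planar switching rule depends on x1 alone, so the
    x1 marginal of the full 3-D hybrid process is exactly the process
    simulated here.
    """
    if n_particles % 2:
        raise ValueError("n_particles must be even")
    if init_policy not in ("zero", "stationary"):
        raise ValueError(f"unknown init policy {init_policy!r}")
    if t_end == 0:
        # degenerate run: everything still sits at the release points
        edges = np.array([-h - bin_width, -h, -h + bin_width, h, h + bin_width])
        edges = np.unique(edges)
        x1 = np.repeat([h, -h], n_particles // 2).astype(float)
        counts, edges = np.histogram(x1, bins=edges)
        expected = counts.astype(float)
        return HalfspaceResult(
            bin_edges=edges, counts=counts, expected=expected,
            n_particles=n_particles, t_end=0.0, x1=x1,
        )
    n_micro_per_bd = int(round(bd.dT / dt))
    if not math.isclose(n_micro_per_bd * dt, bd.dT, rel_tol=1e-9):
        raise ValueError("bd.dT must be an integer multiple of dt")
    n_micro_total = int(round(t_end / dt))
    if not math.isclose(n_micro_total * dt, t_end, rel_tol=1e-9):
        raise ValueError("t_end must be an integer multiple of dt")
    rng = np.random.default_rng(seed)
    sv, su, sz = stationary_std(cg)
    x1 = _kernels.halfspace_kernel(
        *cg.as_tuple(),
        bd.D,
        h,
        dt,
        n_micro_per_bd,
        n_micro_total,
        n_particles,
        init_policy == "stationary",
        sv,
        su,
        sz,
        rng,
    )
    # bin edges congruent to -h modulo bin_width, so that the overlap slab
    # [-h, h] is exactly one bin when bin_width = 2h
    lo_edge = -h - bin_width * math.ceil((-h - float(np.min(x1))) / bin_width + 1e-12)
    hi_edge = -h + bin_width * math.ceil((float(np.max(x1)) + h) / bin_width + 1e-12)
    edges = np.arange(lo_edge, hi_edge + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(x1, bins=edges)
    expected = _halfspace_bin_masses(edges, t_end, bd.D, h, n_particles)
    return HalfspaceResult(
        bin_edges=edges,
        counts=counts,
        expected=expected,
        n_particles=n_particles,
        t_end=t_end,
        x1=x1,
    )


def bd_first_passage_times(
    D: float,
    r: float,
    n_realizations: int,
    dT: float = 0.5,
    seed: int | None = None,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """First-passage times of pure BD walkers from the origin to distance r.

    Independent reference for the escape-time experiment: no model switching,
    just the discretized Brownian walk, vectorized over realizations.
    """
    rng = np.random.default_rng(seed)
    X = np.zeros((n_realizations, 3))
    T = np.full(n_realizations, np.nan)
    alive = np.ones(n_realizations, dtype=bool)
    amp = math.sqrt(2.0 * D * dT)
    for k in range(1, max_steps + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        X[idx] += amp * rng.standard_normal((idx.size, 3))
        crossed = idx[np.linalg.norm(X[idx], axis=1) >= r]
        T[crossed] = k * dT
        alive[crossed] = False
    return T


@dataclass(frozen=True)
class EscapeTheory:
    mean: float
    sd: float
    ci95: tuple[float, float]


def escape_theory(D: float, r: float, n_samples: int = 100) -> EscapeTheory:
    """Brownian first-passage statistics to distance r from the origin.

    The escape time of a 3-D Brownian motion has mean r^2/(6D) and standard
    deviation r^2/(3*sqrt(10)*D); the 95% confidence interval reported is for
    the mean of ``n_samples`` independent realizations.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    if not D > 0:
        raise ValueError("D must be positive")
    mean = r**2 / (6.0 * D)
    sd = r**2 / (3.0 * math.sqrt(10.0) * D)
    half = 1.96 * sd / math.sqrt(n_samples)
    return EscapeTheory(mean=mean, sd=sd, ci95=(mean - half, mean + half))


@dataclass
class EscapeResult:
    """Per-realization first-passage records T(r) on a fixed grid of radii."""

    r_grid: np.ndarray
    T: np.ndarray  # (n_realizations, len(r_grid)); NaN where truncated
    truncated: np.ndarray

    def mean_T(self) -> np.ndarray:
        return np.nanmean(self.T, axis=0)


def escape_time_experiment(
    dec: RegionDecomposition,
    cg: CGParams,
    bd: BDParams,
    r_max: float,
    n_realizations: int = 100,
    seed: int | None = None,
    dt: float = 1e-3,
    fine_model: CGParams | None = None,
    r_grid: np.ndarray | None = None,
    init_policy: str = "zero",
    max_steps: int = 2_000_000_000,
) -> EscapeResult:
    """First-passage times through the five-region multiscale scheme.

    Each realization starts at the origin with a stationary (V, U, Z) draw
    and is evolved with the fine stand-in in Omega_1 u Omega_2, the CG model
    in Omega_3 u Omega_4 and BD in Omega_5 (hysteretic hand-shaking in the
    overlap shells), until its distance from the origin first reaches every
    radius of ``r_grid`` (default: 40 uniform radii from L/10 to ``r_max``).
    Times are recorded at the end of the step that first crosses each radius.

    ``fine_model`` is the parameter set of the fine-scale stand-in; by
    default the CG parameters themselves (the surrogate configuration used
    for validation, where the whole detailed region follows one model).
    """
    if init_policy not in ("zero", "stationary"):
        raise ValueError(f"unknown init policy {init_policy!r}")
    if fine_model is not None and fine_model.as_tuple() != cg.as_tuple():
        raise IonscaleError(
            "only the CG-surrogate fine model is supported by this integrator; "
            "supply fine_model with the same parameters as cg (or None)"
        )
    if r_grid is None:
        r_grid = np.linspace(dec.L / 10.0, r_max, 40)
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    sv, su, sz = stationary_std(cg)
    r1, r2, r3, r4 = dec.half_sides
    T, truncated = _kernels.escape_kernel(
        *cg.as_tuple(),
        bd.D,
        r1,
        r2,
        r3,
        r4,
        dt,
        bd.dT,
        r_grid,
        n_realizations,
        init_policy == "stationary",
        sv,
        su,
        sz,
        max_steps,
        rng,
    )
    return EscapeResult(r_grid=r_grid, T=T, truncated=truncated)
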