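"""Ion moment statistics, coarse-grained model parameters and the maps between them.

The coarse-grained (CG) ion model is the linear SDE system

    dX_i = V_i dt
    dV_i = U_i dt
    dU_i = (-eta1 V_i + Z_i) dt
    dZ_i = -(eta2 Z_i + eta3 U_i) dt + eta4 dW_i,      i = 1, 2, 3,

for the ion position X, velocity V, acceleration U and an auxiliary variable Z.
The four positive parameters eta1..eta4 are determined in closed form by four
stationary statistics of a fine-scale (all-atom) trajectory: the diffusion
constant D and the per-component second moments <V_i^2>, <U_i^2>, <Z_i^2>.

Units are fixed throughout the package: length in angstrom (A), time in
picoseconds (ps), mass in dalton (Da).  There is no unit-conversion layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

from .errors import IncompleteStatisticsError, InvalidStatisticsError, UnknownIonError

__all__ = [
    "MDMomentStats",
    "CGParams",
    "fit_cg_params",
    "implied_stats",
    "builtin_ions",
    "get_ion",
    "read_config",
    "write_config",
    "stats_from_config",
    "params_from_config",
]


@dataclass(frozen=True)
class MDMomentStats:
    """Stationary statistics of one ion estimated from a fine-scale trajectory.

    Parameters
    ----------
    ion : str
        Short ASCII label, e.g. ``"K+"``, ``"Ca2+"``.
    D : float
        Diffusion constant [A^2 ps^-1].
    v2 : float
        Stationary second moment of one velocity component [A^2 ps^-2].
    u2 : float
        Stationary second moment of one acceleration component [A^2 ps^-4].
    z2 : float, optional
        Stationary second moment of one auxiliary-variable component
        [A^2 ps^-6].  May be ``None`` until estimated from data.
    """

    ion: str
    D: float
    v2: float
    u2: float
    z2: float | None = None

    def __post_init__(self):
        for name in ("D", "v2", "u2"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise InvalidStatisticsError(
                    f"invalid statistics: {name} must be positive and finite, got {value!r}"
                )
        if self.z2 is not None and (not (self.z2 > 0.0) or not math.isfinite(self.z2)):
            raise InvalidStatisticsError(
                f"invalid statistics: z2 must be positive and finite, got {self.z2!r}"
            )

    def with_z2(self, z2: float) -> "MDMomentStats":
        """Return a copy with the auxiliary second moment filled in."""
        return replace(self, z2=z2)


@dataclass(frozen=True)
class CGParams:
    """The four parameters of the coarse-grained ion model.

    eta1 [ps^-2] couples acceleration to velocity, eta2 [ps^-1] damps the
    auxiliary variable, eta3 [ps^-2] couples it to acceleration and
    eta4 [A ps^-7/2] sets the white-noise intensity.  Stability of the model
    requires all four to be strictly positive.
    """

    eta1: float
    eta2: float
    eta3: float
    eta4: float

    def __post_init__(self):
        for name in ("eta1", "eta2", "eta3", "eta4"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise InvalidStatisticsError(
                    f"invalid parameters: {name} must be positive and finite, got {value!r}"
                )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.eta1, self.eta2, self.eta3, self.eta4)

    @property
    def stationary_v2(self) -> float:
        """Stationary <V_i^2> = eta4^2 / (2 eta1 eta2 eta3)."""
        return self.eta4**2 / (2.0 * self.eta1 * self.eta2 * self.eta3)

    @property
    def implied_D(self) -> float:
        """Diffusion constant eta4^2 / (2 eta1^2 eta2^2), from eta4/(eta1 eta2) = sqrt(2D)."""
        return self.eta4**2 / (2.0 * self.eta1**2 * self.eta2**2)


def fit_cg_params(stats: MDMomentStats) -> CGParams:
    """Estimate the CG parameters from stationary fine-scale statistics.

    Closed-form steady-state estimators:

        eta1 = <U^2> / <V^2>
        eta3 = <Z^2> / <U^2>
        eta2 = (<Z^2> / D) * (<V^2> / <U^2>)^2
        eta4 = sqrt(2 * eta2 * <Z^2>)

    Raises
    ------
    IncompleteStatisticsError
        If ``stats.z2`` is missing.
    """
    if stats.z2 is None:
        raise IncompleteStatisticsError(
            "incomplete statistics: z2 is required to fit CG parameters"
        )
    eta1 = stats.u2 / stats.v2
    eta3 = stats.z2 / stats.u2
    eta2 = (stats.z2 / stats.D) * (stats.v2 / stats.u2) ** 2
    eta4 = math.sqrt(2.0 * eta2 * stats.z2)
    return CGParams(eta1=eta1, eta2=eta2, eta3=eta3, eta4=eta4)


def implied_stats(params: CGParams, ion: str = "") -> MDMomentStats:
    """Stationary statistics implied by a CG parameter set.

    Exact inverse of :func:`fit_cg_params` (up to floating-point rounding):

        D    = eta4^2 / (2 eta1^2 eta2^2)
        v2   = eta4^2 / (2 eta1 eta2 eta3)
        u2   = eta1 * v2
        z2   = eta1 * eta3 * v2
    """
    v2 = params.stationary_v2
    return MDMomentStats(
        ion=ion,
        D=params.implied_D,
        v2=v2,
        u2=params.eta1 * v2,
        z2=params.eta1 * params.eta3 * v2,
    )


# Stationary averages from the source all-atom MD study (SPC/E water, 25 C):
# D, <V^2>, <U^2>, <Z^2> per ion, and the CG parameters fitted from the
# unrounded averages.  Both tables are stored exactly as printed
# (4 significant figures); refitting from the rounded statistics reproduces
# the parameters to ~0.3% relative.
_TABLE_STATS: dict[str, tuple[float, float, float, float]] = {
    "K+": (0.183, 6.32, 4.86e3, 1.65e7),
    "Na+": (0.128, 10.8, 2.21e4, 8.88e7),
    "Ca2+": (0.053, 6.18, 1.87e4, 9.23e7),
    "Cl-": (0.177, 6.98, 6.56e3, 2.97e7),
}

_TABLE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "K+": (768.7, 152.5, 3.393e3, 7.094e4),
    "Na+": (2.044e3, 166.1, 4.020e3, 1.717e5),
    "Ca2+": (3.026e3, 190.2, 4.933e3, 1.874e5),
    "Cl-": (940.0, 189.7, 4.524e3, 1.061e5),
}


def builtin_ions() -> dict[str, tuple[MDMomentStats, CGParams]]:
    """The four bundled ions (K+, Na+, Ca2+, Cl-) with published statistics
    and fitted CG parameters."""
    out = {}
    for ion, (D, v2, u2, z2) in _TABLE_STATS.items():
        e1, e2, e3, e4 = _TABLE_PARAMS[ion]
        out[ion] = (
            MDMomentStats(ion=ion, D=D, v2=v2, u2=u2, z2=z2),
            CGParams(eta1=e1, eta2=e2, eta3=e3, eta4=e4),
        )
    return out


def get_ion(ion: str) -> tuple[MDMomentStats, CGParams]:
    """Look up one built-in ion by ASCII label ("K+", "Na+", "Ca2+", "Cl-")."""
    table = builtin_ions()
    if ion not in table:
        raise UnknownIonError(
            f"unknown ion {ion!r}; built-in ions are {sorted(table)}"
        )
    return table[ion]


# ---------------------------------------------------------------------------
# plain-text key/value configuration


def read_config(path: str | Path) -> dict[str, str]:
    """Read a ``key = value`` configuration file.

    Blank lines and lines starting with ``#`` are ignored.  Values are
    returned as strings; the caller interprets them.
    """
    entries: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        entries[key.strip()] = value.strip()
    return entries


def write_config(entries: Mapping[str, object], path: str | Path) -> None:
    """Write a mapping as a ``key = value`` file, one entry per line."""
    lines = [f"{key} = {value}" for key, value in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


_STATS_KEYS = {"ion", "D", "v2", "u2", "z2"}
_PARAMS_KEYS = {"ion", "eta1", "eta2", "eta3", "eta4"}


def stats_from_config(entries: Mapping[str, str]) -> MDMomentStats:
    """Build :class:`MDMomentStats` from config entries (keys ion, D, v2, u2, z2)."""
    unknown = set(entries) - _STATS_KEYS
    if unknown:
        raise ValueError(f"unknown config keys for statistics: {sorted(unknown)}")
    z2 = float(entries["z2"]) if "z2" in entries else None
    return MDMomentStats(
        ion=str(entries.get("ion", "")),
        D=float(entries["D"]),
        v2=float(entries["v2"]),
        u2=float(entries["u2"]),
        z2=z2,
    )


def params_from_config(entries: Mapping[str, str]) -> CGParams:
    """Build :class:`CGParams` from config entries (keys eta1..eta4)."""
    unknown = set(entries) - _PARAMS_KEYS
    if unknown:
        raise ValueError(f"unknown config keys for parameters: {sorted(unknown)}")
    return CGParams(
        eta1=float(entries["eta1"]),
        eta2=float(entries["eta2"]),
        eta3=float(entries["eta3"]),
        eta4=float(entries["eta4"]),
    )
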