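"""Uniform-timestep trajectory container and delimited-text I/O.

The on-disk format is a whitespace-delimited table with a header line::

    t x1 x2 x3 v1 v2 v3 u1 u2 u3 [z1 z2 z3]

one row per stored step, units A / ps.  The auxiliary-variable columns are
optional: externally produced fine-scale trajectories typically provide only
position, velocity and acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrajectoryTooShortError

__all__ = ["Trajectory", "read_trajectory", "write_trajectory"]


@dataclass
class Trajectory:
    """Time series of ion state vectors sampled on a uniform grid k*dt.

    Arrays have shape ``(n_steps + 1, 3)``; ``Z`` may be ``None``.
    """

    dt: float
    X: np.ndarray
    V: np.ndarray
    U: np.ndarray
    Z: np.ndarray | None = None
    seed: int | None = None
    t0: float = 0.0
    _t: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if not self.dt > 0.0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.X = np.asarray(self.X, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if self.Z is not None:
            self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.X)
        for name in ("V", "U", "Z"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(
                    f"column length mismatch: X has {n} rows, {name} has {len(arr)}"
                )

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_steps(self) -> int:
        return len(self.X) - 1

    @property
    def t(self) -> np.ndarray:
        if self._t is None or len(self._t) != len(self.X):
            self._t = self.t0 + self.dt * np.arange(len(self.X))
        return self._t

    @property
    def has_z(self) -> bool:
        return self.Z is not None

    def require_steps(self, n: int, what: str = "estimator") -> None:
        """Raise if the trajectory holds fewer than ``n`` steps."""
        if self.n_steps < n:
            raise TrajectoryTooShortError(
                f"trajectory too short for {what}: has {self.n_steps} steps, needs >= {n}"
            )

    def burned(self, burn_in: float) -> "Trajectory":
        """Return a view-like copy with the first ``burn_in`` fraction discarded."""
        if not 0.0 <= burn_in < 1.0:
            raise ValueError(f"burn-in fraction must be in [0, 1), got {burn_in}")
        k = int(burn_in * self.n_steps)
        if k == 0:
            return self
        return Trajectory(
            dt=self.dt,
            X=self.X[k:],
            V=self.V[k:],
            U=self.U[k:],
            Z=None if self.Z is None else self.Z[k:],
            seed=self.seed,
            t0=self.t0 + k * self.dt,
        )


_BASE_COLUMNS = ["t", "x1", "x2", "x3", "v1", "v2", "v3", "u1", "u2", "u3"]
_Z_COLUMNS = ["z1", "z2", "z3"]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a whitespace-delimited text table with header."""
    columns = {"t": traj.t}
    for prefix, arr in (("x", traj.X), ("v", traj.V), ("u", traj.U)):
        for i in range(3):
            columns[f"{prefix}{i + 1}"] = arr[:, i]
    if traj.Z is not None:
        for i in range(3):
            columns[f"z{i + 1}"] = traj.Z[:, i]
    frame = pd.DataFrame(columns)
    frame.to_csv(path, sep=" ", index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` (Z columns optional)."""
    frame = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    missing = [c for c in _BASE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"malformed trajectory file {path}: missing columns {missing}")
    t = frame["t"].to_numpy()
    if len(t) < 2:
        raise TrajectoryTooShortError(
            f"trajectory file {path} has fewer than 2 rows"
        )
    dt_all = np.diff(t)
    dt = float(dt_all[0])
    if dt <= 0 or not np.allclose(dt_all, dt, rtol=1e-8, atol=1e-12):
        raise ValueError(f"trajectory file {path} does not have a uniform timestep")
    grab = lambda prefix: frame[[f"{prefix}{i}" for i in (1, 2, 3)]].to_numpy()
    Z = grab("z") if all(c in frame.columns for c in _Z_COLUMNS) else None
    return Trajectory(dt=dt, X=grab("x"), V=grab("v"), U=grab("u"), Z=Z, t0=float(t[0]))
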