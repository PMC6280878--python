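"""Ensemble and column averaging of CA output, and the scalar mass metric.

Column averages carry the 1/(M*(R+1)) normalization: occupancies are
averaged over M realizations and over the R+1 sites of each column
(the direction transverse to front propagation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnsembleSummary", "column_average", "total_mass"]


@dataclass
class EnsembleSummary:
    """Ensemble- and column-averaged TC/EC density profiles.

    Attributes
    ----------
    times : (n_t,) recording times t = tau * K.
    x_grid : (R+1,) column centres x_i = i*h.
    N, E : (n_t, R+1) column-averaged TC and EC densities.
    M : number of realizations averaged.
    n_bar, e_bar : optional (n_t, R+1, R+1) site averages.
    """

    times: np.ndarray
    x_grid: np.ndarray
    N: np.ndarray
    E: np.ndarray
    M: int
    config: object = None
    n_bar: np.ndarray | None = None
    e_bar: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.N = np.atleast_2d(np.asarray(self.N, dtype=float))
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        if self.N.shape != (self.times.size, self.x_grid.size):
            raise ValueError(f"N shape {self.N.shape} does not match (n_t, R+1)")
        if self.E.shape != self.N.shape:
            raise ValueError("E shape does not match N shape")

    @property
    def h(self) -> float:
        return float(self.x_grid[1] - self.x_grid[0])

    def at_time(self, t: float, atol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
        """(N, E) profiles at recording time t."""
        idx = np.where(np.isclose(self.times, t, atol=atol))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} not recorded (have {self.times})")
        return self.N[idx[0]], self.E[idx[0]]

    def mass(self) -> tuple[np.ndarray, np.ndarray]:
        """Trapezoidal TC and EC mass over x at each recording time."""
        mN = np.array([total_mass(self.N[r], self.h) for r in range(self.times.size)])
        mE = np.array([total_mass(self.E[r], self.h) for r in range(self.times.size)])
        return mN, mE

    @property
    def config_hash(self) -> str:
        payload = {"M": self.M}
        if self.config is not None and hasattr(self.config, "to_dict"):
            payload["config"] = self.config.to_dict()
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def column_average(snapshots, M: int, R: int, times=None, config=None) -> EnsembleSummary:
    """Column-average raw per-realization snapshots.

    Parameters
    ----------
    snapshots : sequence over realizations, each a sequence over recording
        times of (tc_grid, ec_grid) pairs of shape (R+1, R+1).
    M, R : realization count and lattice size (validated against the data).

    Returns the summary with N_i = 1/(M(R+1)) * sum_m sum_j n^m_{i,j} and
    the analogous E_i.
    """
    if len(snapshots) != M:
        raise ValueError(f"expected {M} realizations, got {len(snapshots)}")
    n_t = len(snapshots[0])
    N = np.zeros((n_t, R + 1))
    E = np.zeros((n_t, R + 1))
    for snaps in snapshots:
        if len(snaps) != n_t:
            raise ValueError("realizations disagree on recording times")
        for r, (tc, ec) in enumerate(snaps):
            tc = np.asarray(tc)
            ec = np.asarray(ec)
            if tc.shape != (R + 1, R + 1) or ec.shape != (R + 1, R + 1):
                raise ValueError("snapshot shape does not match lattice size")
            N[r] += tc.sum(axis=1)
            E[r] += ec.sum(axis=1)
    N /= M * (R + 1)
    E /= M * (R + 1)
    if times is None:
        times = np.arange(n_t, dtype=float)
    return EnsembleSummary(times=times, x_grid=np.linspace(0, 1, R + 1),
                           N=N, E=E, M=M, config=config)


def total_mass(profile: np.ndarray, h: float) -> float:
    """Trapezoidal integral of a density profile over x in [0, 1]."""
    profile = np.asarray(profile, dtype=float)
    return float(np.trapezoid(profile, dx=h))
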