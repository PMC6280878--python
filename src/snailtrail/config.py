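"""Microscale configuration for the angiogenesis cellular automaton.

The CA lives on a square lattice with sites (i, j), 0 <= i, j <= R, where i
indexes the direction of front propagation (limbus at i=0, TAF source at
i=R).  Space and time are non-dimensional: x_i = i*h with R*h = 1, and
t = K*tau for discrete step K.  The TAF (tumor angiogenic factor)
concentration is a prescribed linear, quasi-steady field c(x) = x,
discretised as c_i = i*h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CAConfig", "TAFField", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a CA configuration violates a model invariant."""


@dataclass(frozen=True)
class TAFField:
    """Discretised TAF concentration, constant along rows (independent of j).

    The default corneal-assay field is linear, c_i = i*h, which makes the
    transverse movement probabilities exactly 1/4 and drives chemotaxis
    toward the source at x = 1.
    """

    c_grid: np.ndarray  # shape (R+1,), values in [0, 1]

    def __post_init__(self) -> None:
        c = np.asarray(self.c_grid, dtype=float)
        if c.ndim != 1 or c.size < 2:
            raise ConfigError("TAF field must be a 1-D array with >= 2 nodes")
        if np.any(np.diff(c) < 0):
            raise ConfigError("TAF field must be monotone non-decreasing in i")
        if c.min() < 0 or c.max() > 1:
            raise ConfigError("TAF field must lie in [0, 1]")
        object.__setattr__(self, "c_grid", c)

    @classmethod
    def linear(cls, R: int) -> "TAFField":
        """The corneal-assay field c_i = i*h with h = 1/R."""
        return cls(np.linspace(0.0, 1.0, R + 1))

    @property
    def R(self) -> int:
        return self.c_grid.size - 1

    def gradient_stencil(self, k: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-column movement probabilities (P^{x+}_i, P^{x-}_i).

        Interior columns use the central difference c_{i+1} - c_{i-1}; the
        boundary columns clamp the stencil to the available one-sided
        neighbour.  Moves that would exit the lattice are aborted by the
        engine regardless, so the clamp only affects the surviving
        directions at i = 0 and i = R.
        """
        c = self.c_grid
        up = np.empty_like(c)
        up[:-1] = c[1:]
        up[-1] = c[-1]
        down = np.empty_like(c)
        down[1:] = c[:-1]
        down[0] = c[0]
        grad = up - down
        p_plus = (1.0 + k * grad) / 4.0
        p_minus = (1.0 - k * grad) / 4.0
        return p_plus, p_minus


@dataclass(frozen=True)
class CAConfig:
    """All microscale parameters of the CA, plus the model-mode switch.

    Defaults are the standard parameter set used throughout: R = 200,
    h = 1/200, P_m = 1, k = 100, tau = 1/160, K_IC = 32, which map to the
    macroscale coefficients D = 1e-3, chi = 0.4, mu = 160 and t_IC = 0.2.

    mode=1: tip cells (TCs) interact only with TCs (tip-to-tip anastomosis
    with probability a_n, otherwise exclusion); endothelial-cell (EC) counts
    are unbounded non-negative integers.  mode=2: TCs additionally interact
    with ECs (tip-to-sprout anastomosis with probability a_e, EC exclusion
    otherwise, self-loops prohibited) and every site holds at most one cell
    of either type.
    """

    R: int = 200
    P_m: float = 1.0
    k: float = 100.0
    tau: float = 1.0 / 160.0
    P_p: float = 0.0
    a_n: float = 0.0
    a_e: float = 1.0
    mode: int = 1
    K_IC: int = 32
    K_max: int = 320
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R < 2 or self.R % 2 != 0:
            raise ConfigError(
                f"R must be even and >= 2 (alternating initial TC placement); got {self.R}"
            )
        if self.mode not in (1, 2):
            raise ConfigError(f"mode must be 1 or 2, got {self.mode}")
        for name in ("P_m", "P_p", "a_n", "a_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.tau <= 0:
            raise ConfigError(f"tau must be positive, got {self.tau}")
        if self.k < 0:
            raise ConfigError(f"k must be non-negative, got {self.k}")
        # Direction probabilities must be valid for the linear field: the
        # largest central-difference TAF increment is 2h, so k*2h <= 1.
        if self.k * 2.0 * self.h > 1.0 + 1e-12:
            raise ConfigError(
                f"k={self.k} too large for the field gradient: k*2h = "
                f"{self.k * 2 * self.h:.4g} > 1 gives direction probabilities outside [0, 1]"
            )
        if not 0 <= self.K_IC <= self.K_max:
            raise ConfigError("need 0 <= K_IC <= K_max")

    @property
    def h(self) -> float:
        """Lattice spacing; R*h = 1 by construction."""
        return 1.0 / self.R

    @property
    def B(self) -> int:
        """Model indicator: 0 for Model 1, 1 for Model 2."""
        return self.mode - 1

    @property
    def t_IC(self) -> float:
        return self.tau * self.K_IC

    def taf(self) -> TAFField:
        return TAFField.linear(self.R)

    def with_(self, **kwargs) -> "CAConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "R": self.R, "P_m": self.P_m, "k": self.k, "tau": self.tau,
            "P_p": self.P_p, "a_n": self.a_n, "a_e": self.a_e,
            "mode": self.mode, "K_IC": self.K_IC, "K_max": self.K_max,
            "seed": self.seed,
        }
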