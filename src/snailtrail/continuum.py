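"""Mean-field continuum models derived from the CA.

The one-dimensional PDEs for the column-averaged tip-cell density N(x,t)
and stalk-cell density E(x,t) read (B = 0 for Model 1, B = 1 for Model 2)::

    N_t = D (1 - a_n N - B a_e E) N_xx
          - chi [ (1 - N - B a_e E) (N c_x)_x - (1 - a_n) N N_x c_x ]
          - mu (a_n N^2 + B a_e N E)
          + lam c N (1 - N - B E)^2

    E_t = mu N (1 - N + 2 a_n N) - D (1 - 2 a_n) N N_xx
          - chi N [ (1 - a_n) c_x N_x + a_n (N c_x)_x ]

The chemotactic bracket is the algebraically exact rewriting of
(N (1-N) c_x)_x + a_n N N_x c_x - B a_e E (N c_x)_x, chosen so that the
special cases a_n = 0 (viscous-Burgers-like chemotaxis, factor 1 - 2N for
a linear field) and a_n = 1 (factor 1 - N pre-multiplying transport) hold
exactly at the discrete level as well.

Coefficients map from the microscale as D = P_m h^2 / (4 tau),
chi = P_m k h^2 / tau, mu = P_m / tau, lam = P_p / tau, t_IC = tau K_IC.

The branching source is clamped: lam is set to 0 wherever the maximum
density has been reached (N >= 1 in Model 1; N + E >= 1 in Model 2), which
together with the squared vacancy factor keeps the models well-posed.

No-flux boundaries: D N_x - chi N (1 - (1 - a_n) N) c_x = 0 at x = 0, 1,
encoded with second-order ghost nodes.  The E equation contains no
E-derivatives and needs no boundary condition.

:func:`meanfield_lattice_iterate` iterates the column-averaged mean-field
difference equations directly (before any Taylor expansion) and serves as
an independent oracle for the PDE limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .config import CAConfig, TAFField

__all__ = [
    "ContinuumParams", "PDESolution", "map_parameters", "model_rhs",
    "solve_pde", "meanfield_lattice_iterate",
]


@dataclass(frozen=True)
class ContinuumParams:
    """Macroscale coefficients of the mean-field PDEs.

    D : diffusion coefficient (dimensionless, = mu h^2 / 4 when mapped).
    chi : chemotactic coefficient (= mu k h^2; chi/D = 4k).
    mu : motility rate (sets the EC production rate).
    lam : branching rate.
    a_n, a_e : tip-to-tip / tip-to-sprout anastomosis parameters in [0, 1].
    B : model indicator, 0 (Model 1) or 1 (Model 2).
    t_IC : time of the CA profile used as initial condition.
    """

    D: float
    chi: float
    mu: float
    lam: float = 0.0
    a_n: float = 0.0
    a_e: float = 1.0
    B: int = 0
    t_IC: float = 0.0

    def __post_init__(self):
        if self.B not in (0, 1):
            raise ValueError("B must be 0 or 1")
        if self.D < 0 or self.mu < 0:
            raise ValueError("D and mu must be non-negative")

    def with_(self, **kw) -> "ContinuumParams":
        return replace(self, **kw)


@dataclass
class PDESolution:
    """Method-of-lines solution on the uniform grid.

    N, E have shape (n_t, n_x); ``mass_defect`` records the residual of the
    discrete mass balance d/dt int N dx = sources - sinks at the output
    times (a solver diagnostic, not a model quantity).
    """

    x_grid: np.ndarray
    times: np.ndarray
    N: np.ndarray
    E: np.ndarray
    params: ContinuumParams | None = None
    mass_defect: np.ndarray | None = None

    def at_time(self, t: float, atol: float = 1e-9):
        idx = np.where(np.isclose(self.times, t, atol=atol))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} not in solution times {self.times}")
        return self.N[idx[0]], self.E[idx[0]]


def map_parameters(config: CAConfig) -> ContinuumParams:
    """Map microscale CA parameters to macroscale PDE coefficients.

    D = P_m h^2/(4 tau), chi = P_m k h^2/tau, mu = P_m/tau, lam = P_p/tau,
    t_IC = tau K_IC.  The standard parameter set (R=200, P_m=1, k=100,
    tau=1/160, K_IC=32) gives D = 1e-3, chi = 0.4, mu = 160, t_IC = 0.2.
    """
    if config.tau <= 0:
        raise ValueError("tau must be positive")
    h2 = config.h ** 2
    return ContinuumParams(
        D=config.P_m * h2 / (4.0 * config.tau),
        chi=config.P_m * config.k * h2 / config.tau,
        mu=config.P_m / config.tau,
        lam=config.P_p / config.tau,
        a_n=config.a_n,
        a_e=config.a_e,
        B=config.B,
        t_IC=config.tau * config.K_IC,
    )


def _taf_arrays(taf, x):
    """TAF concentration and gradient on the solver grid (with exact
    c_x = 1 for the linear field).  A pre-computed (c, c_x) tuple is
    passed through unchanged (solver hot path)."""
    if isinstance(taf, tuple):
        return taf
    if taf is None:
        return x.copy(), np.ones_like(x)
    c = np.asarray(taf.c_grid if isinstance(taf, TAFField) else taf, dtype=float)
    if c.shape != x.shape:
        raise ValueError("TAF grid does not match solver grid")
    return c, np.gradient(c, x, edge_order=2)


def _ghost_extend(N, h, p: ContinuumParams, cx):
    """Extend N with ghost nodes encoding the no-flux condition
    D N_x - chi N (1 - (1-a_n) N) c_x = 0 to second order."""
    Ne = np.empty(N.size + 2)
    Ne[1:-1] = N
    if p.D > 0:
        r = 2.0 * h * p.chi / p.D
        Ne[0] = N[1] - r * N[0] * (1.0 - (1.0 - p.a_n) * N[0]) * cx[0]
        Ne[-1] = N[-2] + r * N[-1] * (1.0 - (1.0 - p.a_n) * N[-1]) * cx[-1]
    else:
        Ne[0] = N[1]
        Ne[-1] = N[-2]
    return Ne


def _dx(Fe, h):
    """Centered difference of an extended (ghosted) nodal array."""
    return (Fe[2:] - Fe[:-2]) / (2.0 * h)


def model_rhs(N, E, params: ContinuumParams, taf=None, x_grid=None):
    """(dN/dt, dE/dt) of the mean-field PDEs on a shared uniform grid.

    ``taf`` may be a TAFField, a raw concentration array on the grid, or
    None for the default linear field c(x) = x.
    """
    N = np.asarray(N, dtype=float)
    E = np.asarray(E, dtype=float)
    if N.shape != E.shape:
        raise ValueError("N and E must share a grid")
    x = np.linspace(0.0, 1.0, N.size) if x_grid is None else np.asarray(x_grid)
    if x.shape != N.shape:
        raise ValueError("x_grid does not match profile length")
    h = x[1] - x[0]
    p = params
    c, cx = _taf_arrays(taf, x)

    Ne = _ghost_extend(N, h, p, cx)
    Nx = _dx(Ne, h)
    Nxx = (Ne[2:] - 2.0 * Ne[1:-1] + Ne[:-2]) / h ** 2
    # (N c_x)_x with the ghost values and linearly extrapolated c_x
    cxe = np.empty(N.size + 2)
    cxe[1:-1] = cx
    cxe[0] = 2 * cx[0] - cx[1]
    cxe[-1] = 2 * cx[-1] - cx[-2]
    dNcx = _dx(Ne * cxe, h)

    aB = p.B * p.a_e
    diff = p.D * (1.0 - p.a_n * N - aB * E) * Nxx
    chemo = -p.chi * ((1.0 - N - aB * E) * dNcx - (1.0 - p.a_n) * N * Nx * cx)
    sink = -p.mu * (p.a_n * N ** 2 + aB * N * E)
    vac = 1.0 - N - p.B * E
    branch = p.lam * c * N * np.maximum(vac, 0.0) ** 2
    # well-posedness clamp: branching ceases at maximum density
    branch[vac <= 0.0] = 0.0
    dN = diff + chemo + sink + branch

    dE = (p.mu * N * (1.0 - N + 2.0 * p.a_n * N)
          - p.D * (1.0 - 2.0 * p.a_n) * N * Nxx
          - p.chi * N * ((1.0 - p.a_n) * cx * Nx + p.a_n * dNcx))
    return dN, dE


def solve_pde(params: ContinuumParams, N_ic, E_ic, t_out, taf=None,
              x_grid=None, rtol=1e-6, atol=1e-8, method="RK45") -> PDESolution:
    """Method-of-lines integration of the mean-field PDEs.

    The initial profiles (typically CA column averages at t_IC) are posed
    at params.t_IC; output is interpolated at the increasing times
    ``t_out`` (each >= t_IC).  Falls back to BDF with a banded Jacobian
    sparsity pattern if the explicit integrator fails.
    """
    N_ic = np.asarray(N_ic, dtype=float)
    E_ic = np.asarray(E_ic, dtype=float)
    t_out = np.atleast_1d(np.asarray(t_out, dtype=float))
    if np.any(np.diff(t_out) <= 0):
        raise ValueError("t_out must be strictly increasing")
    if t_out[0] < params.t_IC - 1e-12:
        raise ValueError(f"t_out must start at or after t_IC={params.t_IC}")
    x = np.linspace(0.0, 1.0, N_ic.size) if x_grid is None else np.asarray(x_grid)
    n = N_ic.size
    taf_pre = _taf_arrays(taf, x)

    def rhs(t, y):
        dN, dE = model_rhs(y[:n], y[n:], params, taf=taf_pre, x_grid=x)
        return np.concatenate([dN, dE])

    y0 = np.concatenate([N_ic, E_ic])
    t_eval = t_out
    span = (params.t_IC, float(t_out[-1]))
    if span[1] == span[0]:
        sol_N = np.tile(N_ic, (t_out.size, 1))
        sol_E = np.tile(E_ic, (t_out.size, 1))
        return PDESolution(x, t_out, sol_N, sol_E, params)
    def blowup(t, y):
        # TC densities are O(1) and EC densities at most O(mu * t); far
        # beyond that the candidate is diverging
        return 1e3 - float(np.max(np.abs(y)))

    blowup.terminal = True
    res = solve_ivp(rhs, span, y0, t_eval=t_eval, method=method,
                    rtol=rtol, atol=atol, events=blowup)
    if res.status == 1:
        raise RuntimeError("PDE integration diverged (density blow-up)")
    if not res.success and method != "BDF":
        from scipy.sparse import bmat, diags
        band = diags([1.0] * 5, offsets=range(-2, 3), shape=(n, n))
        spar = bmat([[band, band], [band, band]])
        res = solve_ivp(rhs, span, y0, t_eval=t_eval, method="BDF",
                        rtol=rtol, atol=atol, jac_sparsity=spar)
    if not res.success:
        raise RuntimeError(f"PDE integration failed: {res.message}")
    Nt = res.y[:n].T.copy()
    Et = res.y[n:].T.copy()

    # mass-balance defect diagnostic at output times
    h = x[1] - x[0]
    defect = np.empty(t_out.size)
    for r in range(t_out.size):
        dN, _ = model_rhs(Nt[r], Et[r], params, taf=taf, x_grid=x)
        defect[r] = np.trapezoid(dN, dx=h)
    return PDESolution(x, t_out, Nt, Et, params, mass_defect=defect)


def meanfield_lattice_iterate(config: CAConfig, N0, E0, K_steps: int,
                              record_K=None):
    """Iterate the column-averaged mean-field difference equations.

    This is the deterministic update whose Taylor expansion yields the
    PDEs: per step,

      N_i <- N_i + P_m (1 - N_i - B a_e E_i) [P+_{i-1} N_{i-1}
                 + P-_{i+1} N_{i+1} + (1/2) N_i]
                 - P_m N_i Q_i + P_p c_i N_i max(0, 1 - N_i - B E_i)^2
      E_i <- E_i + P_m N_i Q_i
                 + a_n P_m N_i [P+_{i-1} N_{i-1} + P-_{i+1} N_{i+1} + (1/2) N_i]

    with the departure factor
      Q_i = P+_i (1 - (1-a_n) N_{i+1}) + P-_i (1 - (1-a_n) N_{i-1})
            + (1/2)(1 - (1-a_n) N_i),
    boundary moves aborted (the corresponding in/out contributions dropped
    at i=0 and i=R), and EC-target blocking absent because the mean-field
    derivation takes a_e = 1 for departures.  Every departure deposits one
    EC at the origin; tip-to-tip anastomosis converts the resident TC of
    the target site into an EC (the a_n term).

    Returns (times_K, N_traj, E_traj) where the trajectories have one row
    per recorded step (default: every step including K=0).
    """
    R = config.R
    N = np.asarray(N0, dtype=float).copy()
    E = np.asarray(E0, dtype=float).copy()
    if N.size != R + 1 or E.size != R + 1:
        raise ValueError("profiles must have length R+1")
    taf = config.taf()
    pxp, pxm = taf.gradient_stencil(config.k)
    c = taf.c_grid
    P_m, P_p = config.P_m, config.P_p
    a_n, a_e, B = config.a_n, config.a_e, config.B
    if record_K is None:
        record_K = np.arange(K_steps + 1)
    record_K = np.asarray(record_K, dtype=int)
    N_traj = np.empty((record_K.size, R + 1))
    E_traj = np.empty((record_K.size, R + 1))
    ptr = 0
    for K in range(K_steps + 1):
        if ptr < record_K.size and record_K[ptr] == K:
            N_traj[ptr] = N
            E_traj[ptr] = E
            ptr += 1
        if K == K_steps:
            break
        influx = 0.5 * N.copy()          # transverse arrivals
        influx[1:] += pxp[:-1] * N[:-1]   # from the left
        in_x_boundary_ok = pxm[1:] * N[1:]
        influx[:-1] += in_x_boundary_ok   # from the right
        vac_in = 1.0 - N - B * a_e * E
        in_term = P_m * influx * vac_in

        Q = 0.5 * (1.0 - (1.0 - a_n) * N)
        Q[:-1] += pxp[:-1] * (1.0 - (1.0 - a_n) * N[1:])
        Q[1:] += pxm[1:] * (1.0 - (1.0 - a_n) * N[:-1])
        out_term = P_m * N * Q

        vac_b = np.maximum(1.0 - N - B * E, 0.0)
        branch = P_p * c * N * vac_b ** 2

        deposit = out_term
        convert = a_n * P_m * N * influx

        N = N + in_term - out_term + branch
        E = E + deposit + convert
    return config.tau * record_K.astype(float), N_traj, E_traj
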