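"""Modified Byrne–Chaplain (BC) snail-trail comparator model.

A phenomenological model linear in N in its diffusive, chemotactic and
branching terms, with quadratic anastomosis sinks, used as the fitting
baseline against the non-linear mean-field models::

    N_t = D_bc N_xx - chi_bc (N c_x)_x + lam_bc c N - beta_n N^2 - beta_e N E
    E_t = mu_ec N [+ 2 beta_n N^2]

The EC production rate mu_ec is fixed to the mapped motility rate mu
(EC evolution is mu N in the non-volume-excluding limit).  The optional
+2 beta_n N^2 term is the EC-side counterpart of tip-to-tip anastomosis
(two tip cells convert to stalk cells per event); it is on by default and
toggleable via ``tip_tip_ec_source``.

This comparator is reconstructed from the modified BC model's published
description (five fitted parameters; transport and branching linear in N;
quadratic sinks; EC production mu N); the original closed-form statement
is not transcribed here.

Boundaries: no-flux with the linear flux D_bc N_x - chi_bc N c_x = 0 at
x = 0, 1 (the a_n -> 1 limit of the non-linear flux condition).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .continuum import PDESolution, _taf_arrays, _dx

__all__ = ["BCParams", "bc_rhs", "solve_bc"]


@dataclass(frozen=True)
class BCParams:
    """Coefficients of the modified BC model (all non-negative).

    D_bc, chi_bc : diffusion and chemotactic coefficients.
    lam_bc : branching rate (source lam_bc * c * N).
    beta_n, beta_e : tip-to-tip and tip-to-sprout sink rates.
    mu_ec : EC production rate, fixed to the mapped mu.
    tip_tip_ec_source : include +2 beta_n N^2 in dE/dt.
    """

    D_bc: float
    chi_bc: float
    lam_bc: float = 0.0
    beta_n: float = 0.0
    beta_e: float = 0.0
    mu_ec: float = 0.0
    tip_tip_ec_source: bool = True

    def __post_init__(self):
        for name in ("D_bc", "chi_bc", "lam_bc", "beta_n", "beta_e", "mu_ec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_(self, **kw) -> "BCParams":
        return replace(self, **kw)


def _ghost_extend_linear(N, h, p: BCParams, cx):
    """Ghost nodes for the linear no-flux condition D_bc N_x = chi_bc N c_x."""
    Ne = np.empty(N.size + 2)
    Ne[1:-1] = N
    if p.D_bc > 0:
        r = 2.0 * h * p.chi_bc / p.D_bc
        Ne[0] = N[1] - r * N[0] * cx[0]
        Ne[-1] = N[-2] + r * N[-1] * cx[-1]
    else:
        Ne[0] = N[1]
        Ne[-1] = N[-2]
    return Ne


def bc_rhs(N, E, params: BCParams, taf=None, x_grid=None):
    """(dN/dt, dE/dt) of the modified BC model on a shared uniform grid."""
    N = np.asarray(N, dtype=float)
    E = np.asarray(E, dtype=float)
    if N.shape != E.shape:
        raise ValueError("N and E must share a grid")
    x = np.linspace(0.0, 1.0, N.size) if x_grid is None else np.asarray(x_grid)
    if x.shape != N.shape:
        raise ValueError("x_grid does not match profile length")
    h = x[1] - x[0]
    c, cx = _taf_arrays(taf, x)
    Ne = _ghost_extend_linear(N, h, params, cx)
    Nxx = (Ne[2:] - 2.0 * Ne[1:-1] + Ne[:-2]) / h ** 2
    cxe = np.empty(N.size + 2)
    cxe[1:-1] = cx
    cxe[0] = 2 * cx[0] - cx[1]
    cxe[-1] = 2 * cx[-1] - cx[-2]
    dNcx = _dx(Ne * cxe, h)

    dN = (params.D_bc * Nxx - params.chi_bc * dNcx + params.lam_bc * c * N
          - params.beta_n * N ** 2 - params.beta_e * N * E)
    dE = params.mu_ec * N
    if params.tip_tip_ec_source:
        dE = dE + 2.0 * params.beta_n * N ** 2
    return dN, dE


def solve_bc(params: BCParams, N_ic, E_ic, t_out, t_IC=None, taf=None,
             x_grid=None, rtol=1e-6, atol=1e-8, method="RK45") -> PDESolution:
    """Method-of-lines integration of the BC model (same contract as
    :func:`snailtrail.continuum.solve_pde`)."""
    N_ic = np.asarray(N_ic, dtype=float)
    E_ic = np.asarray(E_ic, dtype=float)
    t_out = np.atleast_1d(np.asarray(t_out, dtype=float))
    if np.any(np.diff(t_out) <= 0):
        raise ValueError("t_out must be strictly increasing")
    t0 = float(t_out[0]) if t_IC is None else float(t_IC)
    x = np.linspace(0.0, 1.0, N_ic.size) if x_grid is None else np.asarray(x_grid)
    n = N_ic.size
    taf_pre = _taf_arrays(taf, x)

    def rhs(t, y):
        dN, dE = bc_rhs(y[:n], y[n:], params, taf=taf_pre, x_grid=x)
        return np.concatenate([dN, dE])

    y0 = np.concatenate([N_ic, E_ic])
    if float(t_out[-1]) == t0:
        return PDESolution(x, t_out, np.tile(N_ic, (t_out.size, 1)),
                           np.tile(E_ic, (t_out.size, 1)))
    def blowup(t, y):
        # TC densities are O(1) and EC densities at most O(mu * t); far
        # beyond that the candidate is diverging
        return 1e3 - float(np.max(np.abs(y)))

    blowup.terminal = True
    res = solve_ivp(rhs, (t0, float(t_out[-1])), y0, t_eval=t_out,
                    method=method, rtol=rtol, atol=atol, events=blowup)
    if res.status == 1:
        raise RuntimeError("BC integration diverged (density blow-up)")
    if not res.success and method != "BDF":
        from scipy.sparse import bmat, diags
        band = diags([1.0] * 5, offsets=range(-2, 3), shape=(n, n))
        spar = bmat([[band, band], [band, band]])
        res = solve_ivp(rhs, (t0, float(t_out[-1])), y0, t_eval=t_out,
                        method="BDF", rtol=rtol, atol=atol, jac_sparsity=spar)
    if not res.success:
        raise RuntimeError(f"BC integration failed: {res.message}")
    return PDESolution(x, t_out, res.y[:n].T.copy(), res.y[n:].T.copy())
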