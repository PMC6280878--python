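"""RMSE metrics and bounded parameter estimation.

The continuum models are calibrated against column-averaged CA ensembles:
the CA profile at t_IC seeds the PDE, the PDE is solved to the fit times
(default t = 0.4, 0.6, ..., 2.0), and the per-species root-mean-square
mismatch over all (x, t) pairs is minimized over a boxed parameter domain.
Per species, RMSE = sqrt( mean over fit times and grid nodes of
(model - ensemble)^2 ); the combined objective is rmse_N + rmse_E with
equal weights (exposed via ``species_weighting``).

The search is deterministic: a coarse grid scan (21 points per axis, for
one or two free parameters) locates the basin, then a bounded Nelder-Mead
polish refines to parameter tolerance 1e-5.  For the five-parameter BC
comparator a full grid is impractical, so a deterministic multi-start
Nelder-Mead from mapped-parameter starting points is used instead.

The statsmodels-style surface is :class:`PDECalibration` (model object)
whose ``fit()`` returns a :class:`CalibrationResults` carrying estimates,
repeat-fit uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .averaging import EnsembleSummary
from .bc import BCParams, solve_bc
from .config import CAConfig
from .continuum import ContinuumParams, PDESolution, map_parameters, solve_pde

__all__ = [
    "FitSpec", "FitResult", "rmse", "fit_parameters", "repeat_uncertainty",
    "PDECalibration", "CalibrationResults", "default_bounds",
]

FIT_TIMES_DEFAULT = tuple(np.round(np.arange(0.4, 2.01, 0.2), 10))

#: Fitting bounds for the branching rate by branching probability
#: (lam = P_p / tau with tau = 1/160): P_p = 1e-3 -> [0, 0.16],
#: P_p = 1e-2 -> [0, 1.6], P_p = 4e-2 -> [0, 6.4], P_p = 1e-1 -> [0, 16].
A_E_FLOOR = 1e-3  # half-open bound (0, 1] floored here


def default_bounds(name: str, config: CAConfig) -> tuple[float, float]:
    mapped = map_parameters(config)
    if name == "lam":
        return (0.0, mapped.lam)
    if name == "a_n":
        return (0.0, 1.0)
    if name == "a_e":
        return (A_E_FLOOR, 1.0)
    raise KeyError(name)


@dataclass(frozen=True)
class FitSpec:
    """What to fit: model, free parameters with bounds, fixed parameters.

    model_id : "model1", "model2" or "bc".
    free : mapping name -> (lo, hi) bounds.
    fixed : ContinuumParams or BCParams holding everything not fitted.
    fit_times : times entering the RMSE (the ensemble must contain them
        and t_IC = fixed.t_IC for the continuum models).
    species_weighting : (w_N, w_E) weights of the combined objective.
    """

    model_id: str
    free: dict
    fixed: object
    fit_times: tuple = FIT_TIMES_DEFAULT
    species_weighting: tuple = (1.0, 1.0)
    t_IC: float | None = None

    def __post_init__(self):
        if self.model_id not in ("model1", "model2", "bc"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not self.free:
            raise ValueError("free parameter set must be non-empty")
        for name, (lo, hi) in self.free.items():
            if hi < lo:
                raise ValueError(f"empty bounds for {name}: [{lo}, {hi}]")

    @property
    def start_time(self) -> float:
        if self.t_IC is not None:
            return self.t_IC
        return getattr(self.fixed, "t_IC", 0.0)


@dataclass
class FitResult:
    """Fitted parameter estimates and their fit diagnostics."""

    estimates: dict
    rmse_N: float
    rmse_E: float
    objective: float
    n_objective_evals: int
    converged: bool
    bounds: dict
    repeat_sd: dict | None = None

    def __post_init__(self):
        for name, v in self.estimates.items():
            lo, hi = self.bounds[name]
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(f"estimate {name}={v} outside bounds [{lo},{hi}]")


def rmse(pde: PDESolution, ens: EnsembleSummary, times) -> tuple[float, float]:
    """Per-species RMSE between a PDE solution and an averaged ensemble
    over the given times (all (x, t) pairs pooled per species)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if pde.x_grid.size != ens.x_grid.size:
        raise ValueError("PDE and ensemble grids differ")
    errs_N, errs_E = [], []
    for t in times:
        Np, Ep = pde.at_time(t)
        Ne, Ee = ens.at_time(t)
        errs_N.append(Np - Ne)
        errs_E.append(Ep - Ee)
    rN = float(np.sqrt(np.mean(np.concatenate(errs_N) ** 2)))
    rE = float(np.sqrt(np.mean(np.concatenate(errs_E) ** 2)))
    return rN, rE


def _solve_candidate(spec: FitSpec, theta: dict, ens: EnsembleSummary) -> PDESolution:
    t0 = spec.start_time
    N_ic, E_ic = ens.at_time(t0)
    t_out = np.asarray(spec.fit_times, dtype=float)
    if spec.model_id == "bc":
        params = spec.fixed.with_(**theta)
        return solve_bc(params, N_ic, E_ic, t_out, t_IC=t0, x_grid=ens.x_grid)
    params = spec.fixed.with_(**theta)
    return solve_pde(params, N_ic, E_ic, t_out, x_grid=ens.x_grid)


def _objective(spec: FitSpec, theta: dict, ens: EnsembleSummary):
    try:
        pde = _solve_candidate(spec, theta, ens)
    except RuntimeError:
        return np.inf, np.inf, np.inf
    rN, rE = rmse(pde, ens, spec.fit_times)
    wN, wE = spec.species_weighting
    return wN * rN + wE * rE, rN, rE


def fit_parameters(spec: FitSpec, ens: EnsembleSummary,
                   grid_points: int = 21, xatol: float = 1e-5,
                   maxiter: int | None = None) -> FitResult:
    """Minimize the combined RMSE over the boxed domain.

    Deterministic: grid scan (for <= 2 free parameters) or multi-start
    (otherwise), then bounded Nelder-Mead polish.  Returns best-so-far
    with ``converged=False`` if the local polish does not converge.
    """
    names = list(spec.free)
    bounds = [spec.free[n] for n in names]
    n_evals = 0

    def f(vec):
        nonlocal n_evals
        n_evals += 1
        theta = dict(zip(names, vec))
        return _objective(spec, theta, ens)[0]

    # --- coarse deterministic exploration ---
    starts = []
    if len(names) <= 2:
        axes = [np.linspace(lo, hi, grid_points) if hi > lo else np.array([lo])
                for lo, hi in bounds]
        best_val, best_vec = np.inf, None
        for vec in itertools.product(*axes):
            v = f(np.asarray(vec))
            if v < best_val:
                best_val, best_vec = v, np.asarray(vec)
        starts = [best_vec]
    else:
        mids = np.array([(lo + hi) / 2 for lo, hi in bounds])
        mapped = np.array([np.clip(getattr(spec.fixed, n, m), lo, hi)
                           for n, (lo, hi), m in zip(names, bounds, mids)])
        starts = [mapped, mids]
        best_val, best_vec = np.inf, None
        for s in starts:
            v = f(s)
            if v < best_val:
                best_val, best_vec = v, s

    # --- bounded local polish ---
    converged = False
    for s in ([best_vec] if len(names) <= 2 else starts):
        degenerate = all(hi == lo for lo, hi in bounds)
        if degenerate:
            converged = True
            break
        iters = maxiter if maxiter is not None else min(200 * len(names), 500)
        res = minimize(f, s, method="Nelder-Mead", bounds=bounds,
                       options={"xatol": xatol, "fatol": 1e-8,
                                "maxiter": iters})
        if res.fun < best_val:
            best_val, best_vec = res.fun, res.x
        converged = converged or bool(res.success)

    theta = {n: float(np.clip(v, lo, hi))
             for n, v, (lo, hi) in zip(names, best_vec, bounds)}
    obj, rN, rE = _objective(spec, theta, ens)
    return FitResult(estimates=theta, rmse_N=rN, rmse_E=rE, objective=obj,
                     n_objective_evals=n_evals, converged=converged,
                     bounds=dict(zip(names, bounds)))


def repeat_uncertainty(make_spec, config: CAConfig, M: int, n_repeats: int,
                       base_seed: int, record_K=None, engine: str = "numba"):
    """Across-ensemble repeat variability of the fitted parameters.

    Runs ``n_repeats`` independent ensembles (repeat r uses the disjoint
    seed block base_seed + r*M ... base_seed + (r+1)*M - 1), refits each,
    and reports the across-repeat mean and standard deviation per
    parameter (the +- companion of a fitted value).

    ``make_spec`` maps an EnsembleSummary to a FitSpec (or is a FitSpec,
    reused for every repeat).
    """
    from .ca import run_ensemble

    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if record_K is None:
        record_K = list(range(config.K_IC, config.K_max + 1, config.K_IC))
    fits = []
    for r in range(n_repeats):
        ens = run_ensemble(config, M, base_seed + r * M, record_K, engine=engine)
        spec = make_spec(ens) if callable(make_spec) else make_spec
        fits.append(fit_parameters(spec, ens))
    names = list(fits[0].estimates)
    mean = {n: float(np.mean([fr.estimates[n] for fr in fits])) for n in names}
    sd = {n: float(np.std([fr.estimates[n] for fr in fits], ddof=1)) for n in names}
    return mean, sd, fits


# ---------------------------------------------------------------------------
# Model/Results surface


class PDECalibration:
    """Calibration of a continuum model against an averaged CA ensemble.

    Parameters
    ----------
    ensemble : EnsembleSummary (must contain t_IC and the fit times).
    model : "model1", "model2" or "bc".
    config : CAConfig of the generating CA; fixes the mapped coefficients
        (D, chi, mu and, for the BC comparator, mu_ec = mu).
    free : names of the fitted parameters.  Defaults: ("lam", "a_n") for
        model1 with interior a_n, ("lam",) at the a_n extremes;
        ("lam", "a_e") for model2; the five transport/reaction rates
        for the BC model.
    bounds : optional dict overriding the default boxed domain.

    Examples
    --------
    >>> calib = PDECalibration(ens, model="model1", config=cfg)
    >>> res = calib.fit()
    >>> print(res.summary())
    """

    def __init__(self, ensemble: EnsembleSummary, model: str, config: CAConfig,
                 free=None, bounds=None, fit_times=FIT_TIMES_DEFAULT,
                 species_weighting=(1.0, 1.0)):
        self.ensemble = ensemble
        self.model = model
        self.config = config
        mapped = map_parameters(config)
        if model in ("model1", "model2"):
            B = 0 if model == "model1" else 1
            self.fixed = mapped.with_(B=B)
            if free is None:
                if model == "model1":
                    free = ("lam",) if config.a_n in (0.0, 1.0) else ("lam", "a_n")
                else:
                    free = ("lam", "a_e")
        elif model == "bc":
            self.fixed = BCParams(D_bc=mapped.D, chi_bc=mapped.chi,
                                  lam_bc=mapped.lam, beta_n=mapped.mu * config.a_n,
                                  beta_e=0.0, mu_ec=mapped.mu)
            if free is None:
                free = ("D_bc", "chi_bc", "lam_bc", "beta_n", "beta_e")
        else:
            raise ValueError(f"unknown model {model!r}")
        free_bounds = {}
        for name in free:
            if bounds and name in bounds:
                free_bounds[name] = tuple(bounds[name])
            elif model == "bc":
                free_bounds[name] = self._bc_default_bound(name, mapped)
            else:
                free_bounds[name] = default_bounds(name, config)
        self.spec = FitSpec(model_id=model, free=free_bounds, fixed=self.fixed,
                            fit_times=tuple(fit_times),
                            species_weighting=tuple(species_weighting),
                            t_IC=mapped.t_IC)

    @staticmethod
    def _bc_default_bound(name, mapped):
        # anastomosis sinks: up to the motility rate (their per-capita
        # ceiling); branching: up to the mapped rate, as in the non-linear
        # fits (correlations slow effective branching); transport: up to
        # a few times the mapped coefficients
        if name in ("beta_n", "beta_e"):
            return (0.0, mapped.mu)
        if name == "lam_bc":
            hi = mapped.lam if mapped.lam > 0 else mapped.mu / 100.0
            return (0.0, hi)
        scale = {"D_bc": mapped.D, "chi_bc": mapped.chi}[name]
        return (0.0, 5.0 * scale if scale > 0 else 1.0)

    def fit(self, grid_points: int = 21, xatol: float = 1e-5,
            maxiter: int | None = None) -> "CalibrationResults":
        result = fit_parameters(self.spec, self.ensemble,
                                grid_points=grid_points, xatol=xatol,
                                maxiter=maxiter)
        return CalibrationResults(self, result)


class CalibrationResults:
    """Results of a PDE-to-ensemble calibration.

    Attributes
    ----------
    params : dict of fitted values (tilde parameters).
    rmse_N, rmse_E : per-species fit errors at the optimum.
    bse : across-ensemble repeat standard deviations, populated by
        :meth:`add_repeat_uncertainty`.
    """

    def __init__(self, model: PDECalibration, result: FitResult):
        self.model = model
        self.result = result
        self.params = result.estimates
        self.rmse_N = result.rmse_N
        self.rmse_E = result.rmse_E
        self.bse: dict | None = result.repeat_sd

    def add_repeat_uncertainty(self, M: int, n_repeats: int = 5,
                               base_seed: int = 0, engine: str = "numba"):
        """Quantify across-ensemble variability by re-running and refitting
        n_repeats independent ensembles of size M."""
        mean, sd, _ = repeat_uncertainty(self.model.spec, self.model.config,
                                         M, n_repeats, base_seed, engine=engine)
        self.bse = sd
        return mean, sd

    def solution(self) -> PDESolution:
        """PDE solution at the fitted optimum over the fit times."""
        return _solve_candidate(self.model.spec, self.params, self.model.ensemble)

    def summary(self) -> str:
        lines = [
            "Continuum model calibration",
            "=" * 46,
            f"model:            {self.model.model}",
            f"ensemble size M:  {self.model.ensemble.M}",
            "fit times:        ["
            + ", ".join(f"{t:g}" for t in self.model.spec.fit_times) + "]",
            f"objective evals:  {self.result.n_objective_evals}",
            f"converged:        {self.result.converged}",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'repeat sd':>12}{'bounds':>12}",
        ]
        for name, v in self.params.items():
            sd = f"{self.bse[name]:.4g}" if self.bse and name in self.bse else "-"
            lo, hi = self.result.bounds[name]
            lines.append(f"{name:<10}{v:>12.4f}{sd:>12}{f'[{lo:g},{hi:g}]':>12}")
        lines += [
            "-" * 46,
            f"rmse_N: {self.rmse_N:.5f}   rmse_E: {self.rmse_E:.5f}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        pieces = ", ".join(f"{k}={v:.4f}" for k, v in self.params.items())
        return f"<CalibrationResults {self.model.model}: {pieces}>"
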