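"""Model fitting: FIML optimization, fit indices, SEs, bootstrap CIs.

The optimizer is quasi-Newton (L-BFGS-B) on the flat unconstrained parameter
vector (variances on the log scale).  Convergence follows a gradient
max-norm criterion of 1e-5 and a relative log-likelihood change of 1e-9,
with an iteration cap of 2000 and three jittered restarts (fixed sub-seeds)
if the first start fails.  Standard errors come from the inverse of the
numerically differentiated observed information at the maximizer,
back-transformed to the natural scale through the parameterization's
Jacobian.  Bootstrap confidence intervals resample dyads (whole rows) with
replacement and use percentile limits.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import coefficients as coef_mod
from .data import PanelData
from .likelihood import (PatternStats, baseline_df, fit_baseline,
                         fit_saturated)
from .spec import (ModelSpec, ParameterSet, count_free_parameters,
                   degrees_of_freedom, flatten_parameters, parameter_layout,
                   template_parameters, unflatten_parameters)

__all__ = ["FitResult", "fit", "fit_indices", "start_values", "bootstrap_ci",
           "BootstrapResult"]

log = logging.getLogger("lstar")

_GTOL = 1e-5
_FTOL = 1e-9
_MAXITER = 2000


@dataclass
class FitResult:
    """Estimates, likelihoods, fit indices and diagnostics of one fit."""

    spec: ModelSpec
    params: ParameterSet
    x: np.ndarray  # flat unconstrained estimate
    loglik_model: float
    loglik_saturated: float
    loglik_baseline: float
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    rmsea: float
    converged: bool
    n_used: int
    se: np.ndarray | None = None  # natural-scale per-free-parameter SEs
    param_names: list = field(default_factory=list)
    optimizer_report: dict = field(default_factory=dict)

    @property
    def estimates(self) -> pd.DataFrame:
        """Free parameters on the natural scale, with SEs when available."""
        layout = parameter_layout(self.spec)
        values = [_natural_value(self.params, slot) for slot in layout]
        frame = pd.DataFrame({"estimate": values},
                             index=[s.name for s in layout])
        if self.se is not None:
            frame["se"] = self.se
        return frame

    def summary(self) -> str:
        lines = [
            f"model: {'MR-LST-AR' if self.spec.is_multi_rater else 'LST-AR'} "
            f"(I={self.spec.n_indicators}, L={self.spec.n_occasions}, "
            f"K={self.spec.n_raters})",
            f"n = {self.n_used}, free parameters = "
            f"{count_free_parameters(self.spec)}, converged = {self.converged}",
            f"loglik = {self.loglik_model:.3f} "
            f"(saturated {self.loglik_saturated:.3f}, "
            f"baseline {self.loglik_baseline:.3f})",
            f"chi2({self.df}) = {self.chi2:.3f}   "
            f"CFI = {self.cfi:.3f}   RMSEA = {self.rmsea:.3f}",
        ]
        lines.append("fit advisories: "
                     + ("chi2 < 2*df OK" if self.chi2 < 2 * self.df
                        else "chi2 >= 2*df")
                     + (", CFI > 0.97 OK" if self.cfi > 0.97 else ", CFI <= 0.97")
                     + (", RMSEA < 0.05 OK" if self.rmsea < 0.05
                        else ", RMSEA >= 0.05"))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "cfi": self.cfi,
            "rmsea": self.rmsea, "loglik_model": self.loglik_model,
            "loglik_saturated": self.loglik_saturated,
            "loglik_baseline": self.loglik_baseline,
            "converged": self.converged, "n_used": self.n_used,
            "optimizer_report": {k: v for k, v in self.optimizer_report.items()
                                 if isinstance(v, (int, float, str, bool))},
        }


def _natural_value(params: ParameterSet, slot) -> float:
    fname, idx = slot.targets[0]
    return float(getattr(params, fname)[idx])


def fit_indices(loglik_model: float, loglik_saturated: float,
                loglik_baseline: float, df_model: int, df_baseline: int,
                n: int) -> tuple[float, float, float]:
    """(chi2, CFI, RMSEA) from the three log-likelihoods.

    chi2 = 2(ll_sat - ll_mod); CFI compares the excess over df with the
    baseline's; RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))), NaN at df=0.
    """
    if n < 2:
        raise ValueError("fit indices need n >= 2")
    chi2 = 2.0 * (loglik_saturated - loglik_model)
    chi2_b = 2.0 * (loglik_saturated - loglik_baseline)
    excess = max(chi2 - df_model, 0.0)
    denom = max(chi2_b - df_baseline, chi2 - df_model, 1e-12)
    cfi = 1.0 - excess / denom
    cfi = float(min(max(cfi, 0.0), 1.0))
    if df_model <= 0:
        rmsea = float("nan")
    else:
        rmsea = float(np.sqrt(excess / (df_model * (n - 1))))
    return float(chi2), cfi, rmsea


# ----------------------------------------------------------------------
# Start values
# ----------------------------------------------------------------------


def start_values(spec: ModelSpec, data: PanelData) -> ParameterSet:
    """Deterministic, cheap starting values.

    Intercepts at column means; error variances at half the column
    variances; trait (co)variances from occasion-averaged cross-occasion
    indicator covariances; state-residual variances at a quarter of the mean
    column variance; free loadings at 1 except the non-reference rater's
    trait loadings at 0.5; autoregressive weights at 0.3.
    """
    data.check_spec(spec)
    I, K, L = spec.n_indicators, spec.n_raters, spec.n_occasions
    vals = np.ma.masked_invalid(data.values)
    col_mean = np.asarray(vals.mean(axis=0))
    col_var = np.clip(np.asarray(vals.var(axis=0)), 1e-4, None)
    cov = np.asarray(np.ma.cov(vals, rowvar=False, bias=True))
    cov = np.where(np.isfinite(cov), cov, 0.0)

    params = template_parameters(spec)
    ref = spec.reference_rater
    for k in range(K):
        for l in range(L):
            for i in range(I):
                r = spec.observed_index(i, k, l)
                params.intercepts[i, k, l] = col_mean[r]
                params.err_var[i, k, l] = col_var[r] / 2.0

    def cross_occasion_cov(i, j, k):
        acc = [cov[spec.observed_index(i, k, l), spec.observed_index(j, k, m)]
               for l in range(L) for m in range(L) if l != m]
        return float(np.mean(acc))

    floor = 1e-3 * float(col_var.mean())
    for i in range(I):
        params.phi[i, i] = max(cross_occasion_cov(i, i, ref), floor)
    for i in range(I):
        for j in range(i + 1, I):
            params.phi[i, j] = params.phi[j, i] = cross_occasion_cov(i, j, ref)
    if spec.is_multi_rater:
        nr = spec.nonreference_rater
        for i in range(I):
            params.phi[I + i, I + i] = max(
                cross_occasion_cov(i, i, nr) / 2.0, floor)
        for i in range(I):
            for j in range(i + 1, I):
                c = cross_occasion_cov(i, j, nr) / 2.0
                params.phi[I + i, I + j] = params.phi[I + j, I + i] = c
        params.lam_T[:, nr, :] = 0.5
        params.beta_ps[:] = 0.3
        params.srps_var[:] = max(float(col_var.mean()) / 4.0, floor)
    params.beta[:] = 0.3
    params.sr_var[:] = max(float(col_var.mean()) / 4.0, floor)
    return params


# ----------------------------------------------------------------------
# Fit
# ----------------------------------------------------------------------


def fit(
    spec: ModelSpec,
    data: PanelData,
    start: ParameterSet | None = None,
    compute_se: bool = True,
    multi_start: bool = True,
    compute_indices: bool = True,
    precondition: np.ndarray | None = None,
    _stats: PatternStats | None = None,
    _saturated: tuple | None = None,
) -> FitResult:
    """FIML fit of the model to panel data.

    Deterministic given (data, start, optimizer settings).  Non-convergence
    is reported in the result (``converged=False`` with the best values
    found), never silently ignored.
    """
    data.check_spec(spec)
    if data.n == 0:
        raise ValueError("cannot fit an empty panel")
    stats = _stats if _stats is not None else PatternStats(data)
    layout = parameter_layout(spec)
    from ._objective import FimlObjective

    objective = FimlObjective(spec, stats)
    negloglik = objective.value

    if start is None:
        start = start_values(spec, data)
    x0 = flatten_parameters(start, spec)

    # preconditioning: optimize in x = S y coordinates so the curvature is
    # roughly isotropic (intercept curvature scales with n/var, variance and
    # autoregression curvature is orders of magnitude smaller).  S is either
    # a per-coordinate scale vector or a full linear map (inverse Cholesky of
    # the observed information of a reference fit).
    if precondition is None:
        to_x = lambda y: y
        to_y = lambda x: x
        to_grad = lambda g: g
    else:
        S = np.asarray(precondition, dtype=float)
        if S.ndim == 1:
            to_x = lambda y: S * y
            to_y = lambda x: x / S
            to_grad = lambda g: g * S
        else:
            S_inv = np.linalg.inv(S)
            to_x = lambda y: S @ y
            to_y = lambda x: S_inv @ x
            to_grad = lambda g: S.T @ g

    def fun(y):
        f, g = objective.value_and_grad(to_x(y))
        return f, to_grad(g)

    t0 = time.perf_counter()
    attempts = [to_y(x0)]
    if multi_start:
        rng = np.random.default_rng(20210701)  # fixed jitter sub-seed
        attempts += [to_y(x0 + 0.1 * rng.standard_normal(x0.size))
                     for _ in range(3)]
    best = None
    report: dict = {}
    for trial, ys in enumerate(attempts):
        res = minimize(
            fun, ys, jac=True, method="L-BFGS-B",
            options={"maxiter": _MAXITER, "ftol": _FTOL, "gtol": _GTOL,
                     "maxfun": 10 * _MAXITER},
        )
        ok = bool(res.success) and np.isfinite(res.fun)
        if best is None or res.fun < best.fun:
            best = res
            report = {"trial": trial, "success": ok, "message": str(res.message),
                      "n_iter": int(res.nit), "n_eval": int(res.nfev)}
        if ok:
            break
    converged = bool(report.get("success", False))
    if not converged:
        log.warning("optimizer did not converge: %s", report.get("message"))
    xhat = to_x(best.x)
    params = unflatten_parameters(xhat, spec)
    ll_model = -float(best.fun)

    dfm = degrees_of_freedom(spec)
    dfb = baseline_df(data.n_columns)
    sat_info: dict = {"skipped": True}
    if compute_indices:
        if _saturated is not None:
            mu_s, sigma_s, ll_sat, sat_info = _saturated
        else:
            mu_s, sigma_s, ll_sat, sat_info = fit_saturated(data)
        ll_base = fit_baseline(data)
        chi2, cfi, rmsea = fit_indices(ll_model, ll_sat, ll_base, dfm, dfb,
                                       data.n)
        chi2_b = 2.0 * (ll_sat - ll_base)
    else:
        ll_sat = ll_base = chi2 = chi2_b = cfi = rmsea = float("nan")

    se = None
    if compute_se and converged:
        se = _standard_errors(negloglik, xhat, layout)
    report.update(objective.diagnostics)
    report["saturated"] = sat_info
    report["seconds"] = time.perf_counter() - t0

    return FitResult(
        spec=spec, params=params, x=xhat,
        loglik_model=ll_model, loglik_saturated=float(ll_sat),
        loglik_baseline=float(ll_base),
        chi2=chi2, df=dfm, chi2_baseline=float(chi2_b), df_baseline=dfb,
        cfi=cfi, rmsea=rmsea, converged=converged, n_used=data.n,
        se=se, param_names=[s.name for s in layout],
        optimizer_report=report,
    )


def hessian_preconditioner(spec: ModelSpec, data: PanelData,
                           at: ParameterSet) -> np.ndarray:
    """Inverse-Cholesky preconditioner from the observed information at `at`.

    Returns S with S' H S approximately the identity (H the Hessian of the
    negative log-likelihood, by central differences of the analytic
    gradient); intended to be computed once per dataset and reused across
    bootstrap refits.  Falls back to a diagonal scale when H is not positive
    definite.
    """
    from ._objective import FimlObjective

    objective = FimlObjective(spec, PatternStats(data))
    x = flatten_parameters(at, spec)
    h = 1e-4
    H = np.empty((x.size, x.size))
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = h
        gp = objective.value_and_grad(x + e)[1]
        gm = objective.value_and_grad(x - e)[1]
        H[j] = (gp - gm) / (2 * h)
    H = (H + H.T) / 2.0
    try:
        L = np.linalg.cholesky(H)
        return np.linalg.inv(L).T
    except np.linalg.LinAlgError:
        diag = np.where(np.diag(H) > 1e-8, np.diag(H), 1.0)
        return 1.0 / np.sqrt(diag)


def _standard_errors(negloglik, xhat: np.ndarray, layout) -> np.ndarray:
    """Inverse observed information, back-transformed to the natural scale."""
    from statsmodels.tools.numdiff import approx_hess1

    hess = approx_hess1(xhat, negloglik)
    hess = (hess + hess.T) / 2.0
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    var = np.clip(np.diag(cov), 0.0, None)
    se = np.sqrt(var)
    # delta method: d(exp(x))/dx = exp(x) = natural value for log slots
    jac = np.array([np.exp(xhat[j]) if slot.transform == "log" else 1.0
                    for j, slot in enumerate(layout)])
    return se * jac


# ----------------------------------------------------------------------
# Bootstrap
# ----------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Percentile intervals for free parameters and coefficients."""

    param_intervals: pd.DataFrame  # index: parameter name; lower/upper
    coef_intervals: pd.DataFrame  # index: (indicator, rater, occasion, coefficient)
    level: float
    n_resamples: int
    n_failed: int
    warning: str | None = None


def bootstrap_ci(
    spec: ModelSpec,
    data: PanelData,
    B: int,
    seed: int,
    level: float = 0.95,
    start: ParameterSet | None = None,
    fit_result: FitResult | None = None,
) -> BootstrapResult:
    """Nonparametric dyad bootstrap: resample rows, refit, take percentiles.

    Replicates start at the full-data maximizer, preserving within-dyad
    dependence by resampling whole rows.  Non-converged replicates are
    dropped and counted; more than 20% failures attaches a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if fit_result is None:
        fit_result = fit(spec, data, start=start, compute_se=False)
    layout = parameter_layout(spec)
    names = [s.name for s in layout]
    scale = hessian_preconditioner(spec, data, fit_result.params)
    rng = np.random.default_rng(seed)
    param_draws = []
    coef_draws = []
    n_failed = 0
    for b in range(B):
        rows = rng.integers(0, data.n, size=data.n)
        resample = data.subsample(rows)
        try:
            res = fit(spec, resample, start=fit_result.params,
                      compute_se=False, multi_start=False,
                      compute_indices=False, precondition=scale)
        except Exception:  # pathological resample
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        param_draws.append([_natural_value(res.params, s) for s in layout])
        table = coef_mod.coefficient_table(res.params, spec)
        coef_draws.append(table.to_numpy().ravel())
    if not param_draws:
        raise RuntimeError("every bootstrap replicate failed to converge")
    alpha = (1.0 - level) / 2.0
    pd_arr = np.asarray(param_draws)
    lo, hi = np.nanquantile(pd_arr, [alpha, 1.0 - alpha], axis=0)
    param_intervals = pd.DataFrame({"lower": lo, "upper": hi}, index=names)

    template = coef_mod.coefficient_table(fit_result.params, spec)
    cd = np.asarray(coef_draws)
    with warnings.catch_warnings():
        # undefined coefficient cells (occasion 1, reference rater) are NaN
        # in every draw by design
        warnings.simplefilter("ignore", RuntimeWarning)
        clo = np.nanquantile(cd, alpha, axis=0)
        chi = np.nanquantile(cd, 1.0 - alpha, axis=0)
    long_index = pd.MultiIndex.from_tuples(
        [(i, k, l, c) for (i, k, l) in template.index for c in template.columns],
        names=["indicator", "rater", "occasion", "coefficient"],
    )
    coef_intervals = pd.DataFrame(
        {"lower": clo, "upper": chi}, index=long_index
    ).dropna(how="all")

    warning = None
    if n_failed > 0.2 * B:
        warning = (f"{n_failed}/{B} bootstrap replicates failed to converge; "
                   "intervals may be unreliable")
        log.warning(warning)
    return BootstrapResult(
        param_intervals=param_intervals, coef_intervals=coef_intervals,
        level=level, n_resamples=B, n_failed=n_failed, warning=warning,
    )
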