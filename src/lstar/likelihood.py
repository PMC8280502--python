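"""Multivariate-normal likelihoods under missing data.

Full-information maximum likelihood (FIML) evaluates each dyad's observed
subvector under the corresponding sub-mean and sub-covariance of the implied
moments.  Rows are grouped by missingness pattern, and the per-pattern
contribution is evaluated from sufficient statistics (count, mean, scatter),
which is algebraically identical to the row-by-row sum:

    ll_g = -n_g/2 [ p_g log(2 pi) + log|S_g| + tr(S_g^-1 C_g)
                    + (ybar_g - mu_g)' S_g^-1 (ybar_g - mu_g) ]

with C_g the ML (divide-by-n_g) scatter around the pattern mean.  The
saturated (unstructured) model is fitted by the standard EM algorithm for
the multivariate normal; the baseline (independence) model factorizes into
per-column univariate fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import PanelData
from .moments import implied_moments
from .spec import ModelSpec, ParameterSet

__all__ = [
    "PatternStats",
    "fiml_loglik",
    "gaussian_loglik_from_stats",
    "fit_saturated",
    "fit_baseline",
]

log = logging.getLogger("lstar")

_LOG2PI = float(np.log(2.0 * np.pi))
_PENALTY = -1.0e12


@dataclass
class _Pattern:
    observed: np.ndarray  # observed column indices
    n: int
    mean: np.ndarray
    scatter: np.ndarray  # ML covariance around the pattern mean
    rows: np.ndarray  # row indices (for the EM E-step)
    values: np.ndarray  # observed sub-matrix (n, p_obs)


class PatternStats:
    """Missingness-pattern grouping with per-pattern sufficient statistics."""

    def __init__(self, data: PanelData):
        self.n_total = data.n
        self.n_columns = data.n_columns
        self.patterns: list[_Pattern] = []
        mask = data.missing_mask
        # lexicographic key per row
        keys = np.packbits(mask, axis=1)
        order = np.lexsort(keys.T[::-1])
        sorted_keys = keys[order]
        boundaries = np.any(sorted_keys[1:] != sorted_keys[:-1], axis=1)
        starts = np.concatenate([[0], np.nonzero(boundaries)[0] + 1,
                                 [len(order)]])
        for a, b in zip(starts[:-1], starts[1:]):
            rows = order[a:b]
            obs = np.nonzero(~mask[rows[0]])[0]
            vals = data.values[np.ix_(rows, obs)]
            mean = vals.mean(axis=0)
            centered = vals - mean
            scatter = centered.T @ centered / vals.shape[0]
            self.patterns.append(_Pattern(
                observed=obs, n=len(rows), mean=mean, scatter=scatter,
                rows=rows, values=vals,
            ))

    @property
    def complete(self) -> bool:
        return (len(self.patterns) == 1
                and self.patterns[0].observed.size == self.n_columns)


def gaussian_loglik_from_stats(
    mu_sub: np.ndarray, sigma_sub: np.ndarray,
    n: int, mean: np.ndarray, scatter: np.ndarray,
) -> float:
    """MVN log-likelihood of n iid rows from (count, mean, ML scatter).

    Returns a large finite penalty when the covariance sub-block is not
    positive definite (so the optimizer can back out of the region).
    """
    p = mu_sub.shape[0]
    try:
        chol = np.linalg.cholesky(sigma_sub)
    except np.linalg.LinAlgError:
        return _PENALTY * (1.0 + float(-min(np.linalg.eigvalsh(sigma_sub).min(), 0.0)))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    d = mean - mu_sub
    z = np.linalg.solve(chol, d.reshape(-1, 1)).ravel()
    quad_mean = float(z @ z)
    w = np.linalg.solve(chol, scatter)
    w = np.linalg.solve(chol.T, w)  # sigma^-1 scatter
    trace = float(np.trace(w))
    return -0.5 * n * (p * _LOG2PI + logdet + trace + quad_mean)


def _loglik_from_moments(mu, sigma, stats: PatternStats,
                         diagnostics: dict | None = None) -> float:
    total = 0.0
    penalized = False
    for pat in stats.patterns:
        obs = pat.observed
        ll = gaussian_loglik_from_stats(
            mu[obs], sigma[np.ix_(obs, obs)], pat.n, pat.mean, pat.scatter
        )
        if ll <= _PENALTY:
            penalized = True
        total += ll
    if diagnostics is not None and penalized:
        diagnostics["nonpd_penalty"] = diagnostics.get("nonpd_penalty", 0) + 1
    return total


def fiml_loglik(
    params: ParameterSet, spec: ModelSpec, data: PanelData,
    stats: PatternStats | None = None, diagnostics: dict | None = None,
) -> float:
    """FIML log-likelihood of the data under the model-implied moments."""
    data.check_spec(spec)
    if stats is None:
        stats = PatternStats(data)
    mom = implied_moments(params, spec)
    return _loglik_from_moments(mom.mu, mom.sigma, stats, diagnostics)


# ----------------------------------------------------------------------
# Saturated (unstructured) model via EM
# ----------------------------------------------------------------------


def _initial_moments(data: PanelData) -> tuple[np.ndarray, np.ndarray]:
    vals = np.ma.masked_invalid(data.values)
    mu = np.asarray(vals.mean(axis=0))
    cov = np.asarray(np.ma.cov(vals, rowvar=False, bias=True))
    cov = np.where(np.isfinite(cov), cov, 0.0)
    var = np.clip(np.diag(cov), 1e-8, None)
    np.fill_diagonal(cov, var)
    # shrink off-diagonals toward zero so the start is positive definite
    d = np.sqrt(var)
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -0.95, 0.95)
    np.fill_diagonal(corr, 1.0)
    cov = 0.9 * corr * np.outer(d, d)
    np.fill_diagonal(cov, var)
    return mu, (cov + cov.T) / 2


def fit_saturated(
    data: PanelData, max_iter: int = 500, tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """ML mean and covariance under missingness (EM); also the loglik.

    With complete data this is the closed-form sample mean and divide-by-n
    covariance.  Returns ``(mu, sigma, loglik, info)`` where ``info`` carries
    convergence diagnostics.
    """
    stats = PatternStats(data)
    p = data.n_columns
    n = data.n
    if stats.complete:
        pat = stats.patterns[0]
        mu, sigma = pat.mean.copy(), pat.scatter.copy()
        ll = _loglik_from_moments(mu, sigma, stats)
        return mu, sigma, ll, {"converged": True, "iterations": 0}
    mu, sigma = _initial_moments(data)
    ll_old = -np.inf
    info = {"converged": False, "iterations": max_iter}
    for it in range(max_iter):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        for pat in stats.patterns:
            obs = pat.observed
            mis = np.setdiff1d(np.arange(p), obs, assume_unique=True)
            y = pat.values
            if mis.size == 0:
                t1[obs] += y.sum(axis=0)
                t2[np.ix_(obs, obs)] += y.T @ y
                continue
            s_oo = sigma[np.ix_(obs, obs)]
            s_mo = sigma[np.ix_(mis, obs)]
            b = np.linalg.solve(s_oo, s_mo.T).T  # (m, o)
            cond_cov = sigma[np.ix_(mis, mis)] - b @ s_mo.T
            ym = mu[mis] + (y - mu[obs]) @ b.T  # (n_g, m)
            t1[obs] += y.sum(axis=0)
            t1[mis] += ym.sum(axis=0)
            t2[np.ix_(obs, obs)] += y.T @ y
            t2[np.ix_(obs, mis)] += y.T @ ym
            t2[np.ix_(mis, obs)] += ym.T @ y
            t2[np.ix_(mis, mis)] += ym.T @ ym + pat.n * cond_cov
        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2
        ll = _loglik_from_moments(mu, sigma, stats)
        if np.isfinite(ll) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            info = {"converged": True, "iterations": it + 1}
            break
        ll_old = ll
    else:
        log.warning("saturated-model EM hit the iteration cap (%d)", max_iter)
    ll = _loglik_from_moments(mu, sigma, stats)
    return mu, sigma, ll, info


def fit_baseline(data: PanelData) -> float:
    """Independence-model log-likelihood (free means/variances, zero cov).

    With a diagonal covariance the likelihood factorizes over cells, so the
    MLE is the per-column mean and divide-by-n variance of the observed
    entries of each column.
    """
    total = 0.0
    for j in range(data.n_columns):
        col = data.values[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        v = max(float(col.var()), 1e-12)
        total += -0.5 * col.size * (_LOG2PI + np.log(v) + 1.0)
    return total


def baseline_df(n_columns: int) -> int:
    p = n_columns
    return p * (p + 3) // 2 - 2 * p
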