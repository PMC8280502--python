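"""Model-implied moment structure.

Assembles the mean vector and covariance matrix implied by a
:class:`~lstar.spec.ParameterSet` via the reduced form

    sigma = Lambda * Phi_latent * Lambda' + diag(theta),    mu = intercepts,

where the occasion-factor blocks of ``Phi_latent`` are computed analytically
from the AR(1) recursion Var(O_l) = beta_l^2 Var(O_{l-1}) + Var(SR_l),
Cov(O_l, O_m) = (prod of betas from m+1 to l) * Var(O_m).  The same operator
serves the rater-specific OPS process.  No graph solver is involved; the
closed form is exact for this model class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spec import ModelSpec, ParameterSet, _check_conformity

__all__ = ["MomentStructure", "ar_factor_covariance", "implied_moments"]


@dataclass
class MomentStructure:
    """Implied mean, covariance and the latent covariance they came from."""

    mu: np.ndarray  # (p,)
    sigma: np.ndarray  # (p, p)
    latent_cov: np.ndarray  # (q, q)
    loading_matrix: np.ndarray  # (p, q)
    error_var: np.ndarray  # (p,)
    column_names: list
    latent_names: list

    def to_frames(self) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
        mu = pd.Series(self.mu, index=self.column_names, name="mean")
        sigma = pd.DataFrame(self.sigma, index=self.column_names,
                             columns=self.column_names)
        latent = pd.DataFrame(self.latent_cov, index=self.latent_names,
                              columns=self.latent_names)
        return mu, sigma, latent

    def write_csv(self, prefix: str) -> None:
        """Labeled CSV dump (``<prefix>_mean/cov/latent_cov.csv``)."""
        mu, sigma, latent = self.to_frames()
        mu.to_csv(f"{prefix}_mean.csv", header=True)
        sigma.to_csv(f"{prefix}_cov.csv")
        latent.to_csv(f"{prefix}_latent_cov.csv")


def ar_factor_covariance(betas: np.ndarray, residual_vars: np.ndarray) -> np.ndarray:
    """Covariance of an occasion-factor chain O_1..O_L.

    ``O_1`` equals the first state residual; for l > 1,
    ``O_l = betas[l-2] * O_{l-1} + SR_l`` with independent zero-mean
    residuals of variance ``residual_vars[l-1]``.  Degenerate zero variances
    are allowed.
    """
    betas = np.asarray(betas, dtype=float)
    rv = np.asarray(residual_vars, dtype=float)
    L = rv.shape[0]
    if betas.shape != (L - 1,):
        raise ValueError("need len(betas) == len(residual_vars) - 1")
    if np.any(rv < 0):
        raise ValueError("residual variances must be nonnegative")
    cov = np.zeros((L, L))
    cov[0, 0] = rv[0]
    for l in range(1, L):
        cov[l, l] = betas[l - 1] ** 2 * cov[l - 1, l - 1] + rv[l]
        # Cov(O_l, O_m) = beta_l * Cov(O_{l-1}, O_m) for m < l
        for m in range(l):
            cov[l, m] = cov[m, l] = betas[l - 1] * cov[l - 1, m]
    return cov


def latent_covariance(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Block-diagonal latent covariance: traits, O-chain (, OPS-chain)."""
    nT = spec.n_trait_factors
    L = spec.n_occasions
    q = spec.n_latent
    cov = np.zeros((q, q))
    cov[:nT, :nT] = params.phi
    o0 = nT
    cov[o0:o0 + L, o0:o0 + L] = ar_factor_covariance(params.beta, params.sr_var)
    if spec.is_multi_rater:
        p0 = nT + L
        cov[p0:p0 + L, p0:p0 + L] = ar_factor_covariance(
            params.beta_ps, params.srps_var
        )
    return cov


def loading_matrix(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    I, K, L = spec.n_indicators, spec.n_raters, spec.n_occasions
    nT = spec.n_trait_factors
    lam = np.zeros((spec.n_observed, spec.n_latent))
    nr = spec.nonreference_rater if spec.is_multi_rater else None
    o0 = nT
    p0 = nT + L
    for k in range(K):
        for l in range(L):
            for i in range(I):
                row = spec.observed_index(i, k, l)
                lam[row, i] = params.lam_T[i, k, l]
                lam[row, o0 + l] = params.lam_O[i, k, l]
                if spec.is_multi_rater and k == nr:
                    lam[row, I + i] = params.lam_TPS[i, l]
                    lam[row, p0 + l] = params.lam_OPS[i, l]
    return lam


def implied_moments(params: ParameterSet, spec: ModelSpec) -> MomentStructure:
    """Model-implied moments; exact reduced-form assembly."""
    _check_conformity(params, spec)
    I, K, L = spec.n_indicators, spec.n_raters, spec.n_occasions
    lam = loading_matrix(params, spec)
    lcov = latent_covariance(params, spec)
    theta = np.zeros(spec.n_observed)
    mu = np.zeros(spec.n_observed)
    for k in range(K):
        for l in range(L):
            for i in range(I):
                row = spec.observed_index(i, k, l)
                theta[row] = params.err_var[i, k, l]
                mu[row] = params.intercepts[i, k, l]
    sigma = lam @ lcov @ lam.T + np.diag(theta)
    sigma = (sigma + sigma.T) / 2.0
    return MomentStructure(
        mu=mu,
        sigma=sigma,
        latent_cov=lcov,
        loading_matrix=lam,
        error_var=theta,
        column_names=spec.column_names(),
        latent_names=spec.latent_names(),
    )
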