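"""Variance-decomposition and rater-consistency coefficients.

All coefficients are ratios of structural variance components of the
model-implied moments:

* ``Rel``            reliability, 1 - Var(E)/Var(Y)
* ``OS``             occasion specificity: state-residual share of true variance
* ``TCon``           time consistency: trait + autoregressive carry-over share
* ``Pred_trait1``    part of TCon due to the first-occasion trait
* ``UPred_trait1``   part of TCon due to accumulated situational carry-over
* ``r_S1_Sl``        error-free retest correlation of latent states
* ``RS`` / ``RCon``  rater-specific vs. rater-consistent share of the
                     non-reference rater's true variance (they sum to one);
                     sqrt(RCon) is the error-free cross-rater correlation
* ``RConPred`` / ``RSPred``  rater consistency of the trait-level variance
* ``RConTCon``       rater consistency of the time-consistent variance
* ``RConOS``         rater consistency of the occasion-specific variance;
                     sqrt is the correlation of the state residuals

Conventions: at the first occasion the time-consistent share is defined as
the trait share (so TCon = Pred = 1 - OS there) and UPred is undefined;
undefined cells are NaN, never zero.  Ratios with zero denominators are NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .moments import implied_moments
from .spec import ModelSpec, ParameterSet

__all__ = [
    "reliability",
    "occasion_specificity",
    "time_consistency",
    "predictability_trait1",
    "unpredictability_trait1",
    "state_retest_correlation",
    "state_retest_correlation_closed_form",
    "rater_specificity",
    "rater_consistency",
    "rater_consistent_pred_trait1",
    "rater_specific_pred_trait1",
    "rater_consistent_time_consistency",
    "rater_consistent_occasion_specificity",
    "coefficient_table",
    "COEFFICIENT_COLUMNS",
]

COEFFICIENT_COLUMNS = [
    "Rel", "OS", "TCon", "Pred_trait1", "UPred_trait1", "r_S1_Sl",
    "RS", "RCon", "rcon_corr", "RConOS", "rconos_corr",
    "RConTCon", "RConPred", "RSPred",
]


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


class _Components:
    """Structural variance components of one model instance."""

    def __init__(self, params: ParameterSet, spec: ModelSpec):
        self.params = params
        self.spec = spec
        self.mom = implied_moments(params, spec)
        L = spec.n_occasions
        nT = spec.n_trait_factors
        self.o_cov = self.mom.latent_cov[nT:nT + L, nT:nT + L]
        if spec.is_multi_rater:
            self.ops_cov = self.mom.latent_cov[nT + L:, nT + L:]
        else:
            self.ops_cov = None

    def is_ref(self, k: int) -> bool:
        return k == self.spec.reference_rater or not self.spec.is_multi_rater

    def var_y(self, i, k, l) -> float:
        row = self.spec.observed_index(i, k, l)
        return float(self.mom.sigma[row, row])

    def var_e(self, i, k, l) -> float:
        return float(self.params.err_var[i, k, l])

    def true_var(self, i, k, l) -> float:
        return self.var_y(i, k, l) - self.var_e(i, k, l)

    def trait_part(self, i, k, l) -> float:
        p = self.params
        out = p.lam_T[i, k, l] ** 2 * p.phi[i, i]
        if not self.is_ref(k):
            I = self.spec.n_indicators
            out += p.lam_TPS[i, l] ** 2 * p.phi[I + i, I + i]
        return float(out)

    def carry_part(self, i, k, l) -> float:
        """Accumulated situational carry-over variance (defined for l>0)."""
        if l == 0:
            return float("nan")
        p = self.params
        out = p.lam_O[i, k, l] ** 2 * p.beta[l - 1] ** 2 * self.o_cov[l - 1, l - 1]
        if not self.is_ref(k):
            out += (p.lam_OPS[i, l] ** 2 * p.beta_ps[l - 1] ** 2
                    * self.ops_cov[l - 1, l - 1])
        return float(out)

    def os_part(self, i, k, l) -> float:
        p = self.params
        out = p.lam_O[i, k, l] ** 2 * p.sr_var[l]
        if not self.is_ref(k):
            out += p.lam_OPS[i, l] ** 2 * p.srps_var[l]
        return float(out)

    def state_weights(self, i, k, l) -> np.ndarray:
        """Latent-space composite of the latent state S_ikl."""
        spec, p = self.spec, self.params
        w = np.zeros(spec.n_latent)
        nT = spec.n_trait_factors
        w[i] = p.lam_T[i, k, l]
        w[nT + l] = p.lam_O[i, k, l]
        if not self.is_ref(k):
            I, L = spec.n_indicators, spec.n_occasions
            w[I + i] = p.lam_TPS[i, l]
            w[nT + L + l] = p.lam_OPS[i, l]
        return w


def _components(params, spec) -> _Components:
    if isinstance(params, _Components):
        return params
    return _Components(params, spec)


def reliability(params, spec, i, k, l) -> float:
    c = _components(params, spec)
    vy = c.var_y(i, k, l)
    return 1.0 - c.var_e(i, k, l) / vy if vy > 0 else float("nan")


def occasion_specificity(params, spec, i, k, l) -> float:
    c = _components(params, spec)
    return _ratio(c.os_part(i, k, l), c.true_var(i, k, l))


def time_consistency(params, spec, i, k, l) -> float:
    """Trait plus carry-over share of true variance; trait share at l=1."""
    c = _components(params, spec)
    num = c.trait_part(i, k, l) + (c.carry_part(i, k, l) if l > 0 else 0.0)
    return _ratio(num, c.true_var(i, k, l))


def predictability_trait1(params, spec, i, k, l) -> float:
    c = _components(params, spec)
    return _ratio(c.trait_part(i, k, l), c.true_var(i, k, l))


def unpredictability_trait1(params, spec, i, k, l) -> float:
    if l == 0:
        return float("nan")
    c = _components(params, spec)
    return _ratio(c.carry_part(i, k, l), c.true_var(i, k, l))


def state_retest_correlation(params, spec, i, k, l) -> float:
    """Error-free correlation of S_ik1 with S_ikl from the latent covariance."""
    if l == 0:
        return float("nan")
    c = _components(params, spec)
    w1 = c.state_weights(i, k, 0)
    wl = c.state_weights(i, k, l)
    lcov = c.mom.latent_cov
    v1 = float(w1 @ lcov @ w1)
    vl = float(wl @ lcov @ wl)
    if v1 <= 0 or vl <= 0:
        return float("nan")
    return float(w1 @ lcov @ wl) / np.sqrt(v1 * vl)


def state_retest_correlation_closed_form(params, spec, i, k, l) -> float:
    """Reference-rater retest correlation via the explicit product-of-betas
    closed form (numerator: lambda_T * Var(T) + lambda_SR1 * lambda_Ol *
    prod(beta) * Var(SR_1)); must agree with the generic route."""
    c = _components(params, spec)
    if not c.is_ref(k):
        raise ValueError("closed form applies to the reference rater only")
    if l == 0:
        return float("nan")
    p = c.params
    beta_prod = float(np.prod(p.beta[:l]))
    num = (p.lam_T[i, k, l] * p.phi[i, i]
           + p.lam_O[i, k, 0] * p.lam_O[i, k, l] * beta_prod * p.sr_var[0])
    den = np.sqrt(c.true_var(i, k, 0) * c.true_var(i, k, l))
    return float(num / den) if den > 0 else float("nan")


def _require_nonref(c: _Components, k: int) -> None:
    if c.is_ref(k):
        raise ValueError(
            "rater-consistency coefficients are defined for the "
            "non-reference rater only"
        )


def rater_specificity(params, spec, i, l, k=None) -> float:
    c = _components(params, spec)
    k = c.spec.nonreference_rater if k is None else k
    _require_nonref(c, k)
    p = c.params
    I = c.spec.n_indicators
    num = (p.lam_TPS[i, l] ** 2 * p.phi[I + i, I + i]
           + p.lam_OPS[i, l] ** 2 * c.ops_cov[l, l])
    return _ratio(float(num), c.true_var(i, k, l))


def rater_consistency(params, spec, i, l, k=None) -> float:
    c = _components(params, spec)
    k = c.spec.nonreference_rater if k is None else k
    _require_nonref(c, k)
    p = c.params
    num = (p.lam_T[i, k, l] ** 2 * p.phi[i, i]
           + p.lam_O[i, k, l] ** 2 * c.o_cov[l, l])
    return _ratio(float(num), c.true_var(i, k, l))


def rater_consistent_pred_trait1(params, spec, i, l, k=None) -> float:
    """Target-shared trait variance over total trait-level variance (l>1)."""
    if l == 0:
        return float("nan")
    c = _components(params, spec)
    k = c.spec.nonreference_rater if k is None else k
    _require_nonref(c, k)
    p = c.params
    I = c.spec.n_indicators
    shared = p.lam_T[i, k, l] ** 2 * p.phi[i, i]
    specific = p.lam_TPS[i, l] ** 2 * p.phi[I + i, I + i]
    return _ratio(float(shared), float(shared + specific))


def rater_specific_pred_trait1(params, spec, i, l, k=None) -> float:
    v = rater_consistent_pred_trait1(params, spec, i, l, k)
    return 1.0 - v


def rater_consistent_time_consistency(params, spec, i, l, k=None) -> float:
    """Share of the non-reference rater's time-consistent variance explained
    by the reference rater (trait plus carry-over, over the same plus the
    rater-specific trait and carry-over); reduces to RConPred when all
    autoregressive weights vanish."""
    if l == 0:
        return float("nan")
    c = _components(params, spec)
    k = c.spec.nonreference_rater if k is None else k
    _require_nonref(c, k)
    p = c.params
    I = c.spec.n_indicators
    shared = (p.lam_T[i, k, l] ** 2 * p.phi[i, i]
              + p.lam_O[i, k, l] ** 2 * p.beta[l - 1] ** 2
              * c.o_cov[l - 1, l - 1])
    specific = (p.lam_TPS[i, l] ** 2 * p.phi[I + i, I + i]
                + p.lam_OPS[i, l] ** 2 * p.beta_ps[l - 1] ** 2
                * c.ops_cov[l - 1, l - 1])
    return _ratio(float(shared), float(shared + specific))


def rater_consistent_occasion_specificity(params, spec, i, l, k=None) -> float:
    c = _components(params, spec)
    k = c.spec.nonreference_rater if k is None else k
    _require_nonref(c, k)
    p = c.params
    shared = p.lam_O[i, k, l] ** 2 * p.sr_var[l]
    specific = p.lam_OPS[i, l] ** 2 * p.srps_var[l]
    return _ratio(float(shared), float(shared + specific))


# ----------------------------------------------------------------------
# Table rendering
# ----------------------------------------------------------------------


def coefficient_table(
    fit_or_params, spec: ModelSpec | None = None, cis: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per indicator-(rater-)occasion coefficient table.

    Accepts a fitted result (with ``params``/``spec``/``converged``) or a raw
    :class:`ParameterSet` plus spec.  Undefined cells are NaN.  When ``cis``
    (a bootstrap interval frame indexed like the long format) is given, lower
    and upper columns are attached per coefficient.
    """
    if hasattr(fit_or_params, "params") and hasattr(fit_or_params, "spec"):
        fit = fit_or_params
        if getattr(fit, "converged", True) is False:
            raise ValueError(
                "refusing to tabulate coefficients from a non-converged fit; "
                "inspect FitResult.optimizer_report"
            )
        params, spec = fit.params, fit.spec
    else:
        params = fit_or_params
        if spec is None:
            raise ValueError("spec is required when passing a ParameterSet")
    c = _Components(params, spec)
    rows = []
    index = []
    nonref = spec.nonreference_rater if spec.is_multi_rater else None
    for k in range(spec.n_raters):
        for l in range(spec.n_occasions):
            for i in range(spec.n_indicators):
                index.append((i + 1, k + 1, l + 1))
                row = {
                    "Rel": reliability(c, spec, i, k, l),
                    "OS": occasion_specificity(c, spec, i, k, l),
                    "TCon": time_consistency(c, spec, i, k, l),
                    "Pred_trait1": predictability_trait1(c, spec, i, k, l),
                    "UPred_trait1": unpredictability_trait1(c, spec, i, k, l),
                    "r_S1_Sl": state_retest_correlation(c, spec, i, k, l),
                }
                if spec.is_multi_rater and k == nonref:
                    rcon = rater_consistency(c, spec, i, l, k)
                    rconos = rater_consistent_occasion_specificity(
                        c, spec, i, l, k)
                    rconpred = rater_consistent_pred_trait1(c, spec, i, l, k)
                    row.update({
                        "RS": rater_specificity(c, spec, i, l, k),
                        "RCon": rcon,
                        "rcon_corr": np.sqrt(rcon) if rcon >= 0 else np.nan,
                        "RConOS": rconos,
                        "rconos_corr": np.sqrt(rconos) if rconos >= 0 else np.nan,
                        "RConTCon": rater_consistent_time_consistency(
                            c, spec, i, l, k),
                        "RConPred": rconpred,
                        "RSPred": 1.0 - rconpred,
                    })
                else:
                    row.update({name: np.nan for name in COEFFICIENT_COLUMNS[6:]})
                rows.append(row)
    table = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index,
                                        names=["indicator", "rater", "occasion"]),
        columns=COEFFICIENT_COLUMNS,
    )
    if cis is not None:
        lo = cis["lower"].unstack("coefficient")
        hi = cis["upper"].unstack("coefficient")
        for name in COEFFICIENT_COLUMNS:
            if name in lo.columns:
                table[f"{name}_lo"] = lo[name]
                table[f"{name}_hi"] = hi[name]
    return table


def table_to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy long format: one coefficient value per row (NaN cells dropped)."""
    value_cols = [c for c in table.columns if c in COEFFICIENT_COLUMNS]
    long = (
        table[value_cols]
        .stack()
        .rename("value")
        .rename_axis(["indicator", "rater", "occasion", "coefficient"])
        .reset_index()
    )
    return long
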