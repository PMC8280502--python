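"""Scikit-learn-style estimators wrapping the LST-AR machinery.

``LSTAR`` fits the single-rater latent state-trait model with autoregressive
effects; ``MultiRaterLSTAR`` fits the two-rater CT-C(M-1) extension.  Both
follow the sklearn estimator protocol: constructor arguments are
hyperparameters, ``fit`` accepts a wide table (DataFrame with canonical
columns, a PanelData, or an ndarray in canonical column order; NaN =
missing), and fitted quantities carry trailing underscores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import coefficients as coef_mod
from .data import PanelData
from .fitting import bootstrap_ci, fit
from .spec import ConstraintFlags, ModelSpec, count_free_parameters

__all__ = ["LSTAR", "MultiRaterLSTAR"]


class _BaseLSTAR(BaseEstimator):
    _n_raters = 1

    def __init__(self, n_indicators=3, n_occasions=4, *, constraints=None,
                 compute_se=True, bootstrap=0, level=0.95, random_state=0):
        self.n_indicators = n_indicators
        self.n_occasions = n_occasions
        self.constraints = constraints
        self.compute_se = compute_se
        self.bootstrap = bootstrap
        self.level = level
        self.random_state = random_state

    # -- plumbing ------------------------------------------------------
    def _make_spec(self) -> ModelSpec:
        return ModelSpec(
            n_indicators=self.n_indicators,
            n_occasions=self.n_occasions,
            n_raters=self._n_raters,
            constraints=self.constraints or ConstraintFlags(),
        )

    def _coerce(self, X, spec: ModelSpec) -> PanelData:
        if isinstance(X, PanelData):
            X.check_spec(spec)
            return X
        if isinstance(X, pd.DataFrame):
            return PanelData.from_frame(X, spec=spec)
        X = np.asarray(X, dtype=float)
        return PanelData.from_array(X, column_names=spec.column_names())

    # -- estimator API -------------------------------------------------
    def fit(self, X, y=None):
        """Fit by full-information maximum likelihood.

        X : wide panel, one row per dyad, NaN for missing cells.
        """
        spec = self._make_spec()
        data = self._coerce(X, spec)
        result = fit(spec, data, compute_se=self.compute_se)
        self.spec_ = spec
        self.result_ = result
        self.params_ = result.params
        self.n_features_in_ = spec.n_observed
        self.n_used_ = result.n_used
        self.loglik_ = result.loglik_model
        self.chi2_ = result.chi2
        self.df_ = result.df
        self.cfi_ = result.cfi
        self.rmsea_ = result.rmsea
        self.converged_ = result.converged
        self.se_ = result.se
        self.n_parameters_ = count_free_parameters(spec)
        if self.bootstrap:
            self.bootstrap_result_ = bootstrap_ci(
                spec, data, B=self.bootstrap, seed=self.random_state,
                level=self.level, fit_result=result,
            )
        else:
            self.bootstrap_result_ = None
        return self

    def score(self, X, y=None) -> float:
        """Mean per-row FIML log-likelihood under the fitted parameters."""
        from .likelihood import fiml_loglik

        self._check_fitted()
        data = self._coerce(X, self.spec_)
        return fiml_loglik(self.params_, self.spec_, data) / data.n

    def coefficient_table(self) -> pd.DataFrame:
        """Variance-decomposition coefficients, with bootstrap CIs if run."""
        self._check_fitted()
        cis = (self.bootstrap_result_.coef_intervals
               if self.bootstrap_result_ is not None else None)
        return coef_mod.coefficient_table(self.result_, cis=cis)

    def estimates(self) -> pd.DataFrame:
        self._check_fitted()
        return self.result_.estimates

    def summary(self) -> str:
        self._check_fitted()
        return self.result_.summary()

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted yet; call fit first")


class LSTAR(_BaseLSTAR):
    """Single-rater latent state-trait model with autoregressive effects."""

    _n_raters = 1


class MultiRaterLSTAR(_BaseLSTAR):
    """Two-rater LST-AR model in the CT-C(M-1) sense.

    The reference rater's indicators follow the single-rater structure; the
    second rater's indicators additionally load on rater-specific residual
    trait factors and an autoregressive rater-specific occasion chain.
    """

    _n_raters = 2

    def __init__(self, n_indicators=3, n_occasions=4, *, reference_rater=0,
                 constraints=None, compute_se=True, bootstrap=0, level=0.95,
                 random_state=0):
        super().__init__(n_indicators, n_occasions, constraints=constraints,
                         compute_se=compute_se, bootstrap=bootstrap,
                         level=level, random_state=random_state)
        self.reference_rater = reference_rater

    def _make_spec(self) -> ModelSpec:
        return ModelSpec(
            n_indicators=self.n_indicators,
            n_occasions=self.n_occasions,
            n_raters=2,
            reference_rater=self.reference_rater,
            constraints=self.constraints or ConstraintFlags(),
        )
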