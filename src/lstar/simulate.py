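"""Synthetic dyadic panel generation.

Draws data from the generative model: trait factors (and rater-specific
trait residuals) jointly multivariate normal, state residuals independent
normal feeding the AR(1) occasion chains, observed scores as intercepts plus
loadings times latents plus normal error.  Missingness emulates wave-level
panel attrition: all indicators of a rater-occasion cell go missing
together, as when a participant skips a wave.

Default participation rates mirror a dyadic attachment panel of n = 575
dyads observed at four waves: per-wave target participation
558/463/428/429 and parent participation 405/384/341/323 out of 575.
Because the observed wave counts are not monotone, the default mechanism is
wave-wise MCAR (independent participation per wave at those rates); a
monotone-dropout mechanism with non-increasing rates is available.

Seed handling uses one master seed with fixed sub-streams per stage
(latents, errors, mask), so switching missingness on or off never perturbs
the drawn responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PanelData
from .moments import loading_matrix
from .spec import ModelSpec, ParameterSet, build_default_spec, template_parameters

__all__ = [
    "MissingnessSpec",
    "default_missingness",
    "simulate_dataset",
    "make_paperlike_params",
    "TARGET_WAVE_RATES",
    "PARENT_WAVE_RATES",
]

_N_DYADS = 575
TARGET_WAVE_RATES = tuple(c / _N_DYADS for c in (558, 463, 428, 429))
PARENT_WAVE_RATES = tuple(c / _N_DYADS for c in (405, 384, 341, 323))


@dataclass(frozen=True)
class MissingnessSpec:
    """Wave-participation missingness: mechanism and per rater-wave rates."""

    mechanism: str = "mcar_by_occasion"  # "mcar_by_occasion" | "monotone_dropout" | "none"
    participation_rates: tuple = ()  # (K, L) nested tuples, rate in (0, 1]

    def __post_init__(self):
        if self.mechanism not in ("mcar_by_occasion", "monotone_dropout", "none"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        rates = np.asarray(self.participation_rates, dtype=float)
        if self.mechanism != "none":
            if rates.ndim != 2:
                raise ValueError("participation_rates must be rater x occasion")
            if np.any(rates <= 0) or np.any(rates > 1):
                raise ValueError("participation rates must lie in (0, 1]")
            if self.mechanism == "monotone_dropout" and np.any(
                np.diff(rates, axis=1) > 1e-12
            ):
                raise ValueError(
                    "monotone dropout needs non-increasing rates per rater"
                )

    @property
    def rates(self) -> np.ndarray:
        return np.asarray(self.participation_rates, dtype=float)


def default_missingness(spec: ModelSpec) -> MissingnessSpec:
    """Study-like per-wave participation rates for up to 4 occasions."""
    L = spec.n_occasions
    if L > 4:
        raise ValueError("default rate profile covers at most 4 occasions")
    rows = [TARGET_WAVE_RATES[:L]]
    if spec.is_multi_rater:
        parent = PARENT_WAVE_RATES[:L]
        if spec.reference_rater == 0:
            rows = [TARGET_WAVE_RATES[:L], parent]
        else:
            rows = [parent, TARGET_WAVE_RATES[:L]]
    return MissingnessSpec(mechanism="mcar_by_occasion",
                           participation_rates=tuple(map(tuple, rows)))


def _draw_mask(missing: MissingnessSpec, spec: ModelSpec, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """(n, p) boolean mask, True = missing; whole rater-wave cells drop."""
    p = spec.n_observed
    mask = np.zeros((n, p), dtype=bool)
    if missing.mechanism == "none":
        return mask
    rates = missing.rates
    if rates.shape != (spec.n_raters, spec.n_occasions):
        raise ValueError(
            f"participation_rates shape {rates.shape} does not match "
            f"(K, L) = {(spec.n_raters, spec.n_occasions)}"
        )
    for k in range(spec.n_raters):
        if missing.mechanism == "mcar_by_occasion":
            present = rng.random((n, spec.n_occasions)) < rates[k]
        else:  # monotone dropout: participate up to a last wave
            u = rng.random(n)
            # P(still present at wave l) = rates[k, l]; thresholds decreasing
            present = u[:, None] < rates[k][None, :]
        for l in range(spec.n_occasions):
            cols = [spec.observed_index(i, k, l)
                    for i in range(spec.n_indicators)]
            mask[np.ix_(~present[:, l], cols)] = True
    return mask


def simulate_latents(params: ParameterSet, spec: ModelSpec, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw the stacked latent factors (traits, O-chain, OPS-chain)."""
    nT = spec.n_trait_factors
    L = spec.n_occasions
    lat = np.zeros((n, spec.n_latent))
    phi = np.asarray(params.phi, dtype=float)
    eigval, eigvec = np.linalg.eigh((phi + phi.T) / 2)
    if eigval.min() < -1e-8:
        raise ValueError(
            "trait covariance block is not positive semidefinite "
            f"(min eigenvalue {eigval.min():.3e})"
        )
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    lat[:, :nT] = rng.standard_normal((n, nT)) @ root.T

    def chain(betas, res_vars, offset):
        sr = rng.standard_normal((n, L)) * np.sqrt(np.asarray(res_vars))
        o = np.zeros((n, L))
        o[:, 0] = sr[:, 0]
        for l in range(1, L):
            o[:, l] = betas[l - 1] * o[:, l - 1] + sr[:, l]
        lat[:, offset:offset + L] = o

    if np.any(np.asarray(params.sr_var) < 0):
        raise ValueError("state residual variances must be nonnegative")
    chain(params.beta, params.sr_var, nT)
    if spec.is_multi_rater:
        if np.any(np.asarray(params.srps_var) < 0):
            raise ValueError("rater-specific state residual variances must be "
                             "nonnegative")
        chain(params.beta_ps, params.srps_var, nT + L)
    return lat


def simulate_dataset(
    params: ParameterSet,
    spec: ModelSpec,
    n: int,
    missing: MissingnessSpec | None = None,
    seed: int = 0,
) -> PanelData:
    """Generate a dyadic panel of n rows from the model.

    Reproducible under ``seed``; sub-streams are spawned per stage so the
    response draws are identical whatever the missingness setting.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng_lat, rng_err, rng_mask = (np.random.default_rng(s)
                                  for s in ss.spawn(3))
    lat = simulate_latents(params, spec, n, rng_lat)
    lam = loading_matrix(params, spec)
    theta = np.zeros(spec.n_observed)
    mu = np.zeros(spec.n_observed)
    for k in range(spec.n_raters):
        for l in range(spec.n_occasions):
            for i in range(spec.n_indicators):
                r = spec.observed_index(i, k, l)
                theta[r] = params.err_var[i, k, l]
                mu[r] = params.intercepts[i, k, l]
    if np.any(theta < 0):
        raise ValueError("error variances must be nonnegative")
    y = mu + lat @ lam.T + rng_err.standard_normal((n, spec.n_observed)) * np.sqrt(theta)
    if missing is None:
        missing = MissingnessSpec(mechanism="none")
    mask = _draw_mask(missing, spec, n, rng_mask)
    y = np.where(mask, np.nan, y)
    return PanelData.from_array(y, column_names=spec.column_names())


def make_paperlike_params(spec: ModelSpec | None = None) -> ParameterSet:
    """Deterministic fixture for the default two-rater model.

    Chosen so the coefficient table is qualitatively study-like: high
    trait predictability with a small positive carry-over share for the
    reference rater, near-zero carry-over for the second rater, and rater
    specificity around 0.8-0.9.
    """
    if spec is None:
        spec = build_default_spec(3, 4, 2)
    if not (spec.n_indicators == 3 and spec.n_occasions == 4
            and spec.is_multi_rater):
        raise ValueError("the fixture targets the default (3, 4, 2) spec")
    I = 3
    p = template_parameters(spec)
    ref, nr = spec.reference_rater, spec.nonreference_rater

    p.intercepts[:, ref, :] = np.array([4.5, 4.45, 4.05])[:, None]
    p.intercepts[:, nr, :] = np.array([4.55, 4.5, 4.3])[:, None]

    # reference-rater (target) side
    trait_sd = np.array([0.50, 0.47, 0.60])
    trait_corr = np.array([
        [1.00, 0.51, 0.54],
        [0.51, 1.00, 0.67],
        [0.54, 0.67, 1.00],
    ])
    p.phi[:I, :I] = trait_corr * np.outer(trait_sd, trait_sd)
    p.lam_T[:, ref, 1:] = np.array([0.95, 0.95, 1.0])[:, None]
    p.lam_O[:, ref, :] = np.array([1.0, 1.05, 0.55])[:, None]
    p.beta[:] = 0.30
    p.sr_var[:] = 0.11
    p.err_var[:, ref, :] = np.array([0.10, 0.13, 0.10])[:, None]

    # non-reference (parent) side
    tps_sd = np.array([0.42, 0.45, 0.40])
    tps_corr = np.array([
        [1.00, 0.55, 0.60],
        [0.55, 1.00, 0.55],
        [0.60, 0.55, 1.00],
    ])
    p.phi[I:, I:] = tps_corr * np.outer(tps_sd, tps_sd)
    for i in range(I):
        for j in range(I):
            p.phi[i, I + j] = p.phi[I + j, i] = 0.0 if i == j else 0.02
    p.lam_T[:, nr, :] = np.array([0.37, 0.30, 0.33])[:, None]
    p.lam_TPS[:, 1:] = np.array([1.0, 1.0, 0.95])[:, None]
    p.lam_O[:, nr, :] = np.array([0.26, 0.24, 0.22])[:, None]
    p.lam_OPS[:, :] = np.array([1.0, 0.95, 0.90])[:, None]
    p.beta_ps[:] = 0.05
    p.srps_var[:] = 0.09
    p.err_var[:, nr, :] = np.array([0.10, 0.14, 0.11])[:, None]
    return p
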