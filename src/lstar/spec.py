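"""Model specification and parameter layout for LST-AR / MR-LST-AR models.

A latent state-trait model with autoregressive effects (LST-AR) decomposes
repeated measurements Y_il (indicator i, occasion l) of a single rater into
indicator-specific trait factors T_i, an occasion factor O_l following a
first-order autoregression O_l = beta_l * O_{l-1} + SR_l (O_1 = SR_1), and
measurement error.  The multi-rater extension (MR-LST-AR) adds a second rater
whose indicators load on the reference rater's trait and occasion factors plus
rater-specific residual factors (TPS_i, OPS_l) in the CT-C(M-1) sense, the
OPS process having its own autoregression.

This module defines :class:`ModelSpec` (the model instance), the
:class:`ParameterSet` container holding every structural parameter, the
free/fixed parameter layout implied by the identification and invariance
constraints, and the mapping between structured parameters and the flat
unconstrained vector the optimizer works on.

Conventions
-----------
* Internal indices are 0-based; labels shown to users are 1-based.
* Observed-variable ordering is rater-major, occasion-next, indicator-last:
  column index = (k * L + l) * I + i.
* Latent factor stacking is T_1..T_I, (TPS_1..TPS_I,) O_1..O_L (, OPS_1..OPS_L).
* Variances travel through the flat vector on a log scale; covariances of the
  trait block are unconstrained (symmetry is guaranteed by the layout,
  positive-definiteness is diagnosed, not enforced, so Heywood-type boundary
  solutions stay visible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "ConstraintFlags",
    "ModelSpec",
    "ParameterSet",
    "build_default_spec",
    "count_free_parameters",
    "degrees_of_freedom",
    "flatten_parameters",
    "unflatten_parameters",
    "template_parameters",
    "parameters_to_config",
    "parameters_from_config",
    "save_parameters",
    "load_parameters",
]


class DimensionalityError(ValueError):
    """Raised when a model spec violates the minimal dimensionality."""


@dataclass(frozen=True)
class ConstraintFlags:
    """Invariance / inclusion flags controlling the free-parameter layout.

    The ``equal_*`` flags impose measurement invariance over time (equal
    occasion-factor loadings, equal state-residual variances including the
    first occasion, equal autoregressive weights); the ``mr_*`` variants do
    the same for the rater-specific OPS process of the second rater.
    ``mr_tps_cross_trait_covariances`` is an inclusion flag: when on, the
    cross-indicator covariances Cov(TPS_i, T_j), i != j, are free (the
    same-indicator covariance is zero by the residual-factor definition and
    never free).
    """

    equal_O_loadings_over_time: bool = True
    equal_SR_variance_over_time: bool = True
    equal_beta_over_time: bool = True
    mr_equal_OPS_loadings_over_time: bool = True
    mr_equal_SRPS_variance_over_time: bool = True
    mr_equal_betaOPS_over_time: bool = True
    mr_tps_cross_trait_covariances: bool = True


def _default_labels(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{j + 1}" for j in range(n))


@dataclass(frozen=True)
class ModelSpec:
    """One LST-AR (n_raters=1) or MR-LST-AR (n_raters=2) model instance."""

    n_indicators: int = 3
    n_occasions: int = 4
    n_raters: int = 1
    reference_rater: int = 0
    constraints: ConstraintFlags = field(default_factory=ConstraintFlags)
    indicator_labels: tuple[str, ...] = ()
    occasion_labels: tuple[str, ...] = ()
    rater_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_indicators < 2 or self.n_occasions < 2:
            raise DimensionalityError(
                "need n_indicators >= 2 (indicator-specific traits plus a "
                "unidimensional state residual) and n_occasions >= 2 "
                f"(autoregression); got I={self.n_indicators}, "
                f"L={self.n_occasions}"
            )
        if self.n_raters not in (1, 2):
            raise DimensionalityError("n_raters must be 1 or 2")
        if self.n_raters == 1 and self.reference_rater != 0:
            raise ValueError("reference_rater is only meaningful for 2 raters")
        if not 0 <= self.reference_rater < self.n_raters:
            raise ValueError("reference_rater out of range")
        if not self.indicator_labels:
            object.__setattr__(
                self, "indicator_labels", _default_labels("indicator", self.n_indicators)
            )
        if not self.occasion_labels:
            object.__setattr__(
                self, "occasion_labels", _default_labels("t", self.n_occasions)
            )
        if not self.rater_labels:
            object.__setattr__(
                self, "rater_labels", _default_labels("rater", self.n_raters)
            )

    # ---- dimensions -------------------------------------------------
    @property
    def is_multi_rater(self) -> bool:
        return self.n_raters == 2

    @property
    def nonreference_rater(self) -> int:
        if not self.is_multi_rater:
            raise ValueError("single-rater spec has no non-reference rater")
        return 1 - self.reference_rater

    @property
    def n_observed(self) -> int:
        return self.n_indicators * self.n_raters * self.n_occasions

    @property
    def n_moments(self) -> int:
        """Observed means plus non-redundant (co)variances: p(p+3)/2."""
        p = self.n_observed
        return p * (p + 3) // 2

    @property
    def n_trait_factors(self) -> int:
        return self.n_indicators * (2 if self.is_multi_rater else 1)

    @property
    def n_latent(self) -> int:
        per_rater_occ = 2 if self.is_multi_rater else 1
        return self.n_trait_factors + per_rater_occ * self.n_occasions

    # ---- naming -----------------------------------------------------
    def observed_index(self, i: int, k: int, l: int) -> int:
        return (k * self.n_occasions + l) * self.n_indicators + i

    def column_names(self) -> list[str]:
        """Canonical wide-format column names: indicator<i>_rater<k>_t<l>."""
        names = [""] * self.n_observed
        for k in range(self.n_raters):
            for l in range(self.n_occasions):
                for i in range(self.n_indicators):
                    names[self.observed_index(i, k, l)] = (
                        f"indicator{i + 1}_rater{k + 1}_t{l + 1}"
                    )
        return names

    def latent_names(self) -> list[str]:
        names = [f"T{i + 1}" for i in range(self.n_indicators)]
        if self.is_multi_rater:
            names += [f"TPS{i + 1}" for i in range(self.n_indicators)]
        names += [f"O{l + 1}" for l in range(self.n_occasions)]
        if self.is_multi_rater:
            names += [f"OPS{l + 1}" for l in range(self.n_occasions)]
        return names


def build_default_spec(
    n_indicators: int = 3, n_occasions: int = 4, n_raters: int = 1
) -> ModelSpec:
    """Spec with all invariance constraints on and deterministic labels."""
    return ModelSpec(
        n_indicators=n_indicators, n_occasions=n_occasions, n_raters=n_raters
    )


# ----------------------------------------------------------------------
# Parameter container
# ----------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All structural parameters of one model instance.

    Arrays indexed ``[i, k, l]`` (indicator, rater, occasion); the trait
    covariance ``phi`` is over the stacked trait factors (T's, then TPS's for
    two raters).  Rater-specific entries (``lam_TPS``, ``lam_OPS``,
    ``beta_ps``, ``srps_var``) are ``None`` for single-rater models; the
    arrays indexed by rater simply carry the single rater at k=0 then.
    """

    intercepts: np.ndarray  # (I, K, L)
    lam_T: np.ndarray  # (I, K, L) loadings on the reference traits T_i
    lam_O: np.ndarray  # (I, K, L) loadings on occasion factors O_l
    phi: np.ndarray  # (nT, nT) trait covariance matrix
    beta: np.ndarray  # (L-1,) autoregressive weights of O
    sr_var: np.ndarray  # (L,) state residual variances
    err_var: np.ndarray  # (I, K, L) measurement error variances
    lam_TPS: np.ndarray | None = None  # (I, L) loadings on TPS_i (rater 2)
    lam_OPS: np.ndarray | None = None  # (I, L) loadings on OPS_l (rater 2)
    beta_ps: np.ndarray | None = None  # (L-1,)
    srps_var: np.ndarray | None = None  # (L,)

    def copy(self) -> "ParameterSet":
        def c(a):
            return None if a is None else np.array(a, dtype=float, copy=True)

        return ParameterSet(
            intercepts=c(self.intercepts),
            lam_T=c(self.lam_T),
            lam_O=c(self.lam_O),
            phi=c(self.phi),
            beta=c(self.beta),
            sr_var=c(self.sr_var),
            err_var=c(self.err_var),
            lam_TPS=c(self.lam_TPS),
            lam_OPS=c(self.lam_OPS),
            beta_ps=c(self.beta_ps),
            srps_var=c(self.srps_var),
        )

    def allclose(self, other: "ParameterSet", atol: float = 1e-10) -> bool:
        for name in (
            "intercepts", "lam_T", "lam_O", "phi", "beta", "sr_var",
            "err_var", "lam_TPS", "lam_OPS", "beta_ps", "srps_var",
        ):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.allclose(a, b, atol=atol):
                return False
        return True


def template_parameters(spec: ModelSpec) -> ParameterSet:
    """A conforming ParameterSet with all fixed entries at their fixed values.

    Free entries are filled with neutral defaults (loadings 1, variances 1,
    covariances 0, autoregressive weights 0, intercepts 0); ``unflatten``
    starts from this template so fixed entries can never drift.
    """
    return _template_cached(spec).copy()


@lru_cache(maxsize=128)
def _template_cached(spec: ModelSpec) -> ParameterSet:
    I, K, L = spec.n_indicators, spec.n_raters, spec.n_occasions
    nT = spec.n_trait_factors
    p = ParameterSet(
        intercepts=np.zeros((I, K, L)),
        lam_T=np.ones((I, K, L)),
        lam_O=np.ones((I, K, L)),
        phi=np.eye(nT),
        beta=np.zeros(L - 1),
        sr_var=np.ones(L),
        err_var=np.ones((I, K, L)),
    )
    if spec.is_multi_rater:
        p.lam_TPS = np.ones((I, L))
        p.lam_OPS = np.ones((I, L))
        p.beta_ps = np.zeros(L - 1)
        p.srps_var = np.ones(L)
        # residual trait factors are uncorrelated with same-indicator traits
        for i in range(I):
            p.phi[i, I + i] = p.phi[I + i, i] = 0.0
        if not spec.constraints.mr_tps_cross_trait_covariances:
            for i in range(I):
                for j in range(I):
                    p.phi[i, I + j] = p.phi[I + j, i] = 0.0
    return p


# ----------------------------------------------------------------------
# Free-parameter layout
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class _Slot:
    name: str
    transform: str  # "identity" | "log"
    targets: tuple[tuple[str, tuple[int, ...]], ...]


def _phi_name(spec: ModelSpec, r: int, c: int) -> str:
    names = [f"T{i + 1}" for i in range(spec.n_indicators)]
    if spec.is_multi_rater:
        names += [f"TPS{i + 1}" for i in range(spec.n_indicators)]
    return f"phi.{names[r]}.{names[c]}"


def parameter_layout(spec: ModelSpec) -> tuple[_Slot, ...]:
    """Ordered free-parameter slots; tied entries share one slot (cached)."""
    return _parameter_layout_cached(spec)


@lru_cache(maxsize=128)
def _parameter_layout_cached(spec: ModelSpec) -> tuple[_Slot, ...]:
    I, K, L = spec.n_indicators, spec.n_raters, spec.n_occasions
    ref = spec.reference_rater
    cf = spec.constraints
    slots: list[_Slot] = []

    def add(name, transform, targets):
        slots.append(_Slot(name, transform, tuple(targets)))

    # intercepts: all free
    for k in range(K):
        for l in range(L):
            for i in range(I):
                add(f"a.i{i+1}.k{k+1}.l{l+1}", "identity",
                    [("intercepts", (i, k, l))])

    # trait loadings: reference rater fixed to 1 at l=0, free afterwards;
    # non-reference rater free at every occasion (scale set by the reference)
    for k in range(K):
        for i in range(I):
            for l in range(L):
                if k == ref and l == 0:
                    continue
                add(f"lambda_T.i{i+1}.k{k+1}.l{l+1}", "identity",
                    [("lam_T", (i, k, l))])

    # TPS loadings (non-reference rater): fixed 1 at l=0
    if spec.is_multi_rater:
        nr = spec.nonreference_rater
        for i in range(I):
            for l in range(1, L):
                add(f"lambda_TPS.i{i+1}.k{nr+1}.l{l+1}", "identity",
                    [("lam_TPS", (i, l))])

    # occasion-factor loadings: first indicator of the reference rater fixed
    # to 1 at every occasion (sets the scale of O_l); everything else free,
    # tied over occasions under the invariance flag.  At l=0 the reference
    # rater's entries are the lambda_SR_i1 loadings (O_1 = SR_1).
    for k in range(K):
        for i in range(I):
            if k == ref and i == 0:
                continue
            if cf.equal_O_loadings_over_time:
                add(f"lambda_O.i{i+1}.k{k+1}", "identity",
                    [("lam_O", (i, k, l)) for l in range(L)])
            else:
                for l in range(L):
                    add(f"lambda_O.i{i+1}.k{k+1}.l{l+1}", "identity",
                        [("lam_O", (i, k, l))])

    # OPS loadings: first indicator fixed to 1 (scale of OPS_l)
    if spec.is_multi_rater:
        nr = spec.nonreference_rater
        for i in range(1, I):
            if cf.mr_equal_OPS_loadings_over_time:
                add(f"lambda_OPS.i{i+1}.k{nr+1}", "identity",
                    [("lam_OPS", (i, l)) for l in range(L)])
            else:
                for l in range(L):
                    add(f"lambda_OPS.i{i+1}.k{nr+1}.l{l+1}", "identity",
                        [("lam_OPS", (i, l))])

    # trait covariance block
    nT = spec.n_trait_factors
    for r in range(nT):
        add(_phi_name(spec, r, r), "log", [("phi", (r, r))])
    for r in range(nT):
        for c in range(r + 1, nT):
            if spec.is_multi_rater and r < I and c >= I:
                i, j = r, c - I  # Cov(T_i, TPS_j)
                if i == j:
                    continue  # fixed zero by the residual definition
                if not cf.mr_tps_cross_trait_covariances:
                    continue
            add(_phi_name(spec, r, c), "identity",
                [("phi", (r, c)), ("phi", (c, r))])

    # autoregressive weights and state-residual variances
    if cf.equal_beta_over_time:
        add("beta_O", "identity", [("beta", (l,)) for l in range(L - 1)])
    else:
        for l in range(L - 1):
            add(f"beta_O.l{l+2}", "identity", [("beta", (l,))])
    if cf.equal_SR_variance_over_time:
        add("var_SR", "log", [("sr_var", (l,)) for l in range(L)])
    else:
        for l in range(L):
            add(f"var_SR.l{l+1}", "log", [("sr_var", (l,))])

    if spec.is_multi_rater:
        if cf.mr_equal_betaOPS_over_time:
            add("beta_OPS", "identity", [("beta_ps", (l,)) for l in range(L - 1)])
        else:
            for l in range(L - 1):
                add(f"beta_OPS.l{l+2}", "identity", [("beta_ps", (l,))])
        if cf.mr_equal_SRPS_variance_over_time:
            add("var_SRPS", "log", [("srps_var", (l,)) for l in range(L)])
        else:
            for l in range(L):
                add(f"var_SRPS.l{l+1}", "log", [("srps_var", (l,))])

    # measurement error variances: all free
    for k in range(K):
        for l in range(L):
            for i in range(I):
                add(f"var_E.i{i+1}.k{k+1}.l{l+1}", "log",
                    [("err_var", (i, k, l))])

    return tuple(slots)


def count_free_parameters(spec: ModelSpec) -> int:
    return len(parameter_layout(spec))


def degrees_of_freedom(spec: ModelSpec) -> int:
    return spec.n_moments - count_free_parameters(spec)


# ----------------------------------------------------------------------
# Flatten / unflatten
# ----------------------------------------------------------------------


def _get(params: ParameterSet, target) -> float:
    fname, idx = target
    arr = getattr(params, fname)
    if arr is None:
        raise ValueError(f"parameter field {fname!r} missing from ParameterSet")
    return float(arr[idx])


def _fwd(value: float, transform: str) -> float:
    if transform == "log":
        if value <= 0:
            raise ValueError("variance parameters must be positive to flatten")
        return float(np.log(value))
    return value


def _inv(value: float, transform: str) -> float:
    return float(np.exp(value)) if transform == "log" else value


def _check_conformity(params: ParameterSet, spec: ModelSpec) -> None:
    I, K, L = spec.n_indicators, spec.n_raters, spec.n_occasions
    shapes = {
        "intercepts": (I, K, L), "lam_T": (I, K, L), "lam_O": (I, K, L),
        "phi": (spec.n_trait_factors, spec.n_trait_factors),
        "beta": (L - 1,), "sr_var": (L,), "err_var": (I, K, L),
    }
    if spec.is_multi_rater:
        shapes.update(
            lam_TPS=(I, L), lam_OPS=(I, L), beta_ps=(L - 1,), srps_var=(L,)
        )
    for name, shape in shapes.items():
        arr = getattr(params, name)
        if arr is None or np.asarray(arr).shape != shape:
            raise ValueError(
                f"parameter field {name!r} has shape "
                f"{None if arr is None else np.asarray(arr).shape}, "
                f"expected {shape}"
            )


def flatten_parameters(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Structured parameters -> flat unconstrained vector (free slots only)."""
    _check_conformity(params, spec)
    layout = parameter_layout(spec)
    vec = np.empty(len(layout))
    for j, slot in enumerate(layout):
        vec[j] = _fwd(_get(params, slot.targets[0]), slot.transform)
    return vec


def unflatten_parameters(vector: np.ndarray, spec: ModelSpec) -> ParameterSet:
    """Flat unconstrained vector -> structured parameters (fixed entries set)."""
    layout = parameter_layout(spec)
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(layout),):
        raise ValueError(
            f"vector length {vector.shape} does not match the "
            f"{len(layout)} free parameters of the spec"
        )
    params = template_parameters(spec)
    for value, slot in zip(vector, layout):
        nat = _inv(value, slot.transform)
        for fname, idx in slot.targets:
            getattr(params, fname)[idx] = nat
    return params


# ----------------------------------------------------------------------
# Flat-key config serialization
# ----------------------------------------------------------------------

_FIELD_KEY = {
    "intercepts": "a", "lam_T": "lambda_T", "lam_O": "lambda_O",
    "lam_TPS": "lambda_TPS", "lam_OPS": "lambda_OPS",
    "beta": "beta_O", "beta_ps": "beta_OPS",
    "sr_var": "var_SR", "srps_var": "var_SRPS", "err_var": "var_E",
}


def _entry_keys(spec: ModelSpec) -> list[tuple[str, str, tuple[int, ...]]]:
    """(flat key, field, index) for every structural entry of the model."""
    I, K, L = spec.n_indicators, spec.n_raters, spec.n_occasions
    nr = spec.nonreference_rater if spec.is_multi_rater else None
    out = []
    for fname in ("intercepts", "lam_T", "lam_O", "err_var"):
        key = _FIELD_KEY[fname]
        for i in range(I):
            for k in range(K):
                for l in range(L):
                    out.append((f"{key}.i{i+1}.k{k+1}.l{l+1}", fname, (i, k, l)))
    if spec.is_multi_rater:
        for fname in ("lam_TPS", "lam_OPS"):
            key = _FIELD_KEY[fname]
            for i in range(I):
                for l in range(L):
                    out.append((f"{key}.i{i+1}.k{nr+1}.l{l+1}", fname, (i, l)))
    nT = spec.n_trait_factors
    for r in range(nT):
        for c in range(r, nT):
            out.append((_phi_name(spec, r, c), "phi", (r, c)))
    for l in range(L - 1):
        out.append((f"beta_O.l{l+2}", "beta", (l,)))
    for l in range(L):
        out.append((f"var_SR.l{l+1}", "sr_var", (l,)))
    if spec.is_multi_rater:
        for l in range(L - 1):
            out.append((f"beta_OPS.l{l+2}", "beta_ps", (l,)))
        for l in range(L):
            out.append((f"var_SRPS.l{l+1}", "srps_var", (l,)))
    return out


def parameters_to_config(params: ParameterSet, spec: ModelSpec) -> dict:
    """Flat-key mapping of every entry; fixed entries carry ``fixed: true``."""
    _check_conformity(params, spec)
    free_targets = set()
    for slot in parameter_layout(spec):
        free_targets.update(slot.targets)
    cfg: dict[str, dict] = {}
    for key, fname, idx in _entry_keys(spec):
        value = float(getattr(params, fname)[idx])
        entry: dict = {"value": value}
        # phi entries are stored upper-triangular; either orientation free
        is_free = (fname, idx) in free_targets or (
            fname == "phi" and ("phi", (idx[1], idx[0])) in free_targets
        )
        if not is_free:
            entry["fixed"] = True
        cfg[key] = entry
    return cfg


def parameters_from_config(cfg: dict, spec: ModelSpec) -> ParameterSet:
    params = template_parameters(spec)
    known = {key: (fname, idx) for key, fname, idx in _entry_keys(spec)}
    for key, entry in cfg.items():
        if key not in known:
            raise KeyError(f"unknown parameter key {key!r} for this spec")
        fname, idx = known[key]
        value = float(entry["value"] if isinstance(entry, dict) else entry)
        arr = getattr(params, fname)
        arr[idx] = value
        if fname == "phi":
            arr[idx[1], idx[0]] = value
    return params


def save_parameters(path, params: ParameterSet, spec: ModelSpec) -> None:
    """Write the flat-key config as YAML (by extension) or JSON."""
    cfg = parameters_to_config(params, spec)
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    else:
        with open(path, "w") as fh:
            json.dump(cfg, fh, indent=1, sort_keys=True)


def load_parameters(path, spec: ModelSpec) -> ParameterSet:
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    return parameters_from_config(cfg, spec)
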