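"""Compiled FIML objective with analytic gradient.

The negative log-likelihood is

    f = 1/2 sum_g n_g [ p_g log 2pi + log|S_g| + tr(S_g^-1 C_g) + d_g' S_g^-1 d_g ]

over missingness patterns g (d_g = pattern mean minus model mean).  With
A = S_g^-1 the pattern contributes

    dF/dSigma_g = n_g/2 (A - A C_g A - A d_g d_g' A),   dF/dmu_g = -n_g A d_g,

scattered into full-size accumulators G and g_mu.  The chain rule through
the reduced form Sigma = Lambda Phi Lambda' + diag(theta) gives

    dF/dLambda = 2 G Lambda Phi,   dF/dPhi = Lambda' G Lambda,
    dF/dtheta_r = G_rr,            dF/da = g_mu,

and the AR occasion-chain blocks of Phi are differentiated through the
variance recursion.  Log-scale slots pick up the factor d exp(x)/dx = value.

The slot layout (tied parameters, fixed entries, transforms) is compiled
once into index arrays so an evaluation with gradient costs a small constant
multiple of one likelihood evaluation, independent of the number of free
parameters.
"""

from __future__ import annotations

import numpy as np

from .likelihood import PatternStats, _LOG2PI, _PENALTY
from .moments import ar_factor_covariance
from .spec import (ModelSpec, ParameterSet, parameter_layout,
                   template_parameters)

__all__ = ["FimlObjective", "ar_chain_gradients"]


def ar_chain_gradients(betas: np.ndarray, res_vars: np.ndarray):
    """Covariance of the AR occasion chain plus derivatives.

    Returns ``(cov, dcov_dbeta, dcov_dv)`` with shapes (L,L), (L-1,L,L),
    (L,L,L); forward-mode differentiation of the recursion.
    """
    betas = np.asarray(betas, float)
    rv = np.asarray(res_vars, float)
    L = rv.shape[0]
    cov = ar_factor_covariance(betas, rv)
    d_beta = np.zeros((L - 1, L, L))
    d_v = np.zeros((L, L, L))

    def run(is_beta: bool, j: int) -> np.ndarray:
        D = np.zeros((L, L))
        if not is_beta and j == 0:
            D[0, 0] = 1.0
        for l in range(1, L):
            b = betas[l - 1]
            D[l, l] = b * b * D[l - 1, l - 1]
            if is_beta and j == l - 1:
                D[l, l] += 2.0 * b * cov[l - 1, l - 1]
            if (not is_beta) and j == l:
                D[l, l] += 1.0
            for m in range(l):
                val = b * D[l - 1, m]
                if is_beta and j == l - 1:
                    val += cov[l - 1, m]
                D[l, m] = D[m, l] = val
        return D

    for j in range(L - 1):
        d_beta[j] = run(True, j)
    for j in range(L):
        d_v[j] = run(False, j)
    return cov, d_beta, d_v


# order in which per-entry value/gradient arrays are concatenated
def _field_order(spec: ModelSpec) -> list[str]:
    fields = ["intercepts", "lam_T", "lam_O", "err_var"]
    if spec.is_multi_rater:
        fields += ["lam_TPS", "lam_OPS"]
    fields += ["beta", "sr_var"]
    if spec.is_multi_rater:
        fields += ["beta_ps", "srps_var"]
    fields += ["phi"]
    return fields


class FimlObjective:
    """Negative FIML log-likelihood of one (spec, data) pair, with gradient."""

    def __init__(self, spec: ModelSpec, stats: PatternStats):
        self.spec = spec
        self.stats = stats
        self.layout = parameter_layout(spec)
        self.n_free = len(self.layout)
        I, K, L = spec.n_indicators, spec.n_raters, spec.n_occasions
        self.I, self.K, self.L = I, K, L
        self.nT = spec.n_trait_factors
        self.q = spec.n_latent
        self.p = spec.n_observed
        self.rows = np.empty((I, K, L), dtype=int)
        for i in range(I):
            for k in range(K):
                for l in range(L):
                    self.rows[i, k, l] = spec.observed_index(i, k, l)
        ii = np.arange(I)[:, None, None]
        ll = np.arange(L)[None, None, :]
        self.colsT = np.broadcast_to(ii, (I, K, L)).copy()
        self.colsO = np.broadcast_to(self.nT + ll, (I, K, L)).copy()
        if spec.is_multi_rater:
            self.nr = spec.nonreference_rater
            self.rows_nr = self.rows[:, self.nr, :]
            self.colsTPS = np.broadcast_to(I + np.arange(I)[:, None], (I, L)).copy()
            self.colsOPS = np.broadcast_to(
                self.nT + L + np.arange(L)[None, :], (I, L)).copy()
        self.diagnostics: dict = {}
        self._template = template_parameters(spec)
        self._params = template_parameters(spec)
        self._compile()

    # -- layout compilation -------------------------------------------
    def _compile(self) -> None:
        spec = self.spec
        self.fields = _field_order(spec)
        shapes = {f: np.asarray(getattr(self._template, f)).shape
                  for f in self.fields}
        sizes = {f: int(np.prod(shapes[f])) for f in self.fields}
        offsets = {}
        off = 0
        for f in self.fields:
            offsets[f] = off
            off += sizes[f]
        self.n_entries = off
        self.offsets, self.shapes = offsets, shapes

        def flatpos(fname, idx):
            return offsets[fname] + int(
                np.ravel_multi_index(idx, shapes[fname]))

        # gradient gather matrix: grad = gather @ entry_grad_vec
        gather = np.zeros((self.n_free, self.n_entries))
        # unflatten scatter: entry_value_vec positions per slot
        scatter_pos: list[int] = []
        scatter_slot: list[int] = []
        first_pos = np.empty(self.n_free, dtype=int)
        log_mask = np.zeros(self.n_free, dtype=bool)
        for j, slot in enumerate(self.layout):
            log_mask[j] = slot.transform == "log"
            first_pos[j] = flatpos(*slot.targets[0])
            seen_phi = set()
            for fname, idx in slot.targets:
                pos = flatpos(fname, idx)
                scatter_pos.append(pos)
                scatter_slot.append(j)
                if fname == "phi":
                    r, c = idx
                    key = (min(r, c), max(r, c))
                    if key in seen_phi:
                        continue
                    seen_phi.add(key)
                    gather[j, pos] += 1.0
                    if r != c:
                        gather[j, flatpos("phi", (c, r))] += 1.0
                else:
                    gather[j, pos] += 1.0
        self._gather = gather
        self._scatter_pos = np.asarray(scatter_pos)
        self._scatter_slot = np.asarray(scatter_slot)
        self._first_pos = first_pos
        self._log_mask = log_mask
        # fixed-entry baseline vector (template values everywhere)
        self._base_vec = self._pack_values(self._template)

    def _pack_values(self, params: ParameterSet) -> np.ndarray:
        return np.concatenate(
            [np.asarray(getattr(params, f), float).ravel() for f in self.fields])

    # -- parameters ----------------------------------------------------
    def natural_vector(self, x: np.ndarray) -> np.ndarray:
        """Entry-value vector with free slots filled from x.

        Log-scale arguments are clipped to +-60 so an aggressive line-search
        trial step yields a huge but finite value instead of overflow.
        """
        nat = np.where(self._log_mask, np.exp(np.clip(x, -60.0, 60.0)), x)
        vec = self._base_vec.copy()
        vec[self._scatter_pos] = nat[self._scatter_slot]
        return vec

    def params(self, x: np.ndarray) -> ParameterSet:
        vec = self.natural_vector(x)
        out = self._params
        for f in self.fields:
            arr = getattr(out, f)
            o = self.offsets[f]
            arr.ravel()[:] = vec[o:o + arr.size]
        return out

    # -- assembly ------------------------------------------------------
    def structure(self, x):
        params = self.params(x)
        spec = self.spec
        lam = np.zeros((self.p, self.q))
        lam[self.rows, self.colsT] = params.lam_T
        lam[self.rows, self.colsO] = params.lam_O
        if spec.is_multi_rater:
            lam[self.rows_nr, self.colsTPS] = params.lam_TPS
            lam[self.rows_nr, self.colsOPS] = params.lam_OPS
        lcov = np.zeros((self.q, self.q))
        lcov[:self.nT, :self.nT] = params.phi
        o0, L = self.nT, self.L
        lcov[o0:o0 + L, o0:o0 + L] = ar_factor_covariance(
            params.beta, params.sr_var)
        if spec.is_multi_rater:
            p0 = self.nT + L
            lcov[p0:p0 + L, p0:p0 + L] = ar_factor_covariance(
                params.beta_ps, params.srps_var)
        mu = np.zeros(self.p)
        mu[self.rows] = params.intercepts
        theta = np.zeros(self.p)
        theta[self.rows] = params.err_var
        sigma = lam @ lcov @ lam.T
        sigma[np.diag_indices_from(sigma)] += theta
        return params, mu, sigma, lam, lcov

    # -- value ---------------------------------------------------------
    def value(self, x) -> float:
        _, mu, sigma, _, _ = self.structure(x)
        total = 0.0
        for pat in self.stats.patterns:
            obs = pat.observed
            if obs.size == self.p:
                mu_s, sig_s = mu, sigma
            else:
                mu_s, sig_s = mu[obs], sigma[np.ix_(obs, obs)]
            total += self._pattern_ll(mu_s, sig_s, pat)
        return -total

    @staticmethod
    def _pattern_ll(mu_s, sig_s, pat):
        try:
            chol = np.linalg.cholesky(sig_s)
        except np.linalg.LinAlgError:
            shortfall = -min(float(np.linalg.eigvalsh(sig_s).min()), 0.0)
            return _PENALTY * (1.0 + shortfall)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        d = pat.mean - mu_s
        z = np.linalg.solve(chol, d.reshape(-1, 1)).ravel()
        w = np.linalg.solve(chol.T, np.linalg.solve(chol, pat.scatter))
        return -0.5 * pat.n * (
            mu_s.size * _LOG2PI + logdet + float(np.trace(w)) + float(z @ z))

    # -- value + gradient ---------------------------------------------
    def value_and_grad(self, x):
        params, mu, sigma, lam, lcov = self.structure(x)
        p = self.p
        G = np.zeros((p, p))
        gmu = np.zeros(p)
        total = 0.0
        for pat in self.stats.patterns:
            obs = pat.observed
            complete = obs.size == p
            sig_s = sigma if complete else sigma[np.ix_(obs, obs)]
            try:
                chol = np.linalg.cholesky(sig_s)
            except np.linalg.LinAlgError:
                self.diagnostics["nonpd_penalty"] = (
                    self.diagnostics.get("nonpd_penalty", 0) + 1)
                shortfall = -min(float(np.linalg.eigvalsh(sig_s).min()), 0.0)
                return -_PENALTY * (1.0 + shortfall), np.zeros(self.n_free)
            po = obs.size
            A = np.linalg.solve(chol.T, np.linalg.solve(chol, np.eye(po)))
            d = pat.mean - (mu if complete else mu[obs])
            Ad = A @ d
            AC = A @ pat.scatter
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
            total += -0.5 * pat.n * (
                po * _LOG2PI + logdet + float(np.trace(AC)) + float(d @ Ad))
            Gg = 0.5 * pat.n * (A - AC @ A - np.outer(Ad, Ad))
            if complete:
                G += Gg
                gmu += -pat.n * Ad
            else:
                G[np.ix_(obs, obs)] += Gg
                gmu[obs] += -pat.n * Ad
        G = (G + G.T) / 2.0

        GL = G @ lam  # (p, q)
        H = lam.T @ GL  # dF/dPhi_latent, entrywise
        GLP = 2.0 * GL @ lcov  # dF/dLambda

        nT, L = self.nT, self.L
        _, dbO, dvO = ar_chain_gradients(params.beta, params.sr_var)
        H_O = H[nT:nT + L, nT:nT + L]
        d_beta = np.tensordot(dbO, H_O, axes=([1, 2], [0, 1]))
        d_srv = np.tensordot(dvO, H_O, axes=([1, 2], [0, 1]))
        grads = {
            "intercepts": gmu[self.rows],
            "lam_T": GLP[self.rows, self.colsT],
            "lam_O": GLP[self.rows, self.colsO],
            "err_var": np.diag(G)[self.rows],
            "beta": d_beta,
            "sr_var": d_srv,
            "phi": H[:nT, :nT],
        }
        if self.spec.is_multi_rater:
            H_P = H[nT + L:, nT + L:]
            _, dbP, dvP = ar_chain_gradients(params.beta_ps, params.srps_var)
            grads["lam_TPS"] = GLP[self.rows_nr, self.colsTPS]
            grads["lam_OPS"] = GLP[self.rows_nr, self.colsOPS]
            grads["beta_ps"] = np.tensordot(dbP, H_P, axes=([1, 2], [0, 1]))
            grads["srps_var"] = np.tensordot(dvP, H_P, axes=([1, 2], [0, 1]))

        grad_vec = np.concatenate([np.asarray(grads[f], float).ravel()
                                   for f in self.fields])
        grad = self._gather @ grad_vec
        # chain through exp() for log-scale slots
        nat_first = self.natural_vector(x)[self._first_pos]
        grad = np.where(self._log_mask, grad * nat_first, grad)
        return -total, grad
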