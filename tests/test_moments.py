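"""Implied moment structure: AR chain covariance and reduced-form assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lstar import (ar_factor_covariance, build_default_spec, implied_moments,
                   simulate_dataset, template_parameters)

from conftest import random_params


class TestARChainCovariance:
    def test_no_carry_over_gives_diagonal(self):
        cov = ar_factor_covariance([0.0, 0.0, 0.0], [0.3, 0.3, 0.3, 0.3])
        assert np.allclose(cov, 0.3 * np.eye(4))

    def test_random_walk_closed_form(self):
        # unit-beta chain with unit residuals: Var(O_l) = l,
        # Cov(O_l, O_m) = min(l, m)
        cov = ar_factor_covariance([1.0, 1.0, 1.0], [1.0] * 4)
        lm = np.arange(1, 5)
        assert np.allclose(cov, np.minimum.outer(lm, lm))

    def test_hand_recursion_values(self):
        # beta = 0.5, unit residual variances:
        # Var(O_2) = 0.25 + 1 = 1.25; Var(O_3) = 0.25 * 1.25 + 1 = 1.3125;
        # Cov(O_1, O_3) = 0.5 * 0.5 * 1 = 0.25
        cov = ar_factor_covariance([0.5, 0.5, 0.5], [1.0] * 4)
        assert cov[1, 1] == pytest.approx(1.25)
        assert cov[2, 2] == pytest.approx(1.3125)
        assert cov[0, 2] == pytest.approx(0.25)

    def test_monte_carlo_oracle(self):
        # simulate the recursion directly and compare sample covariance
        betas, rv = np.array([0.6, 0.3]), np.array([0.5, 0.3, 0.4])
        rng = np.random.default_rng(1)
        n = 200_000
        sr = rng.standard_normal((n, 3)) * np.sqrt(rv)
        o = np.empty((n, 3))
        o[:, 0] = sr[:, 0]
        for l in (1, 2):
            o[:, l] = betas[l - 1] * o[:, l - 1] + sr[:, l]
        assert np.allclose(ar_factor_covariance(betas, rv),
                           np.cov(o.T, bias=True), atol=0.01)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-0.95, 0.95), min_size=1, max_size=4),
           st.data())
    def test_always_positive_semidefinite(self, betas, data):
        rv = data.draw(st.lists(st.floats(0.0, 2.0), min_size=len(betas) + 1,
                                max_size=len(betas) + 1))
        cov = ar_factor_covariance(betas, rv)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-10)

    def test_degenerate_zero_variances_allowed(self):
        cov = ar_factor_covariance([0.5], [0.0, 0.0])
        assert np.allclose(cov, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ar_factor_covariance([0.5, 0.5], [1.0, 1.0])


class TestImpliedMoments:
    def test_pure_error_structure(self, rng):
        spec = build_default_spec(3, 4, 1)
        p = template_parameters(spec)
        p.lam_T[:] = 0.0
        p.lam_O[:] = 0.0
        p.phi[:] = 0.0
        p.sr_var[:] = 0.0
        theta = rng.uniform(0.1, 0.5, size=(3, 1, 4))
        p.err_var[:] = theta
        p.intercepts[:] = 4.0
        mom = implied_moments(p, spec)
        flat = np.zeros(12)
        for i in range(3):
            for l in range(4):
                flat[spec.observed_index(i, 0, l)] = theta[i, 0, l]
        assert np.allclose(mom.sigma, np.diag(flat))
        assert np.allclose(mom.mu, 4.0)

    def test_hand_expansion_two_by_two(self):
        # K=1, L=2, I=2: Cov(Y_11, Y_12) expands symbolically to
        # lamT_12 * Var(T_1) + lamO_12 * beta * Var(SR_1)
        spec = build_default_spec(2, 2, 1)
        p = template_parameters(spec)
        p.phi[:] = [[0.3, 0.1], [0.1, 0.25]]
        p.lam_T[:, 0, 1] = [0.8, 0.9]
        p.lam_O[1, 0, :] = 0.7
        p.beta[:] = 0.4
        p.sr_var[:] = 0.2
        p.err_var[:] = 0.1
        mom = implied_moments(p, spec)
        r11 = spec.observed_index(0, 0, 0)
        r12 = spec.observed_index(0, 0, 1)
        assert mom.sigma[r11, r12] == pytest.approx(0.8 * 0.3 + 1.0 * 0.4 * 0.2)
        # second indicator pair picks up both loadings
        r21 = spec.observed_index(1, 0, 0)
        r22 = spec.observed_index(1, 0, 1)
        assert mom.sigma[r21, r22] == pytest.approx(
            0.9 * 0.25 + 0.7 * 0.7 * 0.4 * 0.2)

    def test_simulation_oracle_matches_sigma(self, spec2, paperlike):
        n = 200_000
        data = simulate_dataset(paperlike, spec2, n, seed=11)
        mom = implied_moments(paperlike, spec2)
        sample = np.cov(data.values.T, bias=True)
        scale = np.sqrt(np.outer(np.diag(mom.sigma), np.diag(mom.sigma)))
        # entrywise MC tolerance ~ 3 * sd(cov estimate) ~ 3 sqrt(2/n) scale
        assert np.all(np.abs(sample - mom.sigma) < 4 * np.sqrt(2.0 / n) * scale)
        assert np.allclose(data.values.mean(axis=0), mom.mu,
                           atol=4 * np.sqrt(np.diag(mom.sigma).max() / n) * 3)

    @pytest.mark.parametrize("dims", [(3, 4, 1), (3, 4, 2)])
    def test_variance_decomposition_identity(self, dims, rng):
        # diag(sigma) must equal the sum of trait, occasion and error pieces
        spec = build_default_spec(*dims)
        p = random_params(spec, rng)
        mom = implied_moments(p, spec)
        nT, L = spec.n_trait_factors, spec.n_occasions
        o_var = np.diag(mom.latent_cov)[nT:nT + L]
        I = spec.n_indicators
        for k in range(spec.n_raters):
            for l in range(L):
                for i in range(I):
                    row = spec.observed_index(i, k, l)
                    expected = (p.lam_T[i, k, l] ** 2 * p.phi[i, i]
                                + p.lam_O[i, k, l] ** 2 * o_var[l]
                                + p.err_var[i, k, l])
                    if spec.is_multi_rater and k == spec.nonreference_rater:
                        ops_var = np.diag(mom.latent_cov)[nT + L:]
                        expected += (p.lam_TPS[i, l] ** 2 * p.phi[I + i, I + i]
                                     + p.lam_OPS[i, l] ** 2 * ops_var[l])
                    assert mom.sigma[row, row] == pytest.approx(expected)

    def test_reference_block_equals_single_rater_structure(
            self, spec1, spec2, paperlike, target_params):
        mom2 = implied_moments(paperlike, spec2)
        mom1 = implied_moments(target_params, spec1)
        ref_rows = [spec2.observed_index(i, 0, l)
                    for l in range(4) for i in range(3)]
        order1 = [spec1.observed_index(i, 0, l)
                  for l in range(4) for i in range(3)]
        assert np.allclose(mom2.sigma[np.ix_(ref_rows, ref_rows)],
                           mom1.sigma[np.ix_(order1, order1)])

    def test_zero_beta_constant_loadings_give_compound_symmetry(self, spec1):
        # classical singletrait-multistate limit: per indicator, all
        # cross-occasion covariances equal
        p = template_parameters(spec1)
        p.phi[:] = [[0.3, 0.1, 0.1], [0.1, 0.3, 0.1], [0.1, 0.1, 0.3]]
        p.beta[:] = 0.0
        p.sr_var[:] = 0.2
        p.lam_O[1, 0, :] = 0.8
        p.lam_O[2, 0, :] = 0.6
        p.err_var[:] = 0.1
        mom = implied_moments(p, spec1)
        for i in range(3):
            rows = [spec1.observed_index(i, 0, l) for l in range(4)]
            off = mom.sigma[np.ix_(rows, rows)][~np.eye(4, dtype=bool)]
            assert np.allclose(off, off[0])
            assert np.allclose(np.diag(mom.sigma)[rows],
                               mom.sigma[rows[0], rows[0]])

    def test_moment_csv_export(self, tmp_path, spec1, target_params):
        mom = implied_moments(target_params, spec1)
        mom.write_csv(str(tmp_path / "mom"))
        import pandas as pd

        sigma = pd.read_csv(tmp_path / "mom_cov.csv", index_col=0)
        assert np.allclose(sigma.to_numpy(), mom.sigma)
        assert list(sigma.columns) == spec1.column_names()
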