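"""Variance-decomposition and rater-consistency coefficients.

Checks the closed-form ratios against their exact algebraic identities, a
Monte-Carlo oracle that regenerates the latent variables, and the printed-
table complement relations of the study design they mirror.
"""

import numpy as np
import pandas as pd
import pytest

from lstar import build_default_spec, coefficient_table, template_parameters
from lstar.coefficients import (occasion_specificity, predictability_trait1,
                                rater_consistency,
                                rater_consistent_occasion_specificity,
                                rater_consistent_pred_trait1,
                                rater_consistent_time_consistency,
                                rater_specificity, reliability,
                                state_retest_correlation,
                                state_retest_correlation_closed_form,
                                table_to_long, time_consistency,
                                unpredictability_trait1)
from lstar.simulate import simulate_latents
from lstar.moments import loading_matrix

from conftest import random_params


class TestReliability:
    def test_error_free_indicator(self, spec1, target_params):
        p = target_params.copy()
        p.err_var[:] = 0.0
        assert reliability(p, spec1, 0, 0, 0) == 1.0

    def test_pure_noise_indicator(self, spec1):
        p = template_parameters(spec1)
        p.phi[:] = 0.0
        p.sr_var[:] = 0.0
        p.err_var[:] = 0.3
        assert reliability(p, spec1, 0, 0, 0) == 0.0

    def test_matches_error_share(self, spec1, target_params):
        # tune the error variance to 28% of the total -> reliability 0.720,
        # the complement relation the printed tables rely on
        from lstar.moments import implied_moments

        p = target_params.copy()
        mom = implied_moments(p, spec1)
        row = spec1.observed_index(0, 0, 0)
        true_var = mom.sigma[row, row] - p.err_var[0, 0, 0]
        p.err_var[0, 0, 0] = true_var * 0.28 / 0.72
        assert reliability(p, spec1, 0, 0, 0) == pytest.approx(0.720)


class TestOccasionSpecificityAndConsistency:
    def test_all_true_variance_occasion_specific(self, spec1):
        p = template_parameters(spec1)
        p.phi[:] = 0.0
        p.beta[:] = 0.0
        p.sr_var[:] = 0.2
        p.err_var[:] = 0.1
        assert occasion_specificity(p, spec1, 0, 0, 2) == pytest.approx(1.0)

    def test_zero_state_residual_variance(self, spec1, target_params):
        p = target_params.copy()
        p.sr_var[:] = 0.0
        p.beta[:] = 0.0
        assert occasion_specificity(p, spec1, 1, 0, 1) == 0.0

    @pytest.mark.parametrize("dims", [(3, 4, 1), (3, 4, 2)])
    def test_exact_identities_on_random_parameters(self, dims, rng):
        spec = build_default_spec(*dims)
        for _ in range(20):
            p = random_params(spec, rng)
            for k in range(spec.n_raters):
                for i in range(spec.n_indicators):
                    for l in range(spec.n_occasions):
                        os_ = occasion_specificity(p, spec, i, k, l)
                        tc = time_consistency(p, spec, i, k, l)
                        pr = predictability_trait1(p, spec, i, k, l)
                        assert os_ + tc == pytest.approx(1.0, abs=1e-10)
                        if l == 0:
                            assert tc == pytest.approx(pr, abs=1e-12)
                        else:
                            up = unpredictability_trait1(p, spec, i, k, l)
                            assert pr + up == pytest.approx(tc, abs=1e-10)

    def test_zero_beta_kills_unpredictability(self, spec1, target_params):
        p = target_params.copy()
        p.beta[:] = 0.0
        for l in range(1, 4):
            assert unpredictability_trait1(p, spec1, 0, 0, l) == 0.0
            assert time_consistency(p, spec1, 0, 0, l) == pytest.approx(
                predictability_trait1(p, spec1, 0, 0, l))

    def test_occasion_one_unpredictability_is_undefined(self, spec1,
                                                        target_params):
        assert np.isnan(unpredictability_trait1(target_params, spec1, 0, 0, 0))

    def test_monte_carlo_r_squared_oracle(self, spec1, target_params):
        # TCon is the R^2 of regressing the true state at occasion l on the
        # trait and the previous occasion factor; regenerate the latents and
        # compute that R^2 directly
        rng = np.random.default_rng(12)
        spec, p = spec1, target_params
        n = 400_000
        lat = simulate_latents(p, spec, n, rng)
        nT = spec.n_trait_factors
        i, l = 1, 2
        state = (p.lam_T[i, 0, l] * lat[:, i]
                 + p.lam_O[i, 0, l] * lat[:, nT + l])
        X = np.column_stack([lat[:, i], lat[:, nT + l - 1]])
        Xc = X - X.mean(axis=0)
        sc = state - state.mean()
        coefs = np.linalg.lstsq(Xc, sc, rcond=None)[0]
        r2 = 1 - np.sum((sc - Xc @ coefs) ** 2) / np.sum(sc ** 2)
        assert time_consistency(p, spec, i, 0, l) == pytest.approx(r2,
                                                                   abs=0.01)


class TestRetestCorrelation:
    def test_closed_form_agrees_with_latent_covariance_route(self, rng):
        for dims in [(3, 4, 1), (3, 4, 2)]:
            spec = build_default_spec(*dims)
            for _ in range(25):
                p = random_params(spec, rng)
                for i in range(spec.n_indicators):
                    for l in range(1, spec.n_occasions):
                        a = state_retest_correlation(p, spec, i, 0, l)
                        b = state_retest_correlation_closed_form(
                            p, spec, i, 0, l)
                        assert a == pytest.approx(b, abs=1e-10)

    def test_random_walk_limit(self, spec1):
        # no trait variance, unit beta, equal residuals: r(S_1, S_l) = 1/sqrt(l)
        p = template_parameters(spec1)
        p.phi[:] = 0.0
        p.beta[:] = 1.0
        p.sr_var[:] = 0.3
        p.err_var[:] = 0.1
        for l in range(1, 4):
            assert state_retest_correlation(p, spec1, 0, 0, l) == pytest.approx(
                1 / np.sqrt(l + 1))

    def test_pure_trait_limit_constant_in_time(self, spec1, target_params):
        p = target_params.copy()
        p.beta[:] = 0.0
        p.lam_T[:, 0, :] = 1.0
        p.lam_O[:, 0, :] = p.lam_O[:, 0, :1]
        vals = [state_retest_correlation(p, spec1, 0, 0, l) for l in (1, 2, 3)]
        assert np.allclose(vals, vals[0])
        assert vals[0] == pytest.approx(
            predictability_trait1(p, spec1, 0, 0, 1), abs=1e-10)

    def test_monte_carlo_correlation_oracle(self, spec2, paperlike):
        rng = np.random.default_rng(21)
        spec, p = spec2, paperlike
        n = 400_000
        lat = simulate_latents(p, spec, n, rng)
        nT = spec.n_trait_factors
        L = spec.n_occasions
        i, k, l = 0, 1, 3  # non-reference rater, last occasion
        s1 = (p.lam_T[i, k, 0] * lat[:, i] + p.lam_TPS[i, 0] * lat[:, 3 + i]
              + p.lam_O[i, k, 0] * lat[:, nT] + p.lam_OPS[i, 0] * lat[:, nT + L])
        sl = (p.lam_T[i, k, l] * lat[:, i] + p.lam_TPS[i, l] * lat[:, 3 + i]
              + p.lam_O[i, k, l] * lat[:, nT + l]
              + p.lam_OPS[i, l] * lat[:, nT + L + l])
        mc = np.corrcoef(s1, sl)[0, 1]
        assert state_retest_correlation(p, spec, i, k, l) == pytest.approx(
            mc, abs=0.01)


class TestRaterCoefficients:
    def test_no_rater_specific_variance_means_full_consistency(self, spec2,
                                                               paperlike):
        p = paperlike.copy()
        p.phi[3:, 3:] = 0.0
        p.phi[:3, 3:] = 0.0
        p.phi[3:, :3] = 0.0
        p.srps_var[:] = 0.0
        assert rater_consistency(p, spec2, 0, 1) == pytest.approx(1.0)
        assert rater_specificity(p, spec2, 0, 1) == pytest.approx(0.0)

    def test_specificity_and_consistency_sum_to_one(self, spec2, rng):
        for _ in range(15):
            p = random_params(spec2, rng)
            for i in range(3):
                for l in range(4):
                    rs = rater_specificity(p, spec2, i, l)
                    rc = rater_consistency(p, spec2, i, l)
                    assert rs + rc == pytest.approx(1.0, abs=1e-10)

    def test_complement_pairs_mirror_printed_tables(self, spec2, paperlike):
        # scale the rater-specific variance so RS = 0.835 for one indicator;
        # the package must then report RCon = 0.165 and sqrt = 0.406, the
        # complement structure of the published coefficient tables
        p = paperlike.copy()
        i, l = 0, 0
        shared = (p.lam_T[i, 1, l] ** 2 * p.phi[i, i]
                  + p.lam_O[i, 1, l] ** 2 * p.sr_var[0])
        target_rs = 0.835
        want_specific = shared * target_rs / (1 - target_rs)
        have_specific = (p.lam_TPS[i, l] ** 2 * p.phi[3 + i, 3 + i]
                         + p.lam_OPS[i, l] ** 2 * p.srps_var[0])
        f = want_specific / have_specific
        p.phi[3 + i, 3 + i] *= f
        p.srps_var[:] *= f  # occasion 1: Var(OPS_1) = Var(SRPS_1)
        p.phi[3:, 3:] = np.diag(np.diag(p.phi[3:, 3:]))  # keep PSD simple
        assert rater_specificity(p, spec2, i, l) == pytest.approx(0.835,
                                                                  abs=1e-6)
        rcon = rater_consistency(p, spec2, i, l)
        assert rcon == pytest.approx(0.165, abs=1e-6)
        assert np.sqrt(rcon) == pytest.approx(0.406, abs=5e-4)

    def test_trait_level_complements(self, spec2, rng):
        for _ in range(10):
            p = random_params(spec2, rng)
            for i in range(3):
                for l in range(1, 4):
                    a = rater_consistent_pred_trait1(p, spec2, i, l)
                    assert 0.0 <= a <= 1.0

    def test_zero_tps_variance_gives_full_trait_consistency(self, spec2,
                                                            paperlike):
        p = paperlike.copy()
        p.phi[3:, 3:] = 1e-30 * np.eye(3)
        p.phi[:3, 3:] = 0.0
        p.phi[3:, :3] = 0.0
        assert rater_consistent_pred_trait1(p, spec2, 0, 1) == pytest.approx(1.0)

    def test_zero_shared_trait_loading(self, spec2, paperlike):
        p = paperlike.copy()
        p.lam_T[:, 1, :] = 0.0
        assert rater_consistent_pred_trait1(p, spec2, 0, 1) == 0.0

    def test_time_consistency_reduces_to_trait_version_without_carryover(
            self, spec2, rng):
        for _ in range(10):
            p = random_params(spec2, rng)
            p.beta[:] = 0.0
            p.beta_ps[:] = 0.0
            for i in range(3):
                assert rater_consistent_time_consistency(
                    p, spec2, i, 2) == pytest.approx(
                        rater_consistent_pred_trait1(p, spec2, i, 2), abs=1e-12)

    def test_time_consistent_share_never_exceeds_one(self, spec2, rng):
        for _ in range(20):
            p = random_params(spec2, rng)
            for i in range(3):
                for l in range(1, 4):
                    v = rater_consistent_time_consistency(p, spec2, i, l)
                    assert 0.0 <= v <= 1.0

    def test_occasion_specific_consistency_constant_under_invariance(
            self, spec2, paperlike):
        vals = [rater_consistent_occasion_specificity(paperlike, spec2, 1, l)
                for l in range(4)]
        assert np.allclose(vals, vals[0])

    def test_zero_srps_gives_full_occasion_consistency(self, spec2, paperlike):
        p = paperlike.copy()
        p.srps_var[:] = 0.0
        assert rater_consistent_occasion_specificity(
            p, spec2, 0, 1) == pytest.approx(1.0)

    def test_reference_rater_usage_rejected(self, spec2, paperlike):
        with pytest.raises(ValueError):
            rater_consistency(paperlike, spec2, 0, 1, k=0)

    def test_single_rater_model_has_no_rater_coefficients(self, spec1,
                                                          target_params):
        with pytest.raises(ValueError):
            rater_specificity(target_params, spec1, 0, 1, k=0)


class TestCoefficientTable:
    def test_identities_hold_rowwise(self, spec2, paperlike):
        t = coefficient_table(paperlike, spec2)
        assert np.allclose(t["OS"] + t["TCon"], 1.0)
        nonref = t.xs(2, level="rater")
        assert np.allclose(nonref["RS"] + nonref["RCon"], 1.0)
        assert np.allclose(nonref["rcon_corr"] ** 2, nonref["RCon"])
        later = nonref.query("occasion > 1")
        assert np.allclose(later["RConPred"] + later["RSPred"], 1.0)

    def test_undefined_cells_are_missing_not_zero(self, spec2, paperlike):
        t = coefficient_table(paperlike, spec2)
        first = t.xs(1, level="occasion")
        assert first["UPred_trait1"].isna().all()
        assert first["r_S1_Sl"].isna().all()
        ref = t.xs(1, level="rater")
        assert ref[["RS", "RCon", "RConOS"]].isna().all().all()

    def test_rescaling_all_observables_leaves_ratios_unchanged(self, spec2,
                                                               paperlike):
        c = 3.7
        p = paperlike.copy()
        p.intercepts *= c
        p.err_var *= c ** 2
        p.phi *= c ** 2
        p.sr_var *= c ** 2
        p.srps_var *= c ** 2
        a = coefficient_table(paperlike, spec2)
        b = coefficient_table(p, spec2)
        pd.testing.assert_frame_equal(a, b, atol=1e-10, rtol=0)

    def test_csv_round_trip(self, tmp_path, spec2, paperlike):
        t = coefficient_table(paperlike, spec2)
        path = tmp_path / "coef.csv"
        t.to_csv(path)
        back = pd.read_csv(path, index_col=[0, 1, 2])
        assert np.allclose(back.to_numpy(), t.to_numpy(), equal_nan=True)

    def test_long_format_drops_undefined_cells(self, spec2, paperlike):
        t = coefficient_table(paperlike, spec2)
        long = table_to_long(t)
        assert long["value"].notna().all()
        assert set(long.columns) == {"indicator", "rater", "occasion",
                                     "coefficient", "value"}

    def test_nonconverged_fit_refused(self, spec2, paperlike):
        class FakeFit:
            params = paperlike
            spec = spec2
            converged = False

        with pytest.raises(ValueError):
            coefficient_table(FakeFit())

    def test_paperlike_fixture_is_study_shaped(self, spec2, paperlike):
        t = coefficient_table(paperlike, spec2)
        ref = t.xs(1, level="rater").query("occasion > 1")
        nonref = t.xs(2, level="rater")
        assert (ref["UPred_trait1"] > 0).all()
        assert (nonref.query("occasion > 1")["UPred_trait1"] < 0.01).all()
        assert nonref["RS"].between(0.75, 0.95).all()
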