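import numpy as np
import pandas as pd
import pytest

from helpers import path_diagram_covariance_oracle, univariate_pairs
from twinstable import synthetic_data as sd
from twinstable import twin_sem


def _random_paths(rng, v=3):
    m = rng.normal(0, 0.5, (v, v))
    return np.tril(m)


class TestExpectedCovariance:
    def test_e_only_has_no_cross_twin_covariance(self):
        z = np.zeros((3, 3))
        for zyg in ("MZ", "DZ"):
            sigma = twin_sem.expected_covariance(z, z, np.eye(3), zyg)
            np.testing.assert_allclose(sigma[:3, 3:], 0.0)

    def test_mz_cross_block_is_a_when_c_zero(self):
        rng = np.random.default_rng(0)
        a = _random_paths(rng)
        sigma = twin_sem.expected_covariance(a, np.zeros((3, 3)), np.eye(3), "MZ")
        np.testing.assert_allclose(sigma[:3, 3:], a @ a.T, atol=1e-12)

    def test_matches_latent_simulation_oracle(self):
        rng = np.random.default_rng(1)
        a, c, e = (_random_paths(rng) for _ in range(3))
        for zyg in ("MZ", "DZ"):
            implied = twin_sem.expected_covariance(a, c, e, zyg)
            emp = path_diagram_covariance_oracle(a, c, e, zyg, n_draws=10**6, seed=2)
            np.testing.assert_allclose(emp, implied, atol=0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_psd_for_random_paths(self, seed):
        rng = np.random.default_rng(seed)
        a, c, e = (_random_paths(rng) for _ in range(3))
        for zyg in ("MZ", "DZ"):
            sigma = twin_sem.expected_covariance(a, c, e, zyg)
            np.testing.assert_allclose(sigma, sigma.T)
            assert np.all(np.linalg.eigvalsh(sigma) > -1e-10)

    def test_non_finite_rejected(self):
        bad = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            twin_sem.expected_covariance(bad, np.zeros((2, 2)), np.eye(2), "MZ")


class TestStandardizePaths:
    def _fit(self, a, c, e):
        return twin_sem.CholeskyACEFit(
            a_paths=np.asarray(a, float),
            c_paths=np.asarray(c, float),
            e_paths=np.asarray(e, float),
            mean_model=pd.Series(dtype=float),
            minus2LL=0.0,
            n_mz=1,
            n_dz=1,
        )

    def test_identity_a_only(self):
        fit = self._fit(np.eye(3), np.zeros((3, 3)), np.zeros((3, 3)))
        dec = twin_sem.standardize_paths(fit)
        assert dec.a2[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(dec.c2, 0.0)
        np.testing.assert_allclose(dec.e2, 0.0)

    def test_hand_worked_two_visit_example(self):
        fit = self._fit([[1, 0], [0.5, 1]], np.zeros((2, 2)), np.eye(2))
        dec = twin_sem.standardize_paths(fit)
        # visit 2 total variance = 0.25 + 1 + 1 = 2.25
        assert dec.a2[1, 0] == pytest.approx(0.25 / 2.25)
        assert dec.a2[1, 1] == pytest.approx(1.0 / 2.25)
        assert dec.e2[1, 1] == pytest.approx(1.0 / 2.25)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        fit = self._fit(*(_random_paths(rng) + 0.6 * np.eye(3) for _ in range(3)))
        dec = twin_sem.standardize_paths(fit)
        for v in (1, 2, 3):
            assert dec.visit_total(v) == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_rejected(self):
        fit = self._fit(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            twin_sem.standardize_paths(fit)


@pytest.fixture(scope="module")
def fitted_univariate():
    pairs = univariate_pairs(400, 400, a2=0.4, c2=0.3, seed=5)
    return pairs, twin_sem.fit_cholesky_ace(pairs, n_restarts=2, seed=0)


class TestFitCholeskyACE:
    def test_single_zygosity_rejected(self):
        pairs = univariate_pairs(50, 0, 0.4, 0.3, seed=6)
        with pytest.raises(ValueError):
            twin_sem.fit_cholesky_ace(pairs)

    def test_mle_beats_generating_parameters(self, fitted_univariate):
        pairs, fit = fitted_univariate
        model = twin_sem._ACEModel(pairs)
        mu = float(np.concatenate([pairs.mz, pairs.dz]).mean())
        truth = np.array([np.sqrt(0.4), np.sqrt(0.3), np.sqrt(0.3), mu])
        assert fit.minus2LL <= model.minus2ll(truth) + 1e-6

    def test_saturated_model_nests_cholesky(self, fitted_univariate):
        pairs, fit = fitted_univariate
        assert twin_sem.saturated_minus2ll(pairs) <= fit.minus2LL + 1e-6

    def test_label_swap_invariance(self, fitted_univariate):
        pairs, fit = fitted_univariate
        v = pairs.n_visits
        swapped = twin_sem.TwinPairData(
            mz=np.hstack([pairs.mz[:, v:], pairs.mz[:, :v]]),
            dz=np.hstack([pairs.dz[:, v:], pairs.dz[:, :v]]),
            mz_covariates=pairs.mz_covariates,
            dz_covariates=pairs.dz_covariates,
            covariate_names=pairs.covariate_names,
        )
        refit = twin_sem.fit_cholesky_ace(swapped, n_restarts=2, seed=0)
        assert refit.minus2LL == pytest.approx(fit.minus2LL, abs=1e-3)

    def test_univariate_proportion_recovery(self, fitted_univariate):
        _, fit = fitted_univariate
        dec = twin_sem.standardize_paths(fit)
        assert dec.a2[0, 0] == pytest.approx(0.4, abs=0.12)
        assert dec.c2[0, 0] == pytest.approx(0.3, abs=0.12)

    def test_trivariate_fit_from_cohort(self, small_cohort, cs_generator):
        table = sd.simulate_bin_values(small_cohort, cs_generator, seed=20)
        wide = table.pivot_table(
            index=["individual_id", "visit"], columns="bin", values="value"
        )
        pairs = twin_sem.build_pair_data(wide, small_cohort, "bin_000")
        assert pairs.n_mz == 16 and pairs.n_dz == 8
        fit = twin_sem.fit_cholesky_ace(pairs, n_restarts=2, seed=0)
        dec = twin_sem.standardize_paths(fit)
        for v in (1, 2, 3):
            assert dec.visit_total(v) == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diag(fit.a_paths) >= 0)


class TestConfidenceIntervals:
    def test_interval_brackets_estimate(self, fitted_univariate):
        _, fit = fitted_univariate
        dec = twin_sem.standardize_paths(fit)
        ci = twin_sem.confidence_intervals(fit, [("A", 1, 1)])
        lo, hi = ci[("A", 1, 1)]
        assert lo <= dec.a2[0, 0] <= hi
        assert 0.0 <= lo < hi <= 1.0

    def test_zero_estimate_gets_zero_lower_bound(self):
        pairs = univariate_pairs(300, 300, a2=0.0, c2=0.4, seed=7)
        fit = twin_sem.fit_cholesky_ace(pairs, n_restarts=2, seed=0)
        dec = twin_sem.standardize_paths(fit)
        if dec.a2[0, 0] < 1e-6:  # boundary estimate
            lo, _ = twin_sem.confidence_intervals(fit, [("A", 1, 1)])[("A", 1, 1)]
            assert lo == 0.0

    def test_interval_shrinks_with_sample_size(self):
        widths = []
        for n in (200, 2000):
            pairs = univariate_pairs(n, n, a2=0.4, c2=0.3, seed=8)
            fit = twin_sem.fit_cholesky_ace(pairs, n_restarts=1, seed=0)
            lo, hi = twin_sem.confidence_intervals(fit, [("A", 1, 1)])[("A", 1, 1)]
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestCheckAssumptions:
    def test_null_data_not_rejected_and_lrt_nonnegative(self, small_cohort, cs_generator):
        table = sd.simulate_bin_values(small_cohort, cs_generator, seed=21)
        wide = table.pivot_table(
            index=["individual_id", "visit"], columns="bin", values="value"
        )
        pairs = twin_sem.build_pair_data(wide, small_cohort, "bin_000")
        report = twin_sem.check_assumptions(pairs)
        assert (report["lrt"] >= 0).all()
        assert set(report["test"]) == {
            "means_equal_across_order",
            "means_equal_across_zygosity",
            "variances_equal",
        }

    def test_detects_twin_order_mean_shift(self, default_cohort, cs_generator):
        table = sd.simulate_bin_values(default_cohort, cs_generator, seed=22)
        wide = table.pivot_table(
            index=["individual_id", "visit"], columns="bin", values="value"
        )
        pairs = twin_sem.build_pair_data(wide, default_cohort, "bin_000")
        shifted = twin_sem.TwinPairData(
            mz=pairs.mz + np.r_[np.zeros(3), np.ones(3)],
            dz=pairs.dz + np.r_[np.zeros(3), np.ones(3)],
            mz_covariates=pairs.mz_covariates,
            dz_covariates=pairs.dz_covariates,
            covariate_names=pairs.covariate_names,
        )
        report = twin_sem.check_assumptions(shifted).set_index("test")
        assert report.loc["means_equal_across_order", "p_value"] < 0.001

    def test_single_zygosity_warns(self):
        pairs = univariate_pairs(30, 0, 0.4, 0.3, seed=9)
        with pytest.warns(UserWarning, match="zygosity"):
            twin_sem.check_assumptions(pairs)


class TestSimulatePower:
    def test_degenerate_proportions_rejected(self):
        with pytest.raises(ValueError):
            twin_sem.simulate_power(10, 10, (0.5, 0.4, 0.4), reps=100)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            twin_sem.simulate_power(10, 10, (0.5, 0.2, 0.3), reps=10)

    def test_size_under_null_near_alpha(self):
        size = twin_sem.simulate_power(500, 500, (0.0, 0.3, 0.7), reps=400, seed=3)
        # binomial 2 SE at 400 reps is about 0.022
        assert size == pytest.approx(0.05, abs=0.03)

    def test_high_heritability_large_sample_power(self):
        power = twin_sem.simulate_power(500, 500, (0.95, 0.0, 0.05), reps=150, seed=4)
        assert power > 0.99
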