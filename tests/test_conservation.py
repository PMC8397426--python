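import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinstable import conservation as cons


def _profiles(seed, n=6, bins=8):
    rng = np.random.default_rng(seed)
    idx = [f"ind{i}" for i in range(n)]
    cols = [f"b{j}" for j in range(bins)]
    base = pd.DataFrame(rng.normal(size=(n, bins)), index=idx, columns=cols)
    follow = 0.8 * base + 0.2 * pd.DataFrame(
        rng.normal(size=(n, bins)), index=idx, columns=cols
    )
    return base, follow


class TestProfileCorrelations:
    def test_identical_profiles_have_unit_diagonal(self):
        base, _ = _profiles(0)
        mat = cons.profile_correlations(base, base)
        np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-12)

    def test_uniform_weights_equal_unweighted(self):
        base, follow = _profiles(1)
        plain = cons.profile_correlations(base, follow)
        weighted = cons.profile_correlations(base, follow, weights=np.full(8, 0.125))
        np.testing.assert_allclose(plain.to_numpy(), weighted.to_numpy(), atol=1e-12)

    def test_matches_brute_force_pearson(self):
        base, follow = _profiles(2, n=3, bins=4)
        mat = cons.profile_correlations(base, follow)
        for i in range(3):
            for j in range(3):
                expected = np.corrcoef(base.iloc[i], follow.iloc[j])[0, 1]
                assert mat.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_profile_rejected(self):
        base, follow = _profiles(3)
        base.iloc[2] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            cons.profile_correlations(base, follow)

    def test_indicator_weights_equal_subset(self):
        base, follow = _profiles(4, bins=10)
        subset = ["b0", "b3", "b7", "b9"]
        w = pd.Series([1.0 if c in subset else 0.0 for c in base.columns], index=base.columns)
        by_weight = cons.profile_correlations(base, follow, weights=w)
        by_subset = cons.profile_correlations(base, follow, bins=subset)
        np.testing.assert_allclose(by_weight.to_numpy(), by_subset.to_numpy(), atol=1e-10)


class TestConservationIndex:
    def _matrix_with_rank(self, rank, n=128):
        """Row 0 has its diagonal at the requested descending rank."""
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.uniform(-0.2, 0.2, (n, n)),
            index=range(n),
            columns=range(n),
        )
        # place the diagonal value at the requested descending rank
        vals = np.sort(rng.uniform(-1, 1, n))[::-1]
        m.iloc[0] = np.concatenate([[vals[rank - 1]], np.delete(vals, rank - 1)])
        return m

    def test_top_rank_gives_unit_index(self):
        m = self._matrix_with_rank(1)
        res = cons.conservation_index(m, 0)
        assert res.rank == 1
        assert res.index == 1.0
        assert res.band == "1.00"

    def test_bottom_rank_gives_zero_index(self):
        m = self._matrix_with_rank(128)
        res = cons.conservation_index(m, 0)
        assert res.index == 0.0
        assert res.band == "<0.70"

    def test_rank_39_of_128(self):
        m = self._matrix_with_rank(39)
        res = cons.conservation_index(m, 0)
        assert res.index == pytest.approx(1 - 38 / 127)
        assert res.band == "0.70-0.89"

    def test_non_finite_rejected(self):
        m = self._matrix_with_rank(1)
        m.iloc[0, 5] = np.nan
        with pytest.raises(ValueError):
            cons.conservation_index(m, 0)

    def test_identity_followup_gives_all_unit_indices(self):
        base, _ = _profiles(5)
        mat = cons.profile_correlations(base, base)
        res = cons.conservation_indices(mat)
        assert (res["index"] == 1.0).all()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_invariant_to_monotone_row_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        m = pd.DataFrame(rng.normal(size=(n, n)))
        r1 = cons.conservation_index(m, 3)
        m2 = m.copy()
        m2.iloc[3] = np.tanh(2.0 * m2.iloc[3] + 0.5)  # strictly monotone
        r2 = cons.conservation_index(m2, 3)
        assert r1.index == r2.index


class TestLongitudinalBinWeights:
    def test_no_covariates_equals_plain_pearson(self):
        base, follow = _profiles(6, n=40)
        w = cons.longitudinal_bin_weights(base, follow)
        for c in base.columns:
            expected = max(0.0, np.corrcoef(base[c], follow[c])[0, 1])
            assert w[c] == pytest.approx(expected, abs=1e-10)

    def test_confounder_removal(self):
        rng = np.random.default_rng(7)
        n = 200
        age = rng.uniform(18, 65, n)
        idx = range(n)
        base = pd.DataFrame({"b0": 0.1 * age + rng.normal(0, 0.2, n)}, index=idx)
        follow = pd.DataFrame({"b0": 0.1 * age + rng.normal(0, 0.2, n)}, index=idx)
        for df in (base, follow):
            df["b1"] = rng.normal(size=n)
            df["b2"] = rng.normal(size=n)
        raw = cons.longitudinal_bin_weights(base, follow)
        adj = cons.longitudinal_bin_weights(
            base, follow, pd.DataFrame({"age": age}, index=idx)
        )
        assert raw["b0"] > 0.8
        assert adj["b0"] < 0.2

    def test_recovers_test_retest_correlation(self):
        rng = np.random.default_rng(8)
        n = 500
        latent = rng.normal(size=n)
        idx = range(n)
        base = pd.DataFrame({"b0": np.sqrt(0.6) * latent + np.sqrt(0.4) * rng.normal(size=n)},
                            index=idx)
        follow = pd.DataFrame({"b0": np.sqrt(0.6) * latent + np.sqrt(0.4) * rng.normal(size=n)},
                              index=idx)
        for df in (base, follow):
            df["b1"] = rng.normal(size=n)
            df["b2"] = rng.normal(size=n)
        w = cons.longitudinal_bin_weights(base, follow)
        assert w["b0"] == pytest.approx(0.6, abs=0.1)

    def test_matches_pingouin_partial_correlation(self):
        """Independent cross-check of the residualization against pingouin."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        n = 60
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "age": rng.normal(size=n),
                "sex": rng.integers(0, 2, n).astype(float),
            }
        )
        df["x"] += 0.5 * df["age"]
        df["y"] += 0.5 * df["age"] + 0.3 * df["x"]
        base = pd.DataFrame({"b0": df["x"], "b1": rng.normal(size=n), "b2": rng.normal(size=n)})
        follow = pd.DataFrame({"b0": df["y"], "b1": rng.normal(size=n), "b2": rng.normal(size=n)})
        w = cons.longitudinal_bin_weights(base, follow, df[["age", "sex"]])
        expected = pingouin.partial_corr(df, x="x", y="y", covar=["age", "sex"])["r"].iloc[0]
        assert w["b0"] == pytest.approx(max(0.0, expected), abs=1e-6)

    def test_singular_design_rejected(self):
        base, follow = _profiles(10, n=20)
        cov = pd.DataFrame({"a": np.ones(20), "b": np.ones(20)}, index=base.index)
        with pytest.raises(ValueError, match="singular"):
            cons.longitudinal_bin_weights(base, follow, cov)


class TestSummarizeConservation:
    def test_one_per_band(self):
        res = pd.DataFrame(
            {
                "index": [1.0, 0.95, 0.80, 0.60],
                "band": ["1.00", "0.90-0.99", "0.70-0.89", "<0.70"],
            }
        )
        out = cons.summarize_conservation(res)
        assert out["n"].tolist() == [1, 1, 1, 1]
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_all_unit_indices(self):
        res = pd.DataFrame({"index": [1.0] * 5, "band": ["1.00"] * 5})
        out = cons.summarize_conservation(res)
        assert out.set_index("band").loc["1.00", "percent"] == 100.0

    def test_band_mix_round_trip(self):
        rng = np.random.default_rng(11)
        target = {"1.00": 44, "0.90-0.99": 51, "0.70-0.89": 22, "<0.70": 11}
        samples = {"1.00": [1.0], "0.90-0.99": [0.91, 0.95], "0.70-0.89": [0.75], "<0.70": [0.2]}
        rows = []
        for band, count in target.items():
            for _ in range(count):
                rows.append({"index": rng.choice(samples[band]), "band": band})
        out = cons.summarize_conservation(pd.DataFrame(rows)).set_index("band")
        for band, count in target.items():
            assert out.loc[band, "n"] == count

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cons.summarize_conservation(pd.DataFrame(columns=["band"]))
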