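"""Feature ranking, retention arithmetic, fusion, and leakage guards."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from wheatlnc.selection import (UndefinedCorrelationError, fuse, pearson_r,
                                rank_features, rf_importance, select_deep,
                                select_by_correlation, select_top_fraction)


class TestPearson:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_antisymmetry_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_example_vs_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        xc, yc = x - x.mean(), y - y.mean()
        direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert pearson_r(x, y) == pytest.approx(direct, abs=1e-15)

    @given(st.integers(0, 500))
    def test_matches_scipy_to_1e12(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        assert pearson_r(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 observations"):
            pearson_r(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(0)
    n = 120
    y = rng.uniform(0, 1, n)
    X = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(9)})
    X["signal"] = y + rng.normal(0, 0.01, n)
    return X, y


class TestRfImportance:

    def test_signal_feature_ranks_first(self, signal_data):
        X, y = signal_data
        scores = rf_importance(X, y, n_trees=100, seed=1)
        assert rank_features(scores)[0] == "signal"
        assert scores["signal"] == pytest.approx(1.0)

    def test_pure_noise_importance_near_zero(self):
        rng = np.random.default_rng(3)
        n = 500
        y = rng.uniform(0, 1, n)
        X = pd.DataFrame({"signal": y + rng.normal(0, 0.05, n),
                          "noise": rng.normal(size=n),
                          "noise2": rng.normal(size=n)})
        scores = rf_importance(X, y, n_trees=100, seed=2)
        assert scores["noise"] < 0.1
        assert scores["noise2"] < 0.1

    def test_deterministic_under_seed(self, signal_data):
        X, y = signal_data
        a = rf_importance(X, y, n_trees=50, seed=9)
        b = rf_importance(X, y, n_trees=50, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_permutation_equivariant(self, signal_data):
        # bootstrap draws and OOB permutations are column-order independent;
        # the only residual order effect is split tie-breaking inside the
        # tree learner, which visits features in a seeded random order
        X, y = signal_data
        cols = list(X.columns)
        perm = cols[::-1]
        a = rf_importance(X, y, n_trees=30, seed=4).sort_index()
        b = rf_importance(X[perm], y, n_trees=30, seed=4).sort_index()
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-2)
        assert a.idxmax() == b.idxmax() == "signal"

    def test_scores_nonnegative_max_one(self, signal_data):
        X, y = signal_data
        scores = rf_importance(X, y, n_trees=50, seed=5)
        assert (scores >= 0).all()
        assert scores.max() == pytest.approx(1.0)

    def test_constant_target_rejected(self, signal_data):
        X, _ = signal_data
        with pytest.raises(ValueError, match="constant"):
            rf_importance(X, np.ones(len(X)), n_trees=10)

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0)})
        with pytest.raises(ValueError, match="10 samples"):
            rf_importance(X, np.arange(5.0))


class TestRetentionRules:
    @pytest.mark.parametrize("n,fraction,expected", [
        (26, 0.3, 8),   # round-half-down: 7.8 -> 8
        (25, 0.3, 7),   # 7.5 -> 7
        (10, 0.3, 3),   # exact product
        (3, 0.3, 1),    # floor at 1
    ])
    def test_top_fraction_counts(self, n, fraction, expected):
        ranked = [f"f{i}" for i in range(n)]
        assert len(select_top_fraction(ranked, fraction)) == expected

    def test_top_fraction_is_ranking_prefix(self):
        ranked = [f"f{i}" for i in range(26)]
        retained = select_top_fraction(ranked, 0.3)
        assert retained == ranked[:len(retained)]

    @given(st.integers(1, 60))
    def test_monotone_in_fraction(self, n):
        ranked = [f"f{i}" for i in range(n)]
        prev = set()
        for fraction in (0.1, 0.3, 0.5, 0.8, 1.0):
            cur = set(select_top_fraction(ranked, fraction))
            assert prev <= cur
            prev = cur

    def test_empty_ranking_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_top_fraction([], 0.3)

    def test_ties_broken_lexicographically(self):
        scores = pd.Series({"b": 0.5, "a": 0.5, "c": 0.9})
        assert rank_features(scores) == ["c", "a", "b"]


class TestSelectDeep:
    def test_cap_truncates_when_many_above_threshold(self):
        scores = pd.Series({f"DF_{i:03d}": 1.0 - i * 0.01 for i in range(30)})
        retained = select_deep(scores, threshold=0.45, cap=20)
        assert len(retained) == 20
        assert retained[0] == "DF_000"

    def test_all_below_threshold_without_fallback_warns_empty(self):
        scores = pd.Series({"DF_000": 1.0, "DF_001": 0.2, "DF_002": 0.1})
        # renormalised max is 1.0 > 0.45, so drop it below by construction
        scores = pd.Series({"DF_000": 0.0, "DF_001": 0.0, "DF_002": 0.0})
        with pytest.warns(UserWarning, match="zero features"):
            retained = select_deep(scores, fallback_top_k=False)
        assert retained == []

    def test_single_feature_above_threshold(self):
        scores = pd.Series({"DF_000": 1.0, "DF_001": 0.1, "DF_002": 0.2})
        retained = select_deep(scores, fallback_top_k=False)
        assert retained == ["DF_000"]

    def test_top_k_fallback_guarantees_cap(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.uniform(0, 0.3, 256),
                           index=[f"DF_{i:03d}" for i in range(256)])
        scores.iloc[0] = 1.0
        retained = select_deep(scores, threshold=0.45, cap=20,
                               fallback_top_k=True)
        assert len(retained) == 20


class TestFusion:
    def test_counts_add_up(self):
        fs = fuse([f"v{i}" for i in range(8)], [f"p{i}" for i in range(7)],
                  [f"d{i}" for i in range(20)])
        assert len(fs) == 35
        assert fs.features[:8] == [f"v{i}" for i in range(8)]
        assert fs.provenance["p0"] == "PF"

    def test_empty_family_allowed(self):
        fs = fuse([f"v{i}" for i in range(8)], [f"p{i}" for i in range(7)], [])
        assert len(fs) == 15

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fuse(["a", "b"], ["b"], ["c"])


class TestCorrelationSelection:
    def test_ranked_by_absolute_r(self):
        rng = np.random.default_rng(1)
        n = 60
        y = rng.uniform(0, 1, n)
        X = pd.DataFrame({
            "pos": y + rng.normal(0, 0.1, n),
            "neg": -y + rng.normal(0, 0.05, n),   # strongest, negative sign
            "weak": rng.normal(size=n),
        })
        sel = select_by_correlation(X, y, fraction=0.34)
        assert sel.ranked[0] == "neg"
        assert sel.retained == ["neg"]
        assert 0 <= sel.scores.min() and sel.scores.max() <= 1

    def test_zero_variance_feature_scores_zero(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 1, 30)
        X = pd.DataFrame({"flat": np.ones(30), "ok": y + rng.normal(0, .1, 30)})
        with pytest.warns(UserWarning, match="zero variance"):
            sel = select_by_correlation(X, y, fraction=0.5)
        assert sel.scores["flat"] == 0.0
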