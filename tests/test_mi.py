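import numpy as np
import pytest

from phosphonet.mi import (
    adaptive_partition_mi, dmi, hpmi, imi, null_mi_threshold, null_mi_values,
    rank_rows, spearman_complete,
)

from conftest import mnar_censor


def plugin_mi(table):
    """Independent oracle: plug-in discrete MI (nats) of a contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p = table / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return np.nansum(terms)


def grid_table(x, y, depth):
    """Contingency table of rank vectors on the forced 2^d x 2^d midpoint grid."""
    n = len(x)
    k = 2 ** depth
    edges = 1 + np.arange(k + 1) * (n // k)
    xr = rank_rows(np.asarray(x, float)[None, :])[0]
    yr = rank_rows(np.asarray(y, float)[None, :])[0]
    tab = np.zeros((k, k))
    for xi, yi in zip(xr, yr):
        tab[np.searchsorted(edges, xi, side="right") - 1,
            np.searchsorted(edges, yi, side="right") - 1] += 1
    return tab


class TestAdaptivePartition:
    def test_forced_partition_equals_plugin_contingency_mi(self):
        # 8-point toy set whose forced 2x2 partition is fully informative
        x = np.arange(1.0, 9.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        got = adaptive_partition_mi(x, y, max_depth=1)
        assert got == pytest.approx(plugin_mi(grid_table(x, y, 1)), abs=1e-12)

    @pytest.mark.parametrize("n,depth", [(16, 1), (32, 2), (64, 2), (64, 3)])
    def test_forced_partition_matches_oracle_on_random_points(self, n, depth):
        rng = np.random.default_rng(n + depth)
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        got = adaptive_partition_mi(x, y, max_depth=depth)
        assert got == pytest.approx(plugin_mi(grid_table(x, y, depth)), abs=1e-9)

    def test_perfect_dependence_beats_permutations(self):
        x = np.arange(1.0, 65.0)
        perfect = adaptive_partition_mi(x, x)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert perfect > adaptive_partition_mi(x, rng.permutation(x))

    def test_null_pair_calibrated_against_permutation_null(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        y = rng.permutation(x)
        null = np.array([
            adaptive_partition_mi(x, rng.permutation(x)) for _ in range(1000)
        ])
        assert adaptive_partition_mi(x, y) <= np.quantile(null, 0.95)

    def test_constant_vector_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert adaptive_partition_mi(np.ones(10), np.arange(10.0)) == 0.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="8"):
            adaptive_partition_mi(np.arange(5.0), np.arange(5.0))


class TestHpmi:
    def test_reduces_to_adaptive_mi_without_missingness(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        res = hpmi(x, y)
        assert res.mi == pytest.approx(adaptive_partition_mi(x, y), abs=1e-12)
        assert res.quadrant_counts == (100, 0, 0, 0)

    def test_quadrant_counts_sum_to_n(self):
        rng = np.random.default_rng(3)
        x = mnar_censor(rng.standard_normal(50), 0.3)
        y = mnar_censor(rng.standard_normal(50), 0.5)
        assert sum(hpmi(x, y).quadrant_counts) == 50

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = mnar_censor(rng.standard_normal(60), 0.4)
            y = mnar_censor(rng.standard_normal(60), 0.4)
            assert hpmi(x, y).mi == pytest.approx(hpmi(y, x).mi, abs=1e-12)

    def test_cocensoring_detected_vs_shuffled_missingness(self):
        # x missing exactly when y missing, observed parts independent:
        # co-censoring itself carries information
        rng = np.random.default_rng(5)
        co, ind = [], []
        for _ in range(500):
            x = rng.standard_normal(80)
            y = rng.standard_normal(80)
            miss = rng.random(80) < 0.5
            xc, yc = x.copy(), y.copy()
            xc[miss] = np.nan
            yc[miss] = np.nan
            co.append(hpmi(xc, yc).mi)
            xi, yi = x.copy(), y.copy()
            xi[miss] = np.nan
            yi[rng.permutation(miss)] = np.nan
            ind.append(hpmi(xi, yi).mi)
        assert np.mean(co) > np.mean(ind)

    def test_all_missing_vector_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            hpmi(np.full(10, np.nan), np.arange(10.0))

    def test_nonnegative_and_mostly_null_for_independent_pairs(self):
        rng = np.random.default_rng(6)
        x0 = mnar_censor(rng.standard_normal(100), 0.5)
        null = np.array([hpmi(rng.permutation(x0),
                              mnar_censor(rng.standard_normal(100), 0.5)).mi
                         for _ in range(400)])
        assert (null >= 0).all()
        q95 = np.quantile(null, 0.95)
        fresh = np.array([hpmi(mnar_censor(rng.standard_normal(100), 0.5),
                               mnar_censor(rng.standard_normal(100), 0.5)).mi
                          for _ in range(200)])
        assert np.mean(fresh < q95) >= 0.90


class TestSpearmanComplete:
    def test_identical_and_reversed(self):
        x = np.arange(10.0)
        assert spearman_complete(x, x) == pytest.approx(1.0)
        assert spearman_complete(x, x[::-1]) == pytest.approx(-1.0)

    def test_hand_computed_on_joint_points(self):
        # joint pairs (1,1),(2,3),(3,2): hand Spearman = 0.5
        x = np.array([1, 2, 3, np.nan, 5.0])
        y = np.array([1, 3, 2, 4, np.nan])
        assert spearman_complete(x, y) == pytest.approx(0.5)

    def test_too_few_joint_points_is_nan(self):
        x = np.array([1.0, 2.0, np.nan, np.nan])
        y = np.array([1.0, np.nan, 3.0, 4.0])
        assert np.isnan(spearman_complete(x, y))


@pytest.fixture(scope="module")
def null_matrix():
    rng = np.random.default_rng(7)
    return np.vstack([mnar_censor(rng.standard_normal(60), 0.4)
                      for _ in range(40)])


class TestNullThreshold:

    def test_fwer_one_gives_null_minimum(self, null_matrix):
        thr = null_mi_threshold(null_matrix, fwer=1.0, n_perm=2, seed=0)
        nulls = null_mi_values(null_matrix, n_perm=2, seed=0)
        assert thr == pytest.approx(nulls.min())

    def test_monotone_nonincreasing_in_fwer(self, null_matrix):
        thresholds = [null_mi_threshold(null_matrix, fwer=f, n_perm=3,
                                        n_candidates=20, seed=0)
                      for f in (0.5, 0.2, 0.05)]
        assert thresholds[0] <= thresholds[1] <= thresholds[2]

    def test_unresolvable_quantile_raises_with_minimum(self):
        rng = np.random.default_rng(8)
        tiny = np.vstack([rng.standard_normal(30) for _ in range(5)])
        with pytest.raises(ValueError, match="n_perm >="):
            null_mi_threshold(tiny, fwer=0.05, n_perm=2,
                              n_candidates=10**6, seed=0)


def test_imputation_based_mi_runs_and_is_nonnegative():
    rng = np.random.default_rng(9)
    x = mnar_censor(rng.standard_normal(100), 0.5)
    y = mnar_censor(rng.standard_normal(100), 0.5)
    assert imi(x, y, seed=1) >= 0
    assert dmi(x, y) >= 0
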