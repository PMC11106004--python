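"""Rank-statistic implementations against brute-force and library oracles."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from picoseason.stats import anosim, dunn_posthoc, hellinger, kruskal_wallis, spearman


def rank_then_pearson(x, y):
    """Independent Spearman oracle: midrank both vectors, then Pearson."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(10, 40)
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_large_n_p_matches_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        rho, p = spearman(x, y)
        t = rho * math.sqrt((25 - 2) / (1 - rho**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=23), rel=1e-12)

    def test_small_n_exact_permutation_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = spearman(x, y)
        # brute-force oracle: enumerate all 5! permutations of y
        obs = abs(rank_then_pearson(x, y))
        hits = sum(
            abs(rank_then_pearson(x, np.array(perm))) >= obs - 1e-12
            for perm in permutations(y)
        )
        assert p == pytest.approx(hits / math.factorial(5))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.lists(st.integers(-1000, 1000), min_size=12, max_size=20, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, xs):
        x = np.array(xs, dtype=float) / 7.0
        rng = np.random.default_rng(0)
        y = rng.permutation(x)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x / 150.0), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)


def kw_oracle(values, labels):
    """Direct textbook evaluation of the tie-corrected H statistic."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    n = len(values)
    ranks = sps.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        (labels == g).sum() * (ranks[labels == g].mean() - (n + 1) / 2) ** 2
        for g in np.unique(labels)
    )
    _, counts = np.unique(values, return_counts=True)
    corr = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / corr if corr > 0 else 0.0


class TestKruskalWallis:
    def test_identical_groups_have_zero_h(self):
        h, _ = kruskal_wallis([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_two_group_toy_matches_exhaustive_rank_statistic(self):
        # groups {1,2} and {3,4}: check H against direct evaluation and
        # against every one of the C(4,2) rank-to-group assignments
        values = np.array([1.0, 2.0, 3.0, 4.0])
        h, _ = kruskal_wallis(values, list("aabb"))
        assert h == pytest.approx(kw_oracle(values, np.array(list("aabb"))), abs=1e-12)
        dist = []
        for idx in combinations(range(4), 2):
            lab = np.array(["b"] * 4)
            lab[list(idx)] = "a"
            dist.append(kw_oracle(values, lab))
        assert max(dist) == pytest.approx(h)  # {1,2} vs {3,4} is the extreme split

    def test_all_values_equal_degenerate_convention(self):
        h, p = kruskal_wallis([5.0] * 6, list("aaabbb"))
        assert (h, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])

    def test_random_data_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            g1, g2, g3 = rng.normal(size=8), rng.normal(size=5), rng.normal(size=7)
            h, p = kruskal_wallis(
                np.concatenate([g1, g2, g3]),
                np.repeat(["a", "b", "c"], [8, 5, 7]),
            )
            ref = sps.kruskal(g1, g2, g3)
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


def dunn_oracle(values, labels, ga, gb):
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    n = len(values)
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    var = n * (n + 1) / 12.0 - tie
    na, nb = (labels == ga).sum(), (labels == gb).sum()
    z = (ranks[labels == ga].mean() - ranks[labels == gb].mean()) / math.sqrt(
        var * (1 / na + 1 / nb)
    )
    return z


class TestDunn:
    def test_equal_mean_ranks_give_zero_z(self):
        res = dunn_posthoc([1, 2, 3, 4], list("abba"))
        assert res[0]["z"] == pytest.approx(0.0, abs=1e-12)

    def test_three_group_toy_matches_formula_oracle(self):
        values = np.arange(1.0, 10.0)
        labels = np.repeat(["a", "b", "c"], 3)
        res = dunn_posthoc(values, labels, adjust="none")
        for r in res:
            z = dunn_oracle(values, labels, r["group_a"], r["group_b"])
            assert r["z"] == pytest.approx(z, abs=1e-12)
            assert r["p_raw"] == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-12)

    def test_no_adjustment_keeps_raw_p(self):
        res = dunn_posthoc(np.arange(12.0), np.repeat(list("abc"), 4), adjust="none")
        assert all(r["p_raw"] == r["p_adjusted"] for r in res)

    def test_holm_dominates_raw_and_bonferroni_dominates_holm(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=18) + np.repeat([0, 0.5, 2.0], 6)
        labels = np.repeat(list("abc"), 6)
        holm = dunn_posthoc(values, labels, adjust="holm")
        bonf = dunn_posthoc(values, labels, adjust="bonferroni")
        for rh, rb in zip(holm, bonf):
            assert rh["p_adjusted"] >= rh["p_raw"] - 1e-15
            assert rb["p_adjusted"] >= rh["p_adjusted"] - 1e-15


class TestHellinger:
    def test_basic_vectors(self):
        assert np.allclose(hellinger([1, 1]), [np.sqrt(0.5), np.sqrt(0.5)])
        assert np.allclose(hellinger([4, 0]), [1.0, 0.0])

    def test_euclidean_on_transformed_equals_hellinger_distance(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 50, size=(6, 10)).astype(float)
        x[:, 0] += 1  # positive row sums
        h = hellinger(x)
        for i in range(6):
            for j in range(6):
                pi = x[i] / x[i].sum()
                pj = x[j] / x[j].sum()
                direct = np.sqrt(np.sum((np.sqrt(pi) - np.sqrt(pj)) ** 2))
                assert np.linalg.norm(h[i] - h[j]) == pytest.approx(direct, abs=1e-12)

    def test_zero_row_sum_rejected(self):
        with pytest.raises(ValueError):
            hellinger([0, 0, 0])


def exact_anosim_p(d, labels):
    """Enumerate every distinct two-group labeling of equal size."""
    labels = np.asarray(labels)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranked = sps.rankdata(d[iu])
    m = len(ranked)

    def r_of(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranked[~within].mean() - ranked[within].mean()) / (m / 2)

    obs = r_of(labels)
    k = (labels == labels[0]).sum()
    hits = total = 0
    for idx in combinations(range(n), k):
        lab = np.zeros(n, dtype=int)
        lab[list(idx)] = 1
        total += 1
        if r_of(lab) >= obs - 1e-12:
            hits += 1
    return hits / total, obs


class TestAnosim:
    def test_equal_distances_give_zero_r(self):
        d = np.ones((6, 6)) - np.eye(6)
        r, _ = anosim(d, list("aaabbb"), n_perm=99, seed=0)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_r_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 4))
        x[:5] += 1.0
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        labels = np.repeat(["a", "b"], 5)
        r, _ = anosim(d, labels, n_perm=99, seed=0)
        ref = sk_anosim(DistanceMatrix(d), grouping=list(labels), permutations=0)
        assert r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_permutation_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 3))
        x[:3] += 1.2
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        labels = np.repeat(["a", "b"], 3)
        p_exact, _ = exact_anosim_p(d, labels)
        _, p_perm = anosim(d, labels, n_perm=4999, seed=9)
        se = math.sqrt(p_exact * (1 - p_exact) / 4999) + 1e-4
        assert abs(p_perm - p_exact) <= 4 * se + 2e-3

    def test_r_bounded_and_rank_invariant(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = rng.normal(size=(8, 3))
            d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
            labels = np.repeat(["a", "b"], 4)
            r, _ = anosim(d, labels, n_perm=9, seed=0)
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
            r2, _ = anosim(np.log1p(d), labels, n_perm=9, seed=0)
            assert r2 == pytest.approx(r, abs=1e-12)

    def test_singleton_group_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            anosim(d, ["a", "a", "b"], n_perm=9, seed=0)
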