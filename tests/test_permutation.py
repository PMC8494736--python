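"""Fixed-margin permutation test: counts, P-values, null P-value sets."""

import numpy as np
import pytest

from gimap.errors import ConfigError, DataError
from gimap.matrix import MutationMatrix
from gimap.permutation import (
    PermutationTest,
    build_null_ensemble,
    count_pair_stats,
    empirical_pvalues,
    null_pvalue_set,
    pair_count_matrix,
    sample_fixed_margin_matrix,
)
from _oracles import enumerate_fixed_margin, exact_pair_tail_probs


class TestPairStats:
    def test_direct_counting(self):
        # g1:{s1,s2}, g2:{s2,s3} -> 1 shared sample, 2 exclusive ones
        m = MutationMatrix(["g1", "g2"], ["s1", "s2", "s3"],
                           np.array([[1, 1, 0], [0, 1, 1]]), ["T"] * 3)
        (p,) = count_pair_stats(m)
        assert (p.co_obs, p.me_obs) == (1, 2)
        assert (p.margin_a, p.margin_b) == (2, 2)

    def test_identical_sets_have_no_exclusive_samples(self):
        m = MutationMatrix(["a", "b"], ["s1", "s2", "s3"],
                           np.array([[1, 1, 0], [1, 1, 0]]), ["T"] * 3)
        (p,) = count_pair_stats(m)
        assert (p.co_obs, p.me_obs) == (2, 0)

    def test_disjoint_sets_have_zero_cooccurrence(self):
        m = MutationMatrix(["a", "b"], ["s1", "s2"],
                           np.array([[1, 0], [0, 1]]), ["T"] * 2)
        (p,) = count_pair_stats(m)
        assert p.co_obs == 0
        assert p.me_obs == p.margin_a + p.margin_b

    def test_one_stat_per_unordered_pair(self, small_matrix):
        stats = count_pair_stats(small_matrix)
        assert len(stats) == 6
        pairs = {(s.gene_a, s.gene_b) for s in stats}
        assert all(a < b for a, b in pairs)

    def test_fewer_than_two_genes_gives_empty_list(self):
        m = MutationMatrix(["a"], ["s1", "s2"],
                           np.array([[1, 1]]), ["T"] * 2)
        assert count_pair_stats(m) == []


class TestEnsemble:
    def test_histogram_mass_sums_to_n(self, small_matrix):
        null = build_null_ensemble(small_matrix, 200, seed=0)
        assert (null.hist.sum(axis=1) == 200).all()

    def test_n_below_one_is_fatal(self, small_matrix):
        with pytest.raises(ConfigError):
            build_null_ensemble(small_matrix, 0)

    def test_single_type_block_mode_equals_unblocked(self, small_matrix):
        a = build_null_ensemble(small_matrix, 300, True, seed=5)
        b = build_null_ensemble(small_matrix, 300, False, seed=5)
        assert np.array_equal(a.hist, b.hist)

    def test_single_permutation_preserves_margins(self, rng):
        X = rng.random((6, 30)) < 0.3
        m = MutationMatrix([f"g{i}" for i in range(6)],
                           [f"s{j}" for j in range(30)], X, ["T"] * 30)
        mp = sample_fixed_margin_matrix(m, rng)
        assert np.array_equal(mp.X.sum(1), X.sum(1))
        assert np.array_equal(mp.X.sum(0), X.sum(0))

    def test_blockwise_reservoir_preserves_per_block_margins(self, rng):
        X = rng.random((6, 30)) < 0.3
        types = ["A"] * 12 + ["B"] * 18
        m = MutationMatrix([f"g{i}" for i in range(6)],
                           [f"s{j}" for j in range(30)], X, types)
        null = build_null_ensemble(m, 50, block_by_cancer_type=True,
                                   seed=4, n_reservoir=10)
        for Xp in null.reservoir:
            for _, idx in m.blocks():
                assert np.array_equal(Xp[:, idx].sum(1), X[:, idx].sum(1))
            assert np.array_equal(Xp.sum(0), X.sum(0))


class TestEmpiricalPvalues:
    def test_two_gene_matrix_pvalues_are_exactly_one(self):
        # with 2 genes the co-count is fixed by the margins: every
        # permutation reproduces it, so both tails saturate
        X = np.array([[1, 1, 0, 1, 0], [0, 1, 1, 0, 1]], dtype=bool)
        m = MutationMatrix(["a", "b"], [f"s{i}" for i in range(5)],
                           X, ["T"] * 5)
        res = PermutationTest(m, n_permutations=500, n_pseudo=10).fit(seed=0)
        assert (res.outcomes["p"] == 1.0).all()

    def test_extreme_count_hits_the_plus_one_floor(self):
        n = 400
        rng = np.random.default_rng(0)
        X = rng.random((5, 30)) < 0.4
        X[0] = X[1]  # identical rows: co count maximal
        m = MutationMatrix([f"g{i}" for i in range(5)],
                           [f"s{j}" for j in range(30)], X, ["T"] * 30)
        null = build_null_ensemble(m, n, seed=1)
        stats = count_pair_stats(m)
        pair = next(s for s in stats if (s.gene_a, s.gene_b) == ("g0", "g1"))
        p_co, p_me = empirical_pvalues(pair, null)
        assert p_me == 1.0
        assert p_co >= 1 / (n + 1)

    @pytest.mark.parametrize("shape,density,seed", [
        ((4, 6), 0.4, 0), ((5, 7), 0.3, 1), ((3, 8), 0.5, 2),
    ])
    def test_monte_carlo_matches_enumeration_oracle(self, shape, density,
                                                    seed):
        rng = np.random.default_rng(seed)
        X = rng.random(shape) < density
        X = X[X.sum(1) > 0][:, X[X.sum(1) > 0].sum(0) > 0]
        if X.shape[0] < 2 or X.shape[1] < 1:
            pytest.skip("degenerate draw")
        m = MutationMatrix([f"g{i}" for i in range(X.shape[0])],
                           [f"s{j}" for j in range(X.shape[1])],
                           X, ["T"] * X.shape[1])
        space = enumerate_fixed_margin(X.sum(1), X.sum(0))
        n = 10_000
        null = build_null_ensemble(m, n, seed=seed)
        for k, pair in enumerate(count_pair_stats(m)):
            a = list(m.genes).index(pair.gene_a)
            b = list(m.genes).index(pair.gene_b)
            tail_ge, tail_le = exact_pair_tail_probs(space, a, b, pair.co_obs)
            p_co, p_me = empirical_pvalues(pair, null)
            for p_hat, exact in ((p_co, tail_ge), (p_me, tail_le)):
                se = np.sqrt(exact * (1 - exact) / n)
                # 3 MC standard errors plus the +1/+1 estimator's bias
                assert abs(p_hat - exact) <= 3 * se + 2 / n, (
                    shape, k, p_hat, exact)


class TestNullPvalueSet:
    def test_values_bounded_and_deterministic(self, small_matrix):
        n = 300
        a = build_null_ensemble(small_matrix, n, seed=7, n_reservoir=20)
        nco, nme = null_pvalue_set(a)
        assert len(nco) == 20 * len(count_pair_stats(small_matrix))
        assert np.all((nco >= 1 / (n + 1)) & (nco <= 1.0))
        assert np.all((nme >= 1 / (n + 1)) & (nme <= 1.0))
        b = build_null_ensemble(small_matrix, n, seed=7, n_reservoir=20)
        nco2, _ = null_pvalue_set(b)
        assert np.array_equal(nco, nco2)

    def test_reservoirless_ensemble_refuses(self, small_matrix):
        null = build_null_ensemble(small_matrix, 50, seed=0)
        with pytest.raises(DataError):
            null_pvalue_set(null)


class TestModel:
    def test_pvalue_bounds_and_complementarity(self, small_matrix):
        n = 500
        res = PermutationTest(small_matrix, n_permutations=n,
                              n_pseudo=20).fit(seed=1)
        df = res.outcomes.pivot_table(
            index=["gene_a", "gene_b"], columns="direction", values="p"
        )
        assert (df >= 1 / (n + 1)).all().all()
        # p_co + p_me = (2 + N + ties) / (1 + N) > 1 always
        assert (df["co"] + df["me"] > 1).all()

    def test_observed_pvalues_stochastically_conservative_under_null(self):
        rng = np.random.default_rng(8)
        X = rng.random((40, 60)) < 0.15
        keep = X.sum(1) >= 2
        m = MutationMatrix(
            [f"g{i}" for i in range(40)],
            [f"s{j}" for j in range(60)], X, ["T"] * 60,
        ).subset_genes(np.flatnonzero(keep))
        res = PermutationTest(m, n_permutations=1500, n_pseudo=20).fit(seed=2)
        p = res.outcomes.loc[res.outcomes.direction == "co", "p"].to_numpy()
        grid = np.linspace(0.05, 0.95, 10)
        ecdf = (p[:, None] <= grid).mean(axis=0)
        assert np.all(ecdf <= grid + 0.05)

    def test_same_seed_reproduces_identical_outcomes(self, small_matrix):
        r1 = PermutationTest(small_matrix, 200, n_pseudo=10).fit(seed=9)
        r2 = PermutationTest(small_matrix, 200, n_pseudo=10).fit(seed=9)
        assert r1.outcomes.equals(r2.outcomes)

    def test_summary_mentions_test_and_counts(self, small_matrix):
        res = PermutationTest(small_matrix, 100, n_pseudo=5).fit(seed=0)
        text = res.summary()
        assert "permutation" in text
        assert "gene pairs tested" in text


def test_pair_count_matrix_equals_boolean_intersection(rng):
    X = rng.random((10, 25)) < 0.3
    co = pair_count_matrix(X)
    for a in range(10):
        for b in range(10):
            assert co[a, b] == int((X[a] & X[b]).sum())
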