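"""Weighted-sampling test: weights, bins, adaptive ladder, pan pooling."""

import numpy as np
import pandas as pd
import pytest

from gimap.errors import ConfigError, DataError
from gimap.matrix import MutationMatrix
from gimap.permutation import PairStats
from gimap.wesme import (
    WesmeTest,
    assign_rate_bins,
    binned_null_pvalues,
    compute_sample_weights,
    pan_cancer_wesme,
    pool_matrices,
    run_replicates,
    sample_gene_null,
    wesme_pvalues,
)


class TestSampleWeights:
    def test_uniform_loads_give_uniform_weights(self):
        m = MutationMatrix(["a", "b"], ["s1", "s2", "s3"],
                           np.ones((2, 3)), ["T"] * 3)
        (w,) = compute_sample_weights(m).values()
        assert np.allclose(w, 1 / 3)

    def test_weights_proportional_to_load_and_sum_one_per_type(self):
        X = np.array([[1, 1, 1, 1],
                      [0, 1, 0, 1],
                      [0, 1, 0, 0]], dtype=bool)
        m = MutationMatrix(["a", "b", "c"], ["s1", "s2", "s3", "s4"],
                           X, ["T", "T", "U", "U"])
        w = compute_sample_weights(m)
        assert np.allclose(w["T"].sum(), 1) and np.allclose(w["U"].sum(), 1)
        # s2 has 3x the load of s1; doubling load doubles the raw weight
        assert w["T"]["s2"] == pytest.approx(3 * w["T"]["s1"])


class TestSampleGeneNull:
    def test_full_margin_returns_all_samples(self, rng):
        w = pd.Series([0.25] * 4, index=list("abcd"))
        assert set(sample_gene_null(4, w, rng)) == set("abcd")

    def test_zero_margin_returns_empty(self, rng):
        w = pd.Series([0.5, 0.5], index=["a", "b"])
        assert len(sample_gene_null(0, w, rng)) == 0

    def test_margin_beyond_positive_weights_is_fatal(self, rng):
        w = pd.Series([1.0, 0.0], index=["a", "b"])
        with pytest.raises(DataError):
            sample_gene_null(2, w, rng)


class TestRateBins:
    @pytest.mark.parametrize("margin,expected", [
        (3, "low"),     # 1% of 300
        (6, "high"),    # exactly 2%: boundary is inclusive-high
        (15, "high"),   # 5%
    ])
    def test_two_percent_threshold(self, margin, expected):
        X = np.zeros((2, 300), dtype=bool)
        X[0, :margin] = True
        X[1, :10] = True
        m = MutationMatrix(["g", "other"], [f"s{i}" for i in range(300)],
                           X, ["T"] * 300)
        assert assign_rate_bins(m)["g"] == expected


class TestAdaptiveLadder:
    def test_gene_in_all_samples_gives_pco_one(self, rng):
        w = pd.Series(np.full(10, 0.1), index=[f"s{i}" for i in range(10)])
        pair = PairStats("a", "b", co_obs=4, me_obs=6,
                         margin_a=10, margin_b=4)
        out = wesme_pvalues(pair, w, rng)
        assert out.p_co == 1.0  # null co always equals the partner margin

    def test_high_interim_p_stops_at_first_rung(self, rng):
        w = pd.Series(np.full(12, 1 / 12), index=[f"s{i}" for i in range(12)])
        pair = PairStats("a", "b", co_obs=1, me_obs=8,
                         margin_a=5, margin_b=5)  # utterly typical count
        out = wesme_pvalues(pair, w, rng, ladder=(100, 1000))
        assert out.resamples_used == 100

    def test_extreme_count_escalates_to_the_cap(self, rng):
        w = pd.Series(np.full(40, 1 / 40), index=[f"s{i}" for i in range(40)])
        pair = PairStats("a", "b", co_obs=12, me_obs=0,
                         margin_a=12, margin_b=12)  # perfectly nested
        out = wesme_pvalues(pair, w, rng)
        assert out.resamples_used == 10_000
        assert out.p_co <= 10 / 10_000
        assert out.p_co >= 1 / 10_001


class TestWesmeModel:
    def test_pvalues_within_plus_one_bounds(self, small_matrix):
        res = WesmeTest(small_matrix, ladder=(50,), n_null_perms=20).fit(0)
        p = res.outcomes["p"]
        assert ((p >= 1 / 51) & (p <= 1.0)).all()

    def test_same_seed_identical_outcomes(self, small_matrix):
        a = WesmeTest(small_matrix, ladder=(50,), n_null_perms=20).fit(3)
        b = WesmeTest(small_matrix, ladder=(50,), n_null_perms=20).fit(3)
        assert a.outcomes.equals(b.outcomes)

    def test_null_pvalues_partitioned_by_rate_bin(self, planted_cohort):
        sets = binned_null_pvalues(planted_cohort.matrix, n_null_perms=5,
                                   seed=0, ladder=(50,))
        assert set(k[0] for k in sets) == {"co", "me"}
        n_pairs = sum(len(v) for k, v in sets.items() if k[0] == "co") / 5
        m = planted_cohort.matrix
        assert n_pairs == m.n_genes * (m.n_genes - 1) / 2

    def test_single_bin_matrix_populates_only_one_key(self):
        X = np.zeros((3, 200), dtype=bool)
        X[0, :3] = True
        X[1, 2:5] = True
        X[2, [0, 5]] = True  # all margins < 2% of 200 -> all low
        m = MutationMatrix(["a", "b", "c"], [f"s{i}" for i in range(200)],
                           X, ["T"] * 200)
        sets = binned_null_pvalues(m, n_null_perms=10, seed=1, ladder=(50,))
        assert all(k[1] == "low-low" for k in sets)

    def test_invalid_ladder_rejected(self, small_matrix):
        with pytest.raises(ConfigError):
            WesmeTest(small_matrix, ladder=(100, 100))


class TestPanCancer:
    def _two_type_matrix(self, rng):
        X = rng.random((6, 40)) < 0.3
        return MutationMatrix(
            [f"g{i}" for i in range(6)], [f"s{j:02d}" for j in range(40)],
            X, ["A"] * 15 + ["B"] * 25,
        )

    def test_pretest_count_filters(self, rng):
        m = self._two_type_matrix(rng)
        res = WesmeTest(m, ladder=(50,), n_null_perms=10).fit(0)
        df = res.outcomes
        assert (df.loc[df.direction == "me", "me_obs"] >= 3).all()
        assert (df.loc[df.direction == "co", "co_obs"] >= 1).all()

    def test_single_type_reduces_to_per_type_test(self, small_matrix):
        pooled = pool_matrices({"T": small_matrix})
        assert pooled == small_matrix.canonicalize()
        a = pan_cancer_wesme({"T": small_matrix}, seed=5,
                             ladder=(50,), n_null_perms=10)
        b = WesmeTest(small_matrix.canonicalize(), pretest=True,
                      ladder=(50,), n_null_perms=10).fit(5)
        assert a.outcomes.equals(b.outcomes)

    def test_gene_absent_from_one_type_contributes_margin_zero(self):
        m1 = MutationMatrix(["a", "b"], ["s1", "s2"],
                            np.array([[1, 1], [1, 1]]), ["A", "A"])
        m2 = MutationMatrix(["a", "c"], ["t1", "t2"],
                            np.array([[1, 1], [1, 1]]), ["B", "B"])
        pooled = pool_matrices({"A": m1, "B": m2})
        assert pooled.n_genes == 3
        b = pooled.gene_index("b")
        assert pooled.X[b, pooled.cancer_types == "B"].sum() == 0

    def test_pooled_counts_sum_over_types(self, rng):
        m = self._two_type_matrix(rng)
        res = WesmeTest(m, ladder=(50,), n_null_perms=10).fit(0)
        df = res.outcomes
        co_direct = {}
        for _, r in df.iterrows():
            a = m.gene_index(r.gene_a)
            b = m.gene_index(r.gene_b)
            co_direct[(r.gene_a, r.gene_b)] = int((m.X[a] & m.X[b]).sum())
        assert all(int(r.co_obs) == co_direct[(r.gene_a, r.gene_b)]
                   for _, r in df.iterrows())


class TestReplicates:
    def test_duplicate_seeds_rejected(self, small_matrix):
        with pytest.raises(ConfigError):
            run_replicates(small_matrix, seeds=[1, 1],
                           test_kwargs=dict(ladder=(50,), n_null_perms=5))

    def test_support_counts_bounded_by_n_runs(self, small_matrix):
        reps = run_replicates(
            small_matrix, n_runs=3, seed=0,
            test_kwargs=dict(ladder=(50,), n_null_perms=10),
        )
        assert reps.n_runs == 3
        if len(reps.support):
            assert (reps.support["support"] <= 3).all()

    def test_same_seed_list_reproduces_runs(self, small_matrix):
        kw = dict(ladder=(50,), n_null_perms=10)
        a = run_replicates(small_matrix, seeds=[4, 5], test_kwargs=kw)
        b = run_replicates(small_matrix, seeds=[4, 5], test_kwargs=kw)
        for ra, rb in zip(a.runs, b.runs):
            assert ra.outcomes.equals(rb.outcomes)
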