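"""Synthetic cohort generator: determinism, planted effects, confounders."""

import numpy as np
import pytest

from gimap import io
from gimap.errors import ConfigError
from gimap.simulate import (
    CancerTypeSpec,
    CohortSpec,
    PlantedInteraction,
    SubtypeSpec,
    add_subtype_structure,
    generate_cohort,
    plant_co_pair,
    plant_me_pair,
)
from conftest import planted_cohort_spec, subtype_cohort_spec


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        spec = planted_cohort_spec()
        a = generate_cohort(spec, seed=7)
        b = generate_cohort(spec, seed=7)
        assert a.matrix == b.matrix
        assert a.variants.equals(b.variants)
        assert a.truth.planted.equals(b.truth.planted)

    def test_different_seeds_differ(self):
        spec = planted_cohort_spec()
        a = generate_cohort(spec, seed=7)
        b = generate_cohort(spec, seed=8)
        assert a.matrix != b.matrix


class TestPlantOps:
    def _base(self, rng, n=4000, pa=0.3, pb=0.3):
        X = np.zeros((2, n), dtype=bool)
        X[0] = rng.random(n) < pa
        X[1] = rng.random(n) < pb
        return X

    def test_exclusivity_one_clears_every_double(self, rng):
        X = self._base(rng)
        plant_me_pair(X, 0, 1, 1.0, rng)
        assert (X[0] & X[1]).sum() == 0

    def test_exclusivity_zero_is_identity(self, rng):
        X = self._base(rng)
        before = X.copy()
        plant_me_pair(X, 0, 1, 0.0, rng)
        assert np.array_equal(X, before)

    def test_partial_exclusivity_halves_cooccurrence(self, rng):
        pre, post = [], []
        for _ in range(10):
            X = self._base(rng)
            pre.append((X[0] & X[1]).sum())
            plant_me_pair(X, 0, 1, 0.5, rng)
            post.append((X[0] & X[1]).sum())
        ratio = np.sum(post) / np.sum(pre)
        assert 0.44 <= ratio <= 0.56

    def test_lift_one_preserves_independence(self, rng):
        n = 60_000
        X = np.zeros((2, n), dtype=bool)
        plant_co_pair(X, 0, 1, 1.0 + 1e-12, 0.2, 0.2, rng)
        co = (X[0] & X[1]).mean()
        assert co == pytest.approx(0.04, abs=3 * np.sqrt(0.04 * 0.96 / n))

    def test_lift_multiplies_cooccurrence_and_preserves_margins(self, rng):
        n = 60_000
        lift = 3.0
        X = np.zeros((2, n), dtype=bool)
        plant_co_pair(X, 0, 1, lift, 0.15, 0.2, rng)
        pa, pb = X[0].mean(), X[1].mean()
        assert pa == pytest.approx(0.15, abs=3 * np.sqrt(0.15 * 0.85 / n))
        assert pb == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / n))
        co = (X[0] & X[1]).mean()
        expected = lift * 0.15 * 0.2
        assert co == pytest.approx(expected,
                                   abs=3 * np.sqrt(expected / n) + 1e-4)

    def test_infeasible_lift_reports_maximum(self):
        X = np.zeros((2, 10), dtype=bool)
        with pytest.raises(ConfigError, match="maximal feasible lift"):
            plant_co_pair(X, 0, 1, 10.0, 0.5, 0.5,
                          np.random.default_rng(0))


class TestSubtypes:
    def test_multipliers_and_private_genes(self, rng):
        ct = CancerTypeSpec("T", 500, subtypes=(
            SubtypeSpec("hi", 0.5, load_multiplier=2.0, n_private_genes=2),
            SubtypeSpec("lo", 0.5, load_multiplier=0.5, n_private_genes=1),
        ))
        labels, mult, private = add_subtype_structure(ct, rng)
        assert set(labels) == {"hi", "lo"}
        assert np.all(mult[labels == "hi"] == 2.0)
        assert len(private["hi"]) == 2 and len(private["lo"]) == 1

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum"):
            CancerTypeSpec("T", 10, subtypes=(
                SubtypeSpec("a", 0.5), SubtypeSpec("b", 0.6)))

    def test_mean_load_differs_fourfold_between_subtypes(self):
        cohort = generate_cohort(subtype_cohort_spec(), seed=0)
        loads = cohort.truth.realized_loads
        sub = cohort.truth.subtype_of
        hi = loads[sub[loads.index] == "early"].mean()
        lo = loads[sub[loads.index] == "late"].mean()
        assert 2.5 <= hi / lo <= 6.0

    def test_private_genes_of_different_subtypes_never_cooccur(self):
        cohort = generate_cohort(subtype_cohort_spec(), seed=1)
        m = cohort.matrix
        genes = set(m.genes)
        for a in cohort.truth.private_genes["CT1/early"]:
            for b in cohort.truth.private_genes["CT1/late"]:
                if a in genes and b in genes:
                    co = m.X[m.gene_index(a)] & m.X[m.gene_index(b)]
                    assert co.sum() == 0

    def test_no_subtypes_reduces_to_base_generator(self, rng):
        labels, mult, private = add_subtype_structure(
            CancerTypeSpec("T", 10), rng)
        assert set(labels) == {"none"}
        assert np.all(mult == 1.0) and private == {}


class TestGeneratedStatistics:
    def test_planted_margins_near_expectation(self):
        # exclusivity-1 planting clears one side of each double mutant, so
        # margins shrink from 0.3n by half the expected double count
        spec = planted_cohort_spec()
        margins = []
        for seed in range(8):
            t = generate_cohort(spec, seed=seed).truth
            row = t.planted[t.planted.kind == "mutual_exclusion"].iloc[0]
            margins += [row.realized_margin_a, row.realized_margin_b]
        n = 300
        expected = n * 0.3 - n * 0.09 / 2
        se = np.sqrt(n * 0.3 * 0.7)
        assert abs(np.mean(margins) - expected) < 3 * se / np.sqrt(len(margins))

    def test_planted_cooccurrence_matches_lift(self):
        spec = planted_cohort_spec()
        cos = []
        for seed in range(8):
            t = generate_cohort(spec, seed=seed).truth
            row = t.planted[t.planted.kind == "co_occurrence"].iloc[0]
            cos.append(row.realized_co)
        expected = 300 * 4.0 * 0.15 * 0.15
        assert abs(np.mean(cos) - expected) < 3 * np.sqrt(expected / len(cos))

    def test_hypermutators_exceed_threshold(self):
        spec = CohortSpec.single_type(400, 150, hypermutator_fraction=0.05)
        flagged = total = 0
        for seed in range(3):
            c = generate_cohort(spec, seed=seed)
            counts = c.variants.groupby("sample_id").size()
            for s in c.truth.hypermutators:
                total += 1
                if counts.get(s, 0) > io.hypermutator_threshold():
                    flagged += 1
        assert total > 0
        assert flagged / total >= 0.95

    def test_infeasible_planted_frequency_is_fatal(self):
        with pytest.raises(ConfigError):
            PlantedInteraction("a", "b", "co_occurrence", 4.0, freq_a=0.0)


class TestVariantFile:
    def test_pipeline_reproduces_matrix_from_variant_file(self, tmp_path):
        spec = CohortSpec.single_type(120, 60)
        cohort = generate_cohort(spec, seed=5)
        cohort.write(tmp_path)
        records, report = io.parse_variants(tmp_path / "variants.tsv",
                                            "SYNTHETIC")
        kept, report = io.filter_functional(records, report=report)
        matrix, _ = io.build_matrix(kept, report=report)
        assert matrix == cohort.matrix

    def test_variant_file_contains_silent_fraction(self):
        cohort = generate_cohort(CohortSpec.single_type(100, 50), seed=3)
        silent = (cohort.variants.consequence == "silent").mean()
        assert 0.3 < silent < 0.95  # silent excess dominates raw counts
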