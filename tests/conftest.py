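"""Shared fixtures.

The heavier objects (the planted-pair cohort and its replicate WeSME
runs, the null cohort) are session-scoped because several acceptance
checks interrogate the same fitted objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from gimap.matrix import MutationMatrix
from gimap.simulate import (
    CancerTypeSpec,
    CohortSpec,
    PlantedInteraction,
    SubtypeSpec,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 genes x 6 samples, one cancer type."""
    X = np.array([
        [1, 1, 0, 0, 1, 0],
        [0, 1, 1, 0, 0, 1],
        [1, 0, 0, 1, 0, 1],
        [0, 0, 1, 1, 1, 0],
    ], dtype=bool)
    return MutationMatrix(
        ["G1", "G2", "G3", "G4"],
        [f"s{i}" for i in range(6)],
        X, ["T"] * 6,
    )


def planted_cohort_spec() -> CohortSpec:
    """300 samples, 200 genes: one fully exclusive ME pair at 30%/30%
    margins and one lift-4 co-occurring pair."""
    return CohortSpec.single_type(
        n_samples=300, n_background_genes=196,
        planted=(
            PlantedInteraction("ME1_A", "ME1_B", "mutual_exclusion",
                               1.0, 0.3, 0.3),
            PlantedInteraction("CO1_A", "CO1_B", "co_occurrence",
                               4.0, 0.15, 0.15),
        ),
    )


def subtype_cohort_spec() -> CohortSpec:
    """Two subtypes with a 4x load difference and subtype-private genes:
    the confounder that produces load-driven exclusivity candidates."""
    return CohortSpec(
        cancer_types=(CancerTypeSpec("CT1", 200, subtypes=(
            SubtypeSpec("early", 0.5, load_multiplier=2.0,
                        n_private_genes=3, private_gene_freq=0.3),
            SubtypeSpec("late", 0.5, load_multiplier=0.5,
                        n_private_genes=3, private_gene_freq=0.3),
        )),),
        n_background_genes=80,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    return generate_cohort(planted_cohort_spec(), seed=1)


@pytest.fixture(scope="session")
def null_cohort():
    """Independent genes, no planted interactions."""
    return generate_cohort(CohortSpec.single_type(300, 200), seed=2)


@pytest.fixture(scope="session")
def planted_replicates(planted_cohort):
    from gimap.wesme import run_replicates

    return run_replicates(planted_cohort.matrix, n_runs=10, seed=42)


@pytest.fixture(scope="session")
def planted_permutation(planted_cohort):
    from gimap.permutation import PermutationTest

    return PermutationTest(
        planted_cohort.matrix, n_permutations=10_000
    ).fit(seed=3)
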