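"""Fixed-margin permutation test for co-occurrence and mutual exclusivity.

For every unordered gene pair the observed co-occurrence count (number of
samples carrying both mutations) is compared against its distribution over
matrices drawn uniformly from the set of binary matrices with the observed
row and column sums.  The empirical P-values use the +1/+1 estimator

    p_co = (1 + #{i: co_i >= co_obs}) / (1 + N)
    p_me = (1 + #{i: co_i <= co_obs}) / (1 + N)

so that no P-value is ever zero.  In pan-cancer mode the matrix is permuted
within each cancer type separately (block permutation) so the null respects
per-type mutation-frequency biases, while pair counts are pooled.

A reservoir of permuted matrices is retained and re-scored as
pseudo-observations against the same ensemble; the resulting null P-value
multisets feed the empirical FDR (:mod:`gimap.significance`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._sampling import CurveballChain
from .errors import ConfigError, DataError
from .matrix import MutationMatrix
from .results import InteractionResults
from .significance import empirical_fdr

__all__ = [
    "PairStats",
    "NullEnsemble",
    "count_pair_stats",
    "pair_count_matrix",
    "sample_fixed_margin_matrix",
    "build_null_ensemble",
    "empirical_pvalues",
    "null_pvalue_set",
    "PermutationTest",
]


@dataclass(frozen=True)
class PairStats:
    """Observed counts for one unordered gene pair."""

    gene_a: str
    gene_b: str
    co_obs: int
    me_obs: int
    margin_a: int
    margin_b: int


def pair_count_matrix(X: np.ndarray) -> np.ndarray:
    """Gene x gene co-occurrence count matrix via a single matmul."""
    Xf = np.ascontiguousarray(X, dtype=np.float32)
    return np.rint(Xf @ Xf.T).astype(np.int64)


def count_pair_stats(matrix: MutationMatrix) -> list[PairStats]:
    """One :class:`PairStats` per unordered gene pair (canonical order)."""
    if matrix.n_genes < 2:
        return []
    co = pair_count_matrix(matrix.X)
    k = matrix.margins()
    ia, ib = np.triu_indices(matrix.n_genes, k=1)
    return [
        PairStats(
            gene_a=str(matrix.genes[a]), gene_b=str(matrix.genes[b]),
            co_obs=int(co[a, b]),
            me_obs=int(k[a] + k[b] - 2 * co[a, b]),
            margin_a=int(k[a]), margin_b=int(k[b]),
        )
        for a, b in zip(ia, ib)
    ]


def sample_fixed_margin_matrix(matrix: MutationMatrix,
                               rng: np.random.Generator,
                               burn_in: int | None = None,
                               ) -> MutationMatrix:
    """One (approximately uniform) fixed-margin permutation of ``matrix``."""
    chain = CurveballChain(matrix.X, rng, burn_in=burn_in)
    Xp = chain.sample()
    return MutationMatrix(matrix.genes, matrix.samples, Xp,
                          matrix.cancer_types)


@dataclass
class NullEnsemble:
    """Per-pair null co-count histograms from N fixed-margin permutations.

    ``hist[p, c]`` counts permutations in which pair ``p`` (upper-triangle
    order) had co-count ``c``.  ``reservoir`` holds the dense permuted
    matrices retained for the pseudo-observed null P-value sets.
    """

    n_permutations: int
    genes: np.ndarray
    pair_index: tuple[np.ndarray, np.ndarray]
    hist: np.ndarray  # (n_pairs, max_co + 1) uint32
    block_by_cancer_type: bool
    seed: int | None
    reservoir: list[np.ndarray] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.hist.shape[0]

    def cumulative(self) -> np.ndarray:
        """``cum[p, c]`` = permutations with co-count <= c, leading 0 col."""
        cum = np.zeros(
            (self.hist.shape[0], self.hist.shape[1] + 1), dtype=np.int64
        )
        np.cumsum(self.hist, axis=1, out=cum[:, 1:])
        return cum


def build_null_ensemble(matrix: MutationMatrix, n_permutations: int,
                        block_by_cancer_type: bool = True,
                        seed: int | np.random.Generator | None = None,
                        n_reservoir: int = 0,
                        burn_in: int | None = None,
                        thin: int | None = None) -> NullEnsemble:
    """Accumulate per-pair null co-count histograms over N permutations."""
    if n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    if matrix.n_genes < 2:
        raise DataError("need at least 2 genes")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_genes = matrix.n_genes

    blocks = (list(matrix.blocks()) if block_by_cancer_type
              else [("ALL", np.arange(matrix.n_samples))])
    chains = [
        CurveballChain(matrix.X[:, idx], rng, burn_in=burn_in, thin=thin)
        for _, idx in blocks
    ]

    k = matrix.margins()
    ia, ib = np.triu_indices(n_genes, k=1)
    max_co = int(np.minimum(k[ia], k[ib]).max()) if ia.size else 0
    hist = np.zeros((ia.size, max_co + 2), dtype=np.uint32)
    pair_rows = np.arange(ia.size)

    for _ in range(n_permutations):
        co = np.zeros((n_genes, n_genes), dtype=np.int64)
        for (_, idx), chain in zip(blocks, chains):
            co += pair_count_matrix(chain.sample())
        hist[pair_rows, co[ia, ib]] += 1

    # pseudo-observed matrices are additional permutations from the same
    # chains: scoring an ensemble member against itself floors its p at
    # 2/(1+N) while the observed matrix can reach 1/(1+N), which at small
    # N deflates the null's extreme tail and inflates discoveries
    reservoir: list[np.ndarray] = []
    for _ in range(n_reservoir):
        Xp = np.zeros_like(matrix.X)
        for (_, idx), chain in zip(blocks, chains):
            Xp[:, idx] = chain.sample()
        reservoir.append(Xp)

    return NullEnsemble(
        n_permutations=n_permutations, genes=matrix.genes,
        pair_index=(ia, ib), hist=hist,
        block_by_cancer_type=block_by_cancer_type,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        reservoir=reservoir,
    )


def _pvalues_from_hist(cum: np.ndarray, n: int, co_obs: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized +1/+1 empirical P-values for per-pair observed counts."""
    rows = np.arange(cum.shape[0])
    co_obs = np.minimum(co_obs, cum.shape[1] - 2)
    le = cum[rows, co_obs + 1]
    ge = n - cum[rows, co_obs]
    p_co = (1.0 + ge) / (1.0 + n)
    p_me = (1.0 + le) / (1.0 + n)
    return p_co, p_me


def empirical_pvalues(pair: PairStats, null: NullEnsemble
                      ) -> tuple[float, float]:
    """(p_co, p_me) for one pair against the ensemble (+1/+1 estimator)."""
    ia, ib = null.pair_index
    genes = list(null.genes)
    a, b = genes.index(pair.gene_a), genes.index(pair.gene_b)
    if a > b:
        a, b = b, a
    row = np.flatnonzero((ia == a) & (ib == b))
    if row.size == 0:
        raise KeyError(f"pair {pair.gene_a}-{pair.gene_b} not in ensemble")
    cum = null.cumulative()[row]
    p_co, p_me = _pvalues_from_hist(
        cum, null.n_permutations, np.array([pair.co_obs])
    )
    return float(p_co[0]), float(p_me[0])


def null_pvalue_set(null: NullEnsemble
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Null P-value multisets (S_null) per direction.

    Each reservoir matrix is treated as pseudo-observed and scored against
    the full N-permutation ensemble, exactly as the observed matrix is.
    Returns (all p_co values, all p_me values).
    """
    if not null.reservoir:
        raise DataError(
            "ensemble has no reservoir; rebuild with n_reservoir > 0"
        )
    ia, ib = null.pair_index
    cum = null.cumulative()
    out_co, out_me = [], []
    for Xp in null.reservoir:
        co = pair_count_matrix(Xp)[ia, ib]
        p_co, p_me = _pvalues_from_hist(cum, null.n_permutations, co)
        out_co.append(p_co)
        out_me.append(p_me)
    return np.concatenate(out_co), np.concatenate(out_me)


class PermutationTest:
    """Fixed-margin permutation test over all gene pairs of a matrix.

    Statsmodels-style model object: construct from a
    :class:`~gimap.matrix.MutationMatrix`, call :meth:`fit`, inspect the
    returned :class:`~gimap.results.InteractionResults`.

    Parameters
    ----------
    matrix : MutationMatrix
    n_permutations : int
        Size N of the null ensemble (1e6 at production scale; the much
        smaller desk-scale default keeps interactive use snappy).
    block_by_cancer_type : bool
        Permute within each cancer type separately (pan-cancer mode); with
        a single cancer type this is equivalent to unblocked permutation.
    n_pseudo : int
        Number of permuted matrices re-scored as pseudo-observations for
        the null P-value set (default 100).
    """

    test_name = "permutation"

    def __init__(self, matrix: MutationMatrix, n_permutations: int = 10_000,
                 block_by_cancer_type: bool = True, n_pseudo: int = 100,
                 burn_in: int | None = None, thin: int | None = None) -> None:
        if matrix.n_genes < 2:
            raise DataError("need at least 2 genes to test pairs")
        if n_pseudo > n_permutations:
            raise ConfigError("n_pseudo cannot exceed n_permutations")
        self.matrix = matrix
        self.n_permutations = int(n_permutations)
        self.block_by_cancer_type = block_by_cancer_type
        self.n_pseudo = int(n_pseudo)
        self.burn_in = burn_in
        self.thin = thin

    def fit(self, seed: int | None = None) -> InteractionResults:
        rng = np.random.default_rng(seed)
        m = self.matrix
        null = build_null_ensemble(
            m, self.n_permutations,
            block_by_cancer_type=self.block_by_cancer_type,
            seed=rng, n_reservoir=self.n_pseudo,
            burn_in=self.burn_in, thin=self.thin,
        )
        ia, ib = null.pair_index
        k = m.margins()
        co_obs = pair_count_matrix(m.X)[ia, ib]
        cum = null.cumulative()
        p_co, p_me = _pvalues_from_hist(cum, null.n_permutations, co_obs)
        null_co, null_me = null_pvalue_set(null)

        fdr_co, q_co = empirical_fdr(p_co, null_co)
        fdr_me, q_me = empirical_fdr(p_me, null_me)

        n_types = len(set(m.cancer_types))
        context = "PAN" if n_types > 1 else str(m.cancer_types[0])
        base = pd.DataFrame({
            "gene_a": m.genes[ia], "gene_b": m.genes[ib],
            "co_obs": co_obs, "me_obs": k[ia] + k[ib] - 2 * co_obs,
            "margin_a": k[ia], "margin_b": k[ib],
        })
        rows = []
        for direction, p, fdr, q in (
            ("co", p_co, fdr_co, q_co), ("me", p_me, fdr_me, q_me),
        ):
            df = base.copy()
            df["direction"] = direction
            df["p"] = p
            df["fdr"] = fdr
            df["q"] = q
            rows.append(df)
        outcomes = pd.concat(rows, ignore_index=True)
        outcomes["test"] = self.test_name
        outcomes["cancer_type"] = context
        outcomes["mode"] = "pan" if n_types > 1 else "per_type"
        outcomes["n_resamples"] = self.n_permutations
        outcomes["run_seed"] = seed

        return InteractionResults(
            outcomes=outcomes, test=self.test_name, matrix=m, seed=seed,
            null_pvalues={"co": null_co, "me": null_me},
            params={
                "n_permutations": self.n_permutations,
                "block_by_cancer_type": self.block_by_cancer_type,
                "n_pseudo": self.n_pseudo,
            },
        )
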