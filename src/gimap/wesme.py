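"""Weighted-sampling (WeSME-style) test for co-occurrence and exclusivity.

Instead of permuting the whole matrix, each gene's mutated-sample set is
resampled without replacement with per-sample probabilities proportional
to mutation load (within each cancer type), preserving gene margins
exactly and sample loads in expectation.  P-values use the same +1/+1
estimator as the permutation test, with adaptive resampling: a small
initial null (100 draws) that escalates (1,000 then 10,000 draws) only for
pairs whose interim P-value is low.

FDR is again empirical, but the null P-values come from re-scoring 300
fixed-margin permutations of the matrix and are split by the mutation-rate
bins of the two genes (low/low, low/high, high/high; a gene is "high" when
mutated in at least 2% of samples).  Because fixed-margin permutation
preserves every margin and every load, the weighted-resampling null of a
pair is identical for the observed and each permuted matrix, so a single
resample pool per pair (at its escalation depth) scores both.

Pan-cancer mode pools pair counts across cancer types while resampling
within each type; pairs enter the mutual-exclusivity test only with at
least three mutually exclusive samples and the co-occurrence test only
with at least one co-occurring sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sampling import CurveballChain, weighted_wor_draws
from .errors import ConfigError, DataError
from .matrix import MutationMatrix
from .permutation import pair_count_matrix
from .results import InteractionResults, ReplicateResults
from .significance import empirical_fdr, high_confidence_filter

__all__ = [
    "compute_sample_weights",
    "sample_gene_null",
    "assign_rate_bins",
    "wesme_pvalues",
    "AdaptiveNull",
    "WesmeTest",
    "binned_null_pvalues",
    "pool_matrices",
    "pan_cancer_wesme",
    "run_replicates",
]

BIN_NAMES = {0: "low-low", 1: "low-high", 2: "high-high"}


def compute_sample_weights(matrix: MutationMatrix) -> dict[str, pd.Series]:
    """Per cancer type: sample -> weight, proportional to mutation load,
    normalized to sum 1 within the type."""
    loads = matrix.loads().astype(float)
    out = {}
    for ct, idx in matrix.blocks():
        w = loads[idx]
        total = w.sum()
        if total == 0:
            raise DataError(f"cancer type {ct!r} has zero total load")
        out[ct] = pd.Series(w / total, index=matrix.samples[idx])
    return out


def sample_gene_null(k: int, weights: pd.Series,
                     rng: np.random.Generator) -> np.ndarray:
    """Resample one gene's mutated-sample set: k distinct samples drawn
    with probability proportional to weight, without replacement."""
    w = weights.to_numpy(dtype=float)
    if k > np.count_nonzero(w > 0):
        raise DataError(
            f"margin {k} exceeds the {np.count_nonzero(w > 0)} "
            "positive-weight samples"
        )
    if k == 0:
        return np.array([], dtype=object)
    sel = weighted_wor_draws(np.array([k]), w, 1, rng)[0, 0]
    return weights.index.to_numpy(dtype=object)[sel]


def assign_rate_bins(matrix: MutationMatrix,
                     threshold: float = 0.02) -> pd.Series:
    """"high" iff margin / n_samples >= threshold (boundary inclusive),
    else "low"."""
    rate = matrix.margins() / matrix.n_samples
    return pd.Series(
        np.where(rate >= threshold, "high", "low"), index=matrix.genes
    )


@dataclass
class AdaptiveNull:
    """Adaptive-resampling outcome for one gene pair."""

    gene_a: str
    gene_b: str
    co_obs: int
    p_co: float
    p_me: float
    resamples_used: int


def wesme_pvalues(pair, weights: pd.Series, rng: np.random.Generator,
                  ladder: tuple[int, ...] = (100, 1_000, 10_000),
                  escalation_factor: float = 10.0,
                  max_resamples: int = 10_000) -> AdaptiveNull:
    """Adaptive weighted-resampling P-values for a single pair.

    ``pair`` needs attributes gene_a, gene_b, co_obs, margin_a, margin_b.
    Both genes are resampled independently per draw; escalation proceeds
    up the ladder only while the interim P-value (smaller direction) is
    below ``escalation_factor / current_resamples``.
    """
    w = weights.to_numpy(dtype=float)
    margins = np.array([pair.margin_a, pair.margin_b])
    rungs = [min(d, max_resamples) for d in ladder]
    n_ge = n_le = n_done = 0
    for i, target in enumerate(rungs):
        draws = target - n_done
        if draws > 0:
            B = weighted_wor_draws(margins, w, draws, rng)
            co = (B[:, 0, :] & B[:, 1, :]).sum(axis=1)
            n_ge += int((co >= pair.co_obs).sum())
            n_le += int((co <= pair.co_obs).sum())
            n_done = target
        p_co = (1 + n_ge) / (1 + n_done)
        p_me = (1 + n_le) / (1 + n_done)
        if i + 1 == len(rungs) or n_done >= max_resamples:
            break
        if min(p_co, p_me) >= escalation_factor / n_done:
            break
    return AdaptiveNull(pair.gene_a, pair.gene_b, pair.co_obs,
                        p_co, p_me, n_done)


class WesmeTest:
    """Weighted-sampling interaction test over all gene pairs of a matrix.

    Parameters
    ----------
    matrix : MutationMatrix
        Single- or multi-cancer-type matrix; with several types the test
        runs in pan-cancer mode (pooled counts, per-type resampling).
    ladder : tuple of int
        Adaptive resampling schedule (default 100 -> 1,000 -> 10,000).
    escalation_factor : float
        Escalate a pair while its interim p < factor / current resamples.
    n_null_perms : int
        Fixed-margin permutations re-scored for the FDR null (default 300).
    rate_bin_threshold : float
        Mutated-sample fraction at or above which a gene is "high" rate.
    pretest : bool or None
        Apply the pre-test count filters (me_obs >= min_me_pretest for the
        ME test, co_obs >= min_co_pretest for the co test).  ``None``
        (default) enables them exactly in pan-cancer mode.
    """

    test_name = "wesme"

    def __init__(self, matrix: MutationMatrix,
                 ladder: tuple[int, ...] = (100, 1_000, 10_000),
                 escalation_factor: float = 10.0,
                 max_resamples: int = 10_000,
                 n_null_perms: int = 300,
                 rate_bin_threshold: float = 0.02,
                 pretest: bool | None = None,
                 min_me_pretest: int = 3,
                 min_co_pretest: int = 1,
                 batch_size: int = 50) -> None:
        if matrix.n_genes < 2:
            raise DataError("need at least 2 genes to test pairs")
        if n_null_perms < 1:
            raise ConfigError("n_null_perms must be >= 1")
        if not ladder or any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ConfigError("ladder must be strictly increasing")
        self.matrix = matrix
        self.ladder = tuple(min(int(d), int(max_resamples)) for d in ladder)
        self.ladder = tuple(dict.fromkeys(self.ladder))  # dedupe after cap
        self.escalation_factor = float(escalation_factor)
        self.max_resamples = int(max_resamples)
        self.n_null_perms = int(n_null_perms)
        self.rate_bin_threshold = float(rate_bin_threshold)
        self.n_types = len(set(matrix.cancer_types))
        self.pretest = (self.n_types > 1) if pretest is None else bool(pretest)
        self.min_me_pretest = int(min_me_pretest)
        self.min_co_pretest = int(min_co_pretest)
        self.batch_size = int(batch_size)

        # per-block structure reused across draws
        self._blocks = []
        loads = matrix.loads().astype(float)
        for ct, idx in matrix.blocks():
            w = loads[idx]
            if w.sum() == 0:
                raise DataError(f"cancer type {ct!r} has zero total load")
            self._blocks.append(
                (idx, w / w.sum(), matrix.X[:, idx].sum(axis=1))
            )

    # -- internals ---------------------------------------------------------
    def _accumulate(self, ia_sub, ib_sub, hist, n_draws, rng) -> None:
        """Add ``n_draws`` resampled co-counts to per-pair histograms."""
        genes_sub = np.unique(np.concatenate([ia_sub, ib_sub]))
        pos = np.full(self.matrix.n_genes, -1, dtype=np.int64)
        pos[genes_sub] = np.arange(genes_sub.size)
        sa, sb = pos[ia_sub], pos[ib_sub]
        rows = np.arange(ia_sub.size)
        remaining = n_draws
        while remaining > 0:
            d = min(self.batch_size, remaining)
            remaining -= d
            co = None
            for _, w, kb in self._blocks:
                B = weighted_wor_draws(
                    kb[genes_sub], w, d, rng
                ).astype(np.float32)
                part = B @ B.transpose(0, 2, 1)
                co = part if co is None else co + part
            co = np.rint(co[:, sa, sb]).astype(np.int64)
            for i in range(d):
                hist[rows, co[i]] += 1

    # -- fitting -----------------------------------------------------------
    def fit(self, seed: int | None = None) -> InteractionResults:
        rng = np.random.default_rng(seed)
        m = self.matrix
        k = m.margins()
        ia, ib = np.triu_indices(m.n_genes, k=1)
        co_obs = pair_count_matrix(m.X)[ia, ib]
        me_obs = k[ia] + k[ib] - 2 * co_obs

        if self.pretest:
            tested_me = me_obs >= self.min_me_pretest
            tested_co = co_obs >= self.min_co_pretest
        else:
            tested_me = np.ones(ia.size, dtype=bool)
            tested_co = np.ones(ia.size, dtype=bool)
        tested_any = tested_me | tested_co
        if not tested_any.any():
            raise DataError("no gene pair passes the pre-test count filters")

        max_co = int(np.minimum(k[ia], k[ib]).max())
        n_cols = max_co + 2
        t_rows = np.flatnonzero(tested_any)
        n_pairs = ia.size
        n_t = t_rows.size
        ia_t, ib_t = ia[t_rows], ib[t_rows]
        tco_t = tested_co[t_rows]
        tme_t = tested_me[t_rows]

        # co-occurrence counts of every context: row 0 is the observed
        # matrix, rows 1..n_null_perms are fixed-margin permutations (whose
        # P-values become S_null).  All contexts share the same resample
        # pools — fixed-margin permutation preserves margins and loads, so
        # a pair's weighted-resampling null is context-independent.
        chains = [
            CurveballChain(m.X[:, idx], rng) for idx, _, _ in self._blocks
        ]
        ctx_co = np.empty((1 + self.n_null_perms, n_t), dtype=np.int64)
        ctx_co[0] = co_obs[t_rows]
        for i in range(self.n_null_perms):
            co_p = None
            for chain in chains:
                part = pair_count_matrix(chain.sample())
                co_p = part if co_p is None else co_p + part
            ctx_co[1 + i] = co_p[ia_t, ib_t]

        # adaptive ladder: every context (observed and null) escalates a
        # pair while its own interim p < factor / depth; resample pools are
        # grown to the union of all contexts' demands so each context gets
        # exactly the depth the adaptive procedure assigns it.
        def ctx_pvals(cum, depth_scalar, cols):
            sub = cum[cols]
            rows = np.arange(cols.size)[None, :]
            le = sub[rows, ctx_co[:, cols] + 1]
            ge = depth_scalar - sub[rows, ctx_co[:, cols]]
            p_co = (1.0 + ge) / (1.0 + depth_scalar)
            p_me = (1.0 + le) / (1.0 + depth_scalar)
            return p_co, p_me

        def wants(p_co, p_me, cols, depth_scalar):
            p_rel = np.where(tco_t[cols][None, :], p_co, np.inf)
            p_rel = np.minimum(
                p_rel, np.where(tme_t[cols][None, :], p_me, np.inf)
            )
            return p_rel < self.escalation_factor / depth_scalar

        d0 = self.ladder[0]
        hist = np.zeros((n_t, n_cols), dtype=np.uint32)
        self._accumulate(ia_t, ib_t, hist, d0, rng)
        cum = np.zeros((n_t, n_cols + 1), dtype=np.int64)
        np.cumsum(hist, axis=1, out=cum[:, 1:])

        all_cols = np.arange(n_t)
        p_co_ctx, p_me_ctx = ctx_pvals(cum, d0, all_cols)
        depth_used = np.full((1 + self.n_null_perms, n_t), d0,
                             dtype=np.int64)
        cur_cols = all_cols
        cur_hist = hist
        cur_depth = d0
        active = wants(p_co_ctx, p_me_ctx, all_cols, d0)  # ctx x pair
        for next_depth in self.ladder[1:]:
            esc_pairs = np.flatnonzero(active.any(axis=0))
            if esc_pairs.size == 0:
                break
            local = np.searchsorted(cur_cols, esc_pairs)
            cur_hist = cur_hist[local].copy()
            cur_cols = esc_pairs
            self._accumulate(
                ia_t[cur_cols], ib_t[cur_cols], cur_hist,
                next_depth - cur_depth, rng,
            )
            cur_depth = next_depth
            cum_sub = np.zeros((cur_cols.size, n_cols + 1), dtype=np.int64)
            np.cumsum(cur_hist, axis=1, out=cum_sub[:, 1:])
            le = cum_sub[np.arange(cur_cols.size)[None, :],
                         ctx_co[:, cur_cols] + 1]
            ge = cur_depth - cum_sub[np.arange(cur_cols.size)[None, :],
                                     ctx_co[:, cur_cols]]
            p_co_new = (1.0 + ge) / (1.0 + cur_depth)
            p_me_new = (1.0 + le) / (1.0 + cur_depth)
            upd = active[:, cur_cols]  # contexts that asked for this rung
            sub_co = p_co_ctx[:, cur_cols]
            sub_me = p_me_ctx[:, cur_cols]
            sub_d = depth_used[:, cur_cols]
            sub_co[upd] = p_co_new[upd]
            sub_me[upd] = p_me_new[upd]
            sub_d[upd] = cur_depth
            p_co_ctx[:, cur_cols] = sub_co
            p_me_ctx[:, cur_cols] = sub_me
            depth_used[:, cur_cols] = sub_d
            nxt = np.zeros_like(active)
            nxt[:, cur_cols] = upd & wants(
                p_co_new, p_me_new, cur_cols, cur_depth
            )
            active = nxt

        p_co = np.full(n_pairs, np.nan)
        p_me = np.full(n_pairs, np.nan)
        p_co[t_rows] = p_co_ctx[0]
        p_me[t_rows] = p_me_ctx[0]
        depth = np.zeros(n_pairs, dtype=np.int64)
        depth[t_rows] = depth_used[0]
        null_p_co = p_co_ctx[1:]
        null_p_me = p_me_ctx[1:]

        # rate bins from the original (pooled) mutation rates
        high = (k / m.n_samples) >= self.rate_bin_threshold
        bin_pair = high[ia].astype(int) + high[ib].astype(int)

        # empirical FDR per direction within each rate-bin stratum
        fdr_co = np.full(n_pairs, np.nan)
        q_co = np.full(n_pairs, np.nan)
        fdr_me = np.full(n_pairs, np.nan)
        q_me = np.full(n_pairs, np.nan)
        null_sets: dict[tuple[str, str], np.ndarray] = {}
        for direction, tested, p, fdr, q, null_p in (
            ("co", tested_co, p_co, fdr_co, q_co, null_p_co),
            ("me", tested_me, p_me, fdr_me, q_me, null_p_me),
        ):
            t_pos = np.full(n_pairs, -1, dtype=np.int64)
            t_pos[t_rows] = np.arange(t_rows.size)
            for b in (0, 1, 2):
                mask = tested & (bin_pair == b)
                if not mask.any():
                    continue
                rows = np.flatnonzero(mask)
                nulls = null_p[:, t_pos[rows]].ravel().astype(float)
                null_sets[(direction, BIN_NAMES[b])] = nulls
                fdr[rows], q[rows] = empirical_fdr(p[rows], nulls)

        n_types = self.n_types
        context = "PAN" if n_types > 1 else str(m.cancer_types[0])
        base = pd.DataFrame({
            "gene_a": m.genes[ia], "gene_b": m.genes[ib],
            "co_obs": co_obs, "me_obs": me_obs,
            "margin_a": k[ia], "margin_b": k[ib],
            "rate_bin_pair": [BIN_NAMES[b] for b in bin_pair],
            "n_resamples": depth,
        })
        frames = []
        for direction, tested, p, fdr, q in (
            ("co", tested_co, p_co, fdr_co, q_co),
            ("me", tested_me, p_me, fdr_me, q_me),
        ):
            df = base.loc[tested].copy()
            df["direction"] = direction
            df["p"] = p[tested]
            df["fdr"] = fdr[tested]
            df["q"] = q[tested]
            frames.append(df)
        outcomes = pd.concat(frames, ignore_index=True)
        outcomes["test"] = self.test_name
        outcomes["cancer_type"] = context
        outcomes["mode"] = "pan" if n_types > 1 else "per_type"
        outcomes["run_seed"] = seed

        return InteractionResults(
            outcomes=outcomes, test=self.test_name, matrix=m, seed=seed,
            null_pvalues=null_sets,
            params={
                "ladder": self.ladder,
                "escalation_factor": self.escalation_factor,
                "n_null_perms": self.n_null_perms,
                "rate_bin_threshold": self.rate_bin_threshold,
                "pretest": self.pretest,
            },
        )


def binned_null_pvalues(matrix: MutationMatrix, n_null_perms: int = 300,
                        seed: int | None = None, **kwargs
                        ) -> dict[tuple[str, str], np.ndarray]:
    """Null P-value multisets keyed (direction, rate-bin pair)."""
    res = WesmeTest(matrix, n_null_perms=n_null_perms, **kwargs).fit(seed)
    return res.null_pvalues


def pool_matrices(matrices: dict[str, MutationMatrix]) -> MutationMatrix:
    """Union per-cancer-type matrices into one multi-type matrix.

    A gene absent from a type's matrix contributes margin 0 in that type.
    """
    if not matrices:
        raise DataError("no matrices to pool")
    genes = sorted(set().union(*(m.genes.tolist() for m in matrices.values())))
    gi = {g: i for i, g in enumerate(genes)}
    cols, types, parts = [], [], []
    for ct in sorted(matrices):
        m = matrices[ct]
        block = np.zeros((len(genes), m.n_samples), dtype=bool)
        for i, g in enumerate(m.genes):
            block[gi[g]] = m.X[i]
        parts.append(block)
        cols.extend(m.samples.tolist())
        types.extend([ct] * m.n_samples)
    X = np.concatenate(parts, axis=1)
    order = np.argsort(np.asarray(cols, dtype=str), kind="stable")
    return MutationMatrix(
        genes, np.asarray(cols, dtype=object)[order], X[:, order],
        np.asarray(types, dtype=object)[order],
    )


def pan_cancer_wesme(matrices: dict[str, MutationMatrix],
                     seed: int | None = None, **kwargs) -> InteractionResults:
    """Pan-cancer WeSME: pooled counts, per-type resampling, pre-test
    count filters (me_obs >= 3, co_obs >= 1) active."""
    pooled = pool_matrices(matrices)
    kwargs.setdefault("pretest", True)
    return WesmeTest(pooled, **kwargs).fit(seed)


def run_replicates(matrix: MutationMatrix, n_runs: int = 10,
                   seeds: list[int] | None = None, seed: int | None = None,
                   test_kwargs: dict | None = None,
                   q_max: float = 0.2, p_max: float = 0.1, min_co: int = 3,
                   ) -> ReplicateResults:
    """Repeat the WeSME analysis with distinct randomization seeds.

    Returns per-run results plus per-pair support counts (number of runs
    in which the pair was significant at the selection thresholds).
    """
    if seeds is None:
        rng = np.random.default_rng(seed)
        seeds = []
        while len(seeds) < n_runs:
            s = int(rng.integers(0, 2**31 - 1))
            if s not in seeds:
                seeds.append(s)
    if len(set(seeds)) != len(seeds):
        raise ConfigError("replicate seeds must be distinct")
    model = WesmeTest(matrix, **(test_kwargs or {}))
    runs = [model.fit(s) for s in seeds]
    selections = [r.select(q_max, p_max, min_co) for r in runs]
    support = high_confidence_filter(selections, min_support=1,
                                     n_runs=len(seeds))
    return ReplicateResults(runs=runs, seeds=list(seeds), support=support)
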