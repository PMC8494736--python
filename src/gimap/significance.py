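"""Empirical FDR, candidate selection, and interaction-map bookkeeping.

The multiple-testing correction is empirical because permutation P-values
are discrete and biased toward one, which breaks standard FDR procedures.
For an observed P-value set and a null P-value multiset ``S_null`` (from
re-scored permuted matrices), the FDR at threshold P* is

    FDR(P*) = V(P*) / R(P*)

with ``V(P*)`` the proportion of S_null <= P* times the number of observed
P-values, and ``R(P*)`` the number of observed P-values <= P*.  The
q-value of an observed P* is the smallest FDR among all observed P-values
>= P* (a suffix minimum), capped at 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .matrix import MutationMatrix

__all__ = [
    "empirical_fdr",
    "select_candidates",
    "high_confidence_filter",
    "merge_interaction_map",
    "downsampling_experiment",
]

#: Columns that identify one candidate interaction record.
PAIR_KEY = ["gene_a", "gene_b", "direction"]


def empirical_fdr(observed_p: np.ndarray, null_p: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical FDR and q-value per observed P-value.

    Returns ``(fdr, q)`` aligned with ``observed_p``.  ``fdr`` may exceed
    1 (small R); ``q`` is monotonized by the suffix minimum and capped at 1.
    Ties in P count inclusively on both sides, and the result is invariant
    to the input ordering of duplicates.
    """
    observed_p = np.asarray(observed_p, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    if observed_p.size == 0:
        return np.array([]), np.array([])
    if null_p.size == 0:
        raise DataError("no null distribution: S_null is empty")

    null_sorted = np.sort(null_p)
    order = np.argsort(observed_p, kind="stable")
    p_sorted = observed_p[order]
    n_obs = observed_p.size

    v = (np.searchsorted(null_sorted, p_sorted, side="right")
         / null_p.size) * n_obs
    r = np.searchsorted(p_sorted, p_sorted, side="right")
    fdr_sorted = v / r

    q_sorted = np.minimum(np.minimum.accumulate(fdr_sorted[::-1])[::-1], 1.0)

    fdr = np.empty_like(fdr_sorted)
    q = np.empty_like(q_sorted)
    fdr[order] = fdr_sorted
    q[order] = q_sorted
    return fdr, q


def select_candidates(outcomes: pd.DataFrame, q_max: float = 0.2,
                      p_max: float = 0.1, min_co: int = 3) -> pd.DataFrame:
    """Significant outcomes: q < q_max, p < p_max (strict), and — for the
    co-occurrence direction only — an observed co-count of at least
    ``min_co`` samples."""
    keep = (outcomes["q"] < q_max) & (outcomes["p"] < p_max)
    keep &= (outcomes["direction"] != "co") | (outcomes["co_obs"] >= min_co)
    return outcomes.loc[keep].reset_index(drop=True)


def high_confidence_filter(per_run: list[pd.DataFrame],
                           min_support: int = 9,
                           n_runs: int | None = None,
                           extra_key: list[str] | None = None
                           ) -> pd.DataFrame:
    """Candidates significant in at least ``min_support`` of the runs.

    ``per_run`` holds the selected outcomes of each replicate run (one
    randomization seed each).  Single-run tests (the permutation test is
    run once) pass through by calling with ``min_support=1``.
    """
    n_runs = len(per_run) if n_runs is None else n_runs
    if min_support > n_runs:
        raise ConfigError("min_support cannot exceed the number of runs")
    key = PAIR_KEY + (extra_key or [])
    frames = []
    for i, df in enumerate(per_run):
        if len(df):
            sub = df.copy()
            sub["_run"] = i
            frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=key + ["support", "n_runs"])
    allruns = pd.concat(frames, ignore_index=True)
    support = (
        allruns.groupby(key, as_index=False)["_run"].nunique()
        .rename(columns={"_run": "support"})
    )
    support["n_runs"] = n_runs
    rep = (
        allruns.sort_values("p").drop_duplicates(key)
        .drop(columns=["_run"])
    )
    merged = support.merge(rep, on=key, how="left")
    return (
        merged.loc[merged["support"] >= min_support]
        .sort_values(key).reset_index(drop=True)
    )


def canonical_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with gene_a < gene_b alphabetically in every row."""
    df = df.copy()
    flip = df["gene_a"] > df["gene_b"]
    df.loc[flip, ["gene_a", "gene_b"]] = \
        df.loc[flip, ["gene_b", "gene_a"]].to_numpy()
    if {"margin_a", "margin_b"}.issubset(df.columns):
        df.loc[flip, ["margin_a", "margin_b"]] = \
            df.loc[flip, ["margin_b", "margin_a"]].to_numpy()
    return df


def merge_interaction_map(candidates: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge candidate tables into one interaction map plus a summary.

    ``candidates`` needs columns gene_a, gene_b, direction, cancer_type,
    mode ("per_type"|"pan"), test, and optionally dataset.  One record per
    (pair, cancer_type-or-PAN, direction) comes out, annotated with the
    tests it was detected in ("both" / single test name) and, for pan
    records, whether the pair was also found in a specific cancer type.
    The summary mirrors the usual per-dataset bookkeeping: total and
    unique candidate counts, the co/me split, per-type vs pan counts with
    overlap, and the per-test breakdown.
    """
    if candidates.empty:
        empty = pd.DataFrame(columns=PAIR_KEY + [
            "cancer_type", "mode", "tests_detected_in", "pan_overlap"])
        return empty, pd.DataFrame(columns=["dataset", "metric", "count"])
    cand = canonical_pairs(candidates)
    if "dataset" not in cand.columns:
        cand["dataset"] = "cohort"

    key = ["dataset"] + PAIR_KEY + ["cancer_type", "mode"]
    agg = {"tests": ("test", lambda t: sorted(set(t)))}
    if "co_obs" in cand.columns:
        agg["co_obs"] = ("co_obs", "first")
    records = cand.groupby(key, as_index=False).agg(**agg)
    records["tests_detected_in"] = records["tests"].map(
        lambda t: "both" if len(t) > 1 else f"{t[0]}-only"
    )
    records = records.drop(columns=["tests"])

    # does a pan-mode record recur in some per-type context (and vice versa)?
    per_type_pairs = set(map(tuple, records.loc[
        records["mode"] == "per_type", ["dataset"] + PAIR_KEY
    ].to_numpy()))
    records["pan_overlap"] = [
        (row["mode"] == "pan"
         and (row["dataset"], row["gene_a"], row["gene_b"],
              row["direction"]) in per_type_pairs)
        for _, row in records.iterrows()
    ]
    # flag the same (pair, context) reported in both directions
    dup = records.duplicated(
        ["dataset", "gene_a", "gene_b", "cancer_type", "mode"], keep=False
    ) & ~records.duplicated(key, keep=False)
    records["inconsistent_direction"] = dup

    summaries = []
    for ds, grp in records.groupby("dataset"):
        uniq = grp.drop_duplicates(PAIR_KEY)
        pan = grp[grp["mode"] == "pan"]
        summaries.extend([
            (ds, "all", len(grp)),
            (ds, "unique", len(uniq)),
            (ds, "co_occurring", int((uniq["direction"] == "co").sum())),
            (ds, "mutually_exclusive", int((uniq["direction"] == "me").sum())),
            (ds, "per_cancer_type", int((grp["mode"] == "per_type").sum())),
            (ds, "pan", len(pan)),
            (ds, "pan_overlap_cancer_type", int(pan["pan_overlap"].sum())),
            (ds, "both_tests",
             int((uniq["tests_detected_in"] == "both").sum())),
            (ds, "wesme_only",
             int((uniq["tests_detected_in"] == "wesme-only").sum())),
            (ds, "permutation_only",
             int((uniq["tests_detected_in"] == "permutation-only").sum())),
        ])
    summary = pd.DataFrame(summaries, columns=["dataset", "metric", "count"])
    records = records.sort_values(key).reset_index(drop=True)
    return records, summary


def downsampling_experiment(matrix: MutationMatrix, sizes: list[int],
                            n_reps: int = 10,
                            seed: int | None = None,
                            test_kwargs: dict | None = None,
                            select_kwargs: dict | None = None,
                            min_support: int = 9,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate counts on random sample subsets of decreasing size.

    For each size, ``n_reps`` subsamples are drawn uniformly without
    replacement; each is re-filtered (zero-load samples and singleton
    genes dropped) and run through the WeSME test plus selection.  The
    high-confidence count per size applies the >=9-of-10-replicates rule
    across the replicates of that size.

    Returns ``(per_rep, per_size)`` frames.
    """
    from .wesme import WesmeTest  # local import; wesme depends on this module

    rng = np.random.default_rng(seed)
    test_kwargs = test_kwargs or {}
    select_kwargs = select_kwargs or {}
    rep_rows = []
    size_rows = []
    for size in sizes:
        if size > matrix.n_samples:
            raise ConfigError(
                f"subsample size {size} exceeds cohort size {matrix.n_samples}"
            )
        selections = []
        for rep in range(n_reps):
            cols = np.sort(rng.choice(matrix.n_samples, size, replace=False))
            sub = matrix.subset_samples(cols)
            keep_g = sub.X.sum(axis=1) >= 2
            sub = sub.subset_genes(np.flatnonzero(keep_g))
            keep_s = sub.X.sum(axis=0) >= 1
            sub = sub.subset_samples(np.flatnonzero(keep_s))
            if sub.n_genes < 2:
                sel = pd.DataFrame(columns=PAIR_KEY + ["p", "q", "co_obs"])
            else:
                res = WesmeTest(sub, **test_kwargs).fit(
                    seed=int(rng.integers(0, 2**31 - 1))
                )
                sel = select_candidates(res.outcomes, **select_kwargs)
            selections.append(sel)
            rep_rows.append({
                "size": size, "rep": rep,
                "n_candidates": len(sel.drop_duplicates(PAIR_KEY)),
            })
        hc = high_confidence_filter(selections, min_support=min_support,
                                    n_runs=n_reps)
        size_rows.append({
            "size": size,
            "mean_candidates": float(np.mean(
                [r["n_candidates"] for r in rep_rows if r["size"] == size]
            )),
            "n_high_confidence": len(hc),
        })
    return pd.DataFrame(rep_rows), pd.DataFrame(size_rows)
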