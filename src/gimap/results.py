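"""Results containers for the interaction tests.

:class:`InteractionResults` is what ``PermutationTest.fit()`` and
``WesmeTest.fit()`` return: a long-format outcome table (one row per gene
pair and direction), the null P-value multisets behind the FDR, and
convenience methods for selection, summary, serialization, and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import significance
from .matrix import MutationMatrix

__all__ = ["InteractionResults", "ReplicateResults"]

#: canonical column order of the per-pair outcome TSV
OUTCOME_COLUMNS = [
    "gene_a", "gene_b", "direction", "cancer_type", "mode", "test",
    "co_obs", "me_obs", "margin_a", "margin_b", "p", "fdr", "q",
    "n_resamples", "run_seed",
]


@dataclass
class InteractionResults:
    """Fitted interaction-test results.

    Attributes
    ----------
    outcomes : DataFrame
        One row per tested (gene pair, direction); columns include p, fdr,
        q, observed counts and margins, test identity and run seed.
    null_pvalues : dict
        The S_null multisets used for the FDR, keyed by direction (and,
        for WeSME, rate-bin pair).
    """

    outcomes: pd.DataFrame
    test: str
    matrix: MutationMatrix | None = None
    seed: int | None = None
    null_pvalues: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def select(self, q_max: float = 0.2, p_max: float = 0.1,
               min_co: int = 3) -> pd.DataFrame:
        """Significant outcomes at the default selection thresholds."""
        return significance.select_candidates(
            self.outcomes, q_max=q_max, p_max=p_max, min_co=min_co
        )

    def pvalue(self, gene_a: str, gene_b: str, direction: str) -> float:
        a, b = sorted((gene_a, gene_b))
        df = self.outcomes
        row = df[(df["gene_a"] == a) & (df["gene_b"] == b)
                 & (df["direction"] == direction)]
        if row.empty:
            raise KeyError(f"{a}-{b} ({direction}) was not tested")
        return float(row["p"].iloc[0])

    def summary(self, q_max: float = 0.2, p_max: float = 0.1,
                min_co: int = 3, max_rows: int = 20) -> str:
        """Human-readable summary of the fit and its top candidates."""
        sel = self.select(q_max, p_max, min_co).sort_values("p")
        n_pairs = len(self.outcomes.drop_duplicates(["gene_a", "gene_b"]))
        lines = [
            f"{self.test} interaction test",
            "=" * 46,
            f"gene pairs tested     : {n_pairs}",
            f"outcome rows          : {len(self.outcomes)}",
            f"run seed              : {self.seed}",
        ]
        for k, v in self.params.items():
            lines.append(f"{k:<22}: {v}")
        lines.append(
            f"significant (q<{q_max}, p<{p_max}, co>={min_co}) : {len(sel)}"
        )
        if len(sel):
            cols = ["gene_a", "gene_b", "direction", "cancer_type",
                    "co_obs", "p", "q"]
            cols = [c for c in cols if c in sel.columns]
            lines.append("")
            lines.append(sel[cols].head(max_rows).to_string(index=False))
            if len(sel) > max_rows:
                lines.append(f"... and {len(sel) - max_rows} more")
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        cols = [c for c in OUTCOME_COLUMNS if c in self.outcomes.columns]
        cols += [c for c in self.outcomes.columns if c not in cols]
        self.outcomes[cols].to_csv(path, sep="\t", index=False)

    def plot_pvalues(self, other: "InteractionResults", direction: str = "me",
                     ax=None):
        """Scatter of this test's P-values against another's (log-log)."""
        import matplotlib.pyplot as plt

        key = ["gene_a", "gene_b", "direction"]
        a = self.outcomes[self.outcomes["direction"] == direction]
        b = other.outcomes[other.outcomes["direction"] == direction]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(merged["p_a"], merged["p_b"], ".", alpha=0.4)
        lim = min(merged["p_a"].min(), merged["p_b"].min()) / 2
        ax.plot([lim, 1], [lim, 1], "k--", lw=0.8)
        ax.set_xlabel(f"{self.test} p ({direction})")
        ax.set_ylabel(f"{other.test} p ({direction})")
        return ax


@dataclass
class ReplicateResults:
    """Outcome of repeating a stochastic test with several seeds."""

    runs: list[InteractionResults]
    seeds: list[int]
    support: pd.DataFrame  # per (pair, direction): runs found significant

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def high_confidence(self, min_support: int = 9,
                        q_max: float = 0.2, p_max: float = 0.1,
                        min_co: int = 3) -> pd.DataFrame:
        """Pairs significant in >= min_support of the replicate runs."""
        selections = [r.select(q_max, p_max, min_co) for r in self.runs]
        return significance.high_confidence_filter(
            selections, min_support=min_support, n_runs=self.n_runs
        )

    def summary(self) -> str:
        lines = [
            f"{self.runs[0].test} x {self.n_runs} replicate runs",
            "=" * 46,
            f"seeds: {self.seeds}",
        ]
        hc = self.high_confidence()
        lines.append(f"high-confidence candidates (>=9/{self.n_runs}): "
                     f"{len(hc)}")
        if len(hc):
            cols = [c for c in ["gene_a", "gene_b", "direction", "support",
                                "co_obs", "p", "q"] if c in hc.columns]
            lines.append(hc[cols].to_string(index=False))
        return "\n".join(lines)
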