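"""Mutation load association (MLA) scores and suspect-pair flagging.

A gene whose probability of being mutated rises with a sample's overall
mutation load tends to look mutually exclusive with genes that do not —
an artifact, not an interaction.  The MLA score quantifies this: a
logistic regression of the gene's mutation indicator on sample mutation
load; MLA = slope / SE(slope) (a Wald statistic).  Candidate pairs are
marked "suspect" when

* mutual exclusivity: |MLA_a - MLA_b| > 3 and max(MLA_a, MLA_b) > 3, or
* co-occurrence: both MLA_a > 3 and MLA_b > 3

(strict inequalities).  Loads are the column sums of the same mutation
matrix used for testing; by default the gene's own contribution to the
load is not removed (a leave-one-out switch exists for sensitivity
analysis), and load enters the regression untransformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .matrix import MutationMatrix

__all__ = ["MlaScore", "SuspectFlag", "mutation_load", "mla_score",
           "mla_scores", "flag_suspects"]


@dataclass(frozen=True)
class MlaScore:
    gene: str
    coefficient: float
    std_error: float
    mla: float
    n_samples: int
    status: str  # "ok" | "constant" | "separation" | "no_convergence"

    @property
    def defined(self) -> bool:
        return self.status == "ok" and np.isfinite(self.mla)


@dataclass(frozen=True)
class SuspectFlag:
    gene_a: str
    gene_b: str
    direction: str
    rule: str  # "me_rule" | "co_rule"
    mla_a: float
    mla_b: float


def mutation_load(matrix: MutationMatrix) -> pd.Series:
    """Mutation load per sample: number of mutated genes (column sums)."""
    return pd.Series(matrix.loads(), index=matrix.samples)


def mla_score(gene: str, matrix: MutationMatrix,
              leave_one_out: bool = False) -> MlaScore:
    """MLA of one gene: logistic slope of its indicator on load, / SE.

    Degenerate fits (constant indicator, perfect separation, failed
    convergence) return a score with a status code instead of raising.
    """
    g = matrix.gene_index(gene)
    y = matrix.X[g].astype(float)
    load = matrix.loads().astype(float)
    if leave_one_out:
        load = load - y
    n = matrix.n_samples
    if y.min() == y.max() or load.min() == load.max():
        # constant outcome or constant covariate: no slope to estimate
        return MlaScore(gene, np.nan, np.nan, np.nan, n, "constant")
    exog = sm.add_constant(load)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, exog).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return MlaScore(gene, np.nan, np.nan, np.nan, n, "separation")
    if not fit.mle_retvals.get("converged", False):
        return MlaScore(gene, np.nan, np.nan, np.nan, n, "no_convergence")
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se == 0 or se > 1e4:
        # huge SE is quasi-separation in disguise
        return MlaScore(gene, coef, se, np.nan, n, "separation")
    return MlaScore(gene, coef, se, coef / se, n, "ok")


def mla_scores(matrix: MutationMatrix, genes: list[str] | None = None,
               leave_one_out: bool = False) -> dict[str, MlaScore]:
    """MLA for several genes (default: every gene in the matrix)."""
    genes = list(matrix.genes) if genes is None else genes
    return {g: mla_score(g, matrix, leave_one_out) for g in genes}


def scores_frame(scores: dict[str, MlaScore]) -> pd.DataFrame:
    return pd.DataFrame([
        {"gene": s.gene, "coefficient": s.coefficient, "se": s.std_error,
         "mla": s.mla, "status": s.status}
        for s in scores.values()
    ])


def flag_suspects(candidates: pd.DataFrame, scores: dict[str, MlaScore],
                  threshold: float = 3.0) -> list[SuspectFlag]:
    """Apply the suspect rules to candidate pairs.

    Pairs with an undefined MLA on either gene cannot be flagged and are
    skipped (their genes appear in the scores map with a status code).
    """
    flags: list[SuspectFlag] = []
    seen: set[tuple] = set()
    for _, row in candidates.iterrows():
        key = (row["gene_a"], row["gene_b"], row["direction"])
        if key in seen:
            continue
        seen.add(key)
        sa = scores.get(row["gene_a"])
        sb = scores.get(row["gene_b"])
        if sa is None or sb is None or not sa.defined or not sb.defined:
            continue
        a, b = sa.mla, sb.mla
        if row["direction"] == "me":
            if abs(a - b) > threshold and max(a, b) > threshold:
                flags.append(SuspectFlag(row["gene_a"], row["gene_b"],
                                         "me", "me_rule", a, b))
        elif row["direction"] == "co":
            if min(a, b) > threshold:
                flags.append(SuspectFlag(row["gene_a"], row["gene_b"],
                                         "co", "co_rule", a, b))
    return flags


def suspects_frame(flags: list[SuspectFlag]) -> pd.DataFrame:
    return pd.DataFrame([
        {"gene_a": f.gene_a, "gene_b": f.gene_b, "direction": f.direction,
         "rule": f.rule, "mla_a": f.mla_a, "mla_b": f.mla_b}
        for f in flags
    ], columns=["gene_a", "gene_b", "direction", "rule", "mla_a", "mla_b"])
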