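"""Parsing and filtering of MAF-like somatic variant tables.

Two input dialects are supported, mirroring the two cohort sources the
pipeline was designed around:

* ``TARGET`` — MAF-style files with ``Hugo_Symbol`` / ``Tumor_Sample_Barcode``
  / ``Variant_Classification`` columns and MAF consequence vocabulary.
* ``DKFZ`` — ANNOVAR-style consequence labels (``stopgain``,
  ``non-synonymous``, ...).

A third ``SYNTHETIC`` dialect is used by the cohort simulator; its
vocabulary is configurable.  Only variants whose consequence is in the
dialect's keep-list (exonic classes with a likely functional effect) enter
the mutation matrix.  Hypermutator counting deliberately happens *before*
functional filtering, because that count includes silent SNVs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .matrix import MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "GeneAnnotationAttrs",
    "FilterReport",
    "Dialect",
    "DIALECTS",
    "parse_variants",
    "filter_functional",
    "resolve_overlapping_genes",
    "hypermutator_threshold",
    "flag_hypermutators",
    "build_matrix",
    "CODING_LENGTH_BP",
]

#: Non-redundant coding length (bp) of the reviewed/validated protein-coding
#: gene set used to derive the hypermutator cutoff.  Taken as a given
#: constant; the gene set itself is not part of this package.
CODING_LENGTH_BP = 23_698_355


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_STATUS_RANK = {"KNOWN": 0, "NOVEL": 1, "PUTATIVE": 2, "UNKNOWN": 3}


@dataclass(frozen=True)
class GeneAnnotationAttrs:
    """Annotation attributes used to rank overlapping gene candidates."""

    gencode_v19_status: str = "UNKNOWN"
    gencode_v19_type: str = "other"
    gencode_v27_type: str = "other"
    n_exonic_alterations: int = 0
    n_exonic_alterations_single: int = 0
    name_has_dash: bool = False

    def __post_init__(self) -> None:
        if self.gencode_v19_status not in _STATUS_RANK:
            raise ConfigError(
                f"unknown Gencode v19 status {self.gencode_v19_status!r}"
            )
        if self.n_exonic_alterations < 0 or self.n_exonic_alterations_single < 0:
            raise ConfigError("alteration counts must be >= 0")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/indel call collapsed to gene level."""

    sample_id: str
    gene: str
    consequence: str
    cancer_type: str
    dataset: str
    candidate_genes: tuple[tuple[str, GeneAnnotationAttrs], ...] | None = None


class FilterReport:
    """Per-rule accounting of removed records, samples, and genes.

    Totals must reconcile: input = retained + sum(removed) at every level.
    """

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def add(self, rule: str, level: str, n_removed: int, detail: str = "") -> None:
        if n_removed:
            self.entries.append(
                {"rule": rule, "level": level, "n_removed": int(n_removed),
                 "detail": detail}
            )

    def removed(self, level: str | None = None) -> int:
        return sum(
            e["n_removed"] for e in self.entries
            if level is None or e["level"] == level
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["rule", "level", "n_removed", "detail"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:
        return f"FilterReport({len(self.entries)} rules, {self.removed()} removed)"


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dialect:
    """Column names and consequence vocabulary of one input flavor."""

    name: str
    sample_column: str
    gene_column: str
    consequence_column: str
    cancer_type_column: str | None
    keep: frozenset[str]
    known_drop: frozenset[str]

    def with_columns(self, column_map: dict | None) -> "Dialect":
        if not column_map:
            return self
        return replace(self, **{
            k: v for k, v in column_map.items()
            if k in {"sample_column", "gene_column", "consequence_column",
                     "cancer_type_column"}
        })


#: Functional consequence classes retained for interaction testing.
TARGET_KEEP = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "missense", "nonsense",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "frameshift", "proteinDel", "proteinIns",
})
TARGET_DROP = frozenset({
    "Silent", "silent", "Intron", "RNA", "3'UTR", "5'UTR", "5'Flank",
    "3'Flank", "IGR", "Splice_Site", "Translation_Start_Site",
    "Nonstop_Mutation",
})
DKFZ_KEEP = frozenset({
    "frameshift", "non-frameshift", "non-synonymous", "stopgain", "stoploss",
})
DKFZ_DROP = frozenset({
    "synonymous", "synonymous SNV", "unknown", "ncRNA", "UTR3", "UTR5",
    "intronic", "splicing",
})
SYNTHETIC_KEEP = frozenset({
    "missense", "nonsense", "frameshift", "inframe_indel", "stopgain",
    "stoploss",
})
SYNTHETIC_DROP = frozenset({"silent", "synonymous"})

DIALECTS: dict[str, Dialect] = {
    "TARGET": Dialect(
        "TARGET", "Tumor_Sample_Barcode", "Hugo_Symbol",
        "Variant_Classification", "Cancer_Type", TARGET_KEEP, TARGET_DROP,
    ),
    "DKFZ": Dialect(
        "DKFZ", "sample", "gene", "consequence", "cancer_type",
        DKFZ_KEEP, DKFZ_DROP,
    ),
    "SYNTHETIC": Dialect(
        "SYNTHETIC", "sample_id", "gene", "consequence", "cancer_type",
        SYNTHETIC_KEEP, SYNTHETIC_DROP,
    ),
}


def get_dialect(name: str, column_map: dict | None = None,
                keep: frozenset | None = None) -> Dialect:
    try:
        d = DIALECTS[name.upper()]
    except KeyError:
        raise ConfigError(
            f"unknown dialect {name!r}; expected one of {sorted(DIALECTS)}"
        ) from None
    d = d.with_columns(column_map)
    if keep is not None:
        if d.name != "SYNTHETIC":
            raise ConfigError("keep-list is only configurable for SYNTHETIC")
        d = replace(d, keep=frozenset(keep))
    return d


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def parse_variants(path, dialect: str | Dialect,
                   column_map: dict | None = None,
                   report: FilterReport | None = None,
                   ) -> tuple[list[VariantRecord], FilterReport]:
    """Read a tab-separated variant table into :class:`VariantRecord` rows.

    Malformed rows (missing sample, gene, or consequence) are counted in the
    returned :class:`FilterReport` rather than silently dropped or raised.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect, column_map)
    else:
        dialect = dialect.with_columns(column_map)
    report = report if report is not None else FilterReport()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot read variant table {path}: {exc}") from exc

    needed = [dialect.sample_column, dialect.gene_column,
              dialect.consequence_column]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: missing required column(s) {missing} for dialect "
            f"{dialect.name}"
        )
    has_ct = (dialect.cancer_type_column is not None
              and dialect.cancer_type_column in df.columns)

    records: list[VariantRecord] = []
    n_malformed = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(row)
        sample = _clean(row.get(dialect.sample_column))
        gene = _clean(row.get(dialect.gene_column))
        cons = _clean(row.get(dialect.consequence_column))
        if not sample or not gene or not cons:
            n_malformed += 1
            continue
        ct = _clean(row.get(dialect.cancer_type_column)) if has_ct else ""
        records.append(VariantRecord(
            sample_id=sample, gene=gene, consequence=cons,
            cancer_type=ct or "NA", dataset=dialect.name,
        ))
    report.add("malformed_row", "record", n_malformed,
               "missing sample, gene, or consequence")
    return records, report


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value).strip()


def filter_functional(records: list[VariantRecord],
                      dialect_overrides: dict[str, Dialect] | None = None,
                      report: FilterReport | None = None,
                      ) -> tuple[list[VariantRecord], FilterReport]:
    """Keep only variants whose consequence is in the dialect keep-list.

    Consequences on the dialect's known drop-list are removed under the
    ``non_functional`` rule; anything else is removed under
    ``unknown_consequence`` (graceful degradation on vocabulary drift).
    """
    report = report if report is not None else FilterReport()
    kept: list[VariantRecord] = []
    n_nonfunc = 0
    n_unknown = 0
    for rec in records:
        dialect = (dialect_overrides or {}).get(rec.dataset) \
            or get_dialect(rec.dataset)
        if rec.consequence in dialect.keep:
            kept.append(rec)
        elif rec.consequence in dialect.known_drop:
            n_nonfunc += 1
        else:
            n_unknown += 1
    report.add("non_functional", "record", n_nonfunc,
               "consequence on drop-list")
    report.add("unknown_consequence", "record", n_unknown,
               "consequence not in keep- or drop-list")
    return kept, report


def resolve_overlapping_genes(record: VariantRecord) -> str:
    """Pick one gene for a variant annotated to several overlapping genes.

    Candidates are ranked by, in order: Gencode v19 status (KNOWN best),
    v19 type (protein_coding first), v27 type (protein_coding first), total
    exonic alterations (more first), exonic alterations in single genes
    (more first), and absence of "-" in the name (read-through genes rank
    last).  A full tie falls back to the alphabetically first symbol.
    """
    if not record.candidate_genes:
        return record.gene
    if len(record.candidate_genes) == 1:
        return record.candidate_genes[0][0]

    def key(item: tuple[str, GeneAnnotationAttrs]):
        g, a = item
        return (
            _STATUS_RANK[a.gencode_v19_status],
            0 if a.gencode_v19_type == "protein_coding" else 1,
            0 if a.gencode_v27_type == "protein_coding" else 1,
            -a.n_exonic_alterations,
            -a.n_exonic_alterations_single,
            a.name_has_dash,
        )

    ranked = sorted(record.candidate_genes, key=key)
    best = key(ranked[0])
    tied = [g for g, a in record.candidate_genes if key((g, a)) == best]
    if len(tied) > 1:
        winner = min(tied)
        logger.warning(
            "overlapping-gene vote tied between %s; choosing %s "
            "(alphabetical fallback)", sorted(tied), winner,
        )
        return winner
    return ranked[0][0]


def resolve_all_overlaps(records: list[VariantRecord]) -> list[VariantRecord]:
    """Apply :func:`resolve_overlapping_genes` wherever candidates exist."""
    out = []
    for rec in records:
        if rec.candidate_genes:
            out.append(replace(rec, gene=resolve_overlapping_genes(rec),
                               candidate_genes=None))
        else:
            out.append(rec)
    return out


def hypermutator_threshold(coding_length_bp: int = CODING_LENGTH_BP,
                           coverage_fraction: float = 0.95,
                           rate_per_mb: float = 10.0) -> int:
    """Coding-mutation count above which a sample is a hypermutator.

    ``floor(rate_per_mb * coverage_fraction * coding_length_bp / 1e6)``;
    with the defaults (23,698,355 bp, 95% covered, 10/Mb) this is 225.
    Samples are flagged iff their count strictly exceeds the threshold.
    """
    if coding_length_bp <= 0 or not (0 < coverage_fraction <= 1) \
            or rate_per_mb <= 0:
        raise ConfigError(
            "coding_length_bp and rate_per_mb must be positive and "
            "coverage_fraction in (0, 1]"
        )
    return int(math.floor(
        rate_per_mb * coverage_fraction * coding_length_bp / 1e6
    ))


def flag_hypermutators(records: list[VariantRecord],
                       threshold: int | None = None,
                       gene_universe: set[str] | None = None,
                       ) -> set[str]:
    """Samples whose total variant count (all SNVs incl. silent, all indels)
    strictly exceeds ``threshold``.

    Must be called on *pre-filter* records: the count includes silent
    variants that :func:`filter_functional` later removes.  ``gene_universe``
    optionally restricts counting to a gene set (default: all genes seen).
    """
    if threshold is None:
        threshold = hypermutator_threshold()
    counts: dict[str, int] = {}
    for rec in records:
        if gene_universe is not None and rec.gene not in gene_universe:
            continue
        counts[rec.sample_id] = counts.get(rec.sample_id, 0) + 1
    return {s for s, n in counts.items() if n > threshold}


def build_matrix(records: list[VariantRecord],
                 min_mutated_samples: int = 2,
                 exclude_samples: set[str] | None = None,
                 report: FilterReport | None = None,
                 ) -> tuple[MutationMatrix, FilterReport]:
    """Collapse filtered variants to a binary gene x sample matrix.

    Multiple mutations of one gene in one sample collapse to a single 1.
    Zero-mutation samples are removed first, then genes mutated in fewer
    than ``min_mutated_samples`` samples, in one pass (no iteration).
    Genes and samples come out in alphabetical order.
    """
    report = report if report is not None else FilterReport()
    exclude_samples = exclude_samples or set()

    cells: set[tuple[str, str]] = set()
    sample_ct: dict[str, str] = {}
    n_blocked = 0
    for rec in records:
        if rec.sample_id in exclude_samples:
            n_blocked += 1
            continue
        cells.add((rec.gene, rec.sample_id))
        sample_ct.setdefault(rec.sample_id, rec.cancer_type)
    report.add("sample_blocklist", "record", n_blocked,
               "records of excluded samples (hypermutator/blocklist)")

    if not cells:
        raise DataError(
            "no testable data: no records left after sample exclusion"
        )

    genes = sorted({g for g, _ in cells})
    samples = sorted({s for _, s in cells})
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: j for j, s in enumerate(samples)}
    X = np.zeros((len(genes), len(samples)), dtype=bool)
    for g, s in cells:
        X[gi[g], si[s]] = True

    # samples-then-genes removal, applied once
    keep_s = X.sum(axis=0) >= 1  # vacuously true here; kept for clarity
    report.add("zero_mutation_sample", "sample", int((~keep_s).sum()))
    X = X[:, keep_s]
    samples = [s for s, k in zip(samples, keep_s) if k]

    keep_g = X.sum(axis=1) >= min_mutated_samples
    report.add("singleton_gene", "gene", int((~keep_g).sum()),
               f"mutated in < {min_mutated_samples} samples")
    X = X[keep_g, :]
    genes = [g for g, k in zip(genes, keep_g) if k]

    # dropping genes can orphan samples; a single extra pass removes them
    # (they have no mutated gene left) without iterating to a fixed point
    keep_s2 = X.sum(axis=0) >= 1
    report.add("zero_mutation_sample_after_gene_filter", "sample",
               int((~keep_s2).sum()))
    X = X[:, keep_s2]
    samples = [s for s, k in zip(samples, keep_s2) if k]

    if X.size == 0 or X.shape[0] == 0 or X.shape[1] == 0:
        raise DataError(
            "no testable data after singleton-gene filter "
            f"(min_mutated_samples={min_mutated_samples})"
        )
    matrix = MutationMatrix(
        genes, samples, X, [sample_ct[s] for s in samples]
    )
    return matrix, report
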