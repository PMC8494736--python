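"""Synthetic tumor-cohort generator with planted interactions.

Generates binary mutation matrices (plus the MAF-like variant file behind
them) with the statistical structure the interaction tests assume:

* several cancer types with their own sample counts,
* heterogeneous per-gene mutation frequencies (log-uniform, long-tailed),
* heavy-tailed per-sample mutation loads (log-normal multiplier, mean 1),
* optional subtypes with subtype-specific load multipliers and
  subtype-private genes (the classic confounder that fakes exclusivity),
* optional hypermutator samples (huge load + silent-variant excess), and
* planted co-occurring / mutually exclusive gene pairs with a truth table
  for recovery scoring.

Per sample ``s`` and background gene ``g`` the mutation probability is
``clamp(freq(g) * load_mult(s) * subtype_mult(s), 0, 1)``.  Planted genes
are drawn with fixed, load-independent probabilities so that their
margins and effect sizes are exactly the requested ones; planting order
is base sampling -> co pairs -> ME pairs, and ME clearing may slightly
depress the realized margins (reported in the truth table, not
re-balanced).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import DIALECTS
from .matrix import MutationMatrix

__all__ = [
    "SubtypeSpec", "CancerTypeSpec", "PlantedInteraction", "CohortSpec",
    "TruthTable", "SyntheticCohort", "generate_cohort",
    "plant_me_pair", "plant_co_pair", "add_subtype_structure",
]


@dataclass(frozen=True)
class SubtypeSpec:
    name: str
    fraction: float
    load_multiplier: float = 1.0
    n_private_genes: int = 0
    private_gene_freq: float = 0.25  # within-subtype mutation frequency


@dataclass(frozen=True)
class CancerTypeSpec:
    name: str
    n_samples: int
    subtypes: tuple[SubtypeSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("sample counts must be >= 1")
        if self.subtypes:
            total = sum(s.fraction for s in self.subtypes)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"subtype fractions of {self.name} sum to {total}, not 1"
                )


@dataclass(frozen=True)
class PlantedInteraction:
    """A planted pair: ME with exclusivity in (0, 1] or co with lift > 1.

    ``mechanism="subtype"`` (ME only) realizes the exclusivity indirectly
    by making the two genes private to different subtypes.
    """

    gene_a: str
    gene_b: str
    kind: str  # "mutual_exclusion" | "co_occurrence"
    strength: float
    freq_a: float = 0.15
    freq_b: float = 0.15
    mechanism: str = "direct"  # "direct" | "subtype"
    cancer_type: str | None = None  # None: planted across all samples

    def __post_init__(self) -> None:
        if self.kind == "mutual_exclusion":
            if not (0 < self.strength <= 1):
                raise ConfigError("exclusivity must be in (0, 1]")
        elif self.kind == "co_occurrence":
            if self.strength <= 1:
                raise ConfigError("co-occurrence lift must be > 1")
        else:
            raise ConfigError(f"unknown interaction kind {self.kind!r}")
        if min(self.freq_a, self.freq_b) <= 0:
            raise ConfigError("planted gene frequency must be > 0")
        if self.mechanism not in {"direct", "subtype"}:
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; the defaults are the study conditions."""

    cancer_types: tuple[CancerTypeSpec, ...]
    n_background_genes: int = 200
    freq_low: float | None = None  # default 1 / total samples
    freq_high: float = 0.3
    freq_alpha: float = 1.75  # power-law exponent of the frequency law
    load_sigma: float = 0.6  # log-normal dispersion of sample loads
    hypermutator_fraction: float = 0.0
    hypermutator_multiplier: float = 25.0
    silent_mean: float = 12.0  # silent variants per sample at load mult 1
    planted: tuple[PlantedInteraction, ...] = ()

    def __post_init__(self) -> None:
        if not self.cancer_types:
            raise ConfigError("need at least one cancer type")
        if self.n_background_genes < 1:
            raise ConfigError("need at least one background gene")
        if not (0 <= self.hypermutator_fraction < 1):
            raise ConfigError("hypermutator fraction must be in [0, 1)")
        if self.freq_high > 1 or (self.freq_low or 0) < 0:
            raise ConfigError("frequencies must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(ct.n_samples for ct in self.cancer_types)

    @classmethod
    def default(cls) -> "CohortSpec":
        """Four cancer types (100-400 samples), 200 background genes,
        two planted ME and two planted co pairs."""
        return cls(
            cancer_types=(
                CancerTypeSpec("CT1", 400),
                CancerTypeSpec("CT2", 300),
                CancerTypeSpec("CT3", 200),
                CancerTypeSpec("CT4", 100),
            ),
            n_background_genes=200,
            hypermutator_fraction=0.02,
            planted=(
                PlantedInteraction("ME1_A", "ME1_B", "mutual_exclusion",
                                   1.0, 0.25, 0.25),
                PlantedInteraction("ME2_A", "ME2_B", "mutual_exclusion",
                                   0.8, 0.15, 0.15),
                PlantedInteraction("CO1_A", "CO1_B", "co_occurrence",
                                   4.0, 0.15, 0.15),
                PlantedInteraction("CO2_A", "CO2_B", "co_occurrence",
                                   3.0, 0.2, 0.2),
            ),
        )

    @classmethod
    def single_type(cls, n_samples: int = 300, n_background_genes: int = 196,
                    planted: tuple[PlantedInteraction, ...] = (),
                    **kwargs) -> "CohortSpec":
        return cls(
            cancer_types=(CancerTypeSpec("CT1", n_samples),),
            n_background_genes=n_background_genes, planted=planted, **kwargs
        )


@dataclass
class TruthTable:
    """What was planted and realized; the key for recovery scoring."""

    planted: pd.DataFrame  # pair, kind, strength, mechanism, realized co
    subtype_of: pd.Series  # sample -> subtype label ("none" if no subtypes)
    hypermutators: set[str]
    load_multiplier: pd.Series
    realized_margins: pd.Series
    realized_loads: pd.Series
    dropped_samples: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)
    private_genes: dict[str, list[str]] = field(default_factory=dict)
    seed: int | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        self.planted.to_csv(outdir / "truth_planted.tsv", sep="\t",
                            index=False)
        meta = pd.DataFrame({
            "sample_id": self.subtype_of.index,
            "subtype": self.subtype_of.values,
            "load_multiplier": self.load_multiplier.reindex(
                self.subtype_of.index).values,
            "hypermutator": [s in self.hypermutators
                             for s in self.subtype_of.index],
        })
        meta.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)


@dataclass
class SyntheticCohort:
    matrix: MutationMatrix
    truth: TruthTable
    variants: pd.DataFrame
    spec: CohortSpec
    seed: int | None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.write_tsv(outdir / "matrix.tsv",
                              outdir / "sample_types.tsv")
        with open(outdir / "variants.tsv", "w") as fh:
            fh.write(f"# gimap synthetic cohort, seed={self.seed}\n")
            self.variants.to_csv(fh, sep="\t", index=False)
        self.truth.write(outdir)


# ---------------------------------------------------------------------------
# planting operations
# ---------------------------------------------------------------------------

def plant_me_pair(X: np.ndarray, a: int, b: int, exclusivity: float,
                  rng: np.random.Generator,
                  sample_mask: np.ndarray | None = None) -> np.ndarray:
    """Impose mutual exclusivity on rows ``a`` and ``b`` of ``X`` in place.

    Each double-mutant sample has, with probability ``exclusivity``, one
    of the two mutations (chosen uniformly) cleared.  Margins shrink
    accordingly and are reported, not re-balanced.
    """
    doubles = X[a] & X[b]
    if sample_mask is not None:
        doubles = doubles & sample_mask
    idx = np.flatnonzero(doubles)
    clear = idx[rng.random(idx.size) < exclusivity]
    which = rng.random(clear.size) < 0.5
    X[a, clear[which]] = False
    X[b, clear[~which]] = False
    return X


def plant_co_pair(X: np.ndarray, a: int, b: int, lift: float,
                  pa: float, pb: float, rng: np.random.Generator,
                  sample_mask: np.ndarray | None = None) -> np.ndarray:
    """Redraw rows ``a`` and ``b`` jointly with elevated joint mass.

    Samples the pair per sample from the 2x2 table with margins
    ``(pa, pb)`` and joint probability ``lift * pa * pb`` (copula-style),
    so marginal frequencies are preserved in expectation while the
    co-occurrence probability is multiplied by ``lift``.
    """
    p11 = lift * pa * pb
    if p11 > min(pa, pb) or p11 > 1:
        raise ConfigError(
            f"infeasible lift {lift}: maximal feasible lift is "
            f"{min(pa, pb) / (pa * pb):.3f} for margins ({pa}, {pb})"
        )
    n = X.shape[1]
    mask = np.ones(n, bool) if sample_mask is None else sample_mask
    u = rng.random(n)
    both = u < p11
    a_only = (u >= p11) & (u < pa)
    b_only = (u >= pa) & (u < pa + pb - p11)
    X[a, mask] = (both | a_only)[mask]
    X[b, mask] = (both | b_only)[mask]
    return X


def add_subtype_structure(type_spec: CancerTypeSpec,
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray, dict[str, list[str]]]:
    """Assign samples of one cancer type to subtypes.

    Returns (subtype label per sample, load multiplier per sample,
    subtype -> private gene names).  Private genes are generated here by
    name; the caller gives them non-zero probability only within their
    subtype.  With no subtypes this reduces to a single implicit subtype
    with multiplier 1.
    """
    n = type_spec.n_samples
    if not type_spec.subtypes:
        return (np.array(["none"] * n, dtype=object),
                np.ones(n), {})
    names = [s.name for s in type_spec.subtypes]
    probs = [s.fraction for s in type_spec.subtypes]
    labels = rng.choice(names, size=n, p=probs)
    mult = np.ones(n)
    private: dict[str, list[str]] = {}
    for s in type_spec.subtypes:
        mult[labels == s.name] = s.load_multiplier
        private[s.name] = [
            f"PV_{type_spec.name}_{s.name}_{i:03d}"
            for i in range(s.n_private_genes)
        ]
    return labels.astype(object), mult, private


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _power_law(lo: float, hi: float, alpha: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    """Truncated power-law sample (density ~ f^-alpha on [lo, hi]).

    Most genes end up rare with a tail of frequent drivers, which matches
    the low mutation burden of pediatric tumors (a handful of mutated
    genes per sample, a few recurrent drivers); alpha = 1 is log-uniform.
    """
    u = rng.random(size)
    if abs(alpha - 1.0) < 1e-12:
        return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    b = 1.0 - alpha
    return (lo**b + u * (hi**b - lo**b)) ** (1.0 / b)

def generate_cohort(spec: CohortSpec,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort: matrix + truth table + MAF-like variant table.

    Deterministic given (spec, seed).  The emitted matrix excludes
    zero-mutation samples and singleton genes (recorded in the truth
    table); the variant file is complete, so running it through
    :mod:`gimap.io` reproduces the matrix.
    """
    rng = np.random.default_rng(seed)
    n_total = spec.n_samples

    # -- samples: names, types, subtypes, load multipliers -----------------
    samples, types, subtypes = [], [], []
    mult = []
    private_by_subtype: dict[str, list[str]] = {}
    for ct in spec.cancer_types:
        labels, sub_mult, private = add_subtype_structure(ct, rng)
        for k, v in private.items():
            private_by_subtype[f"{ct.name}/{k}"] = v
        base_mult = rng.lognormal(
            mean=-spec.load_sigma**2 / 2, sigma=spec.load_sigma,
            size=ct.n_samples,
        )
        samples.extend(f"{ct.name}_s{i:04d}" for i in range(ct.n_samples))
        types.extend([ct.name] * ct.n_samples)
        subtypes.extend(labels.tolist())
        mult.append(base_mult * sub_mult)
    mult = np.concatenate(mult)
    samples = np.asarray(samples, dtype=object)
    types = np.asarray(types, dtype=object)
    subtypes = np.asarray(subtypes, dtype=object)

    # hypermutation is a regime of its own (e.g. repair deficiency), not a
    # scaling of the sample's baseline: floor the baseline multiplier at 1
    # so flagged samples reliably exceed the variant-count threshold
    hyper = rng.random(n_total) < spec.hypermutator_fraction
    mult = np.where(hyper,
                    spec.hypermutator_multiplier * np.maximum(mult, 1.0),
                    mult)

    # -- genes and probabilities -------------------------------------------
    bg_genes = [f"BG{i:04d}" for i in range(spec.n_background_genes)]
    lo = spec.freq_low if spec.freq_low is not None else 1.0 / n_total
    freqs = _power_law(lo, spec.freq_high, spec.freq_alpha,
                       spec.n_background_genes, rng)

    genes: list[str] = list(bg_genes)
    prob = freqs[:, None] * mult[None, :]

    # subtype-private genes: mutated only within their subtype
    for key, names in private_by_subtype.items():
        ct_name, sub_name = key.split("/", 1)
        sub_spec = next(
            s for ct in spec.cancer_types if ct.name == ct_name
            for s in ct.subtypes if s.name == sub_name
        )
        in_sub = (types == ct_name) & (subtypes == sub_name)
        for name in names:
            genes.append(name)
            row = np.where(in_sub,
                           sub_spec.private_gene_freq * mult, 0.0)
            prob = np.vstack([prob, row[None, :]])

    # planted genes: fixed probabilities, exempt from load multipliers so
    # margins and effect sizes are exactly as requested
    planted_idx: dict[str, int] = {}
    for p in spec.planted:
        for g, f in ((p.gene_a, p.freq_a), (p.gene_b, p.freq_b)):
            if g in planted_idx:
                continue
            if p.mechanism == "subtype":
                continue  # handled below as private genes
            planted_idx[g] = len(genes)
            genes.append(g)
            prob = np.vstack([prob, np.full((1, n_total), f)])

    # subtype-mechanism ME pairs: genes private to two different subtypes
    for p in spec.planted:
        if p.mechanism != "subtype":
            continue
        ct = next(
            c for c in spec.cancer_types
            if p.cancer_type in (None, c.name) and len(c.subtypes) >= 2
        )
        s1, s2 = ct.subtypes[0], ct.subtypes[1]
        for g, f, sub in ((p.gene_a, p.freq_a, s1), (p.gene_b, p.freq_b, s2)):
            planted_idx[g] = len(genes)
            genes.append(g)
            in_sub = (types == ct.name) & (subtypes == sub.name)
            prob = np.vstack([prob, np.where(in_sub, f, 0.0)[None, :]])

    prob = np.minimum(prob, 1.0)
    X = rng.random(prob.shape) < prob

    # -- impose planted interactions: co pairs, then ME pairs --------------
    gpos = {g: i for i, g in enumerate(genes)}
    type_mask = {
        ct.name: types == ct.name for ct in spec.cancer_types
    }
    for p in spec.planted:
        mask = None if p.cancer_type is None else type_mask[p.cancer_type]
        if p.kind == "co_occurrence":
            plant_co_pair(X, gpos[p.gene_a], gpos[p.gene_b], p.strength,
                          p.freq_a, p.freq_b, rng, mask)
    for p in spec.planted:
        mask = None if p.cancer_type is None else type_mask[p.cancer_type]
        if p.kind == "mutual_exclusion" and p.mechanism == "direct":
            plant_me_pair(X, gpos[p.gene_a], gpos[p.gene_b], p.strength,
                          rng, mask)

    # -- variant-level table -----------------------------------------------
    keep_list = sorted(DIALECTS["SYNTHETIC"].keep)
    gi, si = np.nonzero(X)
    genes_arr = np.asarray(genes, dtype=object)
    rows = pd.DataFrame({
        "sample_id": samples[si],
        "gene": genes_arr[gi],
        "consequence": rng.choice(keep_list, size=gi.size),
        "cancer_type": types[si],
    })
    n_silent = rng.poisson(spec.silent_mean * mult)
    s_idx = np.repeat(np.arange(n_total), n_silent)
    silent = pd.DataFrame({
        "sample_id": samples[s_idx],
        "gene": rng.choice(genes_arr, size=s_idx.size),
        "consequence": "silent",
        "cancer_type": types[s_idx],
    })
    variants = (
        pd.concat([rows, silent], ignore_index=True)
        .sort_values(["sample_id", "gene"], kind="stable")
        .reset_index(drop=True)
    )

    # -- matrix cleanup (zero-load samples, singleton genes) ---------------
    keep_s = X.sum(axis=0) >= 1
    keep_g = X[:, keep_s].sum(axis=1) >= 2
    dropped_genes = genes_arr[~keep_g].tolist()
    # dropping singleton genes can orphan samples; drop those too so the
    # matrix honors the "every sample has a mutated gene" invariant
    keep_s[keep_s] = X[np.ix_(keep_g, keep_s)].sum(axis=0) >= 1
    dropped_samples = samples[~keep_s].tolist()
    matrix = MutationMatrix(
        genes_arr[keep_g], samples[keep_s],
        X[np.ix_(keep_g, keep_s)], types[keep_s],
    ).canonicalize()

    # -- truth -------------------------------------------------------------
    planted_rows = []
    for p in spec.planted:
        a, b = gpos[p.gene_a], gpos[p.gene_b]
        planted_rows.append({
            "gene_a": min(p.gene_a, p.gene_b),
            "gene_b": max(p.gene_a, p.gene_b),
            "kind": p.kind, "strength": p.strength,
            "mechanism": p.mechanism,
            "direction": ("me" if p.kind == "mutual_exclusion" else "co"),
            "realized_co": int((X[a] & X[b]).sum()),
            "realized_margin_a": int(X[a].sum()),
            "realized_margin_b": int(X[b].sum()),
        })
    truth = TruthTable(
        planted=pd.DataFrame(
            planted_rows,
            columns=["gene_a", "gene_b", "kind", "strength", "mechanism",
                     "direction", "realized_co", "realized_margin_a",
                     "realized_margin_b"],
        ),
        subtype_of=pd.Series(subtypes, index=samples),
        hypermutators=set(samples[hyper].tolist()),
        load_multiplier=pd.Series(mult, index=samples),
        realized_margins=pd.Series(X.sum(axis=1), index=genes_arr),
        realized_loads=pd.Series(X.sum(axis=0), index=samples),
        dropped_samples=dropped_samples,
        dropped_genes=dropped_genes,
        private_genes=private_by_subtype,
        seed=seed,
    )
    return SyntheticCohort(matrix=matrix, truth=truth, variants=variants,
                           spec=spec, seed=seed)
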