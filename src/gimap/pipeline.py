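"""End-to-end orchestration: variants -> matrix -> tests -> candidates.

The :func:`run_pipeline` entry point wires the stages together (parse,
hypermutator removal, functional filter, matrix construction, permutation
and/or WeSME tests in per-cancer-type and/or pan-cancer mode, empirical
FDR, selection, replicate-based high-confidence filtering, interaction-map
merging, MLA suspect flagging) and writes TSV outputs plus a run manifest
sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, mla, significance
from .errors import ConfigError, DataError
from .matrix import MutationMatrix
from .permutation import PermutationTest
from .wesme import run_replicates

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study's stated values."""

    variants: list[str] = field(default_factory=list)
    dialect: str = "SYNTHETIC"
    modes: tuple[str, ...] = ("per_type", "pan")
    tests: tuple[str, ...] = ("permutation", "wesme")
    # matrix construction
    min_mutated_samples: int = 2
    sample_blocklist: list[str] = field(default_factory=list)
    hypermutator_rate_per_mb: float = 10.0
    hypermutator_coverage: float = 0.95
    # permutation test
    n_permutations: int = 10_000
    n_pseudo: int = 100
    # wesme test
    wesme_ladder: tuple[int, ...] = (100, 1_000, 10_000)
    wesme_max_resamples: int = 10_000
    wesme_n_null_perms: int = 300
    rate_bin_threshold: float = 0.02
    min_me_pretest: int = 3
    min_co_pretest: int = 1
    n_runs: int = 10
    min_support: int = 9
    # selection
    q_max: float = 0.2
    p_max: float = 0.1
    min_co: int = 3
    # plumbing
    seed: int = 0
    output_dir: str = "gimap_out"
    dataset_label: str = "cohort"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("modes", "tests", "wesme_ladder"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not self.variants:
            raise ConfigError("no variant files configured")
        bad = set(self.modes) - {"per_type", "pan"}
        if bad:
            raise ConfigError(f"unknown modes {sorted(bad)}")
        bad = set(self.tests) - {"permutation", "wesme"}
        if bad:
            raise ConfigError(f"unknown tests {sorted(bad)}")
        if self.min_support > self.n_runs:
            raise ConfigError("min_support cannot exceed n_runs")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_matrices(config: RunConfig
                   ) -> tuple[dict[str, MutationMatrix], io.FilterReport,
                              set[str]]:
    """Stages parse -> hypermutator removal -> filter -> per-type matrices."""
    report = io.FilterReport()
    records = []
    for path in config.variants:
        recs, _ = io.parse_variants(path, config.dialect, report=report)
        records.extend(recs)
    if not records:
        raise DataError("no variant records parsed")

    threshold = io.hypermutator_threshold(
        rate_per_mb=config.hypermutator_rate_per_mb,
        coverage_fraction=config.hypermutator_coverage,
    )
    hypers = io.flag_hypermutators(records, threshold)
    report.add("hypermutator", "sample", len(hypers),
               f"> {threshold} coding mutations")

    records = io.resolve_all_overlaps(records)
    kept, _ = io.filter_functional(records, report=report)
    exclude = hypers | set(config.sample_blocklist)

    by_type: dict[str, list] = {}
    for rec in kept:
        by_type.setdefault(rec.cancer_type, []).append(rec)
    matrices: dict[str, MutationMatrix] = {}
    for ct in sorted(by_type):
        try:
            m, _ = io.build_matrix(
                by_type[ct], config.min_mutated_samples,
                exclude_samples=exclude, report=report,
            )
        except DataError:
            continue  # cancer type with nothing testable
        if m.n_genes >= 2:
            matrices[ct] = m
    if not matrices:
        raise DataError("no cancer type yields a testable matrix")
    return matrices, report, hypers


def run_pipeline(config: RunConfig) -> Path:
    """Run all configured stages; returns the output directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "gimap_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": [],
        "outputs": {},
    }
    stage = "setup"
    try:
        stage = "build_matrices"
        matrices, report, hypers = build_matrices(config)
        manifest["stages"].append(stage)
        manifest["hypermutators"] = sorted(hypers)
        report.write_tsv(outdir / "filter_report.tsv")

        contexts: list[tuple[str, str, MutationMatrix]] = []
        if "per_type" in config.modes:
            contexts += [("per_type", ct, m) for ct, m in matrices.items()]
        if "pan" in config.modes and len(matrices) > 1:
            from .wesme import pool_matrices

            contexts.append(("pan", "PAN", pool_matrices(matrices)))

        wes_kwargs = dict(
            ladder=config.wesme_ladder,
            max_resamples=config.wesme_max_resamples,
            n_null_perms=config.wesme_n_null_perms,
            rate_bin_threshold=config.rate_bin_threshold,
            min_me_pretest=config.min_me_pretest,
            min_co_pretest=config.min_co_pretest,
        )
        sel_kwargs = dict(q_max=config.q_max, p_max=config.p_max,
                          min_co=config.min_co)

        all_candidates = []
        all_outcomes = []
        for mode, label, m in contexts:
            m.write_tsv(outdir / f"matrix_{label}.tsv",
                        outdir / f"samples_{label}.tsv")
            if "permutation" in config.tests:
                stage = f"permutation[{label}]"
                res = PermutationTest(
                    m, n_permutations=config.n_permutations,
                    block_by_cancer_type=(mode == "pan"),
                    n_pseudo=config.n_pseudo,
                ).fit(seed=int(rng.integers(0, 2**31 - 1)))
                res.write_tsv(outdir / f"outcomes_permutation_{label}.tsv")
                all_outcomes.append(res.outcomes)
                sel = res.select(**sel_kwargs).assign(support=1, n_runs=1)
                all_candidates.append(sel)
                manifest["stages"].append(stage)
            if "wesme" in config.tests:
                stage = f"wesme[{label}]"
                reps = run_replicates(
                    m, n_runs=config.n_runs,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    test_kwargs=dict(
                        wes_kwargs, pretest=(mode == "pan")), **sel_kwargs,
                )
                for r in reps.runs:
                    all_outcomes.append(r.outcomes)
                hc = reps.high_confidence(
                    min_support=config.min_support, **sel_kwargs)
                all_candidates.append(hc)
                reps.runs[-1].write_tsv(
                    outdir / f"outcomes_wesme_{label}.tsv")
                reps.support.to_csv(
                    outdir / f"support_wesme_{label}.tsv",
                    sep="\t", index=False)
                manifest["stages"].append(stage)

        stage = "merge"
        candidates = (
            pd.concat(all_candidates, ignore_index=True)
            if all_candidates else pd.DataFrame()
        )
        candidates["dataset"] = config.dataset_label
        imap, summary = significance.merge_interaction_map(candidates)
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        imap.to_csv(outdir / "interaction_map.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "mla"
        suspect_frames = []
        score_frames = []
        for mode, label, m in contexts:
            ctx_cand = imap[imap["cancer_type"] ==
                            ("PAN" if mode == "pan" else label)]
            if ctx_cand.empty:
                continue
            genes = sorted(set(ctx_cand["gene_a"]) | set(ctx_cand["gene_b"]))
            genes = [g for g in genes if g in set(m.genes)]
            scores = mla.mla_scores(m, genes)
            sf = mla.scores_frame(scores).assign(cancer_type=label)
            score_frames.append(sf)
            flags = mla.flag_suspects(ctx_cand, scores)
            if flags:
                suspect_frames.append(
                    mla.suspects_frame(flags).assign(cancer_type=label))
        (pd.concat(score_frames, ignore_index=True) if score_frames
         else pd.DataFrame(columns=["gene", "coefficient", "se", "mla",
                                    "status", "cancer_type"])
         ).to_csv(outdir / "mla_scores.tsv", sep="\t", index=False)
        (pd.concat(suspect_frames, ignore_index=True) if suspect_frames
         else pd.DataFrame(columns=["gene_a", "gene_b", "direction", "rule",
                                    "mla_a", "mla_b", "cancer_type"])
         ).to_csv(outdir / "suspects.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    for p in sorted(outdir.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
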