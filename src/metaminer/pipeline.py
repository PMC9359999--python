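"""End-to-end orchestration: ORFs -> search -> validate -> tree -> quantify.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))``, so every stage is
independently reproducible and two runs with identical inputs, config and
seed produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import ScoringScheme
from .expression import (
    ExpressionMatrix,
    average_replicates,
    heatmap_matrix,
    load_expression,
    top_abundant,
)
from .homology import Hit, search_hits, write_hits
from .knowledgebase import EnzymeSpec, load_knowledgebase
from .orfs import ORFRecord, find_orfs_fasta, write_protein_fasta
from .phylogeny import (
    Msa,
    PhylogenyError,
    bootstrap_support,
    build_msa,
    cocluster_test,
)
from .validation import (
    NOT_RUN,
    ValidationVerdict,
    format_fir_report,
    validate_hit,
    with_coclustering,
)

logger = logging.getLogger(__name__)

# spawn_key stage ids for seed derivation
STAGE_TREE = 1


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run."""

    kb_path: str
    transcripts_path: str
    outdir: str
    samples_manifest: str | None = None
    counts_dir: str | None = None
    min_orf_codons: int = 100
    min_identity: float | None = None  # override KB per-enzyme thresholds
    min_coverage: float | None = None
    bootstrap_replicates: int = 100
    min_support: float = 0.0
    distance_model: str = "poisson"
    pseudocount: float = 1.0
    top_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("min_support", self.min_support, 0.0, 100.0),
            ("pseudocount", self.pseudocount, 1e-12, float("inf")),
        ):
            if not (lo <= value <= hi):
                raise PipelineError(f"{name}={value} out of range [{lo}, {hi}]")
        for name, value in (("min_identity", self.min_identity),
                            ("min_coverage", self.min_coverage)):
            if value is not None and not (0.0 <= value <= 1.0):
                raise PipelineError(f"{name}={value} out of [0, 1]")
        if self.bootstrap_replicates < 1:
            raise PipelineError("bootstrap_replicates must be >= 1")
        if self.min_orf_codons < 1:
            raise PipelineError("min_orf_codons must be >= 1")


def stage_seed(seed: int, stage: int, *extra: int) -> int:
    """Derive a per-stage 31-bit seed from the global seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(stage, *extra))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class PipelineResult:
    summary: dict
    outdir: Path
    verdicts: list[ValidationVerdict] = field(default_factory=list)
    hits: list[Hit] = field(default_factory=list)


def _apply_overrides(specs: list[EnzymeSpec], config: RunConfig) -> list[EnzymeSpec]:
    if config.min_identity is None and config.min_coverage is None:
        return specs
    out = []
    for spec in specs:
        out.append(
            dataclasses.replace(
                spec,
                min_identity=config.min_identity
                if config.min_identity is not None
                else spec.min_identity,
                min_coverage=config.min_coverage
                if config.min_coverage is not None
                else spec.min_coverage,
            )
        )
    return out


def run_pipeline(config: RunConfig, scoring: ScoringScheme | None = None) -> PipelineResult:
    """Run every stage and write the report bundle under ``config.outdir``."""
    scoring = scoring or ScoringScheme()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("metaminer")
    root.addHandler(log_handler)
    try:
        return _run(config, scoring, outdir)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(config: RunConfig, scoring: ScoringScheme, outdir: Path) -> PipelineResult:
    specs = _apply_overrides(load_knowledgebase(config.kb_path), config)
    summary: dict = {
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("outdir",)
        },
        "enzymes": {},
    }
    if not specs:
        logger.warning("knowledge base is empty; nothing to search for")
        summary["n_transcripts"] = 0
        summary["n_orfs"] = 0
        _write_summary(summary, outdir)
        return PipelineResult(summary=summary, outdir=outdir)

    logger.info("stage orfs: scanning %s", config.transcripts_path)
    orf_records = find_orfs_fasta(config.transcripts_path, config.min_orf_codons)
    write_protein_fasta(orf_records, outdir / "orfs.faa")
    proteome = {o.orf_id: o.protein for o in orf_records}
    orf_transcript = {o.orf_id: o.transcript_id for o in orf_records}
    n_transcripts = len({o.transcript_id for o in orf_records})
    logger.info("stage orfs: %d ORFs from %d transcripts",
                len(orf_records), n_transcripts)
    if not orf_records:
        raise PipelineError("stage orfs: no ORFs predicted from the input FASTA")

    logger.info("stage search: %d enzymes x %d ORFs", len(specs), len(proteome))
    hits = search_hits(specs, orf_records, scoring)
    write_hits(hits, outdir / "hits.tsv")

    spec_by_id = {s.enzyme_id: s for s in specs}
    verdicts: dict[tuple[str, str], ValidationVerdict] = {}
    for hit in hits:
        verdicts[(hit.enzyme_id, hit.orf_id)] = validate_hit(
            hit, spec_by_id[hit.enzyme_id], proteome, scoring
        )

    trees_dir = outdir / "trees"
    trees_dir.mkdir(exist_ok=True)
    reports_dir = outdir / "reports"
    reports_dir.mkdir(exist_ok=True)
    for e_idx, spec in enumerate(specs):
        enzyme_verdicts = [
            v for (eid, _), v in verdicts.items() if eid == spec.enzyme_id
        ]
        survivors = [
            v for v in enzyme_verdicts if v.firs_pass and v.motifs_pass
        ]
        taxa = list(spec.references) + [
            (v.orf_id, proteome[v.orf_id]) for v in sorted(survivors, key=lambda v: v.orf_id)
        ]
        if survivors and len(taxa) >= 3:
            logger.info(
                "stage tree: %s with %d candidates", spec.enzyme_id, len(survivors)
            )
            msa = build_msa(taxa, scoring)
            msa.write_fasta(trees_dir / f"{spec.enzyme_id}.aln.fasta")
            tree = bootstrap_support(
                msa,
                model=config.distance_model,
                replicates=config.bootstrap_replicates,
                seed=stage_seed(config.seed, STAGE_TREE, e_idx),
            )
            (trees_dir / f"{spec.enzyme_id}.nwk").write_text(tree.to_newick())
            ref_names = {name for name, _ in spec.references}
            # The joint tree above is the display artifact; each candidate is
            # *decided* on the {references + candidate} subtree, where the
            # anchor-vs-homolog quartet edge is positive and NJ is consistent.
            # Co-planted candidates are all local derivatives of the anchor,
            # so jointly they form a polytomy whose arbitrary resolution can
            # interpose one candidate between the anchor and the references.
            row_by_name = dict(zip(msa.names, msa.rows))
            n_refs = len(spec.references)
            for c_idx, v in enumerate(sorted(survivors, key=lambda v: v.orf_id)):
                sub_names = tuple(n for n, _ in spec.references) + (v.orf_id,)
                sub_msa = Msa(
                    names=sub_names,
                    rows=tuple(row_by_name[n] for n in sub_names),
                )
                if n_refs + 1 < 3:
                    continue
                cand_tree = bootstrap_support(
                    sub_msa,
                    model=config.distance_model,
                    replicates=config.bootstrap_replicates,
                    seed=stage_seed(config.seed, STAGE_TREE, e_idx, c_idx),
                )
                ok = cocluster_test(
                    cand_tree,
                    candidate=v.orf_id,
                    anchor=spec.anchor,
                    min_support=config.min_support,
                    references=ref_names,
                )
                verdicts[(spec.enzyme_id, v.orf_id)] = with_coclustering(v, ok)
        elif survivors:
            logger.warning(
                "stage tree: %s skipped (only %d taxa)", spec.enzyme_id, len(taxa)
            )

    final = list(verdicts.values())
    _write_verdicts(final, outdir / "verdicts.tsv")
    for v in final:
        report = format_fir_report(
            v, spec_by_id[v.enzyme_id], proteome[v.orf_id], scoring
        )
        (reports_dir / f"{v.enzyme_id}__{v.orf_id}.txt").write_text(report)

    mean_tpm = None
    if config.samples_manifest:
        logger.info("stage quantify: %s", config.samples_manifest)
        matrix = load_expression(config.samples_manifest, config.counts_dir)
        matrix.tpm.to_csv(outdir / "tpm.tsv", sep="\t", float_format="%.4f")
        mean_tpm = average_replicates(matrix)
        mean_tpm.to_csv(outdir / "mean_tpm.tsv", sep="\t", float_format="%.4f")
        top_union: list[str] = []
        for tissue in mean_tpm.columns:
            top = top_abundant(mean_tpm, config.top_n, tissue)
            pd.Series(top, name="transcript_id").to_csv(
                outdir / f"top{config.top_n}_{tissue}.tsv", sep="\t", index=False
            )
            top_union.extend(t for t in top if t not in top_union)
        candidate_tids = sorted(
            {
                orf_transcript[v.orf_id]
                for v in final
                if v.final_call == "true_hit" and orf_transcript[v.orf_id] in mean_tpm.index
            }
        )
        heat_ids = top_union + [t for t in candidate_tids if t not in top_union]
        heatmap_matrix(heat_ids, mean_tpm, config.pseudocount).to_csv(
            outdir / "heatmap_log2tpm.tsv", sep="\t", float_format="%.4f"
        )

    for spec in specs:
        enzyme_verdicts = sorted(
            (v for v in final if v.enzyme_id == spec.enzyme_id),
            key=lambda v: v.orf_id,
        )
        validated = [v for v in enzyme_verdicts if v.firs_pass and v.motifs_pass]
        coclustered = [
            v for v in validated if v.coclustering is not False
        ]
        true_hits = [v for v in enzyme_verdicts if v.final_call == "true_hit"]
        candidates = []
        for v in enzyme_verdicts:
            tid = orf_transcript[v.orf_id]
            entry = {
                "orf_id": v.orf_id,
                "transcript_id": tid,
                "fir_pass": v.firs_pass,
                "motif_pass": v.motifs_pass,
                "coclustering": v.coclustering
                if isinstance(v.coclustering, bool)
                else NOT_RUN,
                "final_call": v.final_call,
                "failed_rule": v.failed_rule,
            }
            if mean_tpm is not None and tid in mean_tpm.index:
                entry["mean_tpm"] = {
                    tissue: round(float(mean_tpm.loc[tid, tissue]), 4)
                    for tissue in mean_tpm.columns
                }
            candidates.append(entry)
        summary["enzymes"][spec.enzyme_id] = {
            "n_hits": len(enzyme_verdicts),
            "n_validated": len(validated),
            "n_coclustered": len(coclustered),
            "n_true_hits": len(true_hits),
            "true_hits": sorted(v.orf_id for v in true_hits),
            "candidates": candidates,
        }
    summary["n_transcripts"] = n_transcripts
    summary["n_orfs"] = len(orf_records)
    _write_summary(summary, outdir)
    return PipelineResult(
        summary=summary, outdir=outdir, verdicts=final, hits=hits
    )


def _write_verdicts(verdicts: list[ValidationVerdict], path: Path) -> None:
    rows = []
    for v in sorted(verdicts, key=lambda v: (v.enzyme_id, v.orf_id)):
        rows.append(
            (
                v.enzyme_id,
                v.orf_id,
                v.firs_pass,
                v.motifs_pass,
                v.coclustering if isinstance(v.coclustering, bool) else NOT_RUN,
                v.final_call,
                v.failed_rule or "",
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "enzyme_id", "orf_id", "fir_pass", "motif_pass",
            "coclustering", "final_call", "failed_rule",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_summary(summary: dict, outdir: Path) -> None:
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
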