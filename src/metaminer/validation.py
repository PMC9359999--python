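"""Candidate validation by functionally important residues and motifs.

A homology hit is only trusted when the residues that make the enzyme work
are actually there: each FIR position published on the curated reference is
transferred onto the candidate through one optimal global alignment, and the
residue found in the corresponding column must belong to the allowed set. A
FIR that lands on a gap is a hard fail — presence of the exact residue is the
criterion, with no positional tolerance. Required degenerate motifs must
additionally occur at least once anywhere in the candidate.

Co-clustering with the curated start point (see :mod:`metaminer.phylogeny`)
is the third, optional gate; its outcome is folded into the verdict by the
pipeline after tree construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .align import ScoringScheme, global_align
from .homology import Hit
from .knowledgebase import EnzymeSpec, FIRSpec, MotifPattern

NOT_RUN = "not_run"


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class FIRCheckResult:
    label: str
    ref_position: int
    ref_residue: str
    mapped_position: int | None  # 1-based on the candidate; None = gap
    candidate_residue: str  # "-" when the FIR column is a gap
    passed: bool


@dataclass(frozen=True)
class MotifCheckResult:
    name: str
    found: bool
    positions: tuple[int, ...]  # 1-based match starts, ascending


@dataclass(frozen=True)
class ValidationVerdict:
    """Aggregate FIR / motif / co-clustering outcome for one candidate."""

    orf_id: str
    enzyme_id: str
    fir_results: tuple[FIRCheckResult, ...]
    motif_results: tuple[MotifCheckResult, ...]
    coclustering: bool | str = NOT_RUN
    requires_coclustering: bool = False

    @property
    def firs_pass(self) -> bool:
        return all(r.passed for r in self.fir_results)

    @property
    def motifs_pass(self) -> bool:
        return all(r.found for r in self.motif_results)

    @property
    def failed_rule(self) -> str | None:
        for r in self.fir_results:
            if not r.passed:
                return f"FIR:{r.label}@{r.ref_position}"
        for m in self.motif_results:
            if not m.found:
                return f"motif:{m.name}"
        if self.coclustering is False:
            return "co-clustering"
        if self.coclustering == NOT_RUN and self.requires_coclustering:
            return "co-clustering required but not run"
        return None

    @property
    def final_call(self) -> str:
        return "true_hit" if self.failed_rule is None else "rejected"


def scan_motif(sequence: str, motif: MotifPattern) -> list[int]:
    """All (possibly overlapping) 1-based match starts of a motif.

    Implemented as a compiled regular expression inside a lookahead so that
    overlapping windows are reported; wildcard positions match any residue
    (including X).
    """
    seq = str(sequence).upper()
    parts = []
    for pos in motif.positions:
        if pos is None:
            parts.append(".")
        elif len(pos) == 1:
            parts.append(re.escape(next(iter(pos))))
        else:
            parts.append("[" + "".join(sorted(pos)) + "]")
    pattern = re.compile("(?=(" + "".join(parts) + "))")
    return [m.start() + 1 for m in pattern.finditer(seq)]


def map_fir_positions(
    reference: str,
    candidate: str,
    firs: Sequence[FIRSpec],
    scoring: ScoringScheme | None = None,
) -> list[FIRCheckResult]:
    """Transfer reference FIR positions onto a candidate via global alignment."""
    scoring = scoring or ScoringScheme()
    for fir in firs:
        if fir.ref_position > len(reference):
            raise ValidationError(
                f"FIR {fir.label!r} position {fir.ref_position} beyond reference "
                f"length {len(reference)}"
            )
    aln = global_align(reference, candidate, scoring)
    # column index of each reference position, and candidate residue numbering
    ref_col: dict[int, int] = {}
    rpos = 0
    for col, ch in enumerate(aln.aligned_a):
        if ch != "-":
            rpos += 1
            ref_col[rpos] = col
    cand_pos_at_col: list[int | None] = []
    cpos = 0
    for ch in aln.aligned_b:
        if ch != "-":
            cpos += 1
            cand_pos_at_col.append(cpos)
        else:
            cand_pos_at_col.append(None)
    results = []
    for fir in firs:
        col = ref_col[fir.ref_position]
        cand_residue = aln.aligned_b[col]
        mapped = cand_pos_at_col[col]
        passed = mapped is not None and cand_residue in fir.allowed_residues
        results.append(
            FIRCheckResult(
                label=fir.label,
                ref_position=fir.ref_position,
                ref_residue=reference[fir.ref_position - 1],
                mapped_position=mapped,
                candidate_residue=cand_residue if mapped is not None else "-",
                passed=passed,
            )
        )
    return results


def validate_hit(
    hit: Hit,
    spec: EnzymeSpec,
    proteome: Mapping[str, str],
    scoring: ScoringScheme | None = None,
) -> ValidationVerdict:
    """FIR + motif validation of one hit (co-clustering left ``not_run``).

    A spec with neither FIRs nor motifs passes this stage vacuously but is
    flagged as requiring co-clustering, which then becomes the only gate.
    """
    scoring = scoring or ScoringScheme()
    if hit.orf_id not in proteome:
        raise ValidationError(f"hit references unknown ORF {hit.orf_id!r}")
    if hit.enzyme_id != spec.enzyme_id:
        raise ValidationError(
            f"hit enzyme {hit.enzyme_id!r} does not match spec {spec.enzyme_id!r}"
        )
    candidate = proteome[hit.orf_id]
    fir_results: list[FIRCheckResult] = []
    # align once per distinct FIR reference (normally just the anchor)
    by_ref: dict[str, list[FIRSpec]] = {}
    for fir in spec.firs:
        by_ref.setdefault(fir.reference or spec.anchor, []).append(fir)
    for ref_name in sorted(by_ref):
        fir_results.extend(
            map_fir_positions(
                dict(spec.references)[ref_name], candidate, by_ref[ref_name], scoring
            )
        )
    motif_results = []
    for motif in spec.motifs:
        positions = scan_motif(candidate, motif)
        motif_results.append(
            MotifCheckResult(name=motif.name, found=bool(positions),
                             positions=tuple(positions))
        )
    return ValidationVerdict(
        orf_id=hit.orf_id,
        enzyme_id=spec.enzyme_id,
        fir_results=tuple(fir_results),
        motif_results=tuple(motif_results),
        coclustering=NOT_RUN,
        requires_coclustering=not spec.firs and not spec.motifs,
    )


def with_coclustering(verdict: ValidationVerdict, cocluster: bool) -> ValidationVerdict:
    """Fold a co-clustering outcome into a verdict."""
    return replace(verdict, coclustering=bool(cocluster))


def format_fir_report(
    verdict: ValidationVerdict,
    spec: EnzymeSpec,
    candidate: str,
    scoring: ScoringScheme | None = None,
    context: int = 5,
) -> str:
    """Human-readable report block with an alignment excerpt around each FIR."""
    scoring = scoring or ScoringScheme()
    lines = [
        f"candidate {verdict.orf_id} vs enzyme {verdict.enzyme_id} "
        f"(final call: {verdict.final_call})"
    ]
    by_ref: dict[str, list[FIRSpec]] = {}
    for fir in spec.firs:
        by_ref.setdefault(fir.reference or spec.anchor, []).append(fir)
    for ref_name in sorted(by_ref):
        ref_seq = dict(spec.references)[ref_name]
        aln = global_align(ref_seq, candidate, scoring)
        ref_col = {}
        rpos = 0
        for col, ch in enumerate(aln.aligned_a):
            if ch != "-":
                rpos += 1
                ref_col[rpos] = col
        for fir in by_ref[ref_name]:
            col = ref_col[fir.ref_position]
            lo, hi = max(0, col - context), min(aln.n_columns, col + context + 1)
            res = next(
                r for r in verdict.fir_results
                if r.label == fir.label and r.ref_position == fir.ref_position
            )
            status = "PASS" if res.passed else "FAIL"
            lines.append(
                f"  FIR {fir.label} {ref_seq[fir.ref_position - 1]}{fir.ref_position} "
                f"[{status}] allowed={{{','.join(sorted(fir.allowed_residues))}}}"
            )
            marker = " " * (2 + 4 + col - lo) + "*"
            lines.append(f"  ref {aln.aligned_a[lo:hi]}")
            lines.append(f"  cnd {aln.aligned_b[lo:hi]}")
            lines.append(marker)
    for m in verdict.motif_results:
        status = "found" if m.found else "MISSING"
        where = f" at {list(m.positions)}" if m.positions else ""
        lines.append(f"  motif {m.name}: {status}{where}")
    lines.append(f"  co-clustering: {verdict.coclustering}")
    return "\n".join(lines) + "\n"
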