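"""Homology search of predicted ORFs against curated enzyme references.

Every (enzyme, reference, ORF) pair is aligned locally; an ORF becomes a
:class:`Hit` for an enzyme when its best-scoring reference alignment reaches
that enzyme's identity and reference-coverage thresholds (defaults 30%
identity / 70% coverage, the criterion applied uniformly here). Exhaustive
pairwise alignment replaces heuristic seeding — transcriptome-scale searches
against a handful of curated start points do not need BLAST's index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignmentResult, ScoringScheme, local_align
from .knowledgebase import EnzymeSpec
from .orfs import ORFRecord


class HomologySearchError(ValueError):
    pass


@dataclass(frozen=True)
class Hit:
    """A candidate ORF matched to an enzyme's best reference."""

    enzyme_id: str
    orf_id: str
    reference: str
    score: float
    identity: float
    query_coverage: float  # fraction of the reference covered
    q_start: int
    q_end: int
    t_start: int
    t_end: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise HomologySearchError(
                f"{self.enzyme_id}/{self.orf_id}: identity/coverage out of [0,1]"
            )
        if self.score < 0:
            raise HomologySearchError(f"{self.enzyme_id}/{self.orf_id}: negative score")


def _hit_from_alignment(
    enzyme_id: str, orf_id: str, reference: str, aln: AlignmentResult
) -> Hit:
    return Hit(
        enzyme_id=enzyme_id,
        orf_id=orf_id,
        reference=reference,
        score=aln.score,
        identity=aln.identity,
        query_coverage=aln.query_coverage,
        q_start=aln.a_start,
        q_end=aln.a_end,
        t_start=aln.b_start,
        t_end=aln.b_end,
    )


def search_hits(
    specs: Sequence[EnzymeSpec],
    proteome: Sequence[ORFRecord] | Mapping[str, str],
    scoring: ScoringScheme | None = None,
) -> list[Hit]:
    """Search all ORFs against all enzyme references.

    For each (enzyme, ORF) pair only the best-scoring reference is retained,
    and a Hit is emitted iff identity >= min_identity and reference coverage
    >= min_coverage for that enzyme. Hits are sorted by descending score
    (ties: enzyme_id then orf_id), so output is deterministic.
    """
    scoring = scoring or ScoringScheme()
    if not specs:
        raise HomologySearchError("no enzyme specs given")
    if isinstance(proteome, Mapping):
        proteins = dict(proteome)
    else:
        proteins = {orf.orf_id: orf.protein for orf in proteome}
    if not proteins:
        raise HomologySearchError("empty proteome")
    hits: list[Hit] = []
    for spec in specs:
        if not spec.references:
            raise HomologySearchError(f"{spec.enzyme_id}: no references")
        for orf_id, protein in proteins.items():
            best: tuple[float, float, str, AlignmentResult] | None = None
            for ref_name, ref_seq in spec.references:
                aln = local_align(ref_seq, protein, scoring)
                key = (aln.score, aln.identity)
                if best is None or key > (best[0], best[1]):
                    best = (aln.score, aln.identity, ref_name, aln)
            assert best is not None
            _, _, ref_name, aln = best
            if aln.n_columns == 0:
                continue
            if aln.identity >= spec.min_identity and aln.query_coverage >= spec.min_coverage:
                hits.append(_hit_from_alignment(spec.enzyme_id, orf_id, ref_name, aln))
    hits.sort(key=lambda h: (-h.score, h.enzyme_id, h.orf_id))
    return hits


_HIT_COLUMNS = [
    "enzyme_id", "orf_id", "reference", "score", "identity", "coverage",
    "q_start", "q_end", "t_start", "t_end",
]


def hits_to_frame(hits: Iterable[Hit]) -> pd.DataFrame:
    rows = [
        (h.enzyme_id, h.orf_id, h.reference, h.score, h.identity,
         h.query_coverage, h.q_start, h.q_end, h.t_start, h.t_end)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=_HIT_COLUMNS)


def write_hits(hits: Iterable[Hit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hits(path: str | Path) -> list[Hit]:
    df = pd.read_csv(path, sep="\t")
    return [
        Hit(
            enzyme_id=str(r.enzyme_id),
            orf_id=str(r.orf_id),
            reference=str(r.reference),
            score=float(r.score),
            identity=float(r.identity),
            query_coverage=float(r.coverage),
            q_start=int(r.q_start),
            q_end=int(r.q_end),
            t_start=int(r.t_start),
            t_end=int(r.t_end),
        )
        for r in df.itertuples()
    ]
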