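"""Six-frame open-reading-frame prediction on transcript sequences.

For every transcript, all six reading frames are scanned and, per maximal
stop-free codon run ("segment"), one maximal ORF is emitted:

* segment bounded by stops on both sides and containing an ATG →
  ``complete`` ORF from the first ATG to the stop;
* segment running off the 3' end with an ATG → ``3'-partial``;
* segment starting at the transcript edge (no upstream stop codon) →
  ``5'-partial`` if a stop terminates it, ``internal`` if it also runs off
  the 3' end.

Emitting only the maximal ORF per segment guarantees that no returned ORF is
nested inside another in the same frame. The default minimum length is 100
codons, the conventional cut-off for coding-region prediction on de novo
assemblies. Codons containing N translate to X; ORFs are not split at X.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

VALID_NT = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    _CODON_TABLE.update(table.forward_table)
    for stop in table.stop_codons:
        _CODON_TABLE[stop] = "*"


_build_codon_table()


class ORFError(ValueError):
    pass


def translate_codon(codon: str) -> str:
    """Translate one codon; anything with N (or other ambiguity) becomes X."""
    return _CODON_TABLE.get(codon, "X")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ORFRecord:
    """A predicted ORF with 1-based inclusive forward-strand coordinates.

    ``frame`` is +1/+2/+3 on the forward strand, -1/-2/-3 on the reverse
    complement. The nucleotide span includes the stop codon when one is
    present (complete and 5'-partial ORFs); ``protein`` never contains the
    stop symbol.
    """

    orf_id: str
    transcript_id: str
    frame: int
    start: int
    end: int
    completeness: str  # complete | 5'-partial | 3'-partial | internal
    protein: str

    def __post_init__(self) -> None:
        span = self.end - self.start + 1
        has_stop = self.completeness in ("complete", "5'-partial")
        expected = len(self.protein) * 3 + (3 if has_stop else 0)
        if span != expected:
            raise ORFError(
                f"{self.orf_id}: span {span} inconsistent with protein length "
                f"{len(self.protein)} ({self.completeness})"
            )
        if "*" in self.protein:
            raise ORFError(f"{self.orf_id}: protein contains a stop symbol")


def _scan_frame(seq: str, offset: int, min_length: int) -> Iterator[tuple[int, int, str, str]]:
    """Yield (start0, end0_exclusive, completeness, protein) on one strand/frame.

    Coordinates are 0-based on the given strand's sequence.
    """
    n = len(seq)
    codon_starts = range(offset, n - 2, 3)
    seg_first: int | None = offset if offset + 3 <= n else None
    seg_atg: int | None = None
    for pos in codon_starts:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            yield from _emit(seq, seg_first, seg_atg, pos, True, min_length)
            seg_first = None
            seg_atg = None
            continue
        if seg_first is None:
            seg_first = pos
        if seg_atg is None and codon == "ATG":
            seg_atg = pos
    if seg_first is not None:
        last = codon_starts[-1] + 3 if len(codon_starts) else offset
        yield from _emit(seq, seg_first, seg_atg, last, False, min_length)


def _emit(seq, seg_first, seg_atg, seg_end, has_stop, min_length):
    """Emit the maximal ORF for one stop-free segment, if long enough."""
    if seg_first is None:
        return
    at_edge = seg_first < 3  # segment begins at the transcript 5' edge (this strand)
    if at_edge and seg_atg != seg_first:
        # maximal ORF starts at the edge, upstream of (or without) any ATG
        start = seg_first
        completeness = "5'-partial" if has_stop else "internal"
    else:
        if seg_atg is None:
            return
        start = seg_atg
        completeness = "complete" if has_stop else "3'-partial"
    protein = "".join(
        translate_codon(seq[p : p + 3]) for p in range(start, seg_end, 3)
    )
    if len(protein) < min_length:
        return
    end = seg_end + (3 if has_stop else 0)
    yield (start, end, completeness, protein)


def find_orfs(
    transcript: str,
    transcript_id: str = "transcript",
    min_length: int = 100,
    genetic_code: int = 1,
) -> list[ORFRecord]:
    """Predict ORFs of at least ``min_length`` codons in all six frames.

    Coordinates in the returned records are 1-based inclusive on the forward
    strand regardless of the ORF's strand. Records are sorted by (frame,
    start). An empty sequence yields an empty list; characters outside
    {A,C,G,T,N} are fatal.
    """
    if genetic_code != 1:
        raise ORFError("only the standard genetic code (table 1) is supported")
    if min_length < 1:
        raise ORFError("min_length must be >= 1")
    seq = str(transcript).upper()
    if not seq:
        return []
    bad = set(seq) - VALID_NT
    if bad:
        raise ORFError(f"{transcript_id}: invalid nucleotide characters {sorted(bad)}")
    n = len(seq)
    records: list[ORFRecord] = []
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for offset in range(3):
            frame = strand * (offset + 1)
            for s0, e0, completeness, protein in _scan_frame(s, offset, min_length):
                if strand == 1:
                    start, end = s0 + 1, e0
                else:
                    start, end = n - e0 + 1, n - s0
                orf_id = f"{transcript_id}_f{frame:+d}_{start}-{end}"
                records.append(
                    ORFRecord(
                        orf_id=orf_id,
                        transcript_id=transcript_id,
                        frame=frame,
                        start=start,
                        end=end,
                        completeness=completeness,
                        protein=protein,
                    )
                )
    records.sort(key=lambda r: (r.frame, r.start, r.end))
    return records


def find_orfs_fasta(
    fasta_path: str | Path, min_length: int = 100
) -> list[ORFRecord]:
    """Run :func:`find_orfs` over every record of a transcript FASTA."""
    out: list[ORFRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.extend(find_orfs(str(rec.seq), rec.id, min_length=min_length))
    return out


def write_protein_fasta(orfs: Iterable[ORFRecord], path: str | Path) -> None:
    """Write predicted proteins with pipe-delimited header metadata."""
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(
                f">{orf.orf_id}|{orf.transcript_id}|{orf.frame:+d}"
                f"|{orf.start}-{orf.end}|{orf.completeness}\n"
            )
            for i in range(0, len(orf.protein), 60):
                fh.write(orf.protein[i : i + 60] + "\n")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into {first-header-field: sequence}."""
    return {
        rec.id.split("|")[0]: str(rec.seq)
        for rec in SeqIO.parse(str(path), "fasta")
    }
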