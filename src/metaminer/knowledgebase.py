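"""Curated enzyme knowledge base: the pipeline's trusted "start points".

Each entry bundles, for one biosynthetic enzyme, the curated reference
protein sequences (with a designated *anchor* — the closest-relative sequence
used for residue numbering and phylogenetic co-clustering), the functionally
important residues (FIRs) published for that enzyme, required degenerate
sequence motifs, and the identity/coverage thresholds used when searching a
transcriptome.

The on-disk format is YAML with inline single-letter amino-acid sequences;
see ``docs/methods.md`` for the schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
# full residue alphabet a candidate may carry (X from ambiguous codons)
EXTENDED_AA = STANDARD_AA | {"X"}

logger = logging.getLogger(__name__)


class KnowledgeBaseError(ValueError):
    """Raised for malformed knowledge-base files or invariant violations."""


@dataclass(frozen=True)
class FIRSpec:
    """One functionally important residue on a reference sequence.

    ``ref_position`` is 1-based on the ungapped reference, matching published
    residue numbering (e.g. the catalytic Thr 264 of nicotinate
    N-methyltransferase). ``reference`` names the sequence the position refers
    to; ``None`` means the enzyme's anchor.
    """

    label: str
    ref_position: int
    allowed_residues: frozenset[str]
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.ref_position < 1:
            raise KnowledgeBaseError(
                f"FIR {self.label!r}: ref_position must be >= 1, got {self.ref_position}"
            )
        residues = frozenset(str(r).upper() for r in self.allowed_residues)
        if not residues:
            raise KnowledgeBaseError(f"FIR {self.label!r}: empty allowed_residues")
        bad = residues - STANDARD_AA
        if bad:
            raise KnowledgeBaseError(
                f"FIR {self.label!r}: non-standard residues {sorted(bad)}"
            )
        object.__setattr__(self, "allowed_residues", residues)


WILDCARD = None  # sentinel: motif position matching any residue


@dataclass(frozen=True)
class MotifPattern:
    """A fixed-length degenerate protein motif, e.g. ``(I/V)TENG``.

    ``positions`` holds one entry per motif column: a frozenset of allowed
    residues, or ``None`` for the ``x`` wildcard (any residue).
    """

    name: str
    source: str
    positions: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise KnowledgeBaseError(
                f"motif {self.name!r}: pattern must have >= 2 positions"
            )
        for i, pos in enumerate(self.positions):
            if pos is not None and not pos:
                raise KnowledgeBaseError(
                    f"motif {self.name!r}: empty residue set at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.positions)


def compile_motif(text_pattern: str, name: str | None = None) -> MotifPattern:
    """Compile a degenerate motif string into a :class:`MotifPattern`.

    Syntax: single residues, parenthesised slash-alternations such as
    ``(I/V)``, and ``x`` wildcards. ``"(I/V)TENG"`` compiles to five
    positions, the first being ``{I, V}``.
    """
    text = str(text_pattern).strip()
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            close = text.find(")", i)
            if close == -1:
                raise KnowledgeBaseError(
                    f"motif {text!r}: unbalanced parenthesis at offset {i}"
                )
            options = text[i + 1 : close].split("/")
            residues = set()
            for opt in options:
                opt = opt.strip().upper()
                if len(opt) != 1 or opt not in STANDARD_AA:
                    raise KnowledgeBaseError(
                        f"motif {text!r}: invalid alternation member {opt!r}"
                    )
                residues.add(opt)
            if not residues:
                raise KnowledgeBaseError(f"motif {text!r}: empty alternation")
            positions.append(frozenset(residues))
            i = close + 1
        elif ch == ")":
            raise KnowledgeBaseError(
                f"motif {text!r}: unbalanced parenthesis at offset {i}"
            )
        elif ch in ("x", "X"):
            positions.append(WILDCARD)
            i += 1
        else:
            up = ch.upper()
            if up in STANDARD_AA:
                positions.append(frozenset({up}))
            else:
                raise KnowledgeBaseError(
                    f"motif {text!r}: {ch!r} is not an amino-acid letter"
                )
            i += 1
    return MotifPattern(name=name or text, source=text, positions=tuple(positions))


@dataclass(frozen=True)
class EnzymeSpec:
    """One curated enzyme entry ("start point") of the knowledge base."""

    enzyme_id: str
    ec_number: str
    pathway: str
    references: tuple[tuple[str, str], ...]  # (name, sequence), order preserved
    anchor: str
    firs: tuple[FIRSpec, ...] = ()
    motifs: tuple[MotifPattern, ...] = ()
    min_identity: float = 0.30
    min_coverage: float = 0.70
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.references:
            raise KnowledgeBaseError(f"{self.enzyme_id}: at least one reference required")
        names = [n for n, _ in self.references]
        if len(set(names)) != len(names):
            raise KnowledgeBaseError(f"{self.enzyme_id}: duplicate reference names")
        seqs = dict(self.references)
        for name, seq in self.references:
            bad = set(seq.upper()) - EXTENDED_AA
            if bad:
                raise KnowledgeBaseError(
                    f"{self.enzyme_id}/{name}: invalid residues {sorted(bad)}"
                )
            if not seq:
                raise KnowledgeBaseError(f"{self.enzyme_id}/{name}: empty sequence")
        if self.anchor not in seqs:
            raise KnowledgeBaseError(
                f"{self.enzyme_id}: anchor {self.anchor!r} not among references"
            )
        for fir in self.firs:
            ref_name = fir.reference or self.anchor
            if ref_name not in seqs:
                raise KnowledgeBaseError(
                    f"{self.enzyme_id}: FIR {fir.label!r} names unknown reference "
                    f"{ref_name!r}"
                )
            if fir.ref_position > len(seqs[ref_name]):
                raise KnowledgeBaseError(
                    f"{self.enzyme_id}: FIR {fir.label!r} position {fir.ref_position} "
                    f"exceeds length {len(seqs[ref_name])} of reference {ref_name!r}"
                )
        for value, label in ((self.min_identity, "min_identity"),
                             (self.min_coverage, "min_coverage")):
            if not (0.0 <= value <= 1.0):
                raise KnowledgeBaseError(
                    f"{self.enzyme_id}: {label} must be in [0, 1], got {value}"
                )

    @property
    def reference_sequences(self) -> dict[str, str]:
        return dict(self.references)

    @property
    def anchor_sequence(self) -> str:
        return dict(self.references)[self.anchor]

    def fir_reference(self, fir: FIRSpec) -> str:
        """Sequence of the reference a FIR is numbered on."""
        return dict(self.references)[fir.reference or self.anchor]


# ---------------------------------------------------------------------------
# serialization


def _fir_to_dict(fir: FIRSpec) -> dict:
    d = {
        "label": fir.label,
        "ref_position": fir.ref_position,
        "allowed_residues": "".join(sorted(fir.allowed_residues)),
    }
    if fir.reference is not None:
        d["reference"] = fir.reference
    return d


def _enzyme_to_dict(spec: EnzymeSpec) -> dict:
    d = {
        "enzyme_id": spec.enzyme_id,
        "ec_number": spec.ec_number,
        "pathway": spec.pathway,
        "anchor": spec.anchor,
        "min_identity": spec.min_identity,
        "min_coverage": spec.min_coverage,
        "references": [{"name": n, "sequence": s} for n, s in spec.references],
        "firs": [_fir_to_dict(f) for f in spec.firs],
        "motifs": [{"name": m.name, "pattern": m.source} for m in spec.motifs],
    }
    if spec.notes:
        d["notes"] = spec.notes
    return d


def _enzyme_from_dict(d: dict) -> EnzymeSpec:
    try:
        enzyme_id = d["enzyme_id"]
    except (KeyError, TypeError) as exc:
        raise KnowledgeBaseError(f"enzyme entry missing 'enzyme_id': {d!r}") from exc

    def _field(key, default=None, required=False):
        if required and key not in d:
            raise KnowledgeBaseError(f"{enzyme_id}: missing field {key!r}")
        return d.get(key, default)

    refs = _field("references", required=True)
    references = []
    for r in refs:
        try:
            references.append((str(r["name"]), str(r["sequence"]).upper()))
        except (KeyError, TypeError) as exc:
            raise KnowledgeBaseError(
                f"{enzyme_id}: malformed reference entry {r!r}"
            ) from exc
    firs = []
    for f in _field("firs", []) or []:
        try:
            firs.append(
                FIRSpec(
                    label=str(f["label"]),
                    ref_position=int(f["ref_position"]),
                    allowed_residues=frozenset(str(f["allowed_residues"])),
                    reference=f.get("reference"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise KnowledgeBaseError(f"{enzyme_id}: malformed FIR entry {f!r}") from exc
    motifs = []
    for m in _field("motifs", []) or []:
        try:
            motifs.append(compile_motif(m["pattern"], name=m.get("name")))
        except (KeyError, TypeError) as exc:
            raise KnowledgeBaseError(f"{enzyme_id}: malformed motif entry {m!r}") from exc
    return EnzymeSpec(
        enzyme_id=str(enzyme_id),
        ec_number=str(_field("ec_number", "")),
        pathway=str(_field("pathway", "")),
        references=tuple(references),
        anchor=str(_field("anchor", required=True)),
        firs=tuple(firs),
        motifs=tuple(motifs),
        min_identity=float(_field("min_identity", 0.30)),
        min_coverage=float(_field("min_coverage", 0.70)),
        notes=str(_field("notes", "")),
    )


def load_knowledgebase(path: str | Path) -> list[EnzymeSpec]:
    """Load and validate a knowledge-base YAML file.

    An empty file yields an empty list (with a warning); any invariant
    violation — unparseable YAML, a FIR position past its reference end,
    a missing anchor — raises :class:`KnowledgeBaseError` naming the enzyme
    and field.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise KnowledgeBaseError(f"{path}: YAML parse error: {exc}") from exc
    if data is None:
        logger.warning("knowledge base %s is empty", path)
        return []
    if not isinstance(data, dict) or "enzymes" not in data:
        raise KnowledgeBaseError(f"{path}: expected a top-level 'enzymes' list")
    entries = data["enzymes"] or []
    specs = [_enzyme_from_dict(e) for e in entries]
    ids = [s.enzyme_id for s in specs]
    if len(set(ids)) != len(ids):
        raise KnowledgeBaseError(f"{path}: duplicate enzyme_id values")
    if not specs:
        logger.warning("knowledge base %s contains no enzymes", path)
    return specs


def save_knowledgebase(specs: list[EnzymeSpec], path: str | Path) -> None:
    """Serialize enzyme specs to YAML; inverse of :func:`load_knowledgebase`."""
    payload = {"enzymes": [_enzyme_to_dict(s) for s in specs]}
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=False, width=100000)
    )
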