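"""Worked example knowledge base for five secondary-metabolite enzymes.

The entries cover nicotinate N-methyltransferase (NNMT, trigonelline
pathway), choline monooxygenase (CHMO) and betaine aldehyde dehydrogenase
(BADH, glycine betaine pathway), sterol-3-beta-glucosyltransferase and
beta-glucosidase (diosgenin pathway), with the functionally important
residues and motifs published for each: NNMT substrate-binding Asn21 /
Tyr120 / His124 and catalytic Thr264; BADH proton-acceptor Glu260,
nucleophile Cys294 and cation-pi Trp285 / Trp456; the beta-glucosidase
(I/V)TENG and TFNEP catalytic-glutamate motifs; the glucosyltransferase
PSBD and PSPG motifs; the CHMO Rieske 2Fe-2S and non-heme motifs.

The reference *sequences* here are synthetic stand-ins generated with a
fixed seed — random proteins with the documented residues and motif windows
installed at the documented coordinates — because the pipeline's behaviour
depends only on positions and patterns, not on real UniProt entries. Motif
patterns whose sequences are not published (SAM-binding, PSBD, Rieske,
non-heme) are placeholders and marked non-authoritative in each entry's
notes; the PSPG pattern uses the conserved THCGWNS core. Replace the
sequences and placeholder patterns with curated ones for real analyses.
"""

from __future__ import annotations

import numpy as np

from .knowledgebase import EnzymeSpec, FIRSpec, compile_motif
from .synthetic import mutate_preserving, protected_positions, random_protein

_KB_SEED = 735001


def _install(seq: list[str], start: int, fragment: str) -> None:
    """Overwrite seq (0-based list) with fragment at 1-based position start."""
    for i, ch in enumerate(fragment):
        seq[start - 1 + i] = ch


def _anchor(rng: np.random.Generator, length: int,
            residues: dict[int, str], windows: dict[int, str]) -> str:
    seq = list(random_protein(rng, length))
    for start, fragment in windows.items():
        _install(seq, start, fragment)
    for pos, aa in residues.items():
        seq[pos - 1] = aa
    return "".join(seq)


def _family(enzyme_id: str, ancestor_name: str, ancestor_seq: str,
            spec_firs, spec_motifs, key: int) -> tuple[tuple[str, str], ...]:
    """Anchor plus two relatives, all descended from a common ancestor.

    Deriving every reference from one ancestral sequence (FIRs and motif
    windows preserved throughout) gives the reference set genuine lineage
    structure instead of making the anchor the hub of the family.
    """
    probe = EnzymeSpec(
        enzyme_id=enzyme_id, ec_number="", pathway="",
        references=((ancestor_name, ancestor_seq),), anchor=ancestor_name,
        firs=spec_firs, motifs=spec_motifs,
    )
    protected = protected_positions(probe)
    rng = np.random.default_rng(np.random.SeedSequence(_KB_SEED, spawn_key=(100 + key,)))
    seeds = [int(rng.integers(2**31)) for _ in range(3)]
    anchor = mutate_preserving(ancestor_seq, 0.88, protected, seeds[0])
    hom_a = mutate_preserving(ancestor_seq, 0.75, protected, seeds[1])
    hom_b = mutate_preserving(ancestor_seq, 0.60, protected, seeds[2])
    return (
        (f"{enzyme_id}_anchor", anchor),
        (f"{enzyme_id}_homologA", hom_a),
        (f"{enzyme_id}_homologB", hom_b),
    )


def example_knowledgebase() -> list[EnzymeSpec]:
    """Build the shipped five-enzyme example knowledge base (deterministic)."""
    specs: list[EnzymeSpec] = []

    def make(enzyme_id, ec, pathway, length, residues, windows, firs,
             motifs, notes, key):
        rng = np.random.default_rng(np.random.SeedSequence(_KB_SEED, spawn_key=(key,)))
        ancestor_seq = _anchor(rng, length, residues, windows)
        refs = _family(enzyme_id, f"{enzyme_id}_ancestor", ancestor_seq,
                       firs, motifs, key)
        specs.append(
            EnzymeSpec(
                enzyme_id=enzyme_id, ec_number=ec, pathway=pathway,
                references=refs, anchor=f"{enzyme_id}_anchor",
                firs=firs, motifs=motifs, notes=notes,
            )
        )

    make(
        "NNMT", "2.1.1.7", "trigonelline biosynthesis (alkaloid)",
        350,
        {21: "N", 120: "Y", 124: "H", 264: "T"},
        {60: "LDVGGGTG"},  # SAM-binding placeholder window
        (
            FIRSpec("substrate-binding", 21, frozenset("N")),
            FIRSpec("substrate-binding", 120, frozenset("Y")),
            FIRSpec("substrate-binding", 124, frozenset("H")),
            FIRSpec("catalytic", 264, frozenset("T")),
        ),
        (compile_motif("(L/V)D(V/I)GGG(T/S)G", name="SAM-binding"),),
        "SAM-binding motif pattern is a synthetic placeholder (sequence not "
        "published); reference sequences are synthetic stand-ins.",
        1,
    )
    make(
        "CHMO", "1.14.15.7", "glycine betaine biosynthesis (alkaloid)",
        380,
        {},
        {101: "CSHLGCV", 220: "DKWHG"},
        (),
        (
            compile_motif("C(S/T)H(L/R)GC", name="Rieske-2Fe-2S"),
            compile_motif("D(K/R)WHG", name="non-heme-Fe"),
        ),
        "Rieske and non-heme motif patterns are synthetic placeholders; "
        "reference sequences are synthetic stand-ins.",
        2,
    )
    make(
        "BADH", "1.2.1.8", "glycine betaine biosynthesis (alkaloid)",
        500,
        {260: "E", 285: "W", 294: "C", 456: "W"},
        {},
        (
            FIRSpec("proton acceptor", 260, frozenset("E")),
            FIRSpec("cation-pi", 285, frozenset("W")),
            FIRSpec("nucleophile", 294, frozenset("C")),
            FIRSpec("cation-pi", 456, frozenset("W")),
        ),
        (),
        "Reference sequences are synthetic stand-ins.",
        3,
    )
    make(
        "SGT", "2.4.1.173", "diosgenin biosynthesis (saponin)",
        460,
        {},
        {150: "LGGGTL", 380: "FVTHCGWNS"},
        (),
        (
            compile_motif("(L/I)GG(G/S)T(L/M)", name="PSBD"),
            compile_motif("(F/W)(V/I)THCGWNS", name="PSPG"),
        ),
        "PSBD pattern is a synthetic placeholder; PSPG uses the conserved "
        "THCGWNS core. Reference sequences are synthetic stand-ins.",
        4,
    )
    make(
        "BGL", "3.2.1.21", "diosgenin biosynthesis (saponin)",
        480,
        {},
        {170: "TFNEP", 390: "ITENG"},
        (
            FIRSpec("catalytic acid/base Glu", 173, frozenset("E")),
            FIRSpec("catalytic nucleophile Glu", 392, frozenset("E")),
        ),
        (
            compile_motif("(I/V)TENG", name="(I/V)TENG"),
            compile_motif("TFNEP", name="TFNEP"),
        ),
        "Catalytic glutamates sit inside the TFNEP and (I/V)TENG motifs. "
        "Reference sequences are synthetic stand-ins.",
        5,
    )
    return specs
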