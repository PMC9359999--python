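"""Ground-truthed synthetic transcriptomes for end-to-end verification.

The generator emulates the shape of a de novo plant transcriptome study —
planted enzyme orthologues whose functionally important residues (FIRs) and
motifs are intact, FIR-mutated and motif-mutated decoys that must be
rejected, paralogous near-misses, random background ORFs, and
negative-binomial count matrices over tissues with designated tissue-high
transcripts — while recording every truth in a manifest so each pipeline
stage can be audited.

All outputs are bit-exact reproducible from (design, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .align import STANDARD_AA, ScoringScheme
from .knowledgebase import EnzymeSpec, save_knowledgebase
from .orfs import revcomp
from .validation import scan_motif

NT = "ACGT"


class SyntheticDesignError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticDesign:
    """Study conditions for one synthetic transcriptome.

    Defaults: per enzyme, orthologues at 50/70/90% identity to the anchor,
    one FIR decoy and one motif decoy (where the enzyme defines FIRs/motifs),
    and 200 random background ORFs — the configuration every recovery test
    in this package runs under.
    """

    orthologue_identities: tuple[float, ...] = (0.5, 0.7, 0.9)
    n_fir_decoys: int = 1
    n_motif_decoys: int = 1
    n_paralogs: int = 0
    paralog_identity: float = 0.35
    n_background: int = 200
    background_length: tuple[int, int] = (250, 450)
    utr_length: tuple[int, int] = (30, 90)
    decoy_base_identity: float = 0.9


@dataclass
class PlantedORF:
    """Ground truth for one planted (or background) coding region."""

    orf_class: str  # orthologue | fir_decoy | motif_decoy | paralog | background
    transcript_id: str
    protein: str
    enzyme_id: str | None = None
    source_reference: str | None = None
    target_identity: float | None = None
    realized_identity: float | None = None
    strand: int = 1
    cds_start: int = 0  # 1-based forward-strand coords, stop codon included
    cds_end: int = 0


@dataclass
class SyntheticManifest:
    """Everything the generator knows: planted ORFs and true expression."""

    seed: int
    design: SyntheticDesign
    orfs: list[PlantedORF] = field(default_factory=list)
    expression: pd.DataFrame | None = None  # true mean TPM, transcript x tissue
    transcript_lengths: dict[str, int] = field(default_factory=dict)
    top_sets: dict[str, list[str]] = field(default_factory=dict)
    dispersion: float = 0.1

    def by_class(self, orf_class: str) -> list[PlantedORF]:
        return [o for o in self.orfs if o.orf_class == orf_class]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "design": asdict(self.design),
            "dispersion": self.dispersion,
            "orfs": [asdict(o) for o in self.orfs],
            "transcript_lengths": self.transcript_lengths,
            "top_sets": self.top_sets,
            "expression": None
            if self.expression is None
            else {
                "index": list(self.expression.index),
                "columns": list(self.expression.columns),
                "values": self.expression.values.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticManifest":
        payload = json.loads(Path(path).read_text())
        design = SyntheticDesign(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in payload["design"].items()
            }
        )
        expr = payload["expression"]
        expression = (
            None
            if expr is None
            else pd.DataFrame(
                expr["values"], index=expr["index"], columns=expr["columns"]
            )
        )
        return cls(
            seed=payload["seed"],
            design=design,
            orfs=[PlantedORF(**o) for o in payload["orfs"]],
            expression=expression,
            transcript_lengths=payload["transcript_lengths"],
            top_sets=payload["top_sets"],
            dispersion=payload["dispersion"],
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# protein-level mutagenesis


def _substitution_weights(scheme: ScoringScheme) -> dict[str, tuple[str, np.ndarray]]:
    """Per-residue replacement alphabet and BLOSUM-weighted probabilities."""
    out = {}
    for a in STANDARD_AA:
        others = [b for b in STANDARD_AA if b != a]
        w = np.array([2.0 ** (scheme.score(a, b) / 2.0) for b in others])
        out[a] = ("".join(others), w / w.sum())
    return out


def worst_residue(residue: str, scheme: ScoringScheme | None = None,
                  exclude: frozenset[str] = frozenset()) -> str:
    """The most dissimilar standard residue under the substitution matrix.

    Ties are broken alphabetically; residues in ``exclude`` (and the residue
    itself) are never returned.
    """
    scheme = scheme or ScoringScheme()
    options = [b for b in sorted(STANDARD_AA) if b != residue and b not in exclude]
    if not options:
        raise SyntheticDesignError(f"no replacement residue available for {residue!r}")
    return min(options, key=lambda b: (scheme.score(residue, b), b))


def mutate_preserving(
    reference: str,
    target_identity: float,
    protected_positions: set[int],
    seed: int,
    scheme: ScoringScheme | None = None,
) -> str:
    """Substitute residues to reach a target identity, sparing protected sites.

    ``protected_positions`` are 1-based. Exactly ``round((1-t)*L)``
    unprotected positions are substituted (so realized identity is within
    rounding of the target), each to a different residue drawn from a
    substitution-matrix-weighted proposal. Deterministic given the seed.
    """
    scheme = scheme or ScoringScheme()
    if not (0.0 <= target_identity <= 1.0):
        raise SyntheticDesignError("target_identity must be in [0, 1]")
    L = len(reference)
    k = int(round((1.0 - target_identity) * L))
    if k == 0:
        return reference
    unprotected = [i for i in range(L) if (i + 1) not in protected_positions
                   and reference[i] in STANDARD_AA]
    if k > len(unprotected):
        feasible = 1.0 - len(unprotected) / L
        raise SyntheticDesignError(
            f"target identity {target_identity} infeasible: only "
            f"{len(unprotected)} mutable positions of {L} "
            f"(minimum identity {feasible:.3f})"
        )
    rng = _rng(seed, 0)
    chosen = rng.choice(len(unprotected), size=k, replace=False)
    weights = _substitution_weights(scheme)
    mutant = list(reference)
    for idx in sorted(unprotected[i] for i in chosen):
        alphabet, probs = weights[reference[idx]]
        mutant[idx] = alphabet[rng.choice(len(alphabet), p=probs)]
    return "".join(mutant)


def identity_to(a: str, b: str) -> float:
    """Column identity of two equal-length ungapped sequences."""
    if len(a) != len(b):
        raise SyntheticDesignError("sequences differ in length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def protected_positions(spec: EnzymeSpec) -> set[int]:
    """1-based anchor positions that orthologues must preserve.

    Position 1 (the initiator Met), every anchor-referenced FIR position, and
    every column of every motif window found on the anchor.
    """
    anchor = spec.anchor_sequence
    protected = {1}
    for fir in spec.firs:
        if (fir.reference or spec.anchor) == spec.anchor:
            protected.add(fir.ref_position)
    for motif in spec.motifs:
        for start in scan_motif(anchor, motif):
            protected.update(range(start, start + len(motif)))
    return protected


def _make_fir_decoy(spec: EnzymeSpec, base: str,
                    scheme: ScoringScheme) -> str | None:
    """Mutate every anchor FIR of a base mutant to a disallowed residue."""
    anchor_firs = [f for f in spec.firs if (f.reference or spec.anchor) == spec.anchor]
    if not anchor_firs:
        return None
    decoy = list(base)
    for fir in anchor_firs:
        pos = fir.ref_position - 1
        decoy[pos] = worst_residue(base[pos], scheme, exclude=fir.allowed_residues)
    return "".join(decoy)


def _make_motif_decoy(spec: EnzymeSpec, base: str,
                      scheme: ScoringScheme) -> str | None:
    """Destroy every occurrence of one required motif in a base mutant."""
    if not spec.motifs:
        return None
    motif = spec.motifs[0]
    decoy = list(base)
    for _ in range(20):
        matches = scan_motif("".join(decoy), motif)
        if not matches:
            return "".join(decoy)
        for start in matches:
            for off, posset in enumerate(motif.positions):
                if posset is not None:
                    idx = start - 1 + off
                    decoy[idx] = worst_residue(decoy[idx], scheme, exclude=posset)
                    break
    raise SyntheticDesignError(
        f"{spec.enzyme_id}: could not eliminate motif {motif.name!r}"
    )


# ---------------------------------------------------------------------------
# nucleotide embedding

_CODONS: dict[str, list[str]] = {}


def _build_codons() -> None:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    for codon, aa in table.forward_table.items():
        _CODONS.setdefault(aa, []).append(codon)
    for aa in _CODONS:
        _CODONS[aa].sort()
    _CODONS["*"] = sorted(table.stop_codons)


_build_codons()


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform synonymous codon choice (stop appended)."""
    codons = []
    for aa in protein:
        options = _CODONS.get(aa)
        if options is None:
            raise SyntheticDesignError(f"cannot back-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    codons.append(_CODONS["*"][rng.integers(3)])
    return "".join(codons)


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=length))


def random_protein(rng: np.random.Generator, length: int) -> str:
    aas = sorted(STANDARD_AA)
    body = "".join(aas[i] for i in rng.integers(0, 20, size=length - 1))
    return "M" + body


def _embed(protein: str, rng: np.random.Generator,
           utr_range: tuple[int, int]) -> tuple[str, int, int, int]:
    """Wrap a CDS in random UTRs, randomize strand.

    Returns (transcript, strand, cds_start, cds_end) with 1-based inclusive
    forward-strand coordinates covering ATG..stop. An in-frame TAA is placed
    immediately 5' of the ATG so the planted complete ORF is exactly the
    planted protein.
    """
    cds = back_translate(protein, rng)
    u5 = int(rng.integers(utr_range[0], utr_range[1] + 1))
    u3 = int(rng.integers(utr_range[0], utr_range[1] + 1))
    utr5 = random_nt(rng, max(u5 - 3, 0)) + "TAA"
    utr3 = random_nt(rng, u3)
    forward = utr5 + cds + utr3
    start = len(utr5) + 1
    end = len(utr5) + len(cds)
    strand = 1 if rng.integers(2) == 0 else -1
    if strand == -1:
        n = len(forward)
        forward = revcomp(forward)
        start, end = n - end + 1, n - start + 1
    return forward, strand, start, end


# ---------------------------------------------------------------------------
# transcriptome assembly


def build_transcriptome(
    specs: list[EnzymeSpec],
    design: SyntheticDesign | None = None,
    seed: int = 0,
    scheme: ScoringScheme | None = None,
) -> tuple[list[tuple[str, str]], SyntheticManifest]:
    """Generate a transcript FASTA (as records) and its truth manifest."""
    design = design or SyntheticDesign()
    scheme = scheme or ScoringScheme()
    manifest = SyntheticManifest(seed=seed, design=design)
    records: list[tuple[str, str]] = []
    counter = 0

    def plant(protein: str, orf_class: str, rng, enzyme_id=None,
              source=None, target=None, realized=None) -> None:
        nonlocal counter
        tid = f"synth_t{counter:05d}"
        counter += 1
        transcript, strand, cds_start, cds_end = _embed(
            protein, rng, design.utr_length
        )
        records.append((tid, transcript))
        manifest.transcript_lengths[tid] = len(transcript)
        manifest.orfs.append(
            PlantedORF(
                orf_class=orf_class,
                transcript_id=tid,
                protein=protein,
                enzyme_id=enzyme_id,
                source_reference=source,
                target_identity=target,
                realized_identity=realized,
                strand=strand,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )

    for e_idx, spec in enumerate(specs):
        anchor = spec.anchor_sequence
        prot = protected_positions(spec)
        for o_idx, ident in enumerate(design.orthologue_identities):
            sub_seed = int(_rng(seed, 1, e_idx, o_idx).integers(2**31))
            mutant = mutate_preserving(anchor, ident, prot, sub_seed, scheme)
            plant(
                mutant, "orthologue", _rng(seed, 2, e_idx, o_idx),
                enzyme_id=spec.enzyme_id, source=spec.anchor,
                target=ident, realized=identity_to(anchor, mutant),
            )
        for d_idx in range(design.n_fir_decoys):
            sub_seed = int(_rng(seed, 3, e_idx, d_idx).integers(2**31))
            base = mutate_preserving(
                anchor, design.decoy_base_identity, prot, sub_seed, scheme
            )
            decoy = _make_fir_decoy(spec, base, scheme)
            if decoy is None:
                continue
            plant(
                decoy, "fir_decoy", _rng(seed, 4, e_idx, d_idx),
                enzyme_id=spec.enzyme_id, source=spec.anchor,
                target=design.decoy_base_identity,
                realized=identity_to(anchor, decoy),
            )
        for d_idx in range(design.n_motif_decoys):
            sub_seed = int(_rng(seed, 5, e_idx, d_idx).integers(2**31))
            base = mutate_preserving(
                anchor, design.decoy_base_identity, prot, sub_seed, scheme
            )
            decoy = _make_motif_decoy(spec, base, scheme)
            if decoy is None:
                continue
            plant(
                decoy, "motif_decoy", _rng(seed, 6, e_idx, d_idx),
                enzyme_id=spec.enzyme_id, source=spec.anchor,
                target=design.decoy_base_identity,
                realized=identity_to(anchor, decoy),
            )
        for p_idx in range(design.n_paralogs):
            sub_seed = int(_rng(seed, 7, e_idx, p_idx).integers(2**31))
            mutant = mutate_preserving(
                anchor, design.paralog_identity, {1}, sub_seed, scheme
            )
            plant(
                mutant, "paralog", _rng(seed, 8, e_idx, p_idx),
                enzyme_id=spec.enzyme_id, source=spec.anchor,
                target=design.paralog_identity,
                realized=identity_to(anchor, mutant),
            )
    bg_rng = _rng(seed, 9)
    lo, hi = design.background_length
    for b_idx in range(design.n_background):
        length = int(bg_rng.integers(lo, hi + 1))
        protein = random_protein(bg_rng, length)
        plant(protein, "background", bg_rng)
    return records, manifest


# ---------------------------------------------------------------------------
# expression truths and count simulation


def assign_expression(
    manifest: SyntheticManifest,
    tissues: tuple[str, ...] = ("leaf", "stem", "root"),
    seed: int = 0,
    n_top: int = 20,
    tissue_folds: dict[str, tuple[str, float]] | None = None,
) -> SyntheticManifest:
    """Attach true per-tissue mean TPM values to the manifest.

    Baselines are log-normal and shared across tissues; each tissue gets a
    disjoint designated top set of ``n_top`` transcripts boosted strictly
    above every baseline, so per-tissue top-N ranking has a known answer.
    ``tissue_folds`` maps transcript_id -> (tissue, fold) for explicit
    tissue-specific fold changes (applied after the top-set boost).
    """
    rng = _rng(seed, 10)
    tids = sorted(manifest.transcript_lengths)
    if n_top * len(tissues) > len(tids):
        raise SyntheticDesignError("not enough transcripts for the top sets")
    baseline = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=len(tids))
    expr = pd.DataFrame(
        {tissue: baseline.copy() for tissue in tissues}, index=tids
    )
    pool = list(tids)
    top_sets: dict[str, list[str]] = {}
    max_base = float(baseline.max())
    for tissue in tissues:
        picked_idx = rng.choice(len(pool), size=n_top, replace=False)
        picked = sorted(pool[i] for i in picked_idx)
        pool = [t for t in pool if t not in set(picked)]
        boosts = max_base * rng.uniform(2.0, 4.0, size=n_top)
        expr.loc[picked, tissue] = boosts
        top_sets[tissue] = picked
    for tid, (tissue, fold) in (tissue_folds or {}).items():
        expr.loc[tid, tissue] *= fold
    manifest.expression = expr
    manifest.top_sets = top_sets
    return manifest


def simulate_counts(
    manifest: SyntheticManifest,
    replicates: int = 2,
    library_size: int = 500_000,
    dispersion: float | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Draw negative-binomial count tables per (tissue, replicate).

    Expected counts are proportional to true mean TPM times transcript
    length, scaled to the library size; variance is mu + dispersion * mu^2.
    A dispersion below 1e-8 is the noise-free limit: counts equal rounded
    means. Returns ({sample_id: counts table}, samples manifest frame).
    """
    if manifest.expression is None:
        raise SyntheticDesignError(
            "manifest has no expression truths; call assign_expression first"
        )
    alpha = manifest.dispersion if dispersion is None else dispersion
    expr = manifest.expression
    tids = list(expr.index)
    lengths = np.array([manifest.transcript_lengths[t] for t in tids], dtype=float)
    tables: dict[str, pd.DataFrame] = {}
    sample_rows = []
    for t_idx, tissue in enumerate(expr.columns):
        weights = expr[tissue].to_numpy() * lengths
        mu = library_size * weights / weights.sum()
        for rep in range(1, replicates + 1):
            rng = _rng(seed, 11, t_idx, rep)
            if alpha < 1e-8:
                counts = np.rint(mu).astype(int)
            else:
                n = 1.0 / alpha
                p = n / (n + mu)
                counts = np.where(
                    mu > 0, rng.negative_binomial(n, np.where(mu > 0, p, 1.0)), 0
                ).astype(int)
            sample_id = f"{tissue}_r{rep}"
            tables[sample_id] = pd.DataFrame(
                {
                    "transcript_id": tids,
                    "count": counts,
                    "effective_length": lengths.astype(int),
                }
            )
            sample_rows.append((sample_id, tissue, rep))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "tissue", "replicate"]
    )
    return tables, samples


def write_bundle(
    outdir: str | Path,
    specs: list[EnzymeSpec],
    records: list[tuple[str, str]],
    manifest: SyntheticManifest,
    tables: dict[str, pd.DataFrame] | None = None,
    samples: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic study bundle to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    kb_path = outdir / "knowledgebase.yaml"
    save_knowledgebase(specs, kb_path)
    paths["knowledgebase"] = kb_path
    fasta = outdir / "transcripts.fasta"
    with open(fasta, "w") as fh:
        for tid, seq in records:
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["transcripts"] = fasta
    truth = outdir / "truth.json"
    manifest.to_json(truth)
    paths["truth"] = truth
    if tables is not None and samples is not None:
        counts_dir = outdir / "counts"
        counts_dir.mkdir(exist_ok=True)
        for sample_id, table in tables.items():
            table.to_csv(counts_dir / f"{sample_id}.tsv", sep="\t", index=False)
        samples_path = outdir / "samples.tsv"
        samples.to_csv(samples_path, sep="\t", index=False)
        paths["samples"] = samples_path
        paths["counts_dir"] = counts_dir
    return paths
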