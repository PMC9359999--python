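"""Neighbor-joining phylogenetics and the co-clustering decision rule.

Candidates that survive residue-level validation are placed on an unrooted
neighbor-joining (NJ) tree together with the curated reference sequences.
A candidate is a *true hit* when it falls inside the same well-supported
clade as its designated anchor reference — the closest-relative start point.

The NJ algorithm, bootstrap bipartition supports, and the co-clustering test
are implemented here; :class:`skbio.TreeNode` is used only as the tree
container and for newick input/output. Multiple alignments are delegated to
MAFFT (the two-sequence case reduces to the package's own global aligner).
"""

from __future__ import annotations

import io
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skbio import TreeNode

from .align import ScoringScheme, global_align

# Poisson correction -ln(1-p) diverges as p -> 1; saturated pairs are capped
# at this p so bootstrap replicates of distant sequences stay finite.
MAX_P_DISTANCE = 0.999


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# multiple sequence alignment


@dataclass(frozen=True)
class Msa:
    """An aligned set of named protein sequences (equal-length gapped rows)."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise PhylogenyError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise PhylogenyError("duplicate sequence names in MSA")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PhylogenyError(f"unequal row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def char_matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.rows):
                fh.write(f">{name}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")


def build_msa(
    sequences: Sequence[tuple[str, str]],
    scoring: ScoringScheme | None = None,
) -> Msa:
    """Align >= 2 named protein sequences.

    Two sequences are aligned with the package's global affine-gap aligner;
    larger sets are aligned with MAFFT. Removing gaps from any row recovers
    the corresponding input sequence.
    """
    if len(sequences) < 2:
        raise PhylogenyError("build_msa needs at least two sequences")
    names = [n for n, _ in sequences]
    if len(set(names)) != len(names):
        raise PhylogenyError("duplicate sequence names")
    for name, seq in sequences:
        if not seq:
            raise PhylogenyError(f"{name}: empty sequence")
    if len(sequences) == 2:
        aln = global_align(sequences[0][1], sequences[1][1], scoring)
        return Msa(names=tuple(names), rows=(aln.aligned_a, aln.aligned_b))
    with tempfile.TemporaryDirectory() as tmp:
        in_path = Path(tmp) / "in.fasta"
        with open(in_path, "w") as fh:
            for name, seq in sequences:
                fh.write(f">{name}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--auto", "--anysymbol", str(in_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise PhylogenyError(f"mafft failed: {proc.stderr.strip()[:500]}")
    rows: dict[str, str] = {}
    current = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            rows[current] = ""
        elif current is not None:
            rows[current] += line.strip()
    try:
        ordered = tuple(rows[n].upper() for n in names)
    except KeyError as exc:
        raise PhylogenyError(f"mafft dropped sequence {exc}") from exc
    return Msa(names=tuple(names), rows=ordered)


# ---------------------------------------------------------------------------
# distances


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise PhylogenyError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise PhylogenyError("non-finite distances")
        if np.any(v < 0):
            raise PhylogenyError("negative distances")
        if not np.allclose(v, v.T):
            raise PhylogenyError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(v)) > 0):
            raise PhylogenyError("nonzero diagonal")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def _pairwise_distances(chars: np.ndarray, model: str) -> np.ndarray:
    """Distance matrix from an (n_seq, n_col) residue character array."""
    n = chars.shape[0]
    not_gap = chars != "-"
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = not_gap[i] & not_gap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise PhylogenyError(
                    f"sequences {i} and {j} share no aligned columns"
                )
            p = float((chars[i, shared] != chars[j, shared]).sum()) / n_shared
            if model == "p":
                d = p
            elif model == "poisson":
                d = -np.log(1.0 - min(p, MAX_P_DISTANCE))
            else:
                raise PhylogenyError(f"unknown distance model {model!r}")
            out[i, j] = out[j, i] = d
    return out


def distance_matrix(msa: Msa, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an MSA.

    ``p``: mismatches over shared (both non-gap) columns. ``poisson``:
    -ln(1-p), the Poisson multiple-hit correction. A pair with zero shared
    columns is fatal, naming the pair.
    """
    chars = msa.char_matrix()
    try:
        values = _pairwise_distances(chars, model)
    except PhylogenyError as exc:
        msg = str(exc)
        if "share no aligned columns" in msg:
            # translate indices to names for the error message
            import re as _re

            m = _re.search(r"sequences (\d+) and (\d+)", msg)
            if m:
                i, j = int(m.group(1)), int(m.group(2))
                raise PhylogenyError(
                    f"{msa.names[i]!r} and {msa.names[j]!r} share no aligned columns"
                ) from exc
        raise
    return DistanceMatrix(labels=msa.names, values=values)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class PhyloTree:
    """Unrooted NJ tree: trifurcating root, branch lengths, optional supports.

    ``support_map`` maps canonical bipartitions (the leaf-name frozenset on
    the side containing the alphabetically smallest taxon) to bootstrap
    percentages. ``n_clamped`` counts negative NJ branch lengths clamped to
    zero.
    """

    root: TreeNode
    taxa: frozenset[str]
    n_clamped: int = 0
    support_map: dict[frozenset, float] | None = None

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def canonical_bipartition(self, side: frozenset[str]) -> frozenset[str]:
        return _canonical(side, self.taxa)

    def tip_distances(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Leaf labels and the matrix of path-length distances between them."""
        dm = self.root.cophenet()
        ids = tuple(dm.ids)
        return ids, np.asarray(dm.data, dtype=float)

    def to_newick(self) -> str:
        tree = self.root.copy()
        for node in tree.traverse(include_self=False):
            if not node.is_tip():
                side = frozenset(t.name for t in node.tips())
                sup = None
                if self.support_map is not None:
                    sup = self.support_map.get(_canonical(side, self.taxa))
                node.name = "" if sup is None else str(int(round(sup)))
        buf = io.StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip() + "\n"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a newick string; internal-node labels are read as supports."""
        root = TreeNode.read(io.StringIO(text))
        taxa = frozenset(t.name for t in root.tips())
        support_map: dict[frozenset, float] = {}
        for node in root.traverse(include_self=False):
            if not node.is_tip() and node.name not in (None, ""):
                try:
                    sup = float(node.name)
                except ValueError:
                    continue
                side = frozenset(t.name for t in node.tips())
                support_map[_canonical(side, taxa)] = sup
        return cls(root=root, taxa=taxa,
                   support_map=support_map or None)


def _canonical(side: frozenset[str], taxa: frozenset[str]) -> frozenset[str]:
    """Canonical representative of an unrooted bipartition."""
    return side if min(taxa) in side else taxa - side


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou & Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties are broken on the lexicographically smallest (label, label)
    pair. Negative branch lengths are clamped to zero with the deficit moved
    to the sister branch (counted in ``n_clamped``).
    """
    m = len(d.labels)
    if m < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    D = d.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in d.labels]
    names: list[str] = list(d.labels)
    clamped = 0
    counter = 0
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((names[i], names[j]))), i, j)
            for i, j in ties
            if i < j
        )
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
            clamped += 1
        if lj < 0:
            li += lj
            lj = 0.0
            clamped += 1
        node_i, node_j = nodes[i], nodes[j]
        node_i.length = float(li)
        node_j.length = float(lj)
        new = TreeNode()
        new.extend([node_i, node_j])
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [f"\x00join{counter:06d}"]
        counter += 1
        D = newD
    # resolve the final three nodes around a trifurcating root
    a, b, c = 0, 1, 2
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    lengths = []
    for l in (la, lb, lc):
        if l < 0:
            clamped += 1
            l = 0.0
        lengths.append(float(l))
    root = TreeNode()
    for node, l in zip(nodes, lengths):
        node.length = l
        root.append(node)
    taxa = frozenset(d.labels)
    return PhyloTree(root=root, taxa=taxa, n_clamped=clamped)


def _bipartitions(root: TreeNode, taxa: frozenset[str]) -> set[frozenset]:
    """Canonical non-trivial bipartitions induced by internal edges."""
    parts: set[frozenset] = set()
    for node in root.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            parts.add(_canonical(side, taxa))
    return parts


def bootstrap_support(
    msa: Msa,
    model: str = "poisson",
    replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap bipartition supports.

    Columns are resampled with replacement ``replicates`` times; the support
    of an internal edge is the percentage of replicate trees containing the
    same bipartition. A replicate whose resampled columns leave some pair
    with no shared residues contributes support to no edge.
    """
    if replicates < 1:
        raise PhylogenyError("replicates must be >= 1")
    base = neighbor_joining(distance_matrix(msa, model))
    chars = msa.char_matrix()
    n_cols = chars.shape[1]
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    taxa = base.taxa
    for _ in range(replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        sample = chars[:, idx]
        try:
            values = _pairwise_distances(sample, model)
        except PhylogenyError:
            continue
        tree = neighbor_joining(DistanceMatrix(labels=msa.names, values=values))
        counts.update(_bipartitions(tree.root, taxa))
    support_map = {
        bp: 100.0 * counts.get(bp, 0) / replicates
        for bp in _bipartitions(base.root, taxa)
    }
    base.support_map = support_map
    return base


# ---------------------------------------------------------------------------
# co-clustering


def cocluster_test(
    tree: PhyloTree,
    candidate: str,
    anchor: str,
    min_support: float = 0.0,
    references: Iterable[str] | None = None,
) -> bool:
    """Does the candidate co-cluster with its anchor reference?

    The tree is midpoint-rooted; walking from the candidate tip toward the
    root, the first clade containing at least one reference taxon is the
    candidate's neighbourhood. The test passes iff that clade contains the
    anchor and, when ``min_support`` > 0, the clade's defining edge has
    bootstrap support >= ``min_support``. The default gates on topology
    alone: the innermost candidate/anchor edge of a family fan carries
    little bootstrap signal even for genuine orthologues, so supports are
    reported on the tree rather than thresholded. The whole-tree "clade"
    has no defining edge and fails whenever ``min_support`` > 0.
    """
    names = tree.leaf_names
    for taxon in (candidate, anchor):
        if taxon not in names:
            raise PhylogenyError(f"taxon {taxon!r} not in tree")
    refs = set(references) if references is not None else names - {candidate}
    refs.discard(candidate)
    if not refs:
        raise PhylogenyError("no reference taxa to test co-clustering against")
    if min_support > 0 and tree.support_map is None:
        raise PhylogenyError(
            "min_support > 0 requires bootstrap supports on the tree"
        )
    rooted = tree.root.copy()
    if len(rooted.children) > 1:
        try:
            rooted = rooted.root_at_midpoint()
        except Exception:
            # zero-length or degenerate trees have no midpoint; keep the
            # existing (trifurcating) root as the rooting point
            pass
    node = next(t for t in rooted.tips() if t.name == candidate)
    anc = node.parent
    while anc is not None:
        leaves = {t.name for t in anc.tips()}
        if leaves & refs:
            if anchor not in leaves:
                return False
            if min_support <= 0:
                return True
            if anc.parent is None:
                return False  # whole tree: no defining edge to support
            assert tree.support_map is not None
            sup = tree.support_map.get(
                _canonical(frozenset(leaves), tree.taxa)
            )
            return sup is not None and sup >= min_support
        anc = anc.parent
    return False
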