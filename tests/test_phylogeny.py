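"""MSA, distances, neighbor joining, bootstrap supports, co-clustering."""

import numpy as np
import pytest

from metaminer.evaluation import (
    nj_additive_recovery,
    random_binary_tree,
    tree_to_distance_matrix,
)
from metaminer.phylogeny import (
    DistanceMatrix,
    Msa,
    PhylogenyError,
    PhyloTree,
    _bipartitions,
    bootstrap_support,
    build_msa,
    cocluster_test,
    distance_matrix,
    neighbor_joining,
)
from metaminer.synthetic import mutate_preserving


class TestBuildMsa:
    def test_identical_pair_aligns_without_gaps(self):
        msa = build_msa([("a", "MKTAYIAK"), ("b", "MKTAYIAK")])
        assert msa.rows == ("MKTAYIAK", "MKTAYIAK")

    def test_two_sequences_reduce_to_global_alignment(self):
        msa = build_msa([("a", "ACD"), ("b", "AD")])
        assert msa.n_columns == 3
        assert msa.rows[0] == "ACD"
        assert msa.rows[1].count("-") == 1

    def test_degapping_recovers_inputs_through_mafft(self):
        rng = np.random.default_rng(51)
        parent = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=100)
        )
        seqs = [
            (f"m{k}", mutate_preserving(parent, 0.8, set(), int(rng.integers(2**31))))
            for k in range(6)
        ]
        msa = build_msa(seqs)
        for (name, seq), row in zip(seqs, msa.rows):
            assert row.replace("-", "") == seq

    def test_mutant_family_columns_are_mostly_conserved(self):
        rng = np.random.default_rng(52)
        parent = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=100)
        )
        seqs = [
            (f"m{k}", mutate_preserving(parent, 0.9, set(), int(rng.integers(2**31))))
            for k in range(10)
        ]
        msa = build_msa(seqs)
        chars = msa.char_matrix()
        modal = [
            max(np.unique(chars[:, c], return_counts=True)[1])
            for c in range(msa.n_columns)
        ]
        assert float(np.mean(modal)) >= 6.0

    def test_single_sequence_is_fatal(self):
        with pytest.raises(PhylogenyError):
            build_msa([("a", "MKT")])


class TestDistanceMatrix:
    def test_identical_rows_have_zero_distance(self):
        msa = Msa(names=("a", "b"), rows=("MKTA", "MKTA"))
        dm = distance_matrix(msa, model="p")
        assert dm[("a", "b")] == 0.0

    def test_single_mismatch_gives_quarter_p_distance(self):
        msa = Msa(names=("a", "b"), rows=("AAAA", "AAAT"))
        assert distance_matrix(msa, model="p")[("a", "b")] == 0.25

    def test_poisson_correction_is_minus_log(self):
        msa = Msa(names=("a", "b"), rows=("AAAA", "AAAT"))
        dm = distance_matrix(msa, model="poisson")
        assert dm[("a", "b")] == pytest.approx(-np.log(0.75))

    def test_matches_brute_force_column_counts(self):
        rng = np.random.default_rng(53)
        alphabet = "ACDE-"
        for _ in range(20):
            n, L = int(rng.integers(3, 6)), int(rng.integers(20, 40))
            rows = [
                "".join(alphabet[i] for i in rng.integers(0, 5, size=L))
                for _ in range(n)
            ]
            names = tuple(f"s{k}" for k in range(n))
            try:
                dm = distance_matrix(Msa(names=names, rows=tuple(rows)), model="p")
            except PhylogenyError:
                continue  # a pair without shared columns is legitimately fatal
            for i in range(n):
                for j in range(i + 1, n):
                    shared = mism = 0
                    for x, y in zip(rows[i], rows[j]):
                        if x != "-" and y != "-":
                            shared += 1
                            mism += x != y
                    assert dm[(names[i], names[j])] == pytest.approx(mism / shared)

    def test_zero_overlap_names_the_pair(self):
        msa = Msa(names=("left", "right"), rows=("AA--", "--AA"))
        with pytest.raises(PhylogenyError, match="left.*right"):
            distance_matrix(msa, model="p")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            labels=("a", "b", "c"),
            values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_four_taxon_matrix_recovers_tree(self):
        rng = np.random.default_rng(54)
        true = random_binary_tree(rng, 4)
        dm = tree_to_distance_matrix(true)
        est = neighbor_joining(dm)
        taxa = frozenset(dm.labels)
        assert _bipartitions(true, taxa) == _bipartitions(est.root, taxa)
        ids, values = est.tip_distances()
        order = [ids.index(l) for l in dm.labels]
        assert np.abs(values[np.ix_(order, order)] - dm.values).max() < 1e-9

    def test_random_additive_matrices_always_recover(self):
        res = nj_additive_recovery(n_matrices=30, taxa_range=(5, 8), seed=55)
        assert res["recovered"] == res["n_matrices"]
        assert res["max_path_dev"] < 1e-9

    def test_two_taxa_is_fatal(self):
        dm = DistanceMatrix(labels=("a", "b"), values=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(PhylogenyError):
            neighbor_joining(dm)


def _cluster_msa(seed=56, n_cols=120):
    """Two tight clusters of two sequences each, far from one another."""
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    p1 = "".join(aas[i] for i in rng.integers(0, 20, size=n_cols))
    p2 = "".join(aas[i] for i in rng.integers(0, 20, size=n_cols))
    rows = (
        mutate_preserving(p1, 0.95, set(), 1),
        mutate_preserving(p1, 0.95, set(), 2),
        mutate_preserving(p2, 0.95, set(), 3),
        mutate_preserving(p2, 0.95, set(), 4),
    )
    return Msa(names=("a1", "a2", "b1", "b2"), rows=rows)


class TestBootstrap:
    def test_single_replicate_gives_all_or_nothing_supports(self):
        msa = _cluster_msa()
        tree = bootstrap_support(msa, replicates=1, seed=0)
        assert set(tree.support_map.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        msa = _cluster_msa()
        t1 = bootstrap_support(msa, replicates=30, seed=9)
        t2 = bootstrap_support(msa, replicates=30, seed=9)
        assert t1.support_map == t2.support_map

    def test_cluster_separating_edge_is_strongly_supported(self):
        msa = _cluster_msa()
        tree = bootstrap_support(msa, replicates=100, seed=10)
        sep = tree.canonical_bipartition(frozenset({"a1", "a2"}))
        assert tree.support_map[sep] >= 95.0

    def test_supports_invariant_under_row_permutation(self):
        msa = _cluster_msa()
        perm = Msa(
            names=(msa.names[2], msa.names[0], msa.names[3], msa.names[1]),
            rows=(msa.rows[2], msa.rows[0], msa.rows[3], msa.rows[1]),
        )
        t1 = bootstrap_support(msa, replicates=50, seed=11)
        t2 = bootstrap_support(perm, replicates=50, seed=11)
        assert t1.support_map == t2.support_map


class TestCocluster:
    def test_candidate_sister_to_anchor_passes(self):
        tree = PhyloTree.from_newick(
            "((cand:0.01,anchor:0.01)99:0.5,(refB:0.1,refC:0.1)99:0.5,out:0.6);"
        )
        assert cocluster_test(
            tree, "cand", "anchor", min_support=90,
            references={"anchor", "refB", "refC", "out"},
        )

    def test_candidate_beside_wrong_reference_fails(self):
        tree = PhyloTree.from_newick(
            "((cand:0.05,refB:0.05)95:0.4,(anchor:0.1,refC:0.1)95:0.4,out:0.5);"
        )
        assert not cocluster_test(
            tree, "cand", "anchor", min_support=0,
            references={"anchor", "refB", "refC", "out"},
        )

    def test_zero_support_threshold_is_vacuous(self):
        tree = PhyloTree.from_newick(
            "((cand:0.01,anchor:0.01)5:0.5,(refB:0.1,refC:0.1)5:0.5,out:0.6);"
        )
        assert cocluster_test(
            tree, "cand", "anchor", min_support=0,
            references={"anchor", "refB", "refC", "out"},
        )

    def test_monotone_non_increasing_in_min_support(self):
        tree = PhyloTree.from_newick(
            "((cand:0.01,anchor:0.01)60:0.5,(refB:0.1,refC:0.1)60:0.5,out:0.6);"
        )
        refs = {"anchor", "refB", "refC", "out"}
        outcomes = [
            cocluster_test(tree, "cand", "anchor", min_support=s, references=refs)
            for s in (0, 30, 60, 61, 90)
        ]
        # once False, never True again as the threshold rises
        assert outcomes == sorted(outcomes, reverse=True)

    def test_absent_taxon_is_fatal(self):
        tree = PhyloTree.from_newick("((a:1,b:1)50:1,(c:1,d:1)50:1,e:1);")
        with pytest.raises(PhylogenyError, match="ghost"):
            cocluster_test(tree, "ghost", "a", min_support=0)


class TestNewick:
    def test_round_trip_preserves_taxa_and_supports(self):
        msa = _cluster_msa()
        tree = bootstrap_support(msa, replicates=20, seed=12)
        text = tree.to_newick()
        back = PhyloTree.from_newick(text)
        assert back.taxa == tree.taxa
        for bp, sup in tree.support_map.items():
            assert back.support_map[bp] == pytest.approx(round(sup))
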