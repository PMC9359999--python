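"""Ground-truth generator: mutagenesis, embedding, counts, reproducibility."""

import numpy as np
import pytest

from metaminer.orfs import find_orfs
from metaminer.synthetic import (
    SyntheticDesign,
    SyntheticDesignError,
    SyntheticManifest,
    assign_expression,
    build_transcriptome,
    identity_to,
    mutate_preserving,
    simulate_counts,
)


@pytest.fixture(scope="module")
def small_design():
    return SyntheticDesign(
        orthologue_identities=(0.8,), n_background=10,
        n_fir_decoys=1, n_motif_decoys=1,
    )


@pytest.fixture(scope="module")
def small_bundle(small_design):
    from metaminer.examples import example_knowledgebase

    specs = example_knowledgebase()
    records, manifest = build_transcriptome(specs, small_design, seed=7)
    return specs, records, manifest


class TestMutatePreserving:
    REF = "M" + "ACDEFGHIKLMNPQRSTVWY" * 5  # 101 residues

    def test_full_identity_returns_reference_unchanged(self):
        assert mutate_preserving(self.REF, 1.0, set(), seed=1) == self.REF

    def test_target_identity_hit_with_protected_sites_spared(self):
        protected = set(range(1, 11))
        mutant = mutate_preserving(self.REF, 0.8, protected, seed=2)
        n_subs = sum(a != b for a, b in zip(self.REF, mutant))
        assert n_subs == round(0.2 * len(self.REF))
        assert abs(identity_to(self.REF, mutant) - 0.8) <= 0.03
        for pos in protected:
            assert mutant[pos - 1] == self.REF[pos - 1]

    def test_same_seed_reproduces_mutant_exactly(self):
        a = mutate_preserving(self.REF, 0.6, {1, 5}, seed=3)
        b = mutate_preserving(self.REF, 0.6, {1, 5}, seed=3)
        assert a == b

    def test_infeasible_target_reports_feasible_bound(self):
        protected = set(range(1, len(self.REF)))  # all but the last position
        with pytest.raises(SyntheticDesignError, match="minimum identity"):
            mutate_preserving(self.REF, 0.5, protected, seed=4)


class TestBuildTranscriptome:
    def test_manifest_classes_match_design(self, small_bundle, small_design):
        specs, records, manifest = small_bundle
        n_enzymes = len(specs)
        assert len(manifest.by_class("orthologue")) == n_enzymes
        # FIR decoys only exist for enzymes with anchor FIRs; motif decoys
        # only for enzymes with motifs (3 and 4 of the 5 example enzymes)
        n_fir = sum(1 for s in specs if s.firs)
        n_motif = sum(1 for s in specs if s.motifs)
        assert len(manifest.by_class("fir_decoy")) == n_fir
        assert len(manifest.by_class("motif_decoy")) == n_motif
        assert len(manifest.by_class("background")) == small_design.n_background
        assert len(records) == len(manifest.orfs)

    def test_realized_identity_within_tolerance_of_target(self, small_bundle):
        _, _, manifest = small_bundle
        for orf in manifest.by_class("orthologue"):
            assert abs(orf.realized_identity - orf.target_identity) <= 0.03

    def test_orthologues_preserve_firs_and_motifs(self, small_bundle):
        from metaminer.validation import scan_motif

        specs, _, manifest = small_bundle
        by_id = {s.enzyme_id: s for s in specs}
        for orf in manifest.by_class("orthologue"):
            spec = by_id[orf.enzyme_id]
            anchor = spec.anchor_sequence
            for fir in spec.firs:
                assert orf.protein[fir.ref_position - 1] == anchor[fir.ref_position - 1]
            for motif in spec.motifs:
                assert scan_motif(orf.protein, motif)

    def test_decoys_differ_from_anchor_at_rule_sites_only_by_design(self, small_bundle):
        from metaminer.validation import scan_motif

        specs, _, manifest = small_bundle
        by_id = {s.enzyme_id: s for s in specs}
        for orf in manifest.by_class("fir_decoy"):
            spec = by_id[orf.enzyme_id]
            anchor = spec.anchor_sequence
            broken = [
                f for f in spec.firs
                if orf.protein[f.ref_position - 1] not in f.allowed_residues
            ]
            assert broken, f"{orf.transcript_id} has no broken FIR"
        for orf in manifest.by_class("motif_decoy"):
            spec = by_id[orf.enzyme_id]
            missing = [m for m in spec.motifs if not scan_motif(orf.protein, m)]
            assert missing, f"{orf.transcript_id} still carries all motifs"

    def test_planted_transcript_round_trips_through_orf_finder(self, small_bundle):
        _, records, manifest = small_bundle
        seqs = dict(records)
        for orf in manifest.orfs[:12]:
            transcript = seqs[orf.transcript_id]
            found = find_orfs(transcript, orf.transcript_id, min_length=50)
            proteins = {o.protein for o in found if o.completeness == "complete"}
            assert orf.protein in proteins
            spans = {
                (o.start, o.end)
                for o in found
                if o.protein == orf.protein
            }
            assert (orf.cds_start, orf.cds_end) in spans

    def test_zero_background_design_plants_only_enzymes(self):
        from metaminer.examples import example_knowledgebase

        specs = example_knowledgebase()[:1]
        design = SyntheticDesign(
            orthologue_identities=(0.9,), n_background=0,
            n_fir_decoys=0, n_motif_decoys=0,
        )
        records, manifest = build_transcriptome(specs, design, seed=8)
        assert len(records) == 1
        assert manifest.orfs[0].orf_class == "orthologue"

    def test_same_seed_gives_bit_identical_output(self, small_design):
        from metaminer.examples import example_knowledgebase

        specs = example_knowledgebase()
        r1, m1 = build_transcriptome(specs, small_design, seed=9)
        r2, m2 = build_transcriptome(specs, small_design, seed=9)
        assert r1 == r2
        assert m1.orfs == m2.orfs


class TestExpressionTruths:
    def test_top_sets_are_disjoint_and_sized(self, small_bundle):
        _, _, manifest = small_bundle
        manifest = assign_expression(manifest, seed=7, n_top=5)
        seen = set()
        for tissue, tids in manifest.top_sets.items():
            assert len(tids) == 5
            assert not (set(tids) & seen)
            seen |= set(tids)

    def test_noise_free_counts_equal_rounded_means(self, small_bundle):
        _, _, manifest = small_bundle
        manifest = assign_expression(manifest, seed=7, n_top=5)
        tables, samples = simulate_counts(manifest, dispersion=0.0, seed=7)
        t1 = tables["leaf_r1"].set_index("transcript_id")["count"]
        t2 = tables["leaf_r2"].set_index("transcript_id")["count"]
        assert (t1 == t2).all()  # degenerate NB has no sampling noise

    def test_three_tissues_two_replicates_give_six_samples(self, small_bundle):
        _, _, manifest = small_bundle
        manifest = assign_expression(manifest, seed=7, n_top=5)
        tables, samples = simulate_counts(manifest, replicates=2, seed=7)
        assert len(tables) == 6
        assert sorted(samples.sample_id) == sorted(tables)

    def test_tenfold_leaf_high_transcript_recovers_fold_in_tpm(self, small_bundle):
        import pandas as pd

        from metaminer.expression import ExpressionMatrix, average_replicates

        _, _, manifest = small_bundle
        target = manifest.orfs[0].transcript_id
        manifest = assign_expression(
            manifest, seed=7, n_top=5, tissue_folds={target: ("leaf", 10.0)}
        )
        ratios = []
        for sim_seed in range(5):
            tables, samples = simulate_counts(manifest, seed=sim_seed)
            counts = pd.DataFrame(
                {s: t.set_index("transcript_id")["count"] for s, t in tables.items()}
            )
            lengths = pd.DataFrame(
                {
                    s: t.set_index("transcript_id")["effective_length"]
                    for s, t in tables.items()
                }
            )
            m = ExpressionMatrix(
                counts=counts, lengths=lengths,
                samples=samples.set_index("sample_id"),
            )
            mean = average_replicates(m)
            ratios.append(mean.loc[target, "leaf"] / mean.loc[target, "root"])
        assert all(5.0 <= r <= 20.0 for r in ratios)


class TestManifestSerialization:
    def test_json_round_trip(self, small_bundle, tmp_path):
        _, _, manifest = small_bundle
        manifest = assign_expression(manifest, seed=7, n_top=5)
        path = tmp_path / "truth.json"
        manifest.to_json(path)
        back = SyntheticManifest.from_json(path)
        assert back.seed == manifest.seed
        assert back.design == manifest.design
        assert back.orfs == manifest.orfs
        assert back.top_sets == manifest.top_sets
        assert np.allclose(back.expression.values, manifest.expression.values)
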