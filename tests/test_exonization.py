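"""Orthologue pairing, global alignment, diff extraction and propagation."""

import numpy as np
import pytest
from oracle_impls import gotoh_global_score

from repeatscape.exonization import (
    CascadeReport,
    TranscriptMap,
    extract_diffs,
    find_orthologs,
    global_align,
    map_diffs_to_repeats,
    propagate_to_protein,
    reconstruct_b,
    run_cascade,
)
from repeatscape.genome_model import GeneModel, GenomicInterval, RepeatFeature
from repeatscape.synthetic_data import _random_seq


@pytest.fixture()
def rng():
    return np.random.default_rng(17)


class TestGlobalAlign:
    def test_identical_sequences_score_full_matches(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 20.0
        assert aln.aligned_a == aln.aligned_b == "ACGT"

    def test_length_difference_forces_single_deletion(self):
        aln = global_align("ACGT", "AGT")
        assert aln.aligned_a.count("-") + aln.aligned_b.count("-") == 1

    def test_scores_match_independent_dp_oracle(self, rng):
        for _ in range(30):
            a = _random_seq(rng, int(rng.integers(5, 41)))
            b = _random_seq(rng, int(rng.integers(5, 41)))
            assert global_align(a, b).score == pytest.approx(
                gotoh_global_score(a, b)
            )

    def test_score_is_symmetric(self, rng):
        for _ in range(10):
            a = _random_seq(rng, 30)
            b = _random_seq(rng, 25)
            assert global_align(a, b).score == global_align(b, a).score


class TestExtractDiffs:
    def test_identical_sequences_yield_no_diffs(self):
        assert extract_diffs(global_align("ACGTACGT", "ACGTACGT")) == []

    def test_gap_run_is_one_indel_not_many(self):
        seq_a = "ACGTACGTACGTACGT"
        seq_b = seq_a[:8] + seq_a[11:]  # remove 3 bp
        diffs = extract_diffs(global_align(seq_a, seq_b))
        indels = [d for d in diffs if d.kind != "substitution"]
        assert len(indels) == 1
        assert indels[0].kind == "insertion_a"
        assert indels[0].length == 3

    def test_substitutions_are_per_column(self):
        seq_a = "AAAAAAAAAA"
        seq_b = "AAAATAAAAA"
        diffs = extract_diffs(global_align(seq_a, seq_b))
        assert [d.kind for d in diffs] == ["substitution"]
        assert diffs[0].pos_a == diffs[0].pos_b == 4
        assert diffs[0].seq == "T"

    def test_round_trip_regenerates_second_sequence(self, rng):
        from repeatscape.synthetic_data import _mutate

        for _ in range(20):
            a = _random_seq(rng, int(rng.integers(30, 120)))
            b = _mutate(rng, a, 0.15)
            diffs = extract_diffs(global_align(a, b))
            assert reconstruct_b(a, diffs) == b


class TestTranscriptMap:
    def _gene(self, strand="+"):
        return GeneModel(
            "g",
            GenomicInterval("c", 100, 400, strand),
            (
                GenomicInterval("c", 100, 200, strand),
                GenomicInterval("c", 300, 400, strand),
            ),
        )

    def test_plus_strand_projection(self):
        tm = TranscriptMap(self._gene("+"))
        (seg,) = tm.project(10, 20)
        assert (seg.start, seg.end) == (110, 130)

    def test_junction_spanning_projects_to_two_segments(self):
        tm = TranscriptMap(self._gene("+"))
        segs = tm.project(90, 20)
        assert [(s.start, s.end) for s in segs] == [(190, 200), (300, 310)]

    def test_minus_strand_counts_from_right(self):
        tm = TranscriptMap(self._gene("-"))
        (seg,) = tm.project(0, 10)  # transcript 5' end = rightmost exon end
        assert (seg.start, seg.end) == (390, 400)

    def test_outside_ladder_is_unmappable(self):
        tm = TranscriptMap(self._gene("+"))
        assert tm.project(500, 10) == []


class TestMapDiffsToRepeats:
    def test_diff_inside_planted_repeat_is_flagged(self):
        gene = GeneModel(
            "g", GenomicInterval("c", 0, 300, "+"),
            (GenomicInterval("c", 0, 300, "+"),),
        )
        tm = TranscriptMap(gene)
        rep = RepeatFeature(GenomicInterval("c", 50, 80), "f", "LTR/Gypsy")
        diffs = extract_diffs(
            global_align("A" * 300, "A" * 60 + "CCC" + "A" * 240)
        )
        flagged = map_diffs_to_repeats(diffs, tm, tm, [rep], [])
        assert any(d.in_repeat_a for d in flagged)
        none = map_diffs_to_repeats(diffs, tm, tm, [], [])
        assert not any(d.in_repeat for d in none)


class TestPropagateToProtein:
    def test_synonymous_substitution_yields_no_change(self):
        cds_a = "ATGGAAGAATAA"
        cds_b = "ATGGAAGAGTAA"  # GAA -> GAG, both Glu
        diffs = extract_diffs(global_align(cds_a, cds_b))
        changes, stop = propagate_to_protein(diffs, cds_a, cds_b)
        assert changes == [] and not stop

    def test_nonsynonymous_substitution_reported(self):
        cds_a = "ATGGAAGAATAA"
        cds_b = "ATGGTAGAATAA"  # wait: introduces stop? GTA=Val, fine
        diffs = extract_diffs(global_align(cds_a, cds_b))
        changes, stop = propagate_to_protein(diffs, cds_a, cds_b)
        assert len(changes) == 1 and changes[0].kind == "substitution"
        assert (changes[0].aa_a, changes[0].aa_b) == ("E", "V")

    def test_in_frame_insertion_is_single_aa_insertion(self):
        cds_a = "ATGGAAGAATAA"
        cds_b = "ATGGAACCAGAATAA"  # +CCA after codon 2
        diffs = extract_diffs(global_align(cds_a, cds_b))
        changes, _ = propagate_to_protein(diffs, cds_a, cds_b)
        kinds = [c.kind for c in changes]
        assert kinds == ["aa_insertion_b"]

    def test_frameshift_flagged(self):
        cds_a = "ATGGAAGAACATTAA"
        cds_b = "ATGGAAGGAACATTAA"  # +1 bp
        diffs = extract_diffs(global_align(cds_a, cds_b))
        changes, _ = propagate_to_protein(diffs, cds_a, cds_b)
        assert any(c.kind == "frameshift" for c in changes)

    def test_matches_translate_and_diff_oracle(self, rng):
        from Bio.Seq import Seq

        from repeatscape.synthetic_data import _diverge_cds, _random_cds

        for _ in range(10):
            cds_a = _random_cds(rng, 40)
            cds_b = _diverge_cds(rng, cds_a, 0.1, 0.1)
            diffs = extract_diffs(global_align(cds_a, cds_b))
            changes, stop = propagate_to_protein(diffs, cds_a, cds_b)
            assert not stop
            prot_a, prot_b = str(Seq(cds_a).translate()), str(Seq(cds_b).translate())
            expected = {
                i for i, (x, y) in enumerate(zip(prot_a, prot_b)) if x != y
            }
            got = {c.codon_a for c in changes if c.kind == "substitution"}
            assert got == expected


class TestFindOrthologs:
    def test_identical_proteomes_map_identically(self):
        prot = {
            "p1": "MKVLITGAGGFIGS",
            "p2": "MEEPQSDPSVEPPLS",
            "p3": "MAATLKQPWWKRA",
        }
        pairs = find_orthologs(prot, dict(prot))
        assert all(p.reciprocal for p in pairs)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {
            (k, k) for k in prot
        }

    def test_planted_orthologs_recovered_among_decoys(self, small_study):
        species, manifest, _ = small_study
        a, b = species["speciesA"], species["speciesB"]
        sub_a = dict(sorted(a.proteins.items())[:15])
        truth = {
            p["gene_a"]: p["gene_b"]
            for p in manifest.ortholog_pairs
            if p["gene_a"] in sub_a
        }
        sub_b = {truth[k]: b.proteins[truth[k]] for k in sub_a}
        # decoys: unrelated proteins from elsewhere in species B
        for gid, seq in sorted(b.proteins.items())[-10:]:
            sub_b.setdefault(gid, seq)
        pairs = find_orthologs(sub_a, sub_b)
        recovered = {p.gene_a: p.gene_b for p in pairs if p.reciprocal}
        assert recovered == truth

    def test_paralog_duplicate_leaves_one_reciprocal_partner(self):
        base = "MKVLITGAGGFIGSALVKELV"
        prot_a = {"a1": base}
        prot_b = {"b1": base, "b2": base[:-3] + "WWW"}  # weaker paralog
        pairs = find_orthologs(prot_a, prot_b)
        rec = [p for p in pairs if p.reciprocal]
        assert [(p.gene_a, p.gene_b) for p in rec] == [("a1", "b1")]

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            find_orthologs({}, {"p": "MKV"})


class TestCascade:
    def test_counts_are_monotone_and_bounded(self, small_study):
        species, manifest, _ = small_study
        a, b = species["speciesA"], species["speciesB"]
        genes_a = {g.gene_id: g for g in a.genes}
        genes_b = {g.gene_id: g for g in b.genes}
        pair_diffs, pair_cds = {}, {}
        for p in manifest.ortholog_pairs:
            key = (p["gene_a"], p["gene_b"])
            cds_a = a.transcripts[key[0]]
            cds_b = b.transcripts[key[1]]
            diffs = extract_diffs(global_align(cds_a, cds_b))
            diffs = map_diffs_to_repeats(
                diffs,
                TranscriptMap(genes_a[key[0]]),
                TranscriptMap(genes_b[key[1]]),
                a.repeats,
                b.repeats,
            )
            pair_diffs[key] = diffs
            pair_cds[key] = (cds_a, cds_b)
        report = run_cascade(pair_diffs, pair_cds)
        assert report.total_pairs == len(manifest.ortholog_pairs)
        assert report.pairs_with_repeat_indels <= report.total_pairs
        assert report.pairs_with_aa_changes <= report.total_pairs
        assert report.pairs_with_structure_candidates <= report.pairs_with_aa_changes
        planted = sum(1 for p in manifest.ortholog_pairs if p["exonized"])
        assert report.pairs_with_repeat_indels == planted
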