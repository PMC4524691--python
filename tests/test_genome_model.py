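"""Coordinate model, format round-trips, and interval arithmetic."""

import numpy as np
import pytest

from repeatscape.genome_model import (
    AssemblyIndex,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    ValidationError,
    covered_bases,
    flank,
    merge_intervals,
    read_bed,
    read_gff3_genes,
    read_repeatmasker_out,
    repeat_class_for_superfamily,
    write_bed,
    write_gff3_genes,
    write_repeatmasker_out,
)


def per_base_union(intervals, chrom_len=100_000):
    """Independent oracle: boolean-array union of covered bases."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return int(mask.sum())


class TestGenomicInterval:
    def test_rejects_inverted_and_empty_spans(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 5)

    def test_overlap_bp_is_symmetric_clipped_intersection(self):
        a = GenomicInterval("chr1", 0, 50)
        b = GenomicInterval("chr1", 10, 20)
        assert a.overlap_bp(b) == b.overlap_bp(a) == 10
        assert a.overlap_bp(GenomicInterval("chr2", 0, 50)) == 0


@pytest.mark.parametrize(
    "superfamily,expected",
    [
        ("LTR/Gypsy", "Retrotransposon"),
        ("DNA/TcMar-Stowaway", "DNA transposon"),
        ("RC/Helitron", "DNA transposon"),
        ("SINE/tRNA", "Retrotransposon"),
        ("Unknown", "Uncategorized"),
        ("rRNA", "Other"),
        ("DNA/CMC-EnSpm?", "DNA transposon"),
    ],
)
def test_superfamily_maps_to_exactly_one_class(superfamily, expected):
    assert repeat_class_for_superfamily(superfamily) == expected


class TestRepeatMaskerOut:
    def test_one_based_inclusive_converts_to_half_open(self, tmp_path):
        f = RepeatFeature(
            GenomicInterval("chr1", 100, 200, "+"), "fam1", "LTR/Gypsy"
        )
        path = tmp_path / "r.out"
        write_repeatmasker_out([f], path)
        # the emitted begin column is 1-based: 101..200 spans 100 bases
        line = [l for l in path.read_text().splitlines() if "fam1" in l][0]
        assert line.split()[5:7] == ["101", "200"]
        (back,) = read_repeatmasker_out(path)
        assert (back.interval.start, back.interval.end) == (100, 200)
        assert len(back.interval) == 100

    def test_c_orientation_means_minus_strand(self, tmp_path):
        f = RepeatFeature(
            GenomicInterval("chr1", 5, 25, "-"), "fam1", "DNA/Harbinger"
        )
        path = tmp_path / "r.out"
        write_repeatmasker_out([f], path)
        assert " C " in [l for l in path.read_text().splitlines() if "fam1" in l][0]
        (back,) = read_repeatmasker_out(path)
        assert back.interval.strand == "-"

    def test_round_trip_preserves_all_fields(self, tmp_path, rng):
        feats = []
        for i in range(50):
            start = int(rng.integers(0, 9000))
            length = int(rng.integers(50, 900))
            feats.append(
                RepeatFeature(
                    GenomicInterval(
                        f"chr{int(rng.integers(1, 4))}",
                        start,
                        start + length,
                        "+" if rng.random() < 0.5 else "-",
                    ),
                    family_id=f"fam{i}",
                    superfamily="LTR/Copia",
                    divergence=round(float(rng.uniform(0, 0.4)), 3),
                )
            )
        path = tmp_path / "rt.out"
        write_repeatmasker_out(feats, path)
        back = read_repeatmasker_out(path)
        assert len(back) == 50
        for orig, rec in zip(feats, back):
            assert rec.interval == orig.interval
            assert rec.family_id == orig.family_id
            assert rec.superfamily == orig.superfamily
            assert rec.divergence == pytest.approx(orig.divergence, abs=5e-4)

    def test_out_of_assembly_coordinates_rejected(self, tmp_path):
        f = RepeatFeature(GenomicInterval("chr1", 0, 500), "f", "LTR/Gypsy")
        path = tmp_path / "r.out"
        write_repeatmasker_out([f], path)
        with pytest.raises(ValidationError):
            read_repeatmasker_out(path, assembly=AssemblyIndex({"chr1": 400}))


class TestGff3Genes:
    def test_introns_are_span_minus_exons(self, tmp_path):
        gene = GeneModel(
            "g1",
            GenomicInterval("chr1", 1000, 2000, "+"),
            (
                GenomicInterval("chr1", 1000, 1200, "+"),
                GenomicInterval("chr1", 1500, 2000, "+"),
            ),
        )
        path = tmp_path / "g.gff3"
        write_gff3_genes([gene], path)
        (back,) = read_gff3_genes(path)
        assert [(iv.start, iv.end) for iv in back.introns] == [(1200, 1500)]

    def test_minus_strand_exons_ordered_descending_in_transcript_order(self):
        gene = GeneModel(
            "g1",
            GenomicInterval("chr1", 0, 1000, "-"),
            (
                GenomicInterval("chr1", 0, 200, "-"),
                GenomicInterval("chr1", 500, 1000, "-"),
            ),
        )
        starts = [iv.start for iv in gene.exons_5to3]
        assert starts == sorted(starts, reverse=True)

    def test_simulated_genes_round_trip_with_planted_intron_count(
        self, tmp_path, small_study
    ):
        species, manifest, _ = small_study
        data = species["speciesA"]
        path = tmp_path / "sim.gff3"
        write_gff3_genes(data.genes[:10], path)
        back = read_gff3_genes(path)
        assert len(back) == 10
        truth = {g["gene_id"]: g for g in manifest.genes["speciesA"]}
        for g in back:
            assert len(g.introns) == len(truth[g.gene_id]["introns"])

    def test_exon_outside_gene_span_rejected(self):
        with pytest.raises(ValidationError):
            GeneModel(
                "g1",
                GenomicInterval("chr1", 100, 200),
                (GenomicInterval("chr1", 50, 150),),
            )


class TestIntervalArithmetic:
    def test_merge_unions_overlapping_and_abutting(self):
        out = merge_intervals(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 20)]
        )
        assert [(iv.start, iv.end) for iv in out] == [(0, 20)]
        out = merge_intervals(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20)]
        )
        assert [(iv.start, iv.end) for iv in out] == [(0, 20)]
        assert merge_intervals([]) == []

    def test_merge_matches_per_base_oracle_and_is_idempotent(self, rng):
        ivs = []
        for _ in range(200):
            start = int(rng.integers(0, 9_900))
            ivs.append(
                GenomicInterval("c", start, start + int(rng.integers(1, 400)))
            )
        merged = merge_intervals(ivs)
        assert sum(len(iv) for iv in merged) == per_base_union(ivs, 11_000)
        assert merge_intervals(merged) == merged
        # pairwise disjoint and sorted
        for left, right in zip(merged, merged[1:]):
            assert left.end < right.start

    def test_covered_bases_counts_union_not_sum(self):
        feats = [GenomicInterval("c", 0, 50), GenomicInterval("c", 10, 20)]
        assert covered_bases(feats) == 50
        assert covered_bases([GenomicInterval("c", 0, 100)]) == 100
        region = GenomicInterval("c", 25, 75)
        assert covered_bases(feats, region=region) == 25

    def test_covered_bases_bounded_by_region_and_total(self, rng):
        feats = [
            GenomicInterval("c", int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, 5000, 50), rng.integers(1, 300, 50)
            )
        ]
        region = GenomicInterval("c", 1000, 3000)
        cov = covered_bases(feats, region=region)
        assert cov <= len(region)
        assert cov <= sum(len(f) for f in feats)


class TestFlank:
    def _gene(self, start, end, strand):
        return GeneModel(
            "g", GenomicInterval("chr1", start, end, strand),
            (GenomicInterval("chr1", start, end, strand),),
        )

    def test_plus_strand_window_precedes_gene_start(self):
        w = flank(self._gene(10_000, 12_000, "+"), 5000)
        assert (w.start, w.end) == (5000, 10_000)

    def test_minus_strand_window_mirrors_past_gene_end(self):
        w = flank(self._gene(8_000, 10_000, "-"), 2000)
        assert (w.start, w.end) == (10_000, 12_000)

    def test_edge_clipping(self):
        w = flank(self._gene(1000, 2000, "+"), 5000)
        assert (w.start, w.end) == (0, 1000)
        assert flank(self._gene(0, 1000, "+"), 5000) is None
        asm = AssemblyIndex({"chr1": 10_500})
        w = flank(self._gene(8_000, 10_000, "-"), 2000, asm)
        assert (w.start, w.end) == (10_000, 10_500)


def test_bed_round_trip(tmp_path, rng):
    ivs = [
        GenomicInterval(
            "chr1", int(s), int(s) + int(l), "+" if p < 0.5 else "-"
        )
        for s, l, p in zip(
            rng.integers(0, 5000, 20), rng.integers(1, 100, 20), rng.random(20)
        )
    ]
    path = tmp_path / "x.bed"
    write_bed(ivs, path)
    assert read_bed(path) == ivs
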