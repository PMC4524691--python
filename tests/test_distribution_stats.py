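"""Coverage arithmetic, partitions vs per-base oracle, and the statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from repeatscape.distribution_stats import (
    chromosome_coverage,
    enrichment_binomial,
    genic_intergenic_densities,
    intergenic_enrichment_ttest,
    null_overlap_probability,
    partition_exon_intron,
    partition_genic,
    pct_round2,
    pearson_with_t,
)
from repeatscape.genome_model import (
    AssemblyIndex,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    flank,
    merge_intervals,
)


def _repeat(chrom, start, end, superfamily="LTR/Gypsy"):
    return RepeatFeature(
        GenomicInterval(chrom, start, end), f"f{start}", superfamily
    )


class TestChromosomeCoverage:
    @pytest.mark.parametrize(
        "repeat_bp,chrom_bp,pct",
        [
            (42_301_100, 65_486_253, 64.60),  # most repeat-rich chromosome
            (395_513_917, 810_654_046, 48.79),  # potato genome total
            (470_312_762, 781_666_411, 60.17),  # tomato genome total
            (33_415_365, 85_736_662, 38.97),
        ],
    )
    def test_published_percentages_reproduce(self, repeat_bp, chrom_bp, pct):
        asm = AssemblyIndex({"chr": chrom_bp})
        rows = chromosome_coverage(
            [GenomicInterval("chr", 0, repeat_bp)], asm
        )
        assert rows[0].pct == pct

    def test_no_repeats_gives_zero_everywhere(self):
        asm = AssemblyIndex({"chr1": 1000, "chr2": 500})
        rows = chromosome_coverage([], asm)
        assert [r.pct for r in rows] == [0.0, 0.0, 0.0]

    def test_total_row_sums_bases_before_dividing(self):
        asm = AssemblyIndex({"chr1": 100, "chr2": 300})
        rows = chromosome_coverage(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100)],
            asm,
        )
        total = rows[-1]
        assert (total.repeat_bp, total.chrom_bp, total.pct) == (200, 400, 50.0)

    def test_overlapping_copies_counted_once(self):
        asm = AssemblyIndex({"c": 100})
        rows = chromosome_coverage(
            [_repeat("c", 0, 60), _repeat("c", 40, 80)], asm
        )
        assert rows[0].repeat_bp == 80


class TestPartitions:
    def _gene(self, gene_id, chrom, start, end, exons=None, strand="+"):
        exons = exons or [(start, end)]
        return GeneModel(
            gene_id,
            GenomicInterval(chrom, start, end, strand),
            tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        )

    def test_gene_inside_repeat_is_associated_and_repeat_genic(self):
        asm = AssemblyIndex({"c": 50_000})
        gene = self._gene("g1", "c", 20_000, 21_000)
        rep = _repeat("c", 19_000, 23_000)
        parts, assoc = partition_genic([rep], [gene], asm)
        assert parts["LTR/Gypsy"].n_genic == 1
        assert assoc["g1"]

    def test_upstream_only_overlap_counts_as_genic(self):
        asm = AssemblyIndex({"c": 50_000})
        gene = self._gene("g1", "c", 20_000, 21_000)
        rep = _repeat("c", 16_000, 17_000)  # inside the 5 kb window
        parts, assoc = partition_genic([rep], [gene], asm)
        assert parts["LTR/Gypsy"].n_genic == 1
        assert parts["LTR/Gypsy"].n_upstream == 1
        assert parts["LTR/Gypsy"].n_genebody == 0
        assert assoc["g1"]

    def test_distant_repeat_is_intergenic(self):
        asm = AssemblyIndex({"c": 50_000})
        gene = self._gene("g1", "c", 20_000, 21_000)
        parts, assoc = partition_genic([_repeat("c", 1000, 1500)], [gene], asm)
        assert parts["LTR/Gypsy"].n_intergenic == 1
        assert not assoc["g1"]

    def test_exclusive_exon_intron_rule(self):
        gene = self._gene(
            "g1", "c", 1000, 2000, exons=[(1000, 1300), (1700, 2000)]
        )
        wholly_exonic = _repeat("c", 1100, 1200)
        wholly_intronic = _repeat("c", 1400, 1500)
        straddler = _repeat("c", 1250, 1350)
        parts = partition_exon_intron(
            [wholly_exonic, wholly_intronic, straddler], [gene]
        )
        assert parts["LTR/Gypsy"].n_exonic == 1
        assert parts["LTR/Gypsy"].n_intronic == 1

    def test_flags_match_per_base_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            chrom_len = 30_000
            asm = AssemblyIndex({"c": chrom_len})
            genes = []
            pos = 5500
            gi = 0
            while pos < chrom_len - 2000:
                end = pos + int(rng.integers(300, 1200))
                genes.append(self._gene(f"g{gi}", "c", pos, end))
                pos = end + int(rng.integers(5500, 7000))
                gi += 1
            repeats = [
                _repeat("c", int(s), int(s) + int(l))
                for s, l in zip(
                    rng.integers(0, chrom_len - 600, 60),
                    rng.integers(50, 600, 60),
                )
            ]
            parts, assoc = partition_genic(repeats, genes, asm)
            genic_mask = np.zeros(chrom_len, dtype=bool)
            for g in genes:
                genic_mask[g.interval.start : g.interval.end] = True
                w = flank(g, 5000, asm)
                if w:
                    genic_mask[w.start : w.end] = True
            expected_genic = sum(
                bool(genic_mask[r.interval.start : r.interval.end].any())
                for r in repeats
            )
            got_genic = sum(p.n_genic for p in parts.values())
            assert got_genic == expected_genic
            rep_mask = np.zeros(chrom_len, dtype=bool)
            for r in repeats:
                rep_mask[r.interval.start : r.interval.end] = True
            for g in genes:
                w = flank(g, 5000, asm)
                expect = bool(rep_mask[g.interval.start : g.interval.end].any())
                if w is not None:
                    expect = expect or bool(rep_mask[w.start : w.end].any())
                assert assoc[g.gene_id] == expect

    def test_simulated_partition_recovers_planted_counts(self, small_study):
        species, manifest, _ = small_study
        data = species["speciesA"]
        parts, _ = partition_genic(data.repeats, data.genes, data.assembly)
        assert sum(p.n_genic + p.n_intergenic for p in parts.values()) == len(
            data.repeats
        )


class TestPearsonWithT:
    @pytest.mark.parametrize(
        "r,t",  # published correlation/t-statistic pairs, n = 13 chromosomes
        [
            (0.9620917122, 11.7000058689),
            (0.9544544177, 10.6100060709),
            (-0.9252673099, 8.0902647726),
            (0.1577892178, 0.5299666206),
            (-0.0200565794, 0.0665335318),
        ],
    )
    def test_published_t_statistics_reproduce_from_r(self, r, t):
        # synthesize 13 observations whose sample correlation is exactly r
        n = 13
        x = np.arange(n, dtype=float)
        x = (x - x.mean()) / x.std()
        z = np.sin(np.arange(n))  # any vector; orthogonalized below
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= np.sqrt(z @ z / n)
        y = r * x + math.sqrt(1 - r * r) * z
        res = pearson_with_t(x, y)
        assert res.r == pytest.approx(r, abs=1e-9)
        assert res.t_stat == pytest.approx(t, abs=5e-7)
        assert res.t_stat >= 0  # magnitudes even for negative correlations

    def test_perfect_correlation_flagged_limit(self):
        res = pearson_with_t([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert res.r == pytest.approx(1.0)
        assert math.isinf(res.t_stat)
        assert res.p == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_t([1, 1, 1], [1, 2, 3])

    def test_p_value_matches_t_distribution(self):
        res = pearson_with_t([1, 2, 3, 4, 5.0], [1.1, 2.3, 2.8, 4.2, 4.9])
        expected = 2 * stats.t.sf(res.t_stat, df=3)
        assert res.p == pytest.approx(expected)


class TestEnrichmentBinomial:
    def test_closed_forms(self):
        assert enrichment_binomial(10, 10, 0.5) == pytest.approx(2**-10)
        assert enrichment_binomial(0, 10, 0.5) == 1.0

    def test_matches_direct_summation(self):
        k, n, p0 = 80, 100, 0.5
        expected = sum(
            math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
        )
        assert enrichment_binomial(k, n, p0) == pytest.approx(expected, rel=1e-12)

    def test_invalid_null_probability_rejected(self):
        with pytest.raises(ValueError):
            enrichment_binomial(1, 10, 0.0)
        with pytest.raises(ValueError):
            enrichment_binomial(1, 10, 1.0)


class TestNullOverlapProbability:
    def test_extremes_are_clamped(self):
        asm = AssemblyIndex({"c": 10_000})
        eps = 1e-9
        assert null_overlap_probability([], 100, asm) == eps
        whole = [GenomicInterval("c", 0, 10_000)]
        assert null_overlap_probability(whole, 100, asm) == 1 - eps

    def test_matches_exhaustive_placement_enumeration(self):
        asm = AssemblyIndex({"c": 10_000})
        blocks = merge_intervals(
            [GenomicInterval("c", 2000, 2500), GenomicInterval("c", 7000, 7100)]
        )
        L = 300
        hits = 0
        n_starts = 10_000 - L + 1
        for s in range(n_starts):
            if any(s < b.end and b.start < s + L for b in blocks):
                hits += 1
        assert null_overlap_probability(blocks, L, asm) == pytest.approx(
            hits / n_starts
        )


class TestIntergenicTtest:
    def test_identical_vectors_give_t0_p1(self):
        t, p = intergenic_enrichment_ttest([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == 0.0
        assert p == 1.0

    def test_matches_textbook_paired_formula(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 10, 12)
        b = a + rng.normal(1.0, 0.5, 12)
        t, p = intergenic_enrichment_ttest(a, b)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), df=len(d) - 1)
        assert t == pytest.approx(t_manual, abs=1e-12)
        assert p == pytest.approx(p_manual, abs=1e-12)

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError):
            intergenic_enrichment_ttest([1.0, 2.0], [2.0, 3.0])


def test_pct_round2_uses_round_half_up():
    assert pct_round2(125, 1000) == 12.5
    assert pct_round2(1005, 100000) == 1.01  # 1.005 rounds up, not to even
    assert pct_round2(357_893, 1_061_377) == 33.72
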