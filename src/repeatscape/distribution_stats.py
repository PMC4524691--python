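"""Repeat-distribution statistics: coverage, partitions, correlation, enrichment.

Chromosome coverage uses merged repeat intervals (union of bases), per-
element partitions use raw elements.  "Genic" here means the gene body
plus a 5 kb upstream window, the convention used throughout the repeat-
gene association analyses.  Percentages are reported with round-half-up
at 2 decimals, matching how such tables are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from repeatscape.genome_model import (
    AssemblyIndex,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    covered_bases,
    flank,
    merge_intervals,
)

__all__ = [
    "ChromCoverage",
    "PartitionCounts",
    "CorrelationResult",
    "chromosome_coverage",
    "partition_genic",
    "partition_exon_intron",
    "pearson_with_t",
    "enrichment_binomial",
    "null_overlap_probability",
    "intergenic_enrichment_ttest",
    "pct_round2",
]


def pct_round2(numerator: float, denominator: float) -> float:
    """100*num/den with round-half-up at 2 decimals (table presentation)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChromCoverage:
    chrom: str
    repeat_bp: int
    chrom_bp: int

    @property
    def pct(self) -> float:
        return pct_round2(self.repeat_bp, self.chrom_bp)


def chromosome_coverage(
    repeats: Iterable[RepeatFeature | GenomicInterval],
    assembly: AssemblyIndex,
) -> list[ChromCoverage]:
    """Merged repeat coverage per chromosome plus a genome Total row.

    The Total row sums base counts across chromosomes before dividing,
    so it is not the mean of per-chromosome percentages.
    """
    ivs = [r.interval if isinstance(r, RepeatFeature) else r for r in repeats]
    for iv in ivs:
        assembly.validate(iv)
    merged = merge_intervals(ivs) if ivs else []
    per_chrom: dict[str, int] = {c: 0 for c in assembly.lengths}
    for iv in merged:
        per_chrom[iv.chrom] += len(iv)
    rows = [
        ChromCoverage(chrom, per_chrom[chrom], length)
        for chrom, length in assembly.lengths.items()
    ]
    rows.append(
        ChromCoverage(
            "Total", sum(per_chrom.values()), assembly.total_length
        )
    )
    return rows


@dataclass
class PartitionCounts:
    superfamily: str
    n_genic: int = 0
    n_intergenic: int = 0
    n_upstream: int = 0
    n_genebody: int = 0
    n_exonic: int = 0
    n_intronic: int = 0


def _build_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _tree_overlaps(trees: dict[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


def partition_genic(
    repeats: Sequence[RepeatFeature],
    genes: Sequence[GeneModel],
    assembly: AssemblyIndex | None = None,
    upstream_bp: int = 5000,
) -> tuple[dict[str, PartitionCounts], dict[str, bool]]:
    """Classify every repeat element as genic or intergenic.

    An element is genic iff it overlaps >=1 bp of any gene body or its
    5 kb upstream window; a gene is "repeat-associated" iff >=1 repeat
    overlaps its body or window.  Also tallies, among genic elements,
    overlap with upstream windows vs gene bodies (an element touching
    both counts in both).

    Returns (per-superfamily counts, per-gene associated flags).
    """
    upstream = {}
    for g in genes:
        w = flank(g, upstream_bp, assembly)
        if w is not None:
            upstream[g.gene_id] = w
    body_trees = _build_trees(g.interval for g in genes)
    up_trees = _build_trees(upstream.values())

    counts: dict[str, PartitionCounts] = {}
    for rep in repeats:
        pc = counts.setdefault(rep.superfamily, PartitionCounts(rep.superfamily))
        in_body = _tree_overlaps(body_trees, rep.interval)
        in_up = _tree_overlaps(up_trees, rep.interval)
        if in_body or in_up:
            pc.n_genic += 1
            if in_up:
                pc.n_upstream += 1
            if in_body:
                pc.n_genebody += 1
        else:
            pc.n_intergenic += 1

    rep_trees = _build_trees(r.interval for r in repeats)
    associated = {}
    for g in genes:
        hit = _tree_overlaps(rep_trees, g.interval)
        if not hit and g.gene_id in upstream:
            hit = _tree_overlaps(rep_trees, upstream[g.gene_id])
        associated[g.gene_id] = hit
    return counts, associated


def partition_exon_intron(
    repeats: Sequence[RepeatFeature],
    genes: Sequence[GeneModel],
) -> dict[str, PartitionCounts]:
    """Count elements overlapping exclusively exons or exclusively introns.

    An element is exonic iff every base it shares with gene bodies falls
    in exons; intronic likewise; elements straddling an exon-intron
    junction (or touching no gene) fall in neither bucket.
    """
    exon_trees = _build_trees(e for g in genes for e in g.exons)
    intron_trees = _build_trees(i for g in genes for i in g.introns)
    gene_trees = _build_trees(g.interval for g in genes)
    exon_merged = merge_intervals([e for g in genes for e in g.exons]) or []
    intron_merged = merge_intervals([i for g in genes for i in g.introns]) or []
    gene_merged = merge_intervals([g.interval for g in genes]) or []

    counts: dict[str, PartitionCounts] = {}
    for rep in repeats:
        pc = counts.setdefault(rep.superfamily, PartitionCounts(rep.superfamily))
        iv = rep.interval
        if not _tree_overlaps(gene_trees, iv):
            continue
        genic_bp = sum(iv.overlap_bp(m) for m in gene_merged)
        exon_bp = sum(iv.overlap_bp(m) for m in exon_merged)
        intron_bp = sum(iv.overlap_bp(m) for m in intron_merged)
        touches_exon = _tree_overlaps(exon_trees, iv)
        touches_intron = _tree_overlaps(intron_trees, iv)
        if touches_exon and not touches_intron and exon_bp == genic_bp:
            pc.n_exonic += 1
        elif touches_intron and not touches_exon and intron_bp == genic_bp:
            pc.n_intronic += 1
    return counts


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p: float


def pearson_with_t(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with its t-test: t = |r| sqrt(n-2)/sqrt(1-r^2), df = n-2.

    The t statistic is reported as a magnitude (negative correlations
    carry a positive t), with a two-sided p from Student's t.  Perfect
    correlation yields t = inf and p = 0 (flagged limit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, n=n, t_stat=float("inf"), p=0.0)
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(t, df=n - 2)
    return CorrelationResult(r=r, n=n, t_stat=float(t), p=float(p))


def enrichment_binomial(k_success: int, n_trials: int, p0: float) -> float:
    """Exact one-sided binomial tail P(X >= k | n, p0)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if not 0 <= k_success <= n_trials:
        raise ValueError("require 0 <= k <= n")
    if k_success == 0:
        return 1.0
    return float(stats.binom.sf(k_success - 1, n_trials, p0))


def null_overlap_probability(
    merged_repeats: Sequence[GenomicInterval],
    feature_len: int,
    assembly: AssemblyIndex,
    eps: float = 1e-9,
) -> float:
    """Probability a uniformly placed interval overlaps >=1 repeat block.

    Exact under the discrete placement model: the feature start is
    uniform over the valid starts of each chromosome (weighted by the
    number of starts) and overlap means >=1 shared base.  Computed
    analytically from the merged blocks; clamped to (eps, 1-eps) so the
    value is usable as a binomial null.
    """
    if feature_len <= 0:
        raise ValueError("feature_len must be positive")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged_repeats:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    total_starts = 0
    hit_starts = 0
    for chrom, length in assembly.lengths.items():
        n_starts = length - feature_len + 1
        if n_starts <= 0:
            continue
        total_starts += n_starts
        spans = []
        for iv in by_chrom.get(chrom, []):
            # starts s with [s, s+L) overlapping [b, e): s in [b-L+1, e-1]
            s0 = max(0, iv.start - feature_len + 1)
            s1 = min(n_starts - 1, iv.end - 1)
            if s0 <= s1:
                spans.append(GenomicInterval(chrom, s0, s1 + 1))
        hit_starts += sum(len(iv) for iv in merge_intervals(spans)) if spans else 0
    if total_starts == 0:
        raise ValueError("feature longer than every chromosome")
    p0 = hit_starts / total_starts
    return min(max(p0, eps), 1 - eps)


def intergenic_enrichment_ttest(
    per_family_genic_density: Sequence[float],
    per_family_intergenic_density: Sequence[float],
) -> tuple[float, float]:
    """Paired two-sided t-test on per-family region densities.

    Operands are length-normalized element densities (elements per Mb of
    genic vs intergenic sequence) paired across repeat superfamilies, so
    unequal region sizes do not masquerade as enrichment.
    """
    a = np.asarray(per_family_genic_density, dtype=float)
    b = np.asarray(per_family_intergenic_density, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired superfamily densities")
    if np.all(a == b):  # degenerate: no differences at all
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def genic_intergenic_densities(
    partition: dict[str, PartitionCounts],
    genes: Sequence[GeneModel],
    assembly: AssemblyIndex,
    upstream_bp: int = 5000,
) -> tuple[list[float], list[float]]:
    """Per-superfamily element densities (per Mb) in genic vs intergenic space."""
    windows = [g.interval for g in genes]
    for g in genes:
        w = flank(g, upstream_bp, assembly)
        if w is not None:
            windows.append(w)
    genic_bp = covered_bases(windows)
    intergenic_bp = assembly.total_length - genic_bp
    if genic_bp == 0 or intergenic_bp <= 0:
        raise ValueError("degenerate genic/intergenic partition")
    genic_d, intergenic_d = [], []
    for pc in partition.values():
        genic_d.append(pc.n_genic / (genic_bp / 1e6))
        intergenic_d.append(pc.n_intergenic / (intergenic_bp / 1e6))
    return genic_d, intergenic_d
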