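"""Pre-miRNA placement and eroded-repeat footprint detection.

Pre-miRNA hairpins are placed on the genome by exhaustive substitution-
tolerant matching (both strands).  Each locus's +/-2 kb flank window is
tested for repeat overlap, with an exact binomial enrichment test against
uniform placement.  For orthologous pre-miRNA pairs, the flanking regions
(2 kb up + hairpin + 2 kb down) are compared by iterative local alignment
with masking; conserved motifs >=5 bp that overlap a repeat in at least
one species are footprint candidates, and pairs whose motifs keep the
same relative order and orientation in both species are strong candidates
for an eroded repetitive-element origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from repeatscape import alignment
from repeatscape.alignment import alignment_identity, local_align_best
from repeatscape.annotation_consensus import reverse_complement
from repeatscape.distribution_stats import (
    _build_trees,
    _tree_overlaps,
    enrichment_binomial,
    null_overlap_probability,
)
from repeatscape.genome_model import (
    AssemblyIndex,
    GenomicInterval,
    RepeatFeature,
    merge_intervals,
)

__all__ = [
    "MirnaLocus",
    "FootprintMotif",
    "FootprintCall",
    "map_premirnas",
    "flank_repeat_overlap",
    "pair_orthologous_mirnas",
    "flank_region",
    "call_footprints",
    "mirna_family",
]


@dataclass(frozen=True)
class MirnaLocus:
    mirna_id: str
    interval: GenomicInterval
    copy_index: int
    mismatches: int = 0


@dataclass(frozen=True)
class FootprintMotif:
    motif_seq: str
    pos_a: int  # offset within species-a flank region
    pos_b: int
    strand_consistent: bool = True
    in_repeat_a: bool = False
    in_repeat_b: bool = False

    @property
    def length(self) -> int:
        return len(self.motif_seq)


@dataclass(frozen=True)
class FootprintCall:
    pair_id: str
    motifs: tuple[FootprintMotif, ...]
    species_class: str  # both | a_only | b_only | none
    strength: str  # none | candidate | strong


_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _hamming_positions(genome: np.ndarray, pattern: np.ndarray, k: int) -> np.ndarray:
    """Start offsets where pattern matches with <= k substitutions."""
    g, m = len(genome), len(pattern)
    if g < m:
        return np.empty(0, dtype=int)
    mism = np.zeros(g - m + 1, dtype=np.int32)
    for j in range(m):
        mism += genome[j : g - m + 1 + j] != pattern[j]
    return np.nonzero(mism <= k)[0]


def map_premirnas(
    premirnas: dict[str, str],
    genome: dict[str, str],
    max_mismatch: int = 1,
) -> list[MirnaLocus]:
    """Every genomic placement of each hairpin with <= max_mismatch substitutions.

    Both strands are searched; a multi-locus miRNA yields one record per
    placement, sharing its mirna_id with distinct copy indices.
    """
    loci: list[MirnaLocus] = []
    encoded = {chrom: _encode(seq) for chrom, seq in genome.items()}
    for mirna_id, seq in sorted(premirnas.items()):
        placements = []
        for strand, pat in (("+", seq), ("-", reverse_complement(seq))):
            enc = _encode(pat)
            for chrom in sorted(encoded):
                for start in _hamming_positions(encoded[chrom], enc, max_mismatch):
                    window = genome[chrom][start : start + len(seq)]
                    mism = sum(1 for x, y in zip(window, pat) if x != y)
                    placements.append(
                        (chrom, int(start), strand, mism)
                    )
        for idx, (chrom, start, strand, mism) in enumerate(sorted(placements)):
            loci.append(
                MirnaLocus(
                    mirna_id,
                    GenomicInterval(chrom, start, start + len(seq), strand),
                    copy_index=idx,
                    mismatches=mism,
                )
            )
    return loci


def flank_region(
    locus: MirnaLocus, assembly: AssemblyIndex, flank_bp: int = 2000
) -> GenomicInterval:
    """The +/-flank_bp window around a locus, clipped at chromosome ends."""
    iv = locus.interval
    return GenomicInterval(
        iv.chrom,
        max(0, iv.start - flank_bp),
        min(assembly.lengths[iv.chrom], iv.end + flank_bp),
        iv.strand,
    )


def flank_repeat_overlap(
    loci: list[MirnaLocus],
    repeats: list[RepeatFeature],
    assembly: AssemblyIndex,
    flank_bp: int = 2000,
) -> tuple[dict[tuple[str, int], bool], float]:
    """Per-locus repeat-overlap flags for the +/-2 kb window, plus enrichment p.

    The binomial null is the exact probability that a uniformly placed
    window of the typical (mean) window length overlaps >=1 merged repeat
    block.  With no repeats anywhere the test degenerates to p = 1.
    """
    trees = _build_trees(r.interval for r in repeats)
    flags = {}
    window_lens = []
    for locus in loci:
        window = flank_region(locus, assembly, flank_bp)
        window_lens.append(len(window))
        flags[(locus.mirna_id, locus.copy_index)] = _tree_overlaps(trees, window)
    if not loci or not repeats:
        return flags, 1.0
    merged = merge_intervals([r.interval for r in repeats])
    feature_len = int(round(float(np.mean(window_lens))))
    p0 = null_overlap_probability(merged, feature_len, assembly)
    k = sum(flags.values())
    p = enrichment_binomial(k, len(loci), p0)
    return flags, p


_FAMILY_RE = re.compile(r"(mir|miR|MIR)[-]?(\d+)", re.IGNORECASE)


def mirna_family(name: str) -> str | None:
    """Family stem of a miRBase-style name: stu-miR156a-5p -> MIR156."""
    m = _FAMILY_RE.search(name)
    if m is None:
        return None
    return f"MIR{m.group(2)}"


def pair_orthologous_mirnas(
    set_a: dict[str, str],
    set_b: dict[str, str],
    min_identity: float = 0.7,
) -> list[tuple[str, str, float]]:
    """Orthologous pre-miRNA pairs: same family stem + reciprocal best match.

    Within each shared family stem, candidates are ranked by local-
    alignment identity; a pair is emitted when both members pick each
    other as best partner and identity >= min_identity.
    """
    fams_a: dict[str, list[str]] = {}
    for name in sorted(set_a):
        fam = mirna_family(name)
        if fam:
            fams_a.setdefault(fam, []).append(name)
    fams_b: dict[str, list[str]] = {}
    for name in sorted(set_b):
        fam = mirna_family(name)
        if fam:
            fams_b.setdefault(fam, []).append(name)

    pairs = []
    for fam in sorted(set(fams_a) & set(fams_b)):
        idents: dict[tuple[str, str], float] = {}
        for a in fams_a[fam]:
            for b in fams_b[fam]:
                hit = local_align_best(set_a[a], set_b[b])
                idents[(a, b)] = alignment_identity(hit) if hit else 0.0
        def best(cands: list[str], score) -> str:
            # highest identity; ties -> lexicographically first name
            return max(sorted(cands), key=lambda n: (score(n), [-ord(c) for c in n]))

        for a in fams_a[fam]:
            best_b = best(fams_b[fam], lambda b: idents[(a, b)])
            best_a = best(fams_a[fam], lambda x: idents[(x, best_b)])
            ident = idents[(a, best_b)]
            if best_a == a and ident >= min_identity:
                pairs.append((a, best_b, round(ident, 4)))
    return pairs


def call_footprints(
    pair_id: str,
    locus_a: MirnaLocus,
    locus_b: MirnaLocus,
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    repeats_a: list[RepeatFeature],
    repeats_b: list[RepeatFeature],
    assembly_a: AssemblyIndex,
    assembly_b: AssemblyIndex,
    flank_bp: int = 2000,
    min_score: float = 70.0,
    min_motif_len: int = 5,
) -> FootprintCall:
    """Footprint call for one orthologous locus pair.

    Conserved motifs come from iterative masked local alignment of the
    two flank regions; motifs >= min_motif_len bp overlapping a repeat in
    >=1 species are kept.  The pair is classed by which species carries
    the repeat overlap (both / a_only / b_only / none), and called strong
    when >=2 kept motifs appear in the same relative order (and on
    consistently the same strand) in both species.
    """
    region_a = flank_region(locus_a, assembly_a, flank_bp)
    region_b = flank_region(locus_b, assembly_b, flank_bp)
    seq_a = genome_a[region_a.chrom][region_a.start : region_a.end]
    seq_b = genome_b[region_b.chrom][region_b.start : region_b.end]
    raw = alignment.chained_local_alignments(
        seq_a, seq_b, min_score=min_score, min_motif_len=min_motif_len
    )
    trees_a = _build_trees(r.interval for r in repeats_a)
    trees_b = _build_trees(r.interval for r in repeats_b)
    motifs = []
    for off_a, off_b, motif_seq in raw:
        g_a = GenomicInterval(
            region_a.chrom, region_a.start + off_a, region_a.start + off_a + len(motif_seq)
        )
        g_b = GenomicInterval(
            region_b.chrom, region_b.start + off_b, region_b.start + off_b + len(motif_seq)
        )
        in_a = _tree_overlaps(trees_a, g_a)
        in_b = _tree_overlaps(trees_b, g_b)
        if in_a or in_b:
            motifs.append(
                FootprintMotif(
                    motif_seq,
                    pos_a=off_a,
                    pos_b=off_b,
                    strand_consistent=True,
                    in_repeat_a=in_a,
                    in_repeat_b=in_b,
                )
            )
    if not motifs:
        return FootprintCall(pair_id, (), "none", "none")
    any_a = any(m.in_repeat_a for m in motifs)
    any_b = any(m.in_repeat_b for m in motifs)
    species_class = {
        (True, True): "both",
        (True, False): "a_only",
        (False, True): "b_only",
    }[(any_a, any_b)]
    ordered = sorted(motifs, key=lambda m: m.pos_a)
    collinear = all(
        m2.pos_b > m1.pos_b for m1, m2 in zip(ordered, ordered[1:])
    ) and all(m.strand_consistent for m in ordered)
    strength = "strong" if len(motifs) >= 2 and collinear else "candidate"
    return FootprintCall(pair_id, tuple(ordered), species_class, strength)
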