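"""Expression accounting for repeat families.

RPKM per feature, the family-average abundance (mean over the full
member x condition grid), microarray probe assignment with a strict
>90%-overlap and gene-before-repeat priority, and the small-RNA
processing/mapping profile (adapter clipping, >=17 nt filter,
degradation removal, exhaustive <=1-mismatch mapping to repeat
sequences with a per-length histogram).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from repeatscape.annotation_consensus import reverse_complement
from repeatscape.genome_model import GeneModel, GenomicInterval, RepeatFeature

__all__ = [
    "FeatureCounts",
    "FamilyAbundance",
    "ProbeAssignment",
    "SrnaProfile",
    "rpkm",
    "family_average",
    "assign_probes",
    "process_srna",
    "map_srna",
]


@dataclass(frozen=True)
class FeatureCounts:
    feature_id: str
    raw_count: int
    feature_len: int
    library_total: int

    def __post_init__(self) -> None:
        if self.feature_len <= 0:
            raise ValueError(f"{self.feature_id}: feature_len must be > 0")
        if not 0 <= self.raw_count <= self.library_total:
            raise ValueError(f"{self.feature_id}: raw_count outside [0, total]")


def rpkm(counts: FeatureCounts) -> float:
    """Reads per kilobase of feature per million mapped reads: 1e9*c/(N*L)."""
    if counts.library_total <= 0:
        raise ValueError("library_total must be positive")
    return 1e9 * counts.raw_count / (counts.library_total * counts.feature_len)


@dataclass(frozen=True)
class FamilyAbundance:
    family_id: str
    n_members: int
    n_conditions: int
    average: float


def family_average(
    values: Sequence[float], n_members: int, n_conditions: int
) -> float:
    """Average abundance over the full member x condition grid.

    The denominator is members x conditions; members with no expression
    in a condition contribute zeros (values shorter than the grid are
    zero-padded, mirroring absent entries in a sparse expression table).
    """
    if n_members <= 0 or n_conditions <= 0:
        raise ValueError("n_members and n_conditions must be positive")
    grid = n_members * n_conditions
    if len(values) > grid:
        raise ValueError(f"{len(values)} values exceed {grid}-cell grid")
    return float(sum(values)) / grid


@dataclass(frozen=True)
class ProbeAssignment:
    probe_id: str
    target: str  # gene | repeat | unassigned
    target_id: str | None
    overlap_fraction: float


def _best_overlap(
    placement: GenomicInterval,
    targets: Sequence[tuple[str, GenomicInterval]],
) -> tuple[str | None, float]:
    best_id, best_frac = None, 0.0
    for target_id, iv in targets:
        frac = placement.overlap_bp(iv) / len(placement)
        if frac > best_frac or (frac == best_frac and best_id and target_id < best_id):
            best_id, best_frac = target_id, frac
    return best_id, best_frac


def assign_probes(
    probe_placements: dict[str, GenomicInterval],
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatFeature],
    min_fraction: float = 0.9,
) -> list[ProbeAssignment]:
    """Assign each probe's best genomic placement to a gene or a repeat.

    Gene assignment is tried first (overlap strictly > 90% of the probe
    length), then repeat assignment under the same rule; otherwise the
    probe is unassigned.  Gene priority is strict: a probe >90% inside
    both a gene and a repeat goes to the gene.
    """
    gene_ivs = [(g.gene_id, g.interval) for g in genes]
    rep_ivs = [(r.family_id, r.interval) for r in repeats]
    out = []
    for probe_id in sorted(probe_placements):
        placement = probe_placements[probe_id]
        gid, gfrac = _best_overlap(placement, gene_ivs)
        if gid is not None and gfrac > min_fraction:
            out.append(ProbeAssignment(probe_id, "gene", gid, round(gfrac, 4)))
            continue
        rid, rfrac = _best_overlap(placement, rep_ivs)
        if rid is not None and rfrac > min_fraction:
            out.append(ProbeAssignment(probe_id, "repeat", rid, round(rfrac, 4)))
            continue
        out.append(ProbeAssignment(probe_id, "unassigned", None, 0.0))
    return out


def _clip_adapter(read: str, adapter: str, min_overlap: int = 6) -> str:
    """Clip at the leftmost exact occurrence of an adapter prefix.

    Full-adapter occurrences are found anywhere; at the 3' end a partial
    adapter prefix of >= min_overlap nt also triggers clipping.
    """
    idx = read.find(adapter)
    if idx != -1:
        return read[:idx]
    for k in range(len(adapter) - 1, min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[: len(read) - k]
    return read


def process_srna(
    reads: Iterable[str],
    adapter: str,
    ncrna_seqs: Sequence[str] = (),
    transcript_seqs: Sequence[str] = (),
    min_len: int = 17,
) -> dict[str, int]:
    """Adapter-clip, length-filter and decontaminate small-RNA reads.

    Reads shorter than ``min_len`` after clipping are dropped; reads that
    occur as an exact substring of any non-coding RNA or transcript are
    removed as likely degradation products.  Survivors are deduplicated
    to unique sequences with occurrence counts.
    """
    contaminants = [s.upper() for s in (*ncrna_seqs, *transcript_seqs)]
    unique: dict[str, int] = {}
    for read in reads:
        clipped = _clip_adapter(read.upper(), adapter.upper())
        if len(clipped) < min_len:
            continue
        if any(clipped in c for c in contaminants):
            continue
        unique[clipped] = unique.get(clipped, 0) + 1
    return unique


@dataclass
class SrnaProfile:
    length_histogram: dict[int, int] = field(default_factory=dict)
    superfamily_counts: dict[str, int] = field(default_factory=dict)
    total_unique_reads: int = 0
    mapped_unique_reads: int = 0

    @property
    def mapped_fraction(self) -> float:
        if self.total_unique_reads == 0:
            return 0.0
        return self.mapped_unique_reads / self.total_unique_reads

    @property
    def modal_length(self) -> int | None:
        if not self.length_histogram:
            return None
        return max(
            sorted(self.length_histogram),
            key=lambda k: self.length_histogram[k],
        )


def _matches_with_k_mismatches(read: str, target: str, k: int) -> bool:
    """Substitution-only match test by pigeonhole seed-and-verify.

    Split the read into k+1 chunks; any occurrence with <= k mismatches
    contains >=1 exact chunk, so exact chunk hits anchor the candidate
    windows to verify.  Exhaustive and equivalent to a sliding Hamming
    scan, but near-linear for small k.
    """
    m = len(read)
    if len(target) < m:
        return False
    chunk = m // (k + 1)
    for c in range(k + 1):
        lo = c * chunk
        hi = (c + 1) * chunk if c < k else m
        seed = read[lo:hi]
        idx = target.find(seed)
        while idx != -1:
            start = idx - lo
            if 0 <= start <= len(target) - m:
                mism = 0
                window = target[start : start + m]
                for x, y in zip(window, read):
                    if x != y:
                        mism += 1
                        if mism > k:
                            break
                else:
                    return True
            idx = target.find(seed, idx + 1)
    return False


def map_srna(
    unique_reads: dict[str, int],
    repeat_seqs: dict[str, str],
    superfamily_of: dict[str, str],
    max_mismatch: int = 1,
) -> SrnaProfile:
    """Map unique reads to repeat sequences with <= max_mismatch substitutions.

    No indels; both strands.  A multi-mapping read counts once per
    matched family (each-hit counting), aggregated per superfamily.
    The length histogram covers the retained unique reads.
    """
    profile = SrnaProfile(total_unique_reads=len(unique_reads))
    for read in sorted(unique_reads):
        profile.length_histogram[len(read)] = (
            profile.length_histogram.get(len(read), 0) + 1
        )
        rc = reverse_complement(read)
        mapped_families = set()
        for fam_id in sorted(repeat_seqs):
            target = repeat_seqs[fam_id].upper()
            if _matches_with_k_mismatches(
                read, target, max_mismatch
            ) or _matches_with_k_mismatches(rc, target, max_mismatch):
                mapped_families.add(fam_id)
        if mapped_families:
            profile.mapped_unique_reads += 1
            for fam_id in mapped_families:
                sf = superfamily_of.get(fam_id, "Unknown")
                profile.superfamily_counts[sf] = (
                    profile.superfamily_counts.get(sf, 0) + 1
                )
    return profile
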