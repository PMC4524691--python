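"""Orthologue-alignment cascade for repeat-borne coding changes.

The screen proceeds: reciprocal-best-hit orthologue pairing on proteomes,
global alignment of orthologous transcript (CDS) sequences, extraction of
indels and substitutions, projection of each difference through the exon
ladder onto genomic coordinates to test repeat overlap, and translation
of repeat-overlapping differences to amino-acid level.  Counts are
monotone non-increasing along the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

from repeatscape.alignment import (
    PairwiseAlignment,
    alignment_identity,
    global_align,
    local_align_best,
)
from repeatscape.genome_model import GeneModel, GenomicInterval, RepeatFeature

__all__ = [
    "OrthologPair",
    "SeqDiff",
    "CascadeReport",
    "TranscriptMap",
    "find_orthologs",
    "extract_diffs",
    "reconstruct_b",
    "map_diffs_to_repeats",
    "propagate_to_protein",
    "run_cascade",
]


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    score: float
    identity: float
    reciprocal: bool


@dataclass(frozen=True)
class SeqDiff:
    """One difference between aligned orthologous sequences.

    ``pos_a``/``pos_b`` are ungapped sequence offsets.  For insertions the
    position on the carrying side is the start of the inserted segment;
    the position on the other side is the anchor offset (number of bases
    consumed before the insertion point).  ``seq`` holds the inserted
    segment, or the substituted base on side b.
    """

    kind: str  # insertion_a | insertion_b | substitution
    pos_a: int
    pos_b: int
    length: int
    seq: str = ""
    in_repeat_a: bool = False
    in_repeat_b: bool = False
    unmappable_a: bool = False
    unmappable_b: bool = False

    @property
    def in_repeat(self) -> bool:
        return self.in_repeat_a or self.in_repeat_b


@dataclass
class CascadeReport:
    """Attrition counts along the exonization screen."""

    total_pairs: int = 0
    pairs_with_repeat_indels: int = 0
    pairs_with_repeat_substitutions: int = 0
    pairs_with_aa_changes: int = 0
    pairs_with_structure_candidates: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def find_orthologs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
) -> list[OrthologPair]:
    """Reciprocal-best-hit orthologue pairs between two proteomes.

    Every protein is scored against the other proteome by local protein
    alignment (the score matrix is direction-symmetric, so it is computed
    once); a pair is reciprocal when each member is the other's best hit.
    Ties break by higher identity, then lexicographic partner id.
    Non-reciprocal best hits are reported too (``reciprocal=False``) but
    each gene appears in at most one reciprocal pair.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    from Bio import Align
    from repeatscape.alignment import PROTEIN_GLOBAL, _make_aligner

    aligner = _make_aligner("local", protein=True, params=PROTEIN_GLOBAL)
    names_a = sorted(proteome_a)
    names_b = sorted(proteome_b)
    scores: dict[tuple[str, str], float] = {}
    for a in names_a:
        seq_a = proteome_a[a].replace("*", "X")
        for b in names_b:
            scores[(a, b)] = float(
                aligner.score(seq_a, proteome_b[b].replace("*", "X"))
            )

    def _ident(a: str, b: str) -> float:
        hit = local_align_best(proteome_a[a], proteome_b[b], protein=True)
        return alignment_identity(hit) if hit else 0.0

    def best_of(cands: list[str], score_of, ident_of) -> str:
        top = max(score_of(c) for c in cands)
        tied = sorted(c for c in cands if score_of(c) == top)
        if len(tied) > 1:  # identity computed lazily, only on score ties
            tied.sort(key=lambda c: (-ident_of(c), c))
        return tied[0]

    best_ab = {
        a: best_of(names_b, lambda b: scores[(a, b)], lambda b: _ident(a, b))
        for a in names_a
    }
    best_ba = {
        b: best_of(names_a, lambda a: scores[(a, b)], lambda a: _ident(a, b))
        for b in names_b
    }
    pairs = []
    for a in names_a:
        b = best_ab[a]
        pairs.append(
            OrthologPair(
                a,
                b,
                scores[(a, b)],
                round(_ident(a, b), 4),
                reciprocal=best_ba[b] == a,
            )
        )
    return pairs


def extract_diffs(alignment: PairwiseAlignment) -> list[SeqDiff]:
    """Indels and substitutions from a global alignment.

    Maximal gap runs become single indel events; each mismatching aligned
    column becomes a 1-bp substitution.  Positions are ungapped offsets.
    """
    diffs: list[SeqDiff] = []
    pos_a = pos_b = 0
    gap_kind: str | None = None
    gap_start_a = gap_start_b = 0
    gap_seq: list[str] = []

    def close_gap() -> None:
        nonlocal gap_kind, gap_seq
        if gap_kind is not None:
            diffs.append(
                SeqDiff(
                    kind=gap_kind,
                    pos_a=gap_start_a,
                    pos_b=gap_start_b,
                    length=len(gap_seq),
                    seq="".join(gap_seq),
                )
            )
        gap_kind, gap_seq = None, []

    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == "-" and y == "-":
            continue
        if y == "-":  # extra sequence in a
            if gap_kind != "insertion_a":
                close_gap()
                gap_kind = "insertion_a"
                gap_start_a, gap_start_b = pos_a, pos_b
            gap_seq.append(x)
            pos_a += 1
        elif x == "-":  # extra sequence in b
            if gap_kind != "insertion_b":
                close_gap()
                gap_kind = "insertion_b"
                gap_start_a, gap_start_b = pos_a, pos_b
            gap_seq.append(y)
            pos_b += 1
        else:
            close_gap()
            if x != y:
                diffs.append(
                    SeqDiff(
                        kind="substitution",
                        pos_a=pos_a,
                        pos_b=pos_b,
                        length=1,
                        seq=y,
                    )
                )
            pos_a += 1
            pos_b += 1
    close_gap()
    return diffs


def reconstruct_b(seq_a: str, diffs: Sequence[SeqDiff]) -> str:
    """Regenerate sequence b from sequence a plus its diffs (round-trip)."""
    events = sorted(diffs, key=lambda d: (d.pos_a, d.kind != "insertion_b"))
    out: list[str] = []
    cursor = 0
    for d in events:
        out.append(seq_a[cursor : d.pos_a])
        cursor = d.pos_a
        if d.kind == "substitution":
            out.append(d.seq)
            cursor += 1
        elif d.kind == "insertion_a":
            cursor += d.length  # present in a, absent from b
        else:  # insertion_b
            out.append(d.seq)
    out.append(seq_a[cursor:])
    return "".join(out)


class TranscriptMap:
    """Transcript-offset -> genomic-coordinate projection via the exon ladder."""

    def __init__(self, gene: GeneModel):
        self.gene = gene
        self._ladder: list[tuple[int, GenomicInterval]] = []
        offset = 0
        for exon in gene.exons_5to3:
            self._ladder.append((offset, exon))
            offset += len(exon)
        self.transcript_length = offset

    def project(self, tx_start: int, length: int) -> list[GenomicInterval]:
        """Genomic segments for transcript span [tx_start, tx_start+length).

        A span crossing an exon junction projects to multiple segments.
        Returns [] when the span lies outside the ladder (unmappable).
        """
        if length <= 0 or tx_start < 0 or tx_start >= self.transcript_length:
            return []
        tx_end = min(tx_start + length, self.transcript_length)
        segments = []
        for offset, exon in self._ladder:
            lo = max(tx_start, offset)
            hi = min(tx_end, offset + len(exon))
            if lo >= hi:
                continue
            if self.gene.strand == "-":
                g_end = exon.end - (lo - offset)
                g_start = exon.end - (hi - offset)
            else:
                g_start = exon.start + (lo - offset)
                g_end = exon.start + (hi - offset)
            segments.append(
                GenomicInterval(exon.chrom, g_start, g_end, self.gene.strand)
            )
        return segments


def _overlaps_any(
    segments: Iterable[GenomicInterval], repeats: Sequence[RepeatFeature]
) -> bool:
    for seg in segments:
        for rep in repeats:
            if seg.overlaps(rep.interval):
                return True
    return False


def map_diffs_to_repeats(
    diffs: Sequence[SeqDiff],
    map_a: TranscriptMap | None,
    map_b: TranscriptMap | None,
    repeats_a: Sequence[RepeatFeature],
    repeats_b: Sequence[RepeatFeature],
) -> list[SeqDiff]:
    """Flag each diff with repeat overlap of its genomic projection.

    A diff is in-repeat for a species iff any genomic segment of its
    projection overlaps >=1 bp of a repeat there.  Insertions project
    with their length on the carrying side and 1 bp at the anchor on the
    other.  Unprojectable positions are flagged, not dropped.
    """
    out = []
    for d in diffs:
        len_a = d.length if d.kind != "insertion_b" else 1
        len_b = d.length if d.kind != "insertion_a" else 1
        seg_a = map_a.project(d.pos_a, len_a) if map_a else []
        seg_b = map_b.project(d.pos_b, len_b) if map_b else []
        out.append(
            replace(
                d,
                in_repeat_a=_overlaps_any(seg_a, repeats_a),
                in_repeat_b=_overlaps_any(seg_b, repeats_b),
                unmappable_a=map_a is not None and not seg_a,
                unmappable_b=map_b is not None and not seg_b,
            )
        )
    return out


@dataclass(frozen=True)
class AminoAcidChange:
    kind: str  # substitution | aa_insertion_a | aa_insertion_b | frameshift
    codon_a: int
    codon_b: int
    aa_a: str = ""
    aa_b: str = ""


def propagate_to_protein(
    diffs: Sequence[SeqDiff],
    cds_a: str,
    cds_b: str,
) -> tuple[list[AminoAcidChange], bool]:
    """Translate nucleotide diffs to amino-acid changes.

    Synonymous substitutions yield no change; frame-preserving indels
    (length % 3 == 0) yield amino-acid indels; frame-shifting indels are
    flagged.  Returns (changes, internal_stop_flag); a pair that gains an
    internal stop is excluded from downstream counts by the caller.
    """
    prot_a = str(Seq(cds_a[: len(cds_a) - len(cds_a) % 3]).translate())
    prot_b = str(Seq(cds_b[: len(cds_b) - len(cds_b) % 3]).translate())
    internal_stop = "*" in prot_a[:-1] or "*" in prot_b[:-1]
    changes: list[AminoAcidChange] = []
    for d in diffs:
        ci_a, ci_b = d.pos_a // 3, d.pos_b // 3
        if d.kind == "substitution":
            aa_a = prot_a[ci_a] if ci_a < len(prot_a) else ""
            aa_b = prot_b[ci_b] if ci_b < len(prot_b) else ""
            if aa_a != aa_b:
                changes.append(
                    AminoAcidChange("substitution", ci_a, ci_b, aa_a, aa_b)
                )
        elif d.length % 3 == 0:
            kind = "aa_insertion_a" if d.kind == "insertion_a" else "aa_insertion_b"
            changes.append(AminoAcidChange(kind, ci_a, ci_b))
        else:
            changes.append(AminoAcidChange("frameshift", ci_a, ci_b))
    return changes, internal_stop


def run_cascade(
    pair_diffs: dict[tuple[str, str], list[SeqDiff]],
    pair_cds: dict[tuple[str, str], tuple[str, str]],
    structure_flags: dict[tuple[str, str], bool] | None = None,
    require_both_species: bool = False,
) -> CascadeReport:
    """Aggregate per-pair diffs into the cascade attrition report.

    ``require_both_species=True`` demands repeat overlap in both species
    for a diff to count (default: either species).  Structure candidates
    come from an external flag column since structural modelling is out
    of band.
    """
    report = CascadeReport(total_pairs=len(pair_diffs))
    structure_flags = structure_flags or {}
    for pair, diffs in pair_diffs.items():
        def hits(d: SeqDiff) -> bool:
            if require_both_species:
                return d.in_repeat_a and d.in_repeat_b
            return d.in_repeat
        rep_indels = [d for d in diffs if d.kind != "substitution" and hits(d)]
        rep_subs = [d for d in diffs if d.kind == "substitution" and hits(d)]
        if rep_indels:
            report.pairs_with_repeat_indels += 1
        if rep_subs:
            report.pairs_with_repeat_substitutions += 1
        if not (rep_indels or rep_subs):
            continue
        cds_a, cds_b = pair_cds[pair]
        changes, internal_stop = propagate_to_protein(
            rep_indels + rep_subs, cds_a, cds_b
        )
        if internal_stop or not changes:
            continue
        report.pairs_with_aa_changes += 1
        if structure_flags.get(pair, False):
            report.pairs_with_structure_candidates += 1
    return report
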