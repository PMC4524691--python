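"""Coordinate system, annotation data model, and format readers/writers.

All coordinates are 0-based half-open internally.  The three input dialects
convert at the I/O boundary: RepeatMasker ``.out`` and GFF3 are 1-based
inclusive, BED is already 0-based half-open.  Coverage and overlap are
strand-agnostic; strand is carried for flank construction and footprint
orientation only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "RepeatFeature",
    "GeneModel",
    "AssemblyIndex",
    "ParseError",
    "ValidationError",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "merge_intervals",
    "covered_bases",
    "flank",
    "intervals_overlap",
    "repeat_class_for_superfamily",
]


class ParseError(ValueError):
    """Malformed input line; the message names the file and line number."""


class ValidationError(ValueError):
    """Annotation inconsistent with the assembly or with itself."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Located, optionally stranded span on a chromosome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# Superfamily prefix -> repeat class.  Mirrors the standard RepeatMasker
# class/family nomenclature (e.g. "LTR/Gypsy", "DNA/TcMar-Stowaway").
_CLASS_BY_PREFIX = {
    "DNA": "DNA transposon",
    "RC": "DNA transposon",  # rolling-circle Helitrons
    "LTR": "Retrotransposon",
    "LINE": "Retrotransposon",
    "SINE": "Retrotransposon",
    "Retroposon": "Retrotransposon",
    "Unknown": "Uncategorized",
}


def repeat_class_for_superfamily(superfamily: str) -> str:
    """Map a superfamily label to its repeat class.

    Labels outside the transposon nomenclature (rRNA, snRNA, Satellite, ...)
    fall into "Other".
    """
    prefix = superfamily.split("/", 1)[0].rstrip("?")
    return _CLASS_BY_PREFIX.get(prefix, "Other")


@dataclass(frozen=True)
class RepeatFeature:
    """One annotated repeat copy."""

    interval: GenomicInterval
    family_id: str
    superfamily: str
    source: str = "external"
    divergence: float | None = None

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValidationError("family_id must be non-empty")
        if self.divergence is not None and not 0.0 <= self.divergence <= 1.0:
            raise ValidationError(f"divergence {self.divergence} outside [0, 1]")

    @property
    def repeat_class(self) -> str:
        return repeat_class_for_superfamily(self.superfamily)


@dataclass(frozen=True)
class GeneModel:
    """Protein-coding gene with exon structure.

    Exons are stored sorted by genomic start; ``exons_5to3`` orders them
    by transcription direction.  Introns are the gene span minus exons.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds_phase: int = 0
    transcript_seq: str | None = None
    protein_seq: str | None = None

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for exon in exons:
            if exon.chrom != self.interval.chrom:
                raise ValidationError(
                    f"gene {self.gene_id}: exon on {exon.chrom}, "
                    f"gene on {self.interval.chrom}"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon {exon.start}-{exon.end} outside "
                    f"gene span {self.interval.start}-{self.interval.end}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = exon.end
        if self.cds_phase not in (0, 1, 2):
            raise ValidationError(f"gene {self.gene_id}: cds_phase {self.cds_phase}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def exons_5to3(self) -> tuple[GenomicInterval, ...]:
        if self.strand == "-":
            return tuple(reversed(self.exons))
        return self.exons

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                out.append(
                    GenomicInterval(
                        self.interval.chrom, left.end, right.start, self.strand
                    )
                )
        return tuple(out)


@dataclass(frozen=True)
class AssemblyIndex:
    """Chromosome id -> length map (the `.fai`-style index)."""

    lengths: dict[str, int] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def validate(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.lengths:
            raise ValidationError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self.lengths[interval.chrom]:
            raise ValidationError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"beyond chromosome length {self.lengths[interval.chrom]}"
            )

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "AssemblyIndex":
        return cls({name: len(seq) for name, seq in seqs.items()})


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals: pairwise disjoint, sorted, abutting spans merged.

    Strand is dropped (merged spans are unstranded).  Intervals may come
    from several chromosomes; merging is per-chromosome.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted((iv.start, iv.end) for iv in by_chrom[chrom])
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start <= cur_end:  # overlap or abutting
                cur_end = max(cur_end, end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def covered_bases(
    features: Iterable[GenomicInterval | RepeatFeature],
    region: GenomicInterval | None = None,
    chrom: str | None = None,
) -> int:
    """Bases covered by the union of ``features``, optionally within a region.

    ``region=None`` counts over the whole genome (or one chromosome if
    ``chrom`` is given).  Strand-agnostic; nested/overlapping features
    count once.
    """
    ivs = [f.interval if isinstance(f, RepeatFeature) else f for f in features]
    if chrom is not None:
        ivs = [iv for iv in ivs if iv.chrom == chrom]
    if not ivs:
        return 0
    merged = merge_intervals(ivs)
    if region is None:
        return sum(len(iv) for iv in merged)
    return sum(iv.overlap_bp(region) for iv in merged)


def flank(
    gene: GeneModel,
    upstream_bp: int,
    assembly: AssemblyIndex | None = None,
) -> GenomicInterval | None:
    """Strand-aware window immediately 5' of the gene start, edge-clipped.

    Returns None when the gene starts at the chromosome edge (empty window).
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    iv = gene.interval
    if iv.strand == "-":
        start = iv.end
        end = iv.end + upstream_bp
        if assembly is not None:
            end = min(end, assembly.lengths[iv.chrom])
    else:
        start = max(0, iv.start - upstream_bp)
        end = iv.start
    if start >= end:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def intervals_overlap(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> bool:
    """True iff ``query`` overlaps >=1 bp of any target (linear scan)."""
    return any(query.overlaps(t) for t in targets)


# ---------------------------------------------------------------------------
# RepeatMasker `.out` dialect
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query         matching"
    "    repeat          position in repeat\n"
    "score  div. del. ins.  sequence  begin  end      (left)    repeat"
    "    class/family    begin  end   (left)  ID\n"
    "\n"
)


def read_repeatmasker_out(
    path: str | Path,
    assembly: AssemblyIndex | None = None,
    source: str = "external",
) -> list[RepeatFeature]:
    """Parse a RepeatMasker ``.out`` table into RepeatFeatures.

    The dialect is whitespace-delimited with a 3-line header; coordinates
    are 1-based inclusive and orientation ``C`` means the minus strand.
    The per-copy divergence column (percent) becomes a [0, 1] fraction.
    """
    features: list[RepeatFeature] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score")):
                continue  # header lines
            fields = stripped.split()
            if len(fields) < 11:
                raise ParseError(f"{path.name}:{lineno}: expected >=11 columns")
            try:
                div_pct = float(fields[1])
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                orient = fields[8]
                family_id = fields[9]
                superfamily = fields[10]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            if orient not in ("+", "C"):
                raise ParseError(
                    f"{path.name}:{lineno}: orientation {orient!r} not '+'/'C'"
                )
            strand = "-" if orient == "C" else "+"
            iv = GenomicInterval(chrom, begin - 1, end, strand)
            if assembly is not None:
                assembly.validate(iv)
            features.append(
                RepeatFeature(
                    interval=iv,
                    family_id=family_id,
                    superfamily=superfamily,
                    source=source,
                    divergence=div_pct / 100.0,
                )
            )
    return features


def write_repeatmasker_out(features: Sequence[RepeatFeature], path: str | Path) -> None:
    """Write features back to the ``.out`` dialect (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, f in enumerate(features, 1):
            iv = f.interval
            div = 0.0 if f.divergence is None else f.divergence * 100.0
            orient = "C" if iv.strand == "-" else "+"
            fh.write(
                f"{1000:>5} {div:5.1f}  0.0  0.0  {iv.chrom}  "
                f"{iv.start + 1}  {iv.end}  (0)  {orient}  {f.family_id}  "
                f"{f.superfamily}  1  {len(iv)}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _gff3_attrs(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gff3_genes(
    path: str | Path, assembly: AssemblyIndex | None = None
) -> list[GeneModel]:
    """Assemble GeneModels from GFF3 gene/mRNA/exon records.

    Exons are attached through mRNA Parent links (or directly to genes).
    1-based inclusive coordinates convert to 0-based half-open.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    exon_rows: list[tuple[int, str, int, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path.name}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            a = _gff3_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ParseError(f"{path.name}:{lineno}: gene without ID")
                genes[gid] = {
                    "interval": GenomicInterval(chrom, start_i - 1, end_i, strand),
                    "exons": [],
                    "phase": 0,
                }
            elif ftype == "mRNA":
                tid, parent = a.get("ID"), a.get("Parent")
                if tid and parent:
                    mrna_to_gene[tid] = parent
            elif ftype in ("exon", "CDS"):
                exon_rows.append((lineno, chrom, start_i, end_i, strand, attrs))
    for lineno, chrom, start_i, end_i, strand, attrs in exon_rows:
        a = _gff3_attrs(attrs)
        parent = a.get("Parent", "")
        gid = mrna_to_gene.get(parent, parent)
        if gid not in genes:
            raise ParseError(
                f"{path.name}:{lineno}: exon parent {parent!r} matches no gene"
            )
        iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
        rec = genes[gid]
        # exon and CDS rows describe the same span in our single-transcript
        # models; keep the union of distinct spans
        if iv not in rec["exons"]:
            rec["exons"].append(iv)
    models = []
    for gid, rec in genes.items():
        model = GeneModel(
            gene_id=gid,
            interval=rec["interval"],
            exons=tuple(rec["exons"]),
            cds_phase=rec["phase"],
        )
        if assembly is not None:
            assembly.validate(model.interval)
        models.append(model)
    return models


def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\trepeatscape\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{iv.chrom}\trepeatscape\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for k, exon in enumerate(g.exons, 1):
                fh.write(
                    f"{exon.chrom}\trepeatscape\texon\t{exon.start + 1}\t"
                    f"{exon.end}\t.\t{exon.strand}\t.\t"
                    f"ID={tid}.exon{k};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# BED6 and FASTA
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >=3 columns")
            strand = cols[5] if len(cols) >= 6 else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tfeature_{i}\t0\t{iv.strand}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def shift_interval(iv: GenomicInterval, offset: int) -> GenomicInterval:
    return replace(iv, start=iv.start + offset, end=iv.end + offset)
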