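"""Two-species synthetic genome generator with planted ground truth.

Generates everything the analysis stages consume — multi-chromosome
genomes with planted repeat families (per-copy divergence), protein-
coding genes with orthologue pairs carrying repeat-borne in-frame
indels, upstream TFBS hit tables with planted repeat-attributable
gains, multi-locus pre-miRNAs with conserved eroded-repeat relics in
their flanks, negative-binomially distributed expression counts, and
24-nt-biased small-RNA reads — plus a TruthManifest recording every
planted feature so recovery can be scored without external data.

The default configuration is a desk-scale emulation of a repeat-rich
plant genome pair: ~45-50% repeat coverage dominated by LTR/Gypsy,
LTR/Copia and LINE families, a few hundred genes, and a recently
diverged second species (high CDS identity).  Background sequence is
i.i.d. uniform ACGT.  Per-copy divergence applies substitutions and
indels in a 9:1 event mix, a typical decay assumption for transposable
elements.  Everything is a pure function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from repeatscape.annotation_consensus import reverse_complement
from repeatscape.genome_model import (
    AssemblyIndex,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    write_fasta,
    write_gff3_genes,
    write_repeatmasker_out,
)

__all__ = [
    "FamilySpec",
    "SimConfig",
    "TruthManifest",
    "SpeciesData",
    "simulate_genome",
    "plant_orthologs",
    "plant_mirna_footprints",
    "simulate_reads",
    "simulate_study",
    "write_species",
]

BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# standard-code synonymous codon groups, stop codons excluded
_AA_OF: dict[str, str] = {}
from Bio.Seq import Seq as _Seq  # noqa: E402

for _c in _CODONS:
    _AA_OF[_c] = str(_Seq(_c).translate())
_SYNONYMS: dict[str, list[str]] = {}
for _c, _aa in _AA_OF.items():
    _SYNONYMS.setdefault(_aa, []).append(_c)


@dataclass(frozen=True)
class FamilySpec:
    """One planted repeat family: consensus length, copy number, decay."""

    name: str
    superfamily: str
    consensus_len: int
    n_copies: int
    divergence: float


#: Desk-scale repeat composition: LTR/Gypsy dominant, then LTR/Copia and
#: LINEs, DNA transposons and SINEs minor, plus an Unknown fraction —
#: the qualitative family mix of a repeat-rich Solanaceous genome.
DEFAULT_FAMILIES = (
    FamilySpec("rnd-1_family-1", "LTR/Gypsy", 800, 250, 0.10),
    FamilySpec("rnd-1_family-2", "LTR/Copia", 600, 60, 0.10),
    FamilySpec("rnd-2_family-3", "LINE/L1", 500, 40, 0.12),
    FamilySpec("rnd-2_family-4", "LINE/RTE-BovB", 500, 20, 0.12),
    FamilySpec("rnd-3_family-5", "DNA/TcMar-Stowaway", 250, 60, 0.08),
    FamilySpec("rnd-3_family-6", "DNA/Harbinger", 300, 30, 0.08),
    FamilySpec("rnd-4_family-7", "SINE/tRNA", 150, 40, 0.08),
    FamilySpec("rnd-5_family-8", "Unknown", 400, 60, 0.10),
)


@dataclass
class SimConfig:
    """All knobs of the simulation; the seed fully determines the output."""

    seed: int = 0
    n_chroms: int = 4
    chrom_len: int = 200_000
    gc_content: float = 0.5
    families: tuple[FamilySpec, ...] = DEFAULT_FAMILIES
    indel_event_fraction: float = 0.1  # of divergence events; rest substitutions

    n_genes: int = 200
    exon_count_range: tuple[int, int] = (1, 4)
    exon_len_codons: tuple[int, int] = (40, 120)
    intron_len_range: tuple[int, int] = (80, 200)

    # orthologue divergence (second species), codon-wise
    synonymous_rate: float = 0.06
    nonsynonymous_rate: float = 0.02
    exonization_rate: float = 0.2  # fraction of pairs with a repeat-borne indel
    exonized_indel_codons: tuple[int, int] = (3, 10)

    n_tfs: int = 5
    tfbs_base_rate: float = 2.0  # Poisson mean shared sites per window
    tfbs_gain_rate: float = 1.5  # Poisson mean planted surplus sites
    tfbs_repeat_fraction: tuple[float, ...] = (0.7, 0.35, 0.2, 0.1, 0.05)

    n_mirnas: int = 12
    mirna_hairpin_len: int = 100
    mirna_multilocus: int = 4  # first k miRNAs get extra copies
    mirna_extra_copies: int = 2
    footprint_relic_len: int = 30
    footprint_relic_divergence: float = 0.10
    # footprint class per planted pair, cycled: both / a_only / b_only
    footprint_classes: tuple[str, ...] = (
        "both", "both", "a_only", "b_only", "both", "a_only",
    )
    mirna_flank_bp: int = 2000

    n_conditions: int = 8
    nb_mean_by_superfamily: dict[str, float] = field(
        default_factory=lambda: {
            "LTR/Gypsy": 5.0,
            "LTR/Copia": 8.0,
            "LINE/L1": 12.0,
            "LINE/RTE-BovB": 20.0,
            "DNA/TcMar-Stowaway": 60.0,
            "DNA/Harbinger": 40.0,
            "SINE/tRNA": 25.0,
            "Unknown": 3.0,
        }
    )
    nb_dispersion: float = 2.0

    n_srna_reads: int = 1200
    srna_len_probs: dict[int, float] = field(
        default_factory=lambda: {
            17: 0.04, 18: 0.05, 19: 0.05, 20: 0.07, 21: 0.12, 22: 0.10,
            23: 0.10, 24: 0.30, 25: 0.08, 26: 0.05, 27: 0.02, 28: 0.02,
        }
    )
    srna_adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    srna_contaminant_fraction: float = 0.08
    srna_short_fraction: float = 0.05

    n_probes: int = 120
    probe_len: int = 60


@dataclass
class TruthManifest:
    """Every planted feature with coordinates and intended outcome."""

    repeats: dict[str, list[dict]] = field(default_factory=dict)  # per species
    genes: dict[str, list[dict]] = field(default_factory=dict)
    ortholog_pairs: list[dict] = field(default_factory=list)
    tfbs: list[dict] = field(default_factory=list)
    mirnas: list[dict] = field(default_factory=list)
    footprints: list[dict] = field(default_factory=list)
    expression: list[dict] = field(default_factory=list)
    srna: dict = field(default_factory=dict)
    probes: list[dict] = field(default_factory=list)

    def write(self, path: str | Path, species: dict[str, "SpeciesData"]) -> None:
        self.validate(species)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    def validate(self, species: dict[str, "SpeciesData"]) -> None:
        """Internal consistency with the emitted sequences/annotations."""
        for sp, data in species.items():
            assembly = AssemblyIndex.from_sequences(data.genome)
            for rec in self.repeats.get(sp, []):
                iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"])
                assembly.validate(iv)
            truth_ids = {rec["gene_id"] for rec in self.genes.get(sp, [])}
            emitted_ids = {g.gene_id for g in data.genes}
            if truth_ids != emitted_ids:
                raise ValueError(f"{sp}: manifest genes do not match emitted genes")
            if len(self.repeats.get(sp, [])) != len(data.repeats):
                raise ValueError(f"{sp}: manifest repeat count mismatch")


@dataclass
class SpeciesData:
    """Everything simulated for one species."""

    name: str
    genome: dict[str, str]
    repeats: list[RepeatFeature]
    genes: list[GeneModel]
    transcripts: dict[str, str]
    proteins: dict[str, str]
    premirnas: dict[str, str] = field(default_factory=dict)
    mirna_loci: list[dict] = field(default_factory=list)

    @property
    def assembly(self) -> AssemblyIndex:
        return AssemblyIndex.from_sequences(self.genome)


def _tail_reserve(config: SimConfig) -> int:
    """Bases reserved at each chromosome tail for pre-miRNA windows."""
    window = 2 * config.mirna_flank_bp + config.mirna_hairpin_len + 200
    total_slots = config.n_mirnas + config.mirna_multilocus * config.mirna_extra_copies
    per_chrom = -(-total_slots // config.n_chroms)  # ceil
    return per_chrom * window + 500


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _mutate(
    rng: np.random.Generator,
    seq: str,
    divergence: float,
    indel_fraction: float = 0.1,
    max_indel: int = 6,
) -> str:
    """Apply ~divergence events per base: substitutions plus short indels."""
    out = list(seq)
    n_events = rng.binomial(len(seq), divergence)
    positions = rng.choice(len(seq), size=min(n_events, len(seq)), replace=False)
    deletions = set()
    insertions: dict[int, str] = {}
    for pos in sorted(positions):
        if rng.random() < indel_fraction:
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:
                deletions.update(range(pos, min(pos + size, len(seq))))
            else:
                insertions[pos] = _random_seq(rng, size)
        else:
            current = out[pos]
            choices = [b for b in "ACGT" if b != current]
            out[pos] = choices[int(rng.integers(3))]
    final = []
    for i, base in enumerate(out):
        if i in insertions:
            final.append(insertions[i])
        if i not in deletions:
            final.append(base)
    return "".join(final)


def _substitute_only(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    n = rng.binomial(len(seq), rate)
    for pos in rng.choice(len(seq), size=min(n, len(seq)), replace=False):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = [_CODONS[int(i)] for i in rng.integers(0, len(_CODONS), size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


# ---------------------------------------------------------------------------
# Genome + annotations for one species
# ---------------------------------------------------------------------------


def _build_genes(
    config: SimConfig, rng: np.random.Generator, chroms: list[str], prefix: str
) -> tuple[list[GeneModel], dict[str, str], dict[str, list[tuple[int, int, str]]]]:
    """Gene models with CDS split over exons; returns layout edits per chrom."""
    genes: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    edits: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    cursor = {c: 6000 for c in chroms}  # leave room for upstream windows
    per_chrom = config.n_genes // len(chroms)
    extra = config.n_genes - per_chrom * len(chroms)
    gene_no = 0
    for ci, chrom in enumerate(chroms):
        quota = per_chrom + (1 if ci < extra else 0)
        for _ in range(quota):
            n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
            exon_codons = [
                int(rng.integers(*config.exon_len_codons, endpoint=True))
                for _ in range(n_exons)
            ]
            cds = _random_cds(rng, sum(exon_codons))
            strand = "+" if rng.random() < 0.5 else "-"
            introns = [
                int(rng.integers(*config.intron_len_range, endpoint=True))
                for _ in range(n_exons - 1)
            ]
            start = cursor[chrom] + int(rng.integers(500, 2000))
            # lay exons 5'->3' along the genome for + genes, reversed for -
            exon_nt = [3 * c for c in exon_codons]
            tx_pieces = []
            offset = 0
            for c in exon_codons:
                tx_pieces.append(cds[offset : offset + 3 * c])
                offset += 3 * c
            genomic_pieces = tx_pieces if strand == "+" else [
                reverse_complement(p) for p in reversed(tx_pieces)
            ]
            genomic_lens = exon_nt if strand == "+" else list(reversed(exon_nt))
            exons = []
            pos = start
            for k, (piece, ln) in enumerate(zip(genomic_pieces, genomic_lens)):
                exons.append(GenomicInterval(chrom, pos, pos + ln, strand))
                edits[chrom].append((pos, pos + ln, piece))
                pos += ln
                if k < n_exons - 1:
                    pos += introns[k]
            if pos > config.chrom_len - _tail_reserve(config) - 2500:
                raise ValueError(
                    f"gene layout on {chrom} collides with the reserved "
                    "miRNA tail region; increase chrom_len or reduce n_genes"
                )
            gene_id = f"{prefix}G{gene_no:05d}"
            gene_no += 1
            interval = GenomicInterval(chrom, start, pos, strand)
            genes.append(
                GeneModel(gene_id, interval, tuple(exons), transcript_seq=cds)
            )
            transcripts[gene_id] = cds
            cursor[chrom] = pos
    return genes, transcripts, edits


def simulate_genome(
    config: SimConfig,
    rng: np.random.Generator,
    species: str = "speciesA",
    gene_prefix: str = "A",
) -> tuple[SpeciesData, TruthManifest]:
    """Background genome + planted repeat copies + gene models + truth."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {c: list(_random_seq(rng, config.chrom_len, config.gc_content)) for c in chroms}

    genes, transcripts, gene_edits = _build_genes(config, rng, chroms, gene_prefix)
    for chrom, chrom_edits in gene_edits.items():
        for start, end, piece in chrom_edits:
            if end > config.chrom_len:
                raise ValueError("gene layout exceeds chromosome length")
            genome[chrom][start:end] = list(piece)
    reserved = {
        c: [(s, e) for s, e, _ in gene_edits[c]] for c in chroms
    }  # exon spans: repeats may overlap them in annotation but not rewrite them

    manifest = TruthManifest()
    manifest.genes[species] = [
        {
            "gene_id": g.gene_id,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.strand,
            "n_exons": len(g.exons),
            "introns": [[iv.start, iv.end] for iv in g.introns],
        }
        for g in genes
    ]

    repeats: list[RepeatFeature] = []
    rep_truth: list[dict] = []
    consensi: dict[str, str] = {}
    for fam in config.families:
        consensi[fam.name] = _random_seq(rng, fam.consensus_len)
        for copy_no in range(fam.n_copies):
            copy_seq = _mutate(
                rng, consensi[fam.name], fam.divergence, config.indel_event_fraction
            )
            chrom = chroms[int(rng.integers(len(chroms)))]
            # keep repeat copies clear of the miRNA tail reserve so planted
            # footprint classes stay unambiguous
            start = int(
                rng.integers(
                    0, config.chrom_len - _tail_reserve(config) - len(copy_seq)
                )
            )
            end = start + len(copy_seq)
            # write copy sequence into background but never over exon bases
            # (transcripts are authoritative for coding sequence)
            seg = genome[chrom]
            blocked = [
                (max(start, s), min(end, e))
                for s, e in reserved[chrom]
                if s < end and e > start
            ]
            pos_iter = np.ones(end - start, dtype=bool)
            for s, e in blocked:
                pos_iter[s - start : e - start] = False
            copy_arr = list(copy_seq)
            for i, writable in enumerate(pos_iter):
                if writable:
                    seg[start + i] = copy_arr[i]
            repeats.append(
                RepeatFeature(
                    GenomicInterval(chrom, start, end, "+" if rng.random() < 0.5 else "-"),
                    family_id=fam.name,
                    superfamily=fam.superfamily,
                    source="de_novo",
                    divergence=fam.divergence,
                )
            )
            rep_truth.append(
                {
                    "family": fam.name,
                    "superfamily": fam.superfamily,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "divergence": fam.divergence,
                    "copy": copy_no,
                }
            )
    manifest.repeats[species] = rep_truth

    proteins = {
        gid: str(_Seq(cds).translate()).rstrip("*") for gid, cds in transcripts.items()
    }
    data = SpeciesData(
        name=species,
        genome={c: "".join(genome[c]) for c in chroms},
        repeats=repeats,
        genes=genes,
        transcripts=transcripts,
        proteins=proteins,
    )
    data._consensi = consensi  # type: ignore[attr-defined]
    return data, manifest


# ---------------------------------------------------------------------------
# Second species with planted exonization
# ---------------------------------------------------------------------------


def _diverge_cds(
    rng: np.random.Generator, cds: str, syn_rate: float, nonsyn_rate: float
) -> str:
    """Codon-wise divergence that never introduces a premature stop."""
    codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
    out = [codons[0]]  # keep ATG
    for codon in codons[1:]:
        u = rng.random()
        aa = _AA_OF.get(codon)
        if aa and u < syn_rate and len(_SYNONYMS[aa]) > 1:
            alts = [c for c in _SYNONYMS[aa] if c != codon]
            out.append(alts[int(rng.integers(len(alts)))])
        elif aa and u < syn_rate + nonsyn_rate:
            out.append(_CODONS[int(rng.integers(len(_CODONS)))])
        else:
            out.append(codon)
    return "".join(out) + cds[-3:]


def plant_orthologs(
    config: SimConfig,
    rng: np.random.Generator,
    species_a: SpeciesData,
    manifest: TruthManifest,
    species: str = "speciesB",
) -> SpeciesData:
    """Second-species genome whose genes are diverged copies of species A.

    A fraction ``exonization_rate`` of orthologue pairs receives an
    in-frame insertion drawn from a repeat-family consensus, placed at a
    codon boundary inside one exon of the second species, with a repeat
    feature annotated over the inserted genomic segment (the exonized
    repeat).  The truth manifest records which pairs were hit.
    """
    data_b, manifest_b = simulate_genome(config, rng, species=species, gene_prefix="B")
    manifest.repeats[species] = manifest_b.repeats[species]
    consensi = getattr(species_a, "_consensi")
    exo_fams = [f for f in config.families if f.superfamily != "Unknown"]

    genes_b: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    genome = {c: list(seq) for c, seq in data_b.genome.items()}
    extra_repeats: list[RepeatFeature] = []

    for gene_a, gene_b_slot in zip(species_a.genes, data_b.genes):
        cds_a = species_a.transcripts[gene_a.gene_id]
        cds_b = _diverge_cds(
            rng, cds_a, config.synonymous_rate, config.nonsynonymous_rate
        )
        exonized = rng.random() < config.exonization_rate
        insert_rec = None
        if exonized:
            fam = exo_fams[int(rng.integers(len(exo_fams)))]
            n_codons = int(rng.integers(*config.exonized_indel_codons, endpoint=True))
            raw = consensi[fam.name]
            off = int(rng.integers(0, len(raw) - 3 * n_codons))
            segment = raw[off : off + 3 * n_codons]
            # scrub stop codons so the insertion stays readable in frame
            seg_codons = [
                segment[i : i + 3] if segment[i : i + 3] not in _STOPS
                else _CODONS[int(rng.integers(len(_CODONS)))]
                for i in range(0, len(segment), 3)
            ]
            segment = "".join(seg_codons)
            codon_pos = int(rng.integers(1, len(cds_b) // 3 - 1))
            nt_pos = 3 * codon_pos
            cds_b = cds_b[:nt_pos] + segment + cds_b[nt_pos:]
            insert_rec = {"family": fam.name, "tx_pos": nt_pos, "len": len(segment)}

        # the slot gene's layout is rebuilt for the (possibly longer) CDS:
        # single-exon layout anchored at the slot's start keeps it simple
        # and guarantees the insertion projects inside the gene span
        chrom = gene_b_slot.interval.chrom
        start = gene_b_slot.interval.start
        end = start + len(cds_b)
        if end > len(genome[chrom]):
            raise ValueError("gene slot exceeds chromosome")
        genome[chrom][start:end] = list(cds_b)
        gene_id = gene_b_slot.gene_id
        iv = GenomicInterval(chrom, start, end, "+")
        gene_b = GeneModel(gene_id, iv, (iv,), transcript_seq=cds_b)
        genes_b.append(gene_b)
        transcripts[gene_id] = cds_b

        if insert_rec is not None:
            g_start = start + insert_rec["tx_pos"]
            g_end = g_start + insert_rec["len"]
            fam_spec = next(f for f in exo_fams if f.name == insert_rec["family"])
            extra_repeats.append(
                RepeatFeature(
                    GenomicInterval(chrom, g_start, g_end, "+"),
                    family_id=insert_rec["family"],
                    superfamily=fam_spec.superfamily,
                    source="de_novo",
                    divergence=0.0,
                )
            )
            manifest.repeats[species].append(
                {
                    "family": insert_rec["family"],
                    "superfamily": fam_spec.superfamily,
                    "chrom": chrom,
                    "start": g_start,
                    "end": g_end,
                    "divergence": 0.0,
                    "copy": -1,
                    "exonized_in": gene_id,
                }
            )
        manifest.ortholog_pairs.append(
            {
                "gene_a": gene_a.gene_id,
                "gene_b": gene_id,
                "exonized": bool(exonized),
                "insertion": insert_rec,
            }
        )

    proteins = {
        gid: str(_Seq(cds).translate()).rstrip("*") for gid, cds in transcripts.items()
    }
    manifest.genes[species] = [
        {
            "gene_id": g.gene_id,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.strand,
            "n_exons": len(g.exons),
            "introns": [],
        }
        for g in genes_b
    ]
    return SpeciesData(
        name=species,
        genome={c: "".join(seq) for c, seq in genome.items()},
        repeats=data_b.repeats + extra_repeats,
        genes=genes_b,
        transcripts=transcripts,
        proteins=proteins,
    )


# ---------------------------------------------------------------------------
# miRNAs with footprint relics
# ---------------------------------------------------------------------------


def _hairpin(rng: np.random.Generator, length: int) -> str:
    stem = _random_seq(rng, (length - 20) // 2)
    loop = _random_seq(rng, length - 2 * len(stem))
    return stem + loop + reverse_complement(stem)


def plant_mirna_footprints(
    config: SimConfig,
    rng: np.random.Generator,
    species_a: SpeciesData,
    species_b: SpeciesData,
    manifest: TruthManifest,
) -> None:
    """Insert orthologous pre-miRNAs with conserved relic footprints.

    Each planted pair shares a hairpin (lightly diverged between species)
    placed in otherwise-unrelated flank sequence.  Footprint-positive
    pairs additionally carry a conserved repeat-consensus relic of
    ``footprint_relic_len`` bp in the upstream flank of both species,
    diverged between species at ``footprint_relic_divergence``; a repeat
    feature is annotated over the relic in one or both species according
    to the configured class.  The first ``mirna_multilocus`` miRNAs get
    extra (near-identical) genomic copies in species A.
    """
    consensi = getattr(species_a, "_consensi")
    relic_source = consensi[config.families[0].name]  # Gypsy consensus
    flank = config.mirna_flank_bp
    window = 2 * flank + config.mirna_hairpin_len + 200

    genomes = {
        "A": {c: list(s) for c, s in species_a.genome.items()},
        "B": {c: list(s) for c, s in species_b.genome.items()},
    }
    # reserve windows at chromosome tails, clear of genes and planted repeats
    slots = {"A": [], "B": []}
    for sp, data in (("A", species_a), ("B", species_b)):
        per_chrom_needed = config.n_mirnas + config.mirna_multilocus * config.mirna_extra_copies
        chroms = sorted(data.genome)
        idx = 0
        pos_by_chrom = {c: len(data.genome[c]) - window for c in chroms}
        for _ in range(per_chrom_needed):
            chrom = chroms[idx % len(chroms)]
            start = pos_by_chrom[chrom]
            if start < 0:
                raise ValueError("chromosome too short for miRNA windows")
            slots[sp].append((chrom, start))
            pos_by_chrom[chrom] -= window
            idx += 1

    n_classes = len(config.footprint_classes)
    slot_i = {"A": 0, "B": 0}
    for m in range(config.n_mirnas):
        fam_num = 150 + m
        hairpin_a = _hairpin(rng, config.mirna_hairpin_len)
        hairpin_b = _substitute_only(rng, hairpin_a, 0.02)
        name_a = f"spa-miR{fam_num}"
        name_b = f"spb-miR{fam_num}"
        footprint_class = (
            config.footprint_classes[m % n_classes] if m < n_classes else None
        )
        relic_a = relic_b = None
        if footprint_class is not None:
            off = int(rng.integers(0, len(relic_source) - config.footprint_relic_len))
            relic = relic_source[off : off + config.footprint_relic_len]
            half = config.footprint_relic_divergence / 2
            relic_a = _substitute_only(rng, relic, half)
            relic_b = _substitute_only(rng, relic, half)

        placements = {"A": [], "B": []}
        copies = {"A": 1 + (config.mirna_extra_copies if m < config.mirna_multilocus else 0), "B": 1}
        for sp, data, hairpin in (("A", species_a, hairpin_a), ("B", species_b, hairpin_b)):
            for copy_no in range(copies[sp]):
                chrom, w_start = slots[sp][slot_i[sp]]
                slot_i[sp] += 1
                # overwrite the whole window with fresh background so the
                # two species' flanks share nothing but the planted relic
                fresh = _random_seq(rng, window)
                genomes[sp][chrom][w_start : w_start + window] = list(fresh)
                h_start = w_start + flank
                if copy_no == 0:
                    seq = hairpin
                else:
                    # exactly one substitution: stays within the 1-mismatch
                    # mapping budget, so every planted copy is recoverable
                    pos = int(rng.integers(len(hairpin)))
                    alt = [b for b in "ACGT" if b != hairpin[pos]]
                    seq = (
                        hairpin[:pos]
                        + alt[int(rng.integers(3))]
                        + hairpin[pos + 1 :]
                    )
                genomes[sp][chrom][h_start : h_start + len(seq)] = list(seq)
                placements[sp].append((chrom, h_start, copy_no))
                if copy_no == 0 and footprint_class is not None:
                    relic_seq = relic_a if sp == "A" else relic_b
                    r_start = h_start - flank // 2
                    genomes[sp][chrom][r_start : r_start + len(relic_seq)] = list(
                        relic_seq
                    )
                    annotate = (
                        footprint_class == "both"
                        or (footprint_class == "a_only" and sp == "A")
                        or (footprint_class == "b_only" and sp == "B")
                    )
                    if annotate:
                        rep = RepeatFeature(
                            GenomicInterval(chrom, r_start, r_start + len(relic_seq), "+"),
                            family_id=config.families[0].name,
                            superfamily=config.families[0].superfamily,
                            source="de_novo",
                            divergence=config.footprint_relic_divergence,
                        )
                        target = species_a if sp == "A" else species_b
                        target.repeats.append(rep)
                        manifest.repeats[target.name].append(
                            {
                                "family": rep.family_id,
                                "superfamily": rep.superfamily,
                                "chrom": chrom,
                                "start": r_start,
                                "end": r_start + len(relic_seq),
                                "divergence": config.footprint_relic_divergence,
                                "copy": -2,
                                "relic_for": name_a,
                            }
                        )

        species_a.premirnas[name_a] = hairpin_a
        species_b.premirnas[name_b] = hairpin_b
        manifest.mirnas.append(
            {
                "name_a": name_a,
                "name_b": name_b,
                "loci_a": [
                    {"chrom": c, "start": s, "copy": k} for c, s, k in placements["A"]
                ],
                "loci_b": [
                    {"chrom": c, "start": s, "copy": k} for c, s, k in placements["B"]
                ],
            }
        )
        if footprint_class is not None:
            manifest.footprints.append(
                {
                    "name_a": name_a,
                    "name_b": name_b,
                    "class": footprint_class,
                    "relic_len": config.footprint_relic_len,
                }
            )

    species_a.genome = {c: "".join(seq) for c, seq in genomes["A"].items()}
    species_b.genome = {c: "".join(seq) for c, seq in genomes["B"].items()}


# ---------------------------------------------------------------------------
# Expression, sRNA and probes
# ---------------------------------------------------------------------------


def simulate_reads(
    config: SimConfig,
    rng: np.random.Generator,
    species: SpeciesData,
    manifest: TruthManifest,
) -> dict:
    """Expression counts, small-RNA reads and microarray probe placements.

    Per-member counts follow a negative binomial with a per-superfamily
    mean and common dispersion.  Small-RNA reads are substrings of repeat
    copies with a length distribution peaked at 24 nt, the 3' adapter
    appended, plus configured fractions of transcript-derived
    (degradation) and too-short reads.  Probes are tiled over genes and
    repeats with a mix of clean (>90%) and borderline overlaps.
    """
    # --- RNA-seq style counts per repeat member x condition
    counts_rows = []
    for i, rep in enumerate(species.repeats):
        mean = config.nb_mean_by_superfamily.get(rep.superfamily, 2.0)
        r = config.nb_dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p, size=config.n_conditions)
        counts_rows.append(
            {
                "feature_id": f"{rep.family_id}#{i}",
                "family": rep.family_id,
                "superfamily": rep.superfamily,
                "length": len(rep.interval),
                "counts": [int(c) for c in counts],
            }
        )
        manifest.expression.append(
            {
                "feature_id": f"{rep.family_id}#{i}",
                "superfamily": rep.superfamily,
                "nb_mean": mean,
            }
        )

    # --- small RNA reads
    reads: list[str] = []
    lengths = sorted(config.srna_len_probs)
    probs = np.array([config.srna_len_probs[k] for k in lengths])
    probs = probs / probs.sum()
    n_contam = int(config.n_srna_reads * config.srna_contaminant_fraction)
    n_short = int(config.n_srna_reads * config.srna_short_fraction)
    n_repeat = config.n_srna_reads - n_contam - n_short
    rep_pool = species.repeats
    tx_ids = sorted(species.transcripts)
    for _ in range(n_repeat):
        rep = rep_pool[int(rng.integers(len(rep_pool)))]
        length = lengths[int(rng.choice(len(lengths), p=probs))]
        iv = rep.interval
        if len(iv) <= length:
            continue
        start = int(rng.integers(iv.start, iv.end - length))
        frag = species.genome[iv.chrom][start : start + length]
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        reads.append(frag + config.srna_adapter)
    for _ in range(n_contam):
        tx = species.transcripts[tx_ids[int(rng.integers(len(tx_ids)))]]
        length = lengths[int(rng.choice(len(lengths), p=probs))]
        start = int(rng.integers(0, max(1, len(tx) - length)))
        reads.append(tx[start : start + length] + config.srna_adapter)
    for _ in range(n_short):
        reads.append(_random_seq(rng, int(rng.integers(8, 15))) + config.srna_adapter)
    manifest.srna = {
        "n_repeat_derived": n_repeat,
        "n_contaminant": n_contam,
        "n_too_short": n_short,
        "modal_length_planted": int(lengths[int(np.argmax(probs))]),
    }

    # --- probes
    probe_rows = []
    targets = []
    for g in species.genes:
        targets.append(("gene", g.gene_id, g.interval))
    for i, rep in enumerate(species.repeats):
        targets.append(("repeat", rep.family_id, rep.interval))
    for p_i in range(config.n_probes):
        kind, target_id, iv = targets[int(rng.integers(len(targets)))]
        L = config.probe_len
        if len(iv) <= L + 2:
            continue
        clean = rng.random() < 0.7
        if clean:
            start = int(rng.integers(iv.start, iv.end - L))
            expected = kind
            if kind == "repeat":
                # a repeat probe sitting >90% inside a gene body belongs to
                # the gene under the strict gene-first rule
                probe_iv = GenomicInterval(iv.chrom, start, start + L)
                for g in species.genes:
                    if probe_iv.overlap_bp(g.interval) > 0.9 * L:
                        expected = "gene"
                        break
        else:  # borderline: hang >=50% of the probe outside the feature
            hang = int(rng.integers(L // 2 + 1, L - 2))
            start = iv.start - hang
            if start < 0:
                continue
            expected = "borderline"
        probe_rows.append(
            {
                "probe_id": f"probe_{p_i:04d}",
                "chrom": iv.chrom,
                "start": start,
                "end": start + L,
                "planted_target_kind": expected,
                "planted_target_id": target_id,
            }
        )
    manifest.probes = probe_rows
    return {"counts": counts_rows, "srna_reads": reads, "probes": probe_rows}


# ---------------------------------------------------------------------------
# TFBS hit tables
# ---------------------------------------------------------------------------


def simulate_tfbs(
    config: SimConfig,
    rng: np.random.Generator,
    species_a: SpeciesData,
    species_b: SpeciesData,
    manifest: TruthManifest,
    window_bp: int = 2000,
) -> tuple[list[dict], list[dict]]:
    """Planted TFBS hit tables for both species' upstream windows.

    Each orthologous gene pair gets a shared Poisson count of strong
    (high-score) sites in both windows; species A additionally gains a
    Poisson number of weak (low-score) surplus sites per TF, a configured
    fraction of which is placed inside repeat-overlapping window bases.
    Weak scores mark recently arisen sites, so surplus attribution is
    exact on the planted truth.
    """
    from repeatscape.distribution_stats import _build_trees
    from repeatscape.genome_model import flank as gene_flank

    tf_names = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    rep_trees = _build_trees(r.interval for r in species_a.repeats)

    def window_of(gene, data):
        return gene_flank(gene, window_bp, data.assembly)

    hits_a: list[dict] = []
    hits_b: list[dict] = []

    def repeat_positions(window):
        tree = rep_trees.get(window.chrom)
        covered = []
        if tree:
            for itv in sorted(tree.overlap(window.start, window.end)):
                covered.append(
                    (max(itv.begin, window.start), min(itv.end, window.end))
                )
        return covered

    for pair in manifest.ortholog_pairs:
        gene_a = next(g for g in species_a.genes if g.gene_id == pair["gene_a"])
        gene_b = next(g for g in species_b.genes if g.gene_id == pair["gene_b"])
        win_a = window_of(gene_a, species_a)
        win_b = window_of(gene_b, species_b)
        if win_a is None or win_b is None:
            continue
        rep_spans = repeat_positions(win_a)
        for tf, f_rep in zip(tf_names, config.tfbs_repeat_fraction):
            shared = int(rng.poisson(config.tfbs_base_rate))
            for _ in range(shared):
                rel = int(rng.integers(0, len(win_a) - 8))
                score = float(rng.uniform(50, 100))
                hits_a.append(
                    {
                        "tf_name": tf, "gene_id": gene_a.gene_id,
                        "chrom": win_a.chrom, "start": win_a.start + rel,
                        "end": win_a.start + rel + 8, "strand": "+",
                        "score": round(score, 2),
                    }
                )
                rel_b = min(rel, len(win_b) - 8)
                hits_b.append(
                    {
                        "tf_name": tf, "gene_id": gene_b.gene_id,
                        "chrom": win_b.chrom, "start": win_b.start + rel_b,
                        "end": win_b.start + rel_b + 8, "strand": "+",
                        "score": round(score, 2),
                    }
                )
            surplus = int(rng.poisson(config.tfbs_gain_rate))
            for _ in range(surplus):
                in_repeat = bool(rep_spans) and rng.random() < f_rep
                if in_repeat:
                    s, e = rep_spans[int(rng.integers(len(rep_spans)))]
                    start = int(rng.integers(s, max(s + 1, e - 8)))
                else:
                    # rejection-sample a start clear of repeat spans
                    for _try in range(20):
                        start = win_a.start + int(rng.integers(0, len(win_a) - 8))
                        if not any(s < start + 8 and e > start for s, e in rep_spans):
                            break
                hits_a.append(
                    {
                        "tf_name": tf, "gene_id": gene_a.gene_id,
                        "chrom": win_a.chrom, "start": start,
                        "end": start + 8, "strand": "+",
                        "score": round(float(rng.uniform(1, 49)), 2),
                    }
                )
                manifest.tfbs.append(
                    {
                        "tf_name": tf, "gene_a": gene_a.gene_id,
                        "planted_gain": True, "in_repeat": in_repeat,
                    }
                )
    return hits_a, hits_b


# ---------------------------------------------------------------------------
# Top-level driver + writers
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig) -> tuple[dict[str, SpeciesData], TruthManifest, dict]:
    """Full two-species simulation; returns species data, truth, and tables."""
    rng = np.random.default_rng(config.seed)
    species_a, manifest = simulate_genome(config, rng, species="speciesA", gene_prefix="A")
    species_b = plant_orthologs(config, rng, species_a, manifest)
    plant_mirna_footprints(config, rng, species_a, species_b, manifest)
    hits_a, hits_b = simulate_tfbs(config, rng, species_a, species_b, manifest)
    expression = simulate_reads(config, rng, species_a, manifest)
    return (
        {"speciesA": species_a, "speciesB": species_b},
        manifest,
        {"tfbs_a": hits_a, "tfbs_b": hits_b, **expression},
    )


def write_species(data: SpeciesData, outdir: str | Path) -> None:
    """Emit FASTA / `.out` / GFF3 / protein+transcript FASTA for one species."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(data.genome, outdir / f"{data.name}.genome.fasta")
    write_repeatmasker_out(data.repeats, outdir / f"{data.name}.repeats.out")
    write_gff3_genes(data.genes, outdir / f"{data.name}.genes.gff3")
    write_fasta(data.transcripts, outdir / f"{data.name}.transcripts.fasta")
    write_fasta(data.proteins, outdir / f"{data.name}.proteins.fasta")
    if data.premirnas:
        write_fasta(data.premirnas, outdir / f"{data.name}.premirnas.fasta")
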