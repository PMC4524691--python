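# Methods

`repeatscape` re-implements, as a tested library, a genome-wide
repeat-landscape analysis for a pair of closely related plant genomes:
reconciling repeat-family annotations from several sources, measuring
where repeats sit relative to genes, screening orthologue pairs for
exonized repeat sequence, attributing transcription-factor binding-site
(TFBS) gains in promoters to repeat-derived sequence, detecting eroded
repeat footprints around orthologous miRNAs, and accounting for the
transcriptional abundance of repeat families.  Every stage runs against
a synthetic two-species study with planted ground truth, so the whole
pipeline is exercised and scored without any external download.

## Coordinate model

All coordinates are 0-based, half-open.  The three input dialects
convert at the I/O boundary: RepeatMasker `.out` and GFF3 are 1-based
inclusive (`C` in `.out` denotes the minus strand), BED is already
0-based half-open.  Coverage and overlap are strand-agnostic; strand is
used only to build upstream windows and to orient footprint motifs.
Chromosome coverage is computed on *merged* repeat intervals (union of
bases); per-element counts (genic/intergenic, exon/intron, TFBS
attribution) use raw elements.  A repeat "genic" call means >= 1 bp of
overlap with a gene body or its 5 kb upstream window; exon/intron
assignment is exclusive — an element straddling a junction counts in
neither bucket.  Percentages are printed with round-half-up at two
decimals, the convention of the worked tables the suite reproduces.

## Annotation reconciliation

Each repeat family may carry a de novo label, a homology label, and a
protein-domain label.  Reconciliation: full agreement including domain
evidence is the top confidence tier ("highest"); on disagreement the
domain label wins ("domain_based"); without domain evidence the label
agreed by the sequence-level sources — or the only present one — is used
("agreement_based").  When de novo and homology disagree and no domain
exists, the homology label is kept and the record flagged for audit,
since homology calls are database-backed.  Families with no usable label
are "Unknown" and enter a fixed characterization cascade: non-coding-RNA
hits first ("ncRNA_derived"), then nucleotide-database hits
("pseudo_gene"), then SINE-diagnostic motifs — internal Pol III A-box /
B-box and conserved SINE termini — scanned as IUPAC patterns with a
per-pattern mismatch budget ("SINE_like").  The shipped motif strings
are generic placeholders (configuration, not biology baked into code);
hit-table "significance" defaults to identity >= 0.8 over >= 50% of the
shorter consensus and >= 50 aligned bp for cross-species family
matching, all configurable.  Ties between equal-scoring hits break by
identity, then subject id, for reproducibility.

## Alignment engine

Global alignments are Needleman–Wunsch with affine gaps (DNA: match +5,
mismatch −4, gap open 16, extend 4; protein: BLOSUM62, open 12, extend
2 — the classic EMBOSS Stretcher-style defaults, with end gaps charged
like internal gaps and a gap of length L costing open + L·extend).
Local alignments default to Water-style DNA scoring (open 10, extend
0.5).  The DP engine is Biopython's `PairwiseAligner`; this package
fixes the scoring, makes traceback deterministic, and is checked in the
test suite against independently written Gotoh/Smith–Waterman dynamic
programs.

The chained footprint detector deliberately does **not** use the 0.5
gap extension: with match +5 / mismatch −4 and near-free gaps the best
local alignment of two unrelated kilobase-scale sequences meanders
through cheap gaps and scores in the hundreds, so no fixed score
threshold separates signal from noise.  The detector instead charges
gaps like the global preset (open 16, extend 4), which keeps the
expected per-column drift negative; the minimum chain score of 70 (a
14 bp exact match) then leaves only 0–4 short spurious motifs per
unrelated 2 kb flank pair in simulation, versus a long high-identity
chain for a genuine 30 bp relic.

## Exonization screen

Orthologues are reciprocal best hits under local protein alignment
(best-hit-only pairings are reported but excluded from cascade
denominators, preventing many-to-one double counting).  Orthologous
CDS pairs are globally aligned; maximal gap runs become single indel
events and mismatch columns become 1 bp substitutions, with positions
as ungapped offsets.  Each difference projects through the exon ladder
onto genomic coordinates in both species — a diff spanning an intron
junction projects to multiple segments, any of which can carry the
repeat overlap — and is flagged per species when the projection overlaps
>= 1 bp of a repeat.  By default a diff counts as repeat-borne when
flagged in *either* species (a both-species mode is available).
Flagged diffs are translated: synonymous substitutions vanish,
frame-preserving indels become amino-acid indels, frame-shifting indels
are flagged, and pairs gaining an internal stop are excluded from
downstream counts.  Structure-level candidacy is a terminal external
flag column, since structural modelling is out of scope.

## TFBS gain/loss ledger

TFBS hits are pluggable input (any scanner's hit table); sites count
toward a gene when >= 1 bp lies in its 2 kb upstream window.  Per TF
and orthologue pair the count difference defines |delta| "gained" sites
on the surplus side.  Which physical sites are the gained ones is not
observable, so the surplus is taken deterministically from the weakest
end (lowest score, else most-3' position) — a conservative choice.  A
gained site is repeat-attributed when it overlaps >= 1 bp of a repeat
in the gaining species.  The per-TF screen is an exact one-sided
binomial tail whose null probability defaults to the repeat-covered
fraction of all upstream windows (overridable, and surfaced in the
output); raw p-values are reported next to Benjamini–Hochberg q-values
because dozens of TF families are screened at once.

## miRNA footprints

Pre-miRNA hairpins are placed on the genome by exhaustive
substitution-tolerant search (<= 1 mismatch, both strands; no indels),
so multi-locus miRNAs yield one record per placement.  Each locus's
±2 kb window is tested for repeat overlap; enrichment uses the exact
binomial tail with the discrete uniform-placement null below.
Orthologous miRNAs need the same family stem (miRBase-style name
parsing) *and* a reciprocal best sequence match at identity >= 0.7.
For each orthologous locus pair the flank regions (2 kb up + hairpin +
2 kb down) go through iterative local alignment with masking: the best
alignment above the chain threshold contributes its ungapped identical
runs >= 5 bp as motifs, its spans are masked (masked bases can never
match again, so motifs are disjoint and the iteration terminates), and
alignment repeats.  Motifs overlapping a repeat in >= 1 species are
kept; the pair is classed both / A-only / B-only by which species
carries the overlap, and called *strong* when >= 2 kept motifs appear
in the same relative order and orientation in both species.  Spacing is
deliberately unconstrained.  Multi-locus miRNAs are tested per locus
pair; the pair's call is its best locus-pair call.

## Abundance accounting

RPKM is 10^9 · c / (N · L).  A family's average abundance divides the
summed member abundances by (members × conditions), i.e. the mean over
the full member-by-condition grid; members silent in a condition
contribute zeros, which the grid denominator implies.  Microarray
probes assign to a gene when > 90% of the probe length overlaps it,
else to a repeat under the same rule (gene priority is strict), else
stay unassigned.  Small-RNA reads are 3'-adapter-clipped (leftmost
full-adapter occurrence, or a terminal adapter prefix of >= 6 nt),
dropped below 17 nt, removed when they are exact substrings of any
ncRNA or transcript (degradation products), deduplicated, and mapped to
repeat sequences allowing <= 1 substitution and no indels on either
strand via an exhaustive pigeonhole seed-and-verify search (exactly the
Hamming-neighbourhood answer, verified against a sliding-window oracle
in the tests).  Multi-mapping reads count once per matched family;
a fractional-allocation mode is not provided because per-family
percentages are reported without it.

## Null model for placement enrichment

The binomial null probability p0 for "a feature overlaps >= 1 repeat
block" is computed exactly under discrete uniform placement: the number
of start positions whose length-L interval intersects any merged block,
divided by the number of valid starts, accumulated across chromosomes
and clamped to (1e-9, 1−1e-9).  A closed-form approximation
(covered + blocks·L)/genome was considered and rejected because it is
off by one position per block and disagrees with exhaustive placement
enumeration, which the exact form matches identically.  Under this
null, simulated enrichment p-values are uniform up to binomial
discreteness (KS check in the acceptance suite, 500 replicates,
2000 placements each).

## Synthetic study design

The generator emulates, at desk scale, a repeat-rich Solanaceous genome
pair that diverged recently:

* **Genomes** — 4 chromosomes × 200 kb of i.i.d. uniform ACGT
  background (GC 0.5, configurable; the real genomes are AT-rich, which
  is irrelevant to coordinate arithmetic).
* **Repeats** — 8 families with LTR/Gypsy dominant (250 copies of an
  800 bp consensus), then LTR/Copia, LINEs (L1, RTE-BovB), DNA
  transposons (TcMar-Stowaway, Harbinger), SINE/tRNA and an Unknown
  family: ~520 background copies, ~32% merged genome coverage.
  Per-copy divergence is 8–12% with a 9:1 substitution:indel event mix,
  a typical transposable-element decay assumption.  Copies are placed
  uniformly (overlaps allowed) but keep clear of reserved miRNA
  regions, and never overwrite exon bases (stored transcripts are
  authoritative for coding sequence).
* **Genes and orthologues** — 200 genes with 1–4 exons (40–120 codons
  each), stop-free random CDS.  The second species carries codon-wise
  diverged copies (6% synonymous + 2% non-synonymous, never creating a
  premature stop); a fraction q = 0.2 of pairs receives an in-frame
  3–10 codon insertion cut from a repeat-family consensus (stop codons
  scrubbed), with a repeat feature annotated over the inserted genomic
  segment — the planted exonization truth.
* **TFBS** — 5 TFs; each pair's windows share a Poisson(2.0) count of
  strong sites; species A gains Poisson(1.5) weak (low-score) surplus
  sites per TF, placed inside repeat-overlapping window bases with
  per-TF probability 0.7/0.35/0.2/0.1/0.05.  Weak scores mark the
  planted gains, so surplus attribution is exact on the truth — the
  modelling assumption being that recently exapted sites are weaker
  matches.
* **miRNAs** — 12 hairpin-like pre-miRNAs (100 bp stem-loop-stem)
  shared between species at ~2% divergence; 4 are multi-locus in
  species A with extra copies carrying exactly one substitution.  Six
  pairs get a conserved 30 bp Gypsy-consensus relic in the upstream
  flank (5% divergence per species) annotated as a repeat in both / A
  only / B only (3/2/1); flanks are otherwise independent random
  sequence, so the relic and hairpin are the only shared signal.
* **Expression** — per-member negative-binomial counts over 8
  conditions with per-superfamily means (Stowaway and Harbinger most
  active) and dispersion r = 2.  Small RNA: 1200 reads drawn from
  repeat loci with a length distribution peaked at 24 nt, 3' adapter
  appended, plus 8% transcript-derived degradation reads and 5%
  too-short reads to exercise the filters.  120 microarray probes
  (60-mers) tile genes and repeats, 70% cleanly (> 90% inside), the
  rest hanging over feature edges.

Everything is a pure function of the seed (single `numpy` generator,
integer draws); identical seeds give byte-identical emitted files, and
the truth manifest is validated against the emitted annotations on
every write.

What passing recovery tests does **not** show about real data: the
background is unstructured (no tandem repeats, no GC heterogeneity, no
nested insertions or insertion-age structure), gene models are
single-transcript without UTRs, TFBS hit tables are planted rather than
scanned from sequence, and divergence is homogeneous within a family.
The suite demonstrates correctness of the measurement machinery, not
the biology of any particular genome.

## Problem sizes and numerical choices

The default study (4 × 200 kb, 200 orthologue pairs, 12 miRNA pairs,
1200 sRNA reads) runs the full pipeline in about half a minute on one
core and was chosen so that planted-parameter recovery has useful
statistical power (binomial CI width ~±0.055 at n = 200) while the full
test suite stays interactive.  Tests use a further-reduced 3 × 70 kb
configuration.  Other notable choices: exact binomial tails are
computed in log-space by `scipy.stats.binom.sf`; Pearson's t uses
|r|·sqrt(n−2)/sqrt(1−r²) with a two-sided Student p at n−2 df, reported
as a magnitude (the worked tables print positive t for negative r), and
perfect correlation returns t = inf, p = 0 as a flagged limit; the
paired intergenic-enrichment t-test operates on per-superfamily element
densities (elements per Mb of region class), not raw counts, because
genic and intergenic space differ in size; degenerate identical density
vectors return (t = 0, p = 1) rather than NaN.

## Known limitations

* The cross-species Unknown-family matcher is all-vs-all local
  alignment — quadratic in library size, fine for hundreds of consensi,
  not for tens of thousands.
* The exhaustive <= 1-mismatch mappers are exact but not index-based;
  genome-scale read sets would need an FM-index-backed aligner.
* Gain/loss attribution assumes site counts are comparable across
  species (no scanner-threshold calibration between genomes).
* The footprint caller reports motif coordinates on the forward genome
  strand of each species and does not search inverted (strand-swapped)
  relic arrangements.
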