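"""Reconciliation of repeat-family annotations from three sources.

A repeat-family library typically carries up to three labels per family:
a de novo label (clustering-based discovery), a homology label (similarity
to a curated repeat database), and a domain label (conserved protein
domains in translated frames).  ``reconcile`` merges them into a single
call with a confidence tier.  Families that stay "Unknown" are pushed
through a fixed characterization cascade: non-coding RNA hits, then
nucleotide-database hits (pseudo-genes), then SINE-diagnostic motifs
(internal Pol III A-box/B-box and conserved SINE termini).
"""

from __future__ import annotations

from dataclasses import dataclass

from repeatscape.alignment import alignment_identity, local_align_best

__all__ = [
    "SourceLabels",
    "ConsensusDecision",
    "MotifPattern",
    "HitRecord",
    "reconcile",
    "characterize_unknown",
    "scan_iupac",
    "match_unknown_families",
    "UNKNOWN",
    "DEFAULT_MOTIF_PATTERNS",
]

UNKNOWN = "Unknown"

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SourceLabels:
    """Per-family labels from the three annotation sources (None = absent)."""

    family_id: str
    de_novo_label: str | None = None
    homology_label: str | None = None
    domain_label: str | None = None

    @property
    def present(self) -> dict[str, str]:
        out = {}
        for name in ("de_novo", "homology", "domain"):
            label = getattr(self, f"{name}_label")
            if label is not None and label != UNKNOWN:
                out[name] = label
        return out


@dataclass(frozen=True)
class ConsensusDecision:
    family_id: str
    final_label: str
    confidence: str  # highest | domain_based | agreement_based | unknown
    evidence: tuple[str, ...] = ()
    flagged: bool = False  # de novo vs homology disagreement with no domain


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC motif with a mismatch budget."""

    name: str
    pattern: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.name}: non-IUPAC symbols {sorted(bad)!r}"
            )
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


# Pol III internal promoter boxes and SINE 5'/3' termini.  The exact
# diagnostic strings are configuration, not biology baked into code:
# these defaults are generic placeholder consensi and should be replaced
# with curated patterns for production use.
DEFAULT_MOTIF_PATTERNS = (
    MotifPattern("A_box", "TRGCNNARYNNG", max_mismatches=1),
    MotifPattern("B_box", "GTTCGANNC", max_mismatches=1),
    MotifPattern("sine_5prime", "GGGCTGGTGG", max_mismatches=1),
    MotifPattern("sine_3prime", "CCTACTTTCA", max_mismatches=1),
)


@dataclass(frozen=True, order=True)
class HitRecord:
    """BLAST-style tabular hit (score descending wins; deterministic ties)."""

    query_id: str
    subject_id: str
    subject_class: str  # ncRNA | nt_db | family
    score: float
    identity: float
    aligned_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.score < 0:
            raise ValueError("score must be >= 0")


def reconcile(labels: SourceLabels) -> ConsensusDecision:
    """Merge the three source labels into one consensus call.

    All present labels agree -> that label at "highest" confidence.  On
    disagreement, the domain label wins when present ("domain_based").
    Without a domain label, the label agreed by de novo and homology (or
    the single present one) is used ("agreement_based"); if those two
    disagree, the homology label is kept and the record flagged for audit.
    No usable label -> "Unknown".
    """
    present = labels.present
    if not present:
        return ConsensusDecision(labels.family_id, UNKNOWN, "unknown")
    values = set(present.values())
    if len(values) == 1:
        # full agreement including domain evidence earns the top tier;
        # agreement among sequence-level sources alone is one tier down
        confidence = "highest" if "domain" in present else "agreement_based"
        return ConsensusDecision(
            labels.family_id, values.pop(), confidence, tuple(sorted(present))
        )
    if "domain" in present:
        return ConsensusDecision(
            labels.family_id, present["domain"], "domain_based", ("domain",)
        )
    # de novo vs homology disagree with no domain evidence: fall back to
    # the homology label (database-backed) and flag
    if "homology" in present:
        return ConsensusDecision(
            labels.family_id,
            present["homology"],
            "agreement_based",
            ("homology",),
            flagged="de_novo" in present,
        )
    return ConsensusDecision(
        labels.family_id, present["de_novo"], "agreement_based", ("de_novo",)
    )


def best_hit(hits: list[HitRecord]) -> HitRecord | None:
    """Highest score; ties broken by higher identity, then subject_id."""
    if not hits:
        return None
    return max(hits, key=lambda h: (h.score, h.identity, _NegStr(h.subject_id)))


class _NegStr(str):
    """Reverses string comparison so max() prefers the lexicographically
    smaller subject_id on full ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def scan_iupac(
    seq: str, pattern: MotifPattern
) -> list[tuple[int, str, int]]:
    """All windows matching the IUPAC pattern with <= max_mismatches.

    Both strands are scanned; positions are 0-based offsets of the window
    on the forward sequence.  ``N`` in the subject matches nothing.
    Returns (position, strand, mismatches) sorted by position then strand.
    """
    seq = seq.upper()
    pat = pattern.pattern.upper()
    m = len(pat)
    hits: list[tuple[int, str, int]] = []
    allowed = [set(IUPAC[c]) for c in pat]
    for strand, subject in (("+", seq), ("-", reverse_complement(seq))):
        n = len(subject)
        for i in range(n - m + 1):
            window = subject[i : i + m]
            mism = 0
            for c, ok in zip(window, allowed):
                if c not in ok:  # subject N never matches
                    mism += 1
                    if mism > pattern.max_mismatches:
                        break
            else:
                pos = i if strand == "+" else n - i - m
                hits.append((pos, strand, mism))
    return sorted(hits)


def characterize_unknown(
    family_seq: str,
    ncrna_hits: list[HitRecord],
    nt_hits: list[HitRecord],
    motif_patterns: tuple[MotifPattern, ...] = DEFAULT_MOTIF_PATTERNS,
) -> str:
    """Characterize an Unknown family through the fixed cascade.

    Stage order is fixed: non-coding RNA hits ("ncRNA_derived"), then
    nucleotide-database hits ("pseudo_gene"), then SINE-diagnostic motif
    presence ("SINE_like").  The first stage with qualifying evidence
    wins; otherwise the family stays "Unknown".
    """
    if best_hit(ncrna_hits) is not None:
        return "ncRNA_derived"
    if best_hit(nt_hits) is not None:
        return "pseudo_gene"
    for pattern in motif_patterns:
        if scan_iupac(family_seq, pattern):
            return "SINE_like"
    return UNKNOWN


def match_unknown_families(
    unknowns_a: dict[str, str],
    unknowns_b: dict[str, str],
    min_identity: float = 0.8,
    min_cov: float = 0.5,
    min_aligned_bp: int = 50,
) -> list[tuple[str, str, float]]:
    """Cross-species pairing of Unknown family consensi.

    A pair (a, b) is reported when the best local DNA alignment has
    identity >= ``min_identity`` over >= ``min_cov`` of the shorter
    consensus and >= ``min_aligned_bp`` aligned columns.  One family may
    match several partners (many-to-one homologs are expected when one
    species carries duplicated relatives).
    """
    pairs: list[tuple[str, str, float]] = []
    for name_a, seq_a in sorted(unknowns_a.items()):
        for name_b, seq_b in sorted(unknowns_b.items()):
            hit = local_align_best(seq_a, seq_b)
            if hit is None:
                continue
            ident = alignment_identity(hit)
            shorter = min(len(seq_a), len(seq_b))
            aligned_cols = len(hit.aligned_a)
            cov = min(hit.end_a - hit.start_a, hit.end_b - hit.start_b) / shorter
            if (
                ident >= min_identity
                and cov >= min_cov
                and aligned_cols >= min_aligned_bp
            ):
                pairs.append((name_a, name_b, round(ident, 4)))
    return pairs


def reconcile_table(all_labels: list[SourceLabels]) -> "pandas.DataFrame":
    """Decision table over a family library (family_id, label, confidence)."""
    import pandas as pd

    rows = []
    for labels in all_labels:
        d = reconcile(labels)
        rows.append(
            {
                "family_id": d.family_id,
                "final_label": d.final_label,
                "confidence": d.confidence,
                "evidence": ",".join(d.evidence),
                "flagged": d.flagged,
            }
        )
    return pd.DataFrame(rows)
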