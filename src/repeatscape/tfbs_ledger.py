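"""TFBS counting in 2 kb upstream windows, gain/loss, repeat attribution.

For every transcription factor and every orthologous gene pair, binding
sites in the two species' 2 kb upstream windows are counted; the species
with the surplus "gained" |delta| sites.  Gained sites overlapping a
repeat are attributed to repeat-borne sequence, and per-TF totals are
screened with an exact binomial test whose null probability defaults to
the repeat-covered fraction of all upstream windows.  Raw p-values are
reported alongside Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from repeatscape.distribution_stats import enrichment_binomial, pct_round2
from repeatscape.genome_model import (
    AssemblyIndex,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    covered_bases,
    flank,
)

__all__ = [
    "TFBSHit",
    "GainLossRecord",
    "TFSummary",
    "count_sites",
    "gain_loss",
    "attribute_gains_to_repeats",
    "tfbs_gain_binomial",
    "repeat_fraction_of_windows",
    "benjamini_hochberg",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TFBSHit:
    tf_name: str
    gene_id: str
    interval: GenomicInterval
    score: float | None = None


@dataclass
class GainLossRecord:
    tf_name: str
    gene_a: str
    gene_b: str
    count_a: int
    count_b: int
    gained_sites: list[TFBSHit] = field(default_factory=list)
    gained_in_repeat: int = 0

    @property
    def delta(self) -> int:
        return self.count_a - self.count_b

    @property
    def gaining_species(self) -> str | None:
        if self.delta > 0:
            return "a"
        if self.delta < 0:
            return "b"
        return None


@dataclass(frozen=True)
class TFSummary:
    tf_name: str
    gain_repeat_total: int
    gain_total: int
    binomial_p: float | None = None
    q_value: float | None = None

    @property
    def pct_repeat(self) -> float:
        if self.gain_total == 0:
            return 0.0
        return pct_round2(self.gain_repeat_total, self.gain_total)


def upstream_windows(
    genes: Sequence[GeneModel],
    assembly: AssemblyIndex | None = None,
    window_bp: int = 2000,
) -> dict[str, GenomicInterval]:
    out = {}
    for g in genes:
        w = flank(g, window_bp, assembly)
        if w is not None:
            out[g.gene_id] = w
    return out


def count_sites(
    hits: Iterable[TFBSHit],
    genes: Sequence[GeneModel],
    assembly: AssemblyIndex | None = None,
    window_bp: int = 2000,
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], list[TFBSHit]]]:
    """Per-(TF, gene) site counts within each gene's upstream window.

    A site straddling the window edge counts if >=1 bp lies inside.
    Hits outside their gene's window are skipped with a warning.
    Returns (counts, per-key site lists).
    """
    windows = upstream_windows(genes, assembly, window_bp)
    counts: dict[tuple[str, str], int] = {}
    sites: dict[tuple[str, str], list[TFBSHit]] = {}
    for hit in hits:
        window = windows.get(hit.gene_id)
        if window is None or not hit.interval.overlaps(window):
            log.warning(
                "TFBS hit %s for gene %s outside its upstream window; skipped",
                hit.tf_name,
                hit.gene_id,
            )
            continue
        key = (hit.tf_name, hit.gene_id)
        counts[key] = counts.get(key, 0) + 1
        sites.setdefault(key, []).append(hit)
    return counts, sites


def _surplus_sites(site_list: list[TFBSHit], n: int) -> list[TFBSHit]:
    """The n "gained" sites: lowest-scoring first, else most-3' position.

    Deterministic and conservative; which physical sites are the gained
    ones is not observable, so the surplus is taken from the weakest end.
    """
    if all(s.score is not None for s in site_list):
        ranked = sorted(site_list, key=lambda s: (s.score, -s.interval.start))
    else:
        ranked = sorted(site_list, key=lambda s: -s.interval.start)
    return ranked[:n]


def gain_loss(
    counts_a: dict[tuple[str, str], int],
    counts_b: dict[tuple[str, str], int],
    sites_a: dict[tuple[str, str], list[TFBSHit]],
    sites_b: dict[tuple[str, str], list[TFBSHit]],
    pairs: Sequence[tuple[str, str]],
    tf_names: Sequence[str] | None = None,
) -> list[GainLossRecord]:
    """Per-TF per-pair count difference with the surplus sites enumerated."""
    if tf_names is None:
        tf_names = sorted({tf for tf, _ in counts_a} | {tf for tf, _ in counts_b})
    records = []
    for gene_a, gene_b in pairs:
        for tf in tf_names:
            ca = counts_a.get((tf, gene_a), 0)
            cb = counts_b.get((tf, gene_b), 0)
            rec = GainLossRecord(tf, gene_a, gene_b, ca, cb)
            if rec.delta > 0:
                rec.gained_sites = _surplus_sites(
                    sites_a.get((tf, gene_a), []), rec.delta
                )
            elif rec.delta < 0:
                rec.gained_sites = _surplus_sites(
                    sites_b.get((tf, gene_b), []), -rec.delta
                )
            records.append(rec)
    return records


def repeat_fraction_of_windows(
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatFeature],
    assembly: AssemblyIndex | None = None,
    window_bp: int = 2000,
) -> float:
    """Fraction of upstream-window bases covered by repeats (binomial null)."""
    windows = list(upstream_windows(genes, assembly, window_bp).values())
    total = covered_bases(windows)
    if total == 0:
        raise ValueError("no upstream windows")
    covered = 0
    rep_ivs = [r.interval for r in repeats]
    for w in windows:
        covered += covered_bases(rep_ivs, region=w)
    return covered / total


def tfbs_gain_binomial(
    gain_repeat: int, gain_total: int, p0: float
) -> float | None:
    """One-sided P(X >= gain_repeat | gain_total, p0); None if no gains."""
    if gain_total == 0:
        return None
    return enrichment_binomial(gain_repeat, gain_total, p0)


def benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """BH step-up q-values preserving input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_last, idx in enumerate(reversed(order)):
        rank = m - rank_from_last
        prev = min(prev, pvals[idx] * m / rank)
        q[idx] = prev
    return q


def attribute_gains_to_repeats(
    records: Sequence[GainLossRecord],
    repeats_a: Sequence[RepeatFeature],
    repeats_b: Sequence[RepeatFeature],
    p0: float | None = None,
) -> list[TFSummary]:
    """Fill gained_in_repeat per record and aggregate per-TF summaries.

    A gained site is in-repeat iff its interval overlaps >=1 bp of a
    repeat in the gaining species.  When ``p0`` is given, each TF's
    (gain_repeat, gain_total) pair is screened with the exact binomial
    tail and BH q-values are attached.
    """
    from repeatscape.distribution_stats import _build_trees, _tree_overlaps

    trees = {
        "a": _build_trees(r.interval for r in repeats_a),
        "b": _build_trees(r.interval for r in repeats_b),
    }
    totals: dict[str, list[int]] = {}
    for rec in records:
        species = rec.gaining_species
        rec.gained_in_repeat = 0
        if species is not None:
            rec.gained_in_repeat = sum(
                1
                for site in rec.gained_sites
                if _tree_overlaps(trees[species], site.interval)
            )
        t = totals.setdefault(rec.tf_name, [0, 0])
        t[0] += rec.gained_in_repeat
        t[1] += len(rec.gained_sites)
    summaries = [
        TFSummary(tf, gain_rep, gain_tot)
        for tf, (gain_rep, gain_tot) in sorted(totals.items())
    ]
    if p0 is not None:
        pvals = [
            tfbs_gain_binomial(s.gain_repeat_total, s.gain_total, p0)
            for s in summaries
        ]
        testable = [i for i, p in enumerate(pvals) if p is not None]
        qvals = benjamini_hochberg([pvals[i] for i in testable])
        qmap = dict(zip(testable, qvals))
        summaries = [
            TFSummary(
                s.tf_name,
                s.gain_repeat_total,
                s.gain_total,
                binomial_p=pvals[i],
                q_value=qmap.get(i),
            )
            for i, s in enumerate(summaries)
        ]
    return summaries
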