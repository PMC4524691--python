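"""Stage orchestration over simulated (or user-supplied) inputs.

Stages run in dependency order: simulate -> annotate -> distribution ->
exonize -> tfbs -> mirna -> abundance.  Every emitted number lives in a
stage output file (TSV/JSON) under the run directory; a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from repeatscape import (
    abundance as ab,
    annotation_consensus as ac,
    distribution_stats as ds,
    exonization as ex,
    mirna_footprints as mf,
    synthetic_data as sd,
    tfbs_ledger as tl,
)
from repeatscape.genome_model import GenomicInterval

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = (
    "annotate",
    "distribution",
    "exonize",
    "tfbs",
    "mirna",
    "abundance",
)


@dataclass
class RunConfig:
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    outdir: Path = Path("repeatscape_run")
    stages: tuple[str, ...] = STAGES
    upstream_bp: int = 5000
    tfbs_window_bp: int = 2000
    mirna_flank_bp: int = 2000
    footprint_min_score: float = 70.0
    write_inputs: bool = True


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _stage_annotate(species, outdir: Path) -> dict:
    """Reconcile per-family labels; simulated sources agree except Unknowns."""
    rows = []
    for sp, data in species.items():
        fams = {}
        for rep in data.repeats:
            fams[rep.family_id] = rep.superfamily
        for fam_id, superfam in sorted(fams.items()):
            known = superfam != "Unknown"
            labels = ac.SourceLabels(
                family_id=fam_id,
                de_novo_label=superfam if known else None,
                homology_label=superfam if known else None,
                domain_label=superfam if known else None,
            )
            d = ac.reconcile(labels)
            rows.append(
                {
                    "species": sp,
                    "family_id": fam_id,
                    "final_label": d.final_label,
                    "confidence": d.confidence,
                }
            )
    df = pd.DataFrame(rows)
    _write_tsv(df, outdir / "annotation_decisions.tsv")
    return {"n_families": len(df), "n_unknown": int((df.final_label == "Unknown").sum())}


def _stage_distribution(species, config: RunConfig, outdir: Path) -> dict:
    summary = {}
    for sp, data in species.items():
        assembly = data.assembly
        cov = ds.chromosome_coverage(data.repeats, assembly)
        _write_tsv(
            pd.DataFrame(
                [
                    {"chrom": c.chrom, "repeat_bp": c.repeat_bp,
                     "chrom_bp": c.chrom_bp, "pct": c.pct}
                    for c in cov
                ]
            ),
            outdir / f"{sp}.chromosome_coverage.tsv",
        )
        parts, associated = ds.partition_genic(
            data.repeats, data.genes, assembly, config.upstream_bp
        )
        exin = ds.partition_exon_intron(data.repeats, data.genes)
        part_rows = []
        for sf in sorted(parts):
            pc, ei = parts[sf], exin.get(sf)
            part_rows.append(
                {
                    "superfamily": sf,
                    "n_genic": pc.n_genic,
                    "n_intergenic": pc.n_intergenic,
                    "n_upstream": pc.n_upstream,
                    "n_genebody": pc.n_genebody,
                    "n_exonic": ei.n_exonic if ei else 0,
                    "n_intronic": ei.n_intronic if ei else 0,
                }
            )
        _write_tsv(pd.DataFrame(part_rows), outdir / f"{sp}.partitions.tsv")

        # per-chromosome coverage correlation: superfamily vs gene coverage
        chroms = sorted(assembly.lengths)
        gene_cov = [
            100
            * ds.covered_bases([g.interval for g in data.genes], chrom=c)
            / assembly.lengths[c]
            for c in chroms
        ]
        corr_rows = []
        superfams = sorted({r.superfamily for r in data.repeats})
        for sf in superfams:
            sf_cov = [
                100
                * ds.covered_bases(
                    [r.interval for r in data.repeats if r.superfamily == sf],
                    chrom=c,
                )
                / assembly.lengths[c]
                for c in chroms
            ]
            try:
                res = ds.pearson_with_t(sf_cov, gene_cov)
            except ValueError:
                continue
            corr_rows.append(
                {"superfamily": sf, "pcc": res.r, "t_stat": res.t_stat, "p": res.p}
            )
        _write_tsv(pd.DataFrame(corr_rows), outdir / f"{sp}.coverage_correlation.tsv")

        n_assoc = sum(associated.values())
        n_genic = sum(pc.n_genic for pc in parts.values())
        n_total = len(data.repeats)
        merged = ds.merge_intervals([r.interval for r in data.repeats])
        mean_gene_len = int(
            sum(len(g.interval) for g in data.genes) / max(1, len(data.genes))
        )
        p0 = ds.null_overlap_probability(merged, mean_gene_len, assembly)
        gene_binom_p = ds.enrichment_binomial(n_assoc, len(data.genes), p0)
        genic_d, inter_d = ds.genic_intergenic_densities(
            parts, data.genes, assembly, config.upstream_bp
        )
        t, t_p = ds.intergenic_enrichment_ttest(genic_d, inter_d)
        summary[sp] = {
            "genome_pct_repeats": cov[-1].pct,
            "genes_repeat_associated": n_assoc,
            "n_genes": len(data.genes),
            "pct_genes_associated": ds.pct_round2(n_assoc, len(data.genes)),
            "repeats_genic": n_genic,
            "repeats_total": n_total,
            "pct_repeats_genic": ds.pct_round2(n_genic, n_total),
            "gene_association_binomial_p": gene_binom_p,
            "gene_association_null_p0": p0,
            "intergenic_ttest_t": t,
            "intergenic_ttest_p": t_p,
        }
    with open(outdir / "distribution_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _stage_exonize(species, outdir: Path) -> dict:
    a, b = species["speciesA"], species["speciesB"]
    pairs = ex.find_orthologs(a.proteins, b.proteins)
    reciprocal = [p for p in pairs if p.reciprocal]
    _write_tsv(
        pd.DataFrame(
            [
                {"gene_a": p.gene_a, "gene_b": p.gene_b, "score": p.score,
                 "identity": p.identity, "reciprocal": p.reciprocal}
                for p in pairs
            ]
        ),
        outdir / "ortholog_pairs.tsv",
    )
    genes_a = {g.gene_id: g for g in a.genes}
    genes_b = {g.gene_id: g for g in b.genes}
    pair_diffs: dict[tuple[str, str], list[ex.SeqDiff]] = {}
    pair_cds: dict[tuple[str, str], tuple[str, str]] = {}
    diff_rows = []
    for p in reciprocal:
        cds_a, cds_b = a.transcripts[p.gene_a], b.transcripts[p.gene_b]
        aln = ex.global_align(cds_a, cds_b)
        diffs = ex.extract_diffs(aln)
        diffs = ex.map_diffs_to_repeats(
            diffs,
            ex.TranscriptMap(genes_a[p.gene_a]),
            ex.TranscriptMap(genes_b[p.gene_b]),
            a.repeats,
            b.repeats,
        )
        key = (p.gene_a, p.gene_b)
        pair_diffs[key] = diffs
        pair_cds[key] = (cds_a, cds_b)
        for d in diffs:
            if d.in_repeat:
                diff_rows.append(
                    {
                        "gene_a": p.gene_a, "gene_b": p.gene_b, "kind": d.kind,
                        "pos_a": d.pos_a, "pos_b": d.pos_b, "length": d.length,
                        "in_repeat_a": d.in_repeat_a, "in_repeat_b": d.in_repeat_b,
                    }
                )
    report = ex.run_cascade(pair_diffs, pair_cds)
    _write_tsv(pd.DataFrame(diff_rows), outdir / "repeat_diffs.tsv")
    with open(outdir / "exonization_cascade.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=1, sort_keys=True)
    return report.as_dict()


def _hits_from_rows(rows) -> list[tl.TFBSHit]:
    return [
        tl.TFBSHit(
            r["tf_name"],
            r["gene_id"],
            GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]),
            score=r.get("score"),
        )
        for r in rows
    ]


def _stage_tfbs(species, tables, config: RunConfig, outdir: Path) -> dict:
    a, b = species["speciesA"], species["speciesB"]
    hits_a = _hits_from_rows(tables["tfbs_a"])
    hits_b = _hits_from_rows(tables["tfbs_b"])
    counts_a, sites_a = tl.count_sites(hits_a, a.genes, a.assembly, config.tfbs_window_bp)
    counts_b, sites_b = tl.count_sites(hits_b, b.genes, b.assembly, config.tfbs_window_bp)
    pairs = [
        (r["gene_a"], r["gene_b"])
        for r in tables.get("ortholog_pairs", [])
    ] or [(p["gene_a"], p["gene_b"]) for p in tables["truth_pairs"]]
    records = tl.gain_loss(counts_a, counts_b, sites_a, sites_b, pairs)
    p0 = tl.repeat_fraction_of_windows(
        a.genes, a.repeats, a.assembly, config.tfbs_window_bp
    )
    summaries = tl.attribute_gains_to_repeats(records, a.repeats, b.repeats, p0=p0)
    df = pd.DataFrame(
        [
            {
                "tf_name": s.tf_name,
                "gain_in_repeat": s.gain_repeat_total,
                "gain_total": s.gain_total,
                "pct_repeat": s.pct_repeat,
                "binomial_p": s.binomial_p,
                "q_value": s.q_value,
                "null_p0": p0,
            }
            for s in summaries
        ]
    )
    _write_tsv(df, outdir / "tfbs_gain_summary.tsv")
    return {
        "null_p0": p0,
        "summaries": {s.tf_name: [s.gain_repeat_total, s.gain_total] for s in summaries},
    }


def _stage_mirna(species, config: RunConfig, outdir: Path) -> dict:
    a, b = species["speciesA"], species["speciesB"]
    loci_a = mf.map_premirnas(a.premirnas, a.genome)
    loci_b = mf.map_premirnas(b.premirnas, b.genome)
    flags_a, enr_a = mf.flank_repeat_overlap(
        loci_a, a.repeats, a.assembly, config.mirna_flank_bp
    )
    flags_b, enr_b = mf.flank_repeat_overlap(
        loci_b, b.repeats, b.assembly, config.mirna_flank_bp
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "species": sp, "mirna_id": l.mirna_id, "copy": l.copy_index,
                    "chrom": l.interval.chrom, "start": l.interval.start,
                    "end": l.interval.end, "strand": l.interval.strand,
                    "flank_repeat_overlap": flags[(l.mirna_id, l.copy_index)],
                }
                for sp, loci, flags in (("A", loci_a, flags_a), ("B", loci_b, flags_b))
                for l in loci
            ]
        ),
        outdir / "mirna_loci.tsv",
    )
    ortho = mf.pair_orthologous_mirnas(a.premirnas, b.premirnas)
    by_id_a: dict[str, list[mf.MirnaLocus]] = {}
    for l in loci_a:
        by_id_a.setdefault(l.mirna_id, []).append(l)
    by_id_b: dict[str, list[mf.MirnaLocus]] = {}
    for l in loci_b:
        by_id_b.setdefault(l.mirna_id, []).append(l)
    calls = []
    for name_a, name_b, ident in ortho:
        best = None
        for la in by_id_a.get(name_a, []):
            for lb in by_id_b.get(name_b, []):
                call = mf.call_footprints(
                    f"{name_a}|{name_b}", la, lb,
                    a.genome, b.genome, a.repeats, b.repeats,
                    a.assembly, b.assembly,
                    config.mirna_flank_bp, config.footprint_min_score,
                )
                rank = {"none": 0, "candidate": 1, "strong": 2}[call.strength]
                if best is None or rank > {"none": 0, "candidate": 1, "strong": 2}[
                    best.strength
                ]:
                    best = call
        if best is not None:
            calls.append(best)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "pair": c.pair_id, "class": c.species_class,
                    "strength": c.strength, "n_motifs": len(c.motifs),
                }
                for c in calls
            ]
        ),
        outdir / "mirna_footprints.tsv",
    )
    class_counts: dict[str, int] = {}
    for c in calls:
        class_counts[c.species_class] = class_counts.get(c.species_class, 0) + 1
    return {
        "n_loci_a": len(loci_a),
        "n_loci_b": len(loci_b),
        "flank_enrichment_p_a": enr_a,
        "flank_enrichment_p_b": enr_b,
        "n_ortholog_pairs": len(ortho),
        "footprint_classes": class_counts,
        "n_strong": sum(1 for c in calls if c.strength == "strong"),
    }


def _stage_abundance(species, tables, config: RunConfig, outdir: Path) -> dict:
    a = species["speciesA"]
    counts_rows = tables["counts"]
    n_cond = len(counts_rows[0]["counts"]) if counts_rows else 0
    lib_totals = [
        sum(r["counts"][c] for r in counts_rows) for c in range(n_cond)
    ]
    fam_values: dict[str, list[float]] = {}
    fam_superfam: dict[str, str] = {}
    fam_members: dict[str, set] = {}
    rpkm_rows = []
    for r in counts_rows:
        for c in range(n_cond):
            fc = ab.FeatureCounts(
                r["feature_id"], r["counts"][c], r["length"], max(1, lib_totals[c])
            )
            val = ab.rpkm(fc)
            fam_values.setdefault(r["superfamily"], []).append(val)
            rpkm_rows.append(
                {"feature_id": r["feature_id"], "condition": c, "rpkm": val}
            )
        fam_superfam[r["superfamily"]] = r["superfamily"]
        fam_members.setdefault(r["superfamily"], set()).add(r["feature_id"])
    fam_rows = []
    for sf in sorted(fam_values):
        avg = ab.family_average(
            fam_values[sf], len(fam_members[sf]), n_cond
        )
        fam_rows.append(
            {
                "superfamily": sf,
                "n_members": len(fam_members[sf]),
                "n_conditions": n_cond,
                "average_rpkm": avg,
            }
        )
    _write_tsv(pd.DataFrame(fam_rows), outdir / "family_abundance.tsv")

    placements = {
        r["probe_id"]: GenomicInterval(r["chrom"], r["start"], r["end"])
        for r in tables["probes"]
    }
    assignments = ab.assign_probes(placements, a.genes, a.repeats)
    _write_tsv(
        pd.DataFrame(
            [
                {"probe_id": p.probe_id, "target": p.target,
                 "target_id": p.target_id, "overlap_fraction": p.overlap_fraction}
                for p in assignments
            ]
        ),
        outdir / "probe_assignments.tsv",
    )

    sim = config.sim
    unique = ab.process_srna(
        tables["srna_reads"],
        sim.srna_adapter,
        ncrna_seqs=(),
        transcript_seqs=[a.transcripts[t] for t in sorted(a.transcripts)],
    )
    rep_seqs = {}
    superfamily_of = {}
    for i, rep in enumerate(a.repeats):
        fid = f"{rep.family_id}#{i}"
        iv = rep.interval
        rep_seqs[fid] = a.genome[iv.chrom][iv.start : iv.end]
        superfamily_of[fid] = rep.superfamily
    profile = ab.map_srna(unique, rep_seqs, superfamily_of)
    _write_tsv(
        pd.DataFrame(
            [
                {"length": k, "n_unique_reads": v}
                for k, v in sorted(profile.length_histogram.items())
            ]
        ),
        outdir / "srna_length_histogram.tsv",
    )
    _write_tsv(pd.DataFrame(rpkm_rows), outdir / "member_rpkm.tsv")
    _write_tsv(
        pd.DataFrame(
            [
                {"superfamily": sf, "n_mapped_reads": n}
                for sf, n in sorted(profile.superfamily_counts.items())
            ]
        ),
        outdir / "srna_superfamily_counts.tsv",
    )
    return {
        "n_unique_srna": profile.total_unique_reads,
        "srna_mapped_fraction": profile.mapped_fraction,
        "srna_modal_length": profile.modal_length,
        "top_family_rpkm": max(fam_rows, key=lambda r: r["average_rpkm"])["superfamily"]
        if fam_rows
        else None,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the aggregated JSON summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species, manifest, tables = sd.simulate_study(config.sim)
    tables["truth_pairs"] = manifest.ortholog_pairs
    if config.write_inputs:
        inputs = outdir / "inputs"
        for data in species.values():
            sd.write_species(data, inputs)
        manifest.write(inputs / "truth_manifest.json", species)

    summary: dict = {"seed": config.sim.seed, "stages": list(config.stages)}
    runners = {
        "annotate": lambda: _stage_annotate(species, outdir),
        "distribution": lambda: _stage_distribution(species, config, outdir),
        "exonize": lambda: _stage_exonize(species, outdir),
        "tfbs": lambda: _stage_tfbs(species, tables, config, outdir),
        "mirna": lambda: _stage_mirna(species, config, outdir),
        "abundance": lambda: _stage_abundance(species, tables, config, outdir),
    }
    for stage in config.stages:
        summary[stage] = runners[stage]()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
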