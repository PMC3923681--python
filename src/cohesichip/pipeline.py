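"""End-to-end orchestration: simulate -> annotate -> profile -> repeats ->
enrich, with a consolidated JSON + text report of the summary statistics.

The report is fully determined by the config (no timestamps in the report
body); logging goes to stderr and never affects results.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation_expression import (annotate_peaks, expression_from_counts,
                                    promoter_class_fractions)
from .colocalization import (coloc_score, conservation,
                             nearest_peak_distances, signal_profile)
from .enrichment_stats import (MotifSpec, assign_genes_to_peaks,
                               gene_list_overlap_test,
                               motif_enrichment_vs_random_promoters,
                               motif_site_fraction)
from .formats_io import write_table
from .repeat_enrichment import (class_rpk10m, fold_enrichment,
                                weight_and_filter)
from .synthetic_data import (SimConfig, default_config, generate_world,
                             simulate_expression, simulate_reads, write_world)

log = logging.getLogger("cohesichip")


def report_fractions(part: int, total: int) -> str:
    """Percentage string rounded to the nearest integer, ties away from
    zero (912/1138 -> "80%", 122/1118 -> "11%")."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if part < 0:
        raise ValueError("part must be >= 0")
    pct = 100.0 * part / total
    return f"{int(math.floor(pct + 0.5))}%"


def _stage(name):
    log.info("stage: %s", name)


def run_all(config: SimConfig, outdir, profile_flank: int = 1000,
            profile_bin: int = 10, center_halfwidth: int = 200,
            motif_arm_size: int | None = None,
            write_files: bool = False) -> dict:
    """Run the full synthetic pipeline and write report.json / report.txt.

    The first configured factor is the reference factor (peaks annotated,
    profiled against the second factor's reads, motif-tested); the factor
    named "input" is the control for repeat enrichment. Any stage failure
    propagates with the stage name prepended; partial outputs already
    written are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}
    stage = "simulate"
    try:
        world = generate_world(config)
        if write_files:
            write_world(world, outdir / "sim", write_reads=False)
        ref = config.factors[0].name
        peaks = world.truth.factor_peaks[ref]
        reads = {f.name: simulate_reads(world, f.name)[0]
                 for f in config.factors}

        stage = "annotate"
        _stage(stage)
        table, summary = annotate_peaks(peaks, world.genes,
                                        world.chrom_lengths)
        write_table(table, outdir / f"annotation_{ref}.tsv")
        write_table(summary, outdir / f"annotation_summary_{ref}.tsv")
        counts, total_rna = simulate_expression(world)
        expr = expression_from_counts(world.genes, counts, total_rna)
        cpg_frac, expr_frac, n_prom = promoter_class_fractions(
            table, world.genes, expr)
        prom_count = int(summary.loc[summary.label == "promoter",
                                     "count"].iloc[0])
        report["annotation"] = {
            "factor": ref,
            "n_peaks": len(peaks),
            "promoter_count": prom_count,
            "promoter_fraction": prom_count / len(peaks),
            "promoter_pct": report_fractions(prom_count, len(peaks)),
            "label_counts": dict(zip(summary.label, summary["count"].astype(int))),
            "cpg_fraction_of_bound_promoters": cpg_frac,
            "expressed_fraction_of_bound_genes": expr_frac,
        }

        stage = "profile"
        _stage(stage)
        profile_report = {}
        if len(config.factors) > 1:
            other = config.factors[1].name
            mat = signal_profile(peaks, reads[other], flank=profile_flank,
                                 bin_size=profile_bin, factor=other)
            write_table(mat.to_frame(), outdir / f"profile_{ref}_{other}.tsv")
            profile_report[f"{other}_at_{ref}"] = coloc_score(
                mat, center_halfwidth)
            # gene-oriented distances are defined for promoter-assigned
            # peaks; restrict to those (the promoter-centric comparison)
            by_id = {g.gene_id: g for g in world.genes}
            prom = table[table.label == "promoter"]
            prom_names = set(prom["peak"])
            sel = [(pk, by_id[gid].strand) for pk, gid in
                   zip(peaks, table["gene_id"])
                   if pk.name in prom_names and gid in by_id]
            records, dist_summary = nearest_peak_distances(
                [pk for pk, _ in sel], world.truth.factor_peaks[other],
                orientation="gene", strands_a=[s for _, s in sel],
                hist_halfwidth=500, hist_bin=100)
            write_table(pd.DataFrame([r.__dict__ for r in records]),
                        outdir / f"distances_{ref}_{other}.tsv")
            profile_report["nearest_" + other] = dist_summary
        mat_self = signal_profile(peaks, reads[ref], flank=profile_flank,
                                  bin_size=profile_bin, factor=ref)
        profile_report[f"{ref}_at_{ref}"] = coloc_score(mat_self,
                                                        center_halfwidth)
        report["profile"] = profile_report

        stage = "repeats"
        _stage(stage)
        if world.repeats and "input" in reads:
            chip_kept, _, chip_total = weight_and_filter(reads[ref])
            inp_kept, _, inp_total = weight_and_filter(reads["input"])
            chip_stats = class_rpk10m(chip_kept, world.repeats, chip_total)
            inp_stats = class_rpk10m(inp_kept, world.repeats, inp_total)
            folds = fold_enrichment(chip_stats, inp_stats)
            write_table(folds, outdir / "repeat_enrichment.tsv")
            report["repeats"] = {
                row["class"]: row["fold"] for _, row in folds.iterrows()
            }

        stage = "motif"
        _stage(stage)
        bound_cpg = {gid: world.promoter_sequences[gid]
                     for gid in sorted(world.truth.bound_genes)
                     if {g.gene_id: g for g in world.genes}[gid].cpg_promoter}
        all_cpg = {g.gene_id: world.promoter_sequences[g.gene_id]
                   for g in world.genes if g.cpg_promoter}
        motif = MotifSpec(name="CCAAT-box", consensus=config.motif.consensus)
        if motif_arm_size is not None and len(bound_cpg) > motif_arm_size:
            keep = sorted(bound_cpg)[:motif_arm_size]
            bound_cpg = {k: bound_cpg[k] for k in keep}
        frac, ci, _ = motif_site_fraction(list(bound_cpg.values()), motif)
        enr = motif_enrichment_vs_random_promoters(
            bound_cpg, all_cpg, motif, seed=config.seed)
        report["motif"] = {
            "bound_site_fraction": frac, "ci": list(ci),
            "enrichment": enr.to_dict(),
        }

        stage = "gene_overlap"
        _stage(stage)
        if world.truth.de_genes:
            near = assign_genes_to_peaks(peaks, world.genes, window=2000)
            universe = [g.gene_id for g in world.genes]
            ov = gene_list_overlap_test(near, world.truth.de_genes, universe,
                                        seed=config.seed, n_resamples=1000)
            report["gene_overlap"] = ov.to_dict()

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonify)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(render_report(report))
    with open(outdir / "config.json", "w") as fh:
        json.dump(_config_dict(config), fh, indent=1, sort_keys=True)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_dict(config: SimConfig) -> dict:
    from dataclasses import asdict
    return asdict(config)


def render_report(report: dict) -> str:
    lines = [f"cohesichip v{report.get('version')} — synthetic pipeline "
             f"report (seed {report.get('seed')})", ""]
    ann = report.get("annotation")
    if ann:
        lines += [
            f"Peak annotation ({ann['factor']}, {ann['n_peaks']} peaks):",
            f"  promoter: {ann['promoter_count']} ({ann['promoter_pct']})",
            f"  labels: {ann['label_counts']}",
            f"  CpG fraction of bound promoters: "
            f"{ann['cpg_fraction_of_bound_promoters']:.3f}",
            f"  expressed fraction of bound genes: "
            f"{ann['expressed_fraction_of_bound_genes']:.3f}", "",
        ]
    prof = report.get("profile")
    if prof:
        lines.append("Colocalization:")
        for key, val in prof.items():
            if isinstance(val, dict):
                lines.append(
                    f"  {key}: modal bin {val['modal_bin']}, "
                    f"upstream fraction {val['upstream_fraction']:.3f}")
            else:
                lines.append(f"  coloc score {key}: {val:.2f}")
        lines.append("")
    if "repeats" in report:
        lines.append("Repeat fold enrichment (ChIP/input):")
        for cls, fold in report["repeats"].items():
            lines.append(f"  {cls}: {fold:.1f}")
        lines.append("")
    if "motif" in report:
        m = report["motif"]
        e = m["enrichment"]
        lines += [
            f"Motif: bound-site fraction {m['bound_site_fraction']:.2f}, "
            f"Fisher p {e['p_value']:.2e} (odds ratio {e['odds_ratio']:.2f})",
            "",
        ]
    if "gene_overlap" in report:
        g = report["gene_overlap"]
        lines += [
            f"Gene-list overlap: {g['observed_overlap']} observed vs "
            f"{g['expected_overlap']:.1f} expected "
            f"(fold {g['fold']:.2f}, p {g['p_value']:.2e})",
        ]
    return "\n".join(lines) + "\n"
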