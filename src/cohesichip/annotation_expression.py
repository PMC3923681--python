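"""Peak annotation by a priority region scheme and RPKM expression calls.

Each gene defines four strand-oriented windows: promoter (TSS +/- 1 kb),
upstream (from -5 kb to -1 kb of the TSS), gene body (from TSS + 1 kb to the
gene end) and downstream (5 kb past the gene end). A peak, extended by
+/-150 bp, is assigned the single highest-priority window it intersects
(promoter > gene body > upstream > downstream); peaks matching none are
intergenic. Expression is quantified per gene as the RPKM of the most highly
expressed isoform; genes with RPKM > 0.6 (strictly) are called expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .formats_io import GeneModel, GenomicInterval, Peak

PROMOTER_HALFWIDTH = 1000
UPSTREAM_EXTENT = 5000
DOWNSTREAM_EXTENT = 5000
PEAK_EXTENSION = 150
EXPRESSED_RPKM_CUTOFF = 0.6

#: category -> priority rank (lower wins); intergenic is the fallback
REGION_PRIORITY = {"promoter": 0, "gene_body": 1, "upstream": 2, "downstream": 3}
REGION_LABELS = ("promoter", "gene_body", "upstream", "downstream", "intergenic")


@dataclass(frozen=True)
class RegionLabel:
    """The annotation of one peak: a region category and its gene (if any)."""

    label: str
    gene_id: Optional[str] = None
    distance_to_tss: Optional[int] = None  # strand-oriented; negative = upstream

    def __post_init__(self):
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    rpkm_per_isoform: tuple
    gene_rpkm: float
    expressed: bool


def region_windows(gene: GeneModel, chrom_length: Optional[int] = None) -> dict:
    """The four annotation windows of a gene, strand-oriented and clipped.

    Returns ``{category: (start, end)}`` half-open; a window may be empty
    (start == end), e.g. the gene body of a gene shorter than 1 kb.
    """
    t = gene.tss
    if gene.strand == "+":
        windows = {
            "promoter": (t - PROMOTER_HALFWIDTH, t + PROMOTER_HALFWIDTH),
            "upstream": (t - UPSTREAM_EXTENT, t - PROMOTER_HALFWIDTH),
            "gene_body": (t + PROMOTER_HALFWIDTH, gene.end),
            "downstream": (gene.end, gene.end + DOWNSTREAM_EXTENT),
        }
    else:
        windows = {
            "promoter": (t - PROMOTER_HALFWIDTH, t + PROMOTER_HALFWIDTH),
            "upstream": (t + PROMOTER_HALFWIDTH, t + UPSTREAM_EXTENT),
            "gene_body": (gene.start, t - PROMOTER_HALFWIDTH),
            "downstream": (gene.start - DOWNSTREAM_EXTENT, gene.start),
        }
    clipped = {}
    for cat, (s, e) in windows.items():
        s = max(0, s)
        if chrom_length is not None:
            e = min(e, chrom_length)
        clipped[cat] = (s, max(s, e))  # empty window if degenerate
    return clipped


class GeneWindowIndex:
    """Interval-tree index of all genes' annotation windows, per chromosome."""

    def __init__(self, genes: Sequence[GeneModel],
                 chrom_lengths: Optional[Mapping[str, int]] = None):
        self._trees: dict[str, IntervalTree] = {}
        self.genes = {g.gene_id: g for g in genes}
        for g in genes:
            clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for cat, (s, e) in region_windows(g, clen).items():
                if e > s:
                    tree.addi(s, e, (REGION_PRIORITY[cat], cat, g.gene_id, g.tss))

    def query(self, chrom: str, start: int, end: int):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def _oriented_tss_distance(summit: int, gene: GeneModel) -> int:
    d = summit - gene.tss
    return d if gene.strand == "+" else -d


def classify_peak(peak: Peak, index: GeneWindowIndex) -> RegionLabel:
    """Assign one region label to a peak.

    The peak interval is extended by 150 bp on both sides; among all gene
    windows it intersects by >=1 bp, the category highest in the preference
    order wins. Ties within one category go to the gene whose TSS is nearest
    to the summit (then lexicographically smallest gene_id).
    """
    start = max(0, peak.interval.start - PEAK_EXTENSION)
    end = peak.interval.end + PEAK_EXTENSION
    hits = index.query(peak.chrom, start, end)
    if not hits:
        return RegionLabel("intergenic")
    best = min(hits, key=lambda h: (h[0], abs(peak.summit - h[3]), h[2]))
    _, cat, gene_id, _ = best
    gene = index.genes[gene_id]
    return RegionLabel(cat, gene_id, _oriented_tss_distance(peak.summit, gene))


def annotate_peaks(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                   chrom_lengths: Optional[Mapping[str, int]] = None):
    """Annotate every peak; return (per-peak table, per-label summary).

    The summary's fractions sum to 1 over the five labels.
    """
    if not peaks:
        raise ValueError("annotate_peaks requires a non-empty peak set")
    index = GeneWindowIndex(genes, chrom_lengths)
    rows = []
    for pk in peaks:
        lab = classify_peak(pk, index)
        rows.append({
            "peak": pk.name, "chrom": pk.chrom, "start": pk.interval.start,
            "end": pk.interval.end, "summit": pk.summit, "score": pk.score,
            "label": lab.label, "gene_id": lab.gene_id if lab.gene_id else "",
            "distance_to_tss": lab.distance_to_tss
            if lab.distance_to_tss is not None else "",
        })
    table = pd.DataFrame(rows)
    counts = table["label"].value_counts()
    total = len(table)
    summary = pd.DataFrame({
        "label": REGION_LABELS,
        "count": [int(counts.get(lab, 0)) for lab in REGION_LABELS],
    })
    summary["fraction"] = summary["count"] / total
    return table, summary


def promoter_class_fractions(annotation: pd.DataFrame,
                             genes: Sequence[GeneModel],
                             expression: Mapping[str, ExpressionRecord]):
    """Among promoter-labeled peaks: fraction at CpG-island promoters and
    fraction whose gene is expressed. Returns ``(cpg_fraction,
    expressed_fraction, n_promoter_peaks)``; fractions are NaN when there
    are no promoter peaks.
    """
    by_id = {g.gene_id: g for g in genes}
    prom = annotation[annotation["label"] == "promoter"]
    if prom.empty:
        return float("nan"), float("nan"), 0
    n_cpg = n_expr = 0
    for gid in prom["gene_id"]:
        if gid not in by_id:
            raise KeyError(f"promoter-labeled peak references unknown gene {gid!r}")
        if by_id[gid].cpg_promoter:
            n_cpg += 1
        rec = expression.get(gid)
        if rec is None:
            raise KeyError(f"no expression record for gene {gid!r}")
        if rec.expressed:
            n_expr += 1
    n = len(prom)
    return n_cpg / n, n_expr / n, n


def compute_rpkm(gene: GeneModel, exon_counts: Mapping[str, Sequence[float]],
                 total_mapped_reads: float) -> ExpressionRecord:
    """Per-isoform RPKM and the gene-level expression call.

    ``exon_counts[tx_id]`` holds one read count per exon of that isoform
    (in exon order). RPKM = summed exon counts / (exonic length in kb x
    total mapped reads in millions); the gene value is the max over
    isoforms and the expressed call is strict (RPKM > 0.6).
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    rpkms = []
    for tx_id, exons in gene.isoforms:
        exonic_len = sum(ex.length for ex in exons)
        if exonic_len == 0:
            raise ValueError(f"isoform {tx_id} has zero exonic length")
        counts = exon_counts.get(tx_id, [0.0] * len(exons))
        if len(counts) != len(exons):
            raise ValueError(
                f"isoform {tx_id}: {len(counts)} counts for {len(exons)} exons"
            )
        rpkm = sum(counts) / ((exonic_len / 1e3) * (total_mapped_reads / 1e6))
        rpkms.append(rpkm)
    gene_rpkm = max(rpkms)
    return ExpressionRecord(gene.gene_id, tuple(rpkms), gene_rpkm,
                            expressed=gene_rpkm > EXPRESSED_RPKM_CUTOFF)


def expression_from_counts(genes: Sequence[GeneModel], counts: pd.DataFrame,
                           total_mapped_reads: float) -> dict:
    """Build ExpressionRecords for all genes from a long-format exon-count
    table (columns gene_id, transcript_id, exon_index, count)."""
    records = {}
    grouped = {}
    if len(counts):
        for (gid, tid), sub in counts.groupby(["gene_id", "transcript_id"]):
            grouped.setdefault(gid, {})[tid] = (
                sub.sort_values("exon_index")["count"].tolist()
            )
    for g in genes:
        records[g.gene_id] = compute_rpkm(
            g, grouped.get(g.gene_id, {}), total_mapped_reads
        )
    return records
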