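"""Synthetic worlds with the statistical structure the analyses assume.

The generator plants every parameter the downstream modules estimate —
promoter-binding fraction, summit offsets between factors, read enrichment
over a uniform background, multi-mapping over repeat families, CpG and
expression bias at bound promoters, and motif occupancy — and records the
ground truth so each module's recovery can be tested without any download.

Determinism: every component (genome layout, each factor's peaks, each
factor's reads, expression, motif sequences) draws from its own stream
spawned from the master seed, so e.g. changing a factor's read count never
perturbs the genome. All outputs are bit-exact under a fixed config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import (AlignedRead, GeneModel, GenomicInterval, Peak,
                         RepeatRegion, write_bed, write_fasta, write_genes,
                         write_repeats, write_table)
from .enrichment_stats import IUPAC, _revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FactorConfig:
    """One ChIP'd factor: its peak geometry and read budget.

    ``enrichment`` (e) is the expected 5'-end read density within
    summit +/- 200 bp divided by the background density; ``offset_mu`` /
    ``offset_sigma`` place promoter-anchored summits relative to the TSS in
    strand-oriented coordinates (negative = upstream). ``repeat_boost``
    maps repeat class names to a fold increase of read density over the
    class's regions (input-like samples leave it empty).
    """

    name: str
    n_peaks: int
    promoter_fraction: float = 0.0
    offset_mu: float = 0.0
    offset_sigma: float = 0.0
    n_reads: int = 100_000
    enrichment: float = 10.0
    repeat_boost: dict = field(default_factory=dict)

    def validate(self):
        if not 0.0 <= self.promoter_fraction <= 1.0:
            raise ValueError("promoter_fraction must be in [0, 1]")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        for cls, b in self.repeat_boost.items():
            if b < 1.0:
                raise ValueError(f"repeat boost for {cls!r} must be >= 1")


@dataclass
class ColocPair:
    """Planted colocalization: ``shared_fraction`` of factor A's peaks get a
    matching factor-B peak (same gene when A's peak is promoter-anchored,
    same summit + ~20 bp jitter otherwise)."""

    factor_a: str
    factor_b: str
    shared_fraction: float

    def validate(self):
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")


@dataclass
class RepeatClassConfig:
    """A repeat family: ``n_regions`` identical copies of length
    ``region_len``. Reads from a copy align to ``min(n_regions,
    multi_map_n)`` locations and are weighted accordingly downstream.
    ``n_bound`` regions can be marked for an extra ``bound_boost``-fold
    ChIP density on top of any class-level boost."""

    repeat_class: str
    family: str
    n_regions: int
    region_len: int = 500
    multi_map_n: int = 5
    n_bound: int = 0
    bound_boost: float = 1.0


@dataclass
class ExpressionConfig:
    """Per-gene expression: an on/off mixture with a lognormal "on" level.

    Bound-promoter genes are "on" with probability
    ``expressed_fraction_bound`` (falling back to the background ``p_on``
    when None) and their level is multiplied by ``1 + bound_boost``; with
    ``bound_boost = 0`` and ``expressed_fraction_bound = None`` the bound
    and unbound distributions are identical. ``min_on_rpkm`` floors the
    "on" level so the RPKM > 0.6 expression call survives Poisson counting
    noise at the configured depth.
    """

    total_reads: int = 10_000_000
    log_mu: float = float(np.log(10.0))
    log_sigma: float = 1.0
    min_on_rpkm: float = 2.0
    p_on: float = 0.6
    expressed_fraction_bound: Optional[float] = 0.98
    bound_boost: float = 0.0


@dataclass
class MotifConfig:
    """Planted motif occupancy at promoter sequences (bound vs unbound).

    Background sequence is generated motif-free by rejection, so the
    planted occupancy equals the expected fraction of sequences with a hit.
    """

    consensus: str = "CCAAT"
    occupancy_bound: float = 0.8
    occupancy_unbound: float = 0.4
    promoter_seq_len: int = 101


@dataclass
class DEConfig:
    """A synthetic differentially-expressed gene list with a planted excess
    of bound-promoter genes (``frac_from_bound`` of the list)."""

    n_genes: int = 300
    frac_from_bound: float = 0.6


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 10
    chrom_length: int = 10_000_000
    n_genes: int = 2500
    cpg_fraction: float = 0.6
    cpg_fraction_bound: float = 0.9
    factors: list = field(default_factory=list)
    coloc_pairs: list = field(default_factory=list)
    fragment_len: int = 200
    read_len: int = 36
    repeat_classes: list = field(default_factory=list)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    de: Optional[DEConfig] = field(default_factory=DEConfig)

    def validate(self):
        for p in (self.cpg_fraction, self.cpg_fraction_bound):
            if not 0.0 <= p <= 1.0:
                raise ValueError("cpg fractions must be in [0, 1]")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        for f in self.factors:
            f.validate()
        for pair in self.coloc_pairs:
            pair.validate()
            if pair.factor_a not in names or pair.factor_b not in names:
                raise ValueError(f"unknown factor in pair {pair}")
        for m in (self.motif.occupancy_bound, self.motif.occupancy_unbound):
            if not 0.0 <= m <= 1.0:
                raise ValueError("motif occupancies must be in [0, 1]")

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length


def default_config(seed: int = 0) -> SimConfig:
    """The study conditions the generator emulates by default: a strongly
    promoter-biased loading factor (80% promoter peaks, summits 150 bp
    upstream of the TSS and of the polymerase), a polymerase factor present
    at 95% of its sites, an input sample, 10-fold rRNA repeat enrichment
    with 5-way multi-mapping, 90%-CpG / 98%-expressed bound promoters, and
    CCAAT-box occupancy of 0.8 at bound vs 0.4 at unbound promoters."""
    return SimConfig(
        seed=seed,
        factors=[
            FactorConfig("nipbl", n_peaks=1000, promoter_fraction=0.8,
                         offset_mu=-150.0, offset_sigma=40.0,
                         n_reads=100_000, enrichment=10.0,
                         repeat_boost={"rRNA": 10.0}),
            FactorConfig("polii", n_peaks=1500, promoter_fraction=0.9,
                         offset_mu=0.0, offset_sigma=0.0,
                         n_reads=100_000, enrichment=10.0),
            FactorConfig("input", n_peaks=0, n_reads=100_000),
        ],
        coloc_pairs=[ColocPair("nipbl", "polii", 0.95)],
        repeat_classes=[
            RepeatClassConfig("rRNA", "LSU", n_regions=250, region_len=500,
                              multi_map_n=5),
            RepeatClassConfig("rRNA", "SSU", n_regions=217, region_len=500,
                              multi_map_n=5),
        ],
    )


# ---------------------------------------------------------------------------
# Truth and world containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Everything needed to recompute the planted parameters."""

    factor_peaks: dict          # name -> list[Peak]
    factor_anchor_gene: dict    # name -> list[gene_id or None], per peak
    factor_strengths: dict      # name -> np.ndarray of planted strengths
    bound_genes: set            # promoter genes of the first factor
    expression_true: dict       # gene_id -> (true_rpkm, on: bool)
    motif_planted: dict         # gene_id -> bool
    de_genes: list
    repeat_bound: list          # indices of extra-boosted repeat regions


@dataclass
class SyntheticWorld:
    config: SimConfig
    chrom_lengths: dict
    genes: list
    repeats: list
    promoter_sequences: dict    # gene_id -> sequence (TSS-centered window)
    truth: SyntheticTruth


def _stream(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# Sequence helpers (shared with tests and the acceptance script)
# ---------------------------------------------------------------------------

def _consensus_allowed(consensus: str) -> list:
    """Per-position boolean (4,) arrays of allowed bases (ACGT order)."""
    out = []
    for ch in consensus.upper():
        allowed = np.zeros(4, dtype=bool)
        for b in IUPAC[ch]:
            allowed["ACGT".index(b)] = True
        out.append(allowed)
    return out


def _match_rows(arr: np.ndarray, consensus: str) -> np.ndarray:
    """Rows of an (n, L) base-index array matching the consensus on either
    strand at any offset."""
    n, L = arr.shape
    hit = np.zeros(n, dtype=bool)
    for cons in (consensus, _revcomp(consensus)):
        allowed = _consensus_allowed(cons)
        m = len(allowed)
        for off in range(L - m + 1):
            sub = np.ones(n, dtype=bool)
            for k in range(m):
                sub &= allowed[k][arr[:, off + k]]
                if not sub.any():
                    break
            hit |= sub
    return hit


def simulate_promoter_sequences(n: int, occupancy: float, consensus: str,
                                length: int, rng: np.random.Generator):
    """``n`` random sequences, motif-free by rejection, with the consensus
    planted (random offset and strand) in a Bernoulli(``occupancy``) subset.

    Returns ``(sequences, planted flags)``.
    """
    arr = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    while True:
        bad = _match_rows(arr, consensus)
        if not bad.any():
            break
        arr[bad] = rng.integers(0, 4, size=(int(bad.sum()), length),
                                dtype=np.uint8)
    planted = rng.random(n) < occupancy
    m = len(consensus)
    offsets = rng.integers(0, length - m + 1, size=n)
    strands = rng.random(n) < 0.5
    for i in np.nonzero(planted)[0]:
        cons = consensus if strands[i] else _revcomp(consensus)
        concrete = "".join(
            IUPAC[ch][rng.integers(0, len(IUPAC[ch]))] for ch in cons)
        idx = np.frombuffer(concrete.encode(), dtype=np.uint8)
        arr[i, offsets[i]:offsets[i] + m] = np.searchsorted(_BASES, idx)
    seqs = ["".join("ACGT"[b] for b in row) for row in arr]
    return seqs, planted


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def _place_genes(config: SimConfig, rng: np.random.Generator) -> list:
    """Non-overlapping genes spread over the chromosomes, with exon/intron
    structure and 1-2 isoforms each."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    genes = []
    gidx = 0
    for ci, chrom in enumerate(chroms):
        n_here = int(per_chrom[ci])
        if n_here == 0:
            continue
        margin = 10_000
        max_span = 4000
        # one slot per gene, jittered within the slot: capacity is exact
        slot = (config.chrom_length - 2 * margin) / n_here
        if slot < max_span + 1000:
            raise ValueError("n_genes too large for genome")
        for j in range(n_here):
            span = int(rng.integers(1500, max_span + 1))
            jitter = int(rng.integers(0, int(slot - span - 500)))
            start = margin + int(j * slot) + jitter
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{gidx:05d}"
            gidx += 1
            # exon structure: k exons from 2k-1 alternating segments
            k = int(rng.integers(1, 4))
            if k == 1:
                exons1 = [GenomicInterval(chrom, start, end, strand)]
            else:
                cuts = np.sort(rng.choice(
                    np.arange(start + 50, end - 50), size=2 * (k - 1),
                    replace=False))
                bounds = [start, *cuts.tolist(), end]
                exons1 = [
                    GenomicInterval(chrom, bounds[2 * j], bounds[2 * j + 1],
                                    strand)
                    for j in range(k)
                ]
            isoforms = [(f"{gid}.t1", tuple(exons1))]
            if k > 1 and rng.random() < 0.5:
                # second isoform drops one internal exon
                drop = int(rng.integers(1, k))
                exons2 = tuple(e for j, e in enumerate(exons1) if j != drop)
                isoforms.append((f"{gid}.t2", exons2))
            genes.append(GeneModel(gid, chrom, strand, start, end,
                                   tuple(isoforms)))
    return genes


def _place_repeats(config: SimConfig, rng: np.random.Generator) -> list:
    """Repeat regions placed uniformly, non-overlapping with each other
    (they may overlap genes)."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    placed: dict[str, list] = {c: [] for c in chroms}
    regions = []
    for rc in config.repeat_classes:
        for j in range(rc.n_regions):
            for _attempt in range(1000):
                chrom = chroms[int(rng.integers(0, config.n_chroms))]
                start = int(rng.integers(0, config.chrom_length - rc.region_len))
                end = start + rc.region_len
                if all(e <= start or s >= end for s, e in placed[chrom]):
                    placed[chrom].append((start, end))
                    regions.append(RepeatRegion(
                        GenomicInterval(chrom, start, end, ".",
                                        f"{rc.repeat_class}:{rc.family}"),
                        rc.repeat_class, rc.family))
                    break
            else:
                raise ValueError("could not place repeat regions; genome too "
                                 "small for the configured repeat load")
    return regions


def _oriented_summit(gene: GeneModel, offset: float) -> int:
    off = int(round(offset))
    return gene.tss + off if gene.strand == "+" else gene.tss - off


def _make_peak(chrom: str, summit: int, score: float, name: str,
               chrom_length: int, rng: np.random.Generator) -> Peak:
    width = int(rng.integers(200, 401))
    off = int(rng.integers(width // 4, 3 * width // 4 + 1))
    start = max(0, summit - off)
    end = min(chrom_length, max(start + width, summit + 1))
    return Peak(GenomicInterval(chrom, start, end, ".", name, score),
                summit, score)


def generate_world(config: SimConfig) -> SyntheticWorld:
    """Generate genes, repeats, factor peak sets, promoter sequences,
    expression truth and a DE gene list for one synthetic study."""
    config.validate()
    chrom_lengths = {f"chr{i + 1}": config.chrom_length
                     for i in range(config.n_chroms)}
    genes = _place_genes(config, _stream(config, 0))
    repeats = _place_repeats(config, _stream(config, 1))
    by_id = {g.gene_id: g for g in genes}
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    def near_promoter(chrom: str, pos: int, margin: int = 1500) -> bool:
        arr = tss_by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        j = np.searchsorted(arr, pos)
        return any(abs(pos - int(arr[k])) < margin
                   for k in (j - 1, j) if 0 <= k < len(arr))

    # --- factor peaks -----------------------------------------------------
    shared_by: dict[str, dict] = {f.name: {} for f in config.factors}
    for pair in config.coloc_pairs:
        shared_by[pair.factor_b][pair.factor_a] = pair.shared_fraction

    factor_peaks: dict[str, list] = {}
    factor_anchor: dict[str, list] = {}
    factor_strengths: dict[str, np.ndarray] = {}
    chroms = list(chrom_lengths)
    for fi, fc in enumerate(config.factors):
        rng = _stream(config, 2, fi)
        peaks: list[Peak] = []
        anchors: list = []
        strengths = rng.lognormal(0.0, 0.5, size=fc.n_peaks)
        scores = strengths * rng.lognormal(0.0, 0.2, size=fc.n_peaks)
        n_placed = 0
        # peaks anchored to another factor's peaks (planted colocalization)
        for src_name, frac in sorted(shared_by[fc.name].items()):
            src_peaks = factor_peaks[src_name]
            src_anchor = factor_anchor[src_name]
            n_shared = int(round(frac * len(src_peaks)))
            if n_placed + n_shared > fc.n_peaks:
                raise ValueError(
                    f"factor {fc.name}: shared peaks exceed n_peaks")
            take = rng.choice(len(src_peaks), size=n_shared, replace=False)
            for k in sorted(take.tolist()):
                gid = src_anchor[k]
                if gid is not None:
                    g = by_id[gid]
                    summit = _oriented_summit(
                        g, rng.normal(fc.offset_mu, fc.offset_sigma))
                    chrom = g.chrom
                else:
                    chrom = src_peaks[k].chrom
                    summit = src_peaks[k].summit + int(round(rng.normal(0, 20)))
                summit = min(max(summit, 0), chrom_lengths[chrom] - 1)
                peaks.append(_make_peak(chrom, summit, float(scores[n_placed]),
                                        f"{fc.name}_p{n_placed:05d}",
                                        chrom_lengths[chrom], rng))
                anchors.append(gid)
                n_placed += 1
        # remaining peaks follow the factor's own promoter/background split
        gene_pool = list(range(len(genes)))
        while n_placed < fc.n_peaks:
            if rng.random() < fc.promoter_fraction and gene_pool:
                gi = gene_pool.pop(int(rng.integers(0, len(gene_pool))))
                g = genes[gi]
                summit = _oriented_summit(
                    g, rng.normal(fc.offset_mu, fc.offset_sigma))
                summit = min(max(summit, 0), chrom_lengths[g.chrom] - 1)
                peaks.append(_make_peak(g.chrom, summit,
                                        float(scores[n_placed]),
                                        f"{fc.name}_p{n_placed:05d}",
                                        chrom_lengths[g.chrom], rng))
                anchors.append(g.gene_id)
            else:
                while True:  # background peaks avoid promoter neighborhoods
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    summit = int(rng.integers(2000,
                                              chrom_lengths[chrom] - 2000))
                    if not near_promoter(chrom, summit):
                        break
                peaks.append(_make_peak(chrom, summit, float(scores[n_placed]),
                                        f"{fc.name}_p{n_placed:05d}",
                                        chrom_lengths[chrom], rng))
                anchors.append(None)
            n_placed += 1
        factor_peaks[fc.name] = peaks
        factor_anchor[fc.name] = anchors
        factor_strengths[fc.name] = strengths

    # --- bound genes, CpG flags ------------------------------------------
    bound_genes = set()
    if config.factors:
        first = config.factors[0].name
        bound_genes = {g for g in factor_anchor[first] if g is not None}
    rng_cpg = _stream(config, 3)
    flagged = []
    for g in genes:
        p = (config.cpg_fraction_bound if g.gene_id in bound_genes
             else config.cpg_fraction)
        flagged.append(GeneModel(g.gene_id, g.chrom, g.strand, g.start, g.end,
                                 g.isoforms,
                                 cpg_promoter=bool(rng_cpg.random() < p)))
    genes = flagged
    by_id = {g.gene_id: g for g in genes}

    # --- expression truth -------------------------------------------------
    rng_expr = _stream(config, 4)
    ec = config.expression
    expression_true = {}
    for g in genes:
        bound = g.gene_id in bound_genes
        p_on = (ec.expressed_fraction_bound
                if bound and ec.expressed_fraction_bound is not None
                else ec.p_on)
        on = bool(rng_expr.random() < p_on)
        if on:
            level = max(ec.min_on_rpkm,
                        float(rng_expr.lognormal(ec.log_mu, ec.log_sigma)))
            if bound:
                level *= 1.0 + ec.bound_boost
        else:
            level = 0.0
        expression_true[g.gene_id] = (level, on)

    # --- promoter sequences with planted motif ----------------------------
    rng_motif = _stream(config, 5)
    mc = config.motif
    order = [g.gene_id for g in genes]
    bound_mask = np.array([gid in bound_genes for gid in order])
    seqs = [None] * len(order)
    planted_flags = np.zeros(len(order), dtype=bool)
    for mask, occ in ((bound_mask, mc.occupancy_bound),
                      (~bound_mask, mc.occupancy_unbound)):
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        s, planted = simulate_promoter_sequences(
            len(idx), occ, mc.consensus, mc.promoter_seq_len, rng_motif)
        for k, i in enumerate(idx):
            seqs[i] = s[k]
        planted_flags[idx] = planted
    promoter_sequences = dict(zip(order, seqs))
    motif_planted = dict(zip(order, planted_flags.tolist()))

    # --- DE gene list ------------------------------------------------------
    rng_de = _stream(config, 6)
    de_genes: list = []
    if config.de is not None and config.de.n_genes > 0:
        bound_list = sorted(bound_genes)
        other_list = sorted(set(by_id) - bound_genes)
        n_b = min(int(round(config.de.n_genes * config.de.frac_from_bound)),
                  len(bound_list))
        n_o = min(config.de.n_genes - n_b, len(other_list))
        de_genes = sorted(
            [bound_list[i] for i in
             rng_de.choice(len(bound_list), size=n_b, replace=False)]
            + [other_list[i] for i in
               rng_de.choice(len(other_list), size=n_o, replace=False)])

    # --- extra-boosted repeat regions --------------------------------------
    rng_rep = _stream(config, 7)
    repeat_bound: list = []
    offset = 0
    for rc in config.repeat_classes:
        if rc.n_bound > 0:
            take = rng_rep.choice(rc.n_regions, size=rc.n_bound, replace=False)
            repeat_bound.extend(int(offset + t) for t in sorted(take.tolist()))
        offset += rc.n_regions

    truth = SyntheticTruth(
        factor_peaks=factor_peaks, factor_anchor_gene=factor_anchor,
        factor_strengths=factor_strengths, bound_genes=bound_genes,
        expression_true=expression_true, motif_planted=motif_planted,
        de_genes=de_genes, repeat_bound=repeat_bound,
    )
    return SyntheticWorld(config, chrom_lengths, genes, repeats,
                          promoter_sequences, truth)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def expected_profile_reads_per_peak(config: SimConfig, fc: FactorConfig,
                                    window_halfwidth: int = 200) -> tuple:
    """Closed-form read budget: (reads per peak, background reads,
    background density per bp) implied by the factor's enrichment e.

    e is defined as (background + peak-read) 5'-end density within
    summit +/- ``window_halfwidth`` divided by the background density, so
    m * q = (e - 1) * 2w * lambda with q the normal mass inside the window
    and lambda = n_bg / effective genome length (repeat boosts expand the
    effective length).
    """
    sd = config.fragment_len / 2.0
    q = float(stats.norm.cdf(window_halfwidth / sd)
              - stats.norm.cdf(-window_halfwidth / sd))
    g_eff = float(config.genome_length)
    for rc in config.repeat_classes:
        boost = fc.repeat_boost.get(rc.repeat_class, 1.0)
        g_eff += (boost * rc.bound_boost - 1.0) * rc.n_bound * rc.region_len
        g_eff += (boost - 1.0) * (rc.n_regions - rc.n_bound) * rc.region_len
    P = fc.n_peaks
    w2 = 2.0 * window_halfwidth
    if P == 0 or fc.enrichment <= 1.0:
        return 0.0, float(fc.n_reads), fc.n_reads / g_eff
    c = P * (fc.enrichment - 1.0) * w2 / (q * g_eff)
    r_peaks = c * fc.n_reads / (1.0 + c)
    n_bg = fc.n_reads - r_peaks
    return r_peaks / P, n_bg, n_bg / g_eff


def simulate_reads(world: SyntheticWorld, factor: str):
    """Simulate one factor's aligned reads.

    Returns ``(alignments, sources)``: a list of AlignedRead records (one
    per alignment; multi-mapping reads over a repeat family contribute one
    record per copy, all sharing the read id and n_hits) and a per-read
    source array (peak index, or -1 for background/repeat).
    """
    config = world.config
    names = [f.name for f in config.factors]
    if factor not in names:
        raise ValueError(f"unknown factor {factor!r}")
    fi = names.index(factor)
    fc = config.factors[fi]
    rng = _stream(config, 8, fi)
    chrom_lengths = world.chrom_lengths
    chroms = list(chrom_lengths)
    sd = config.fragment_len / 2.0

    m_per_peak, n_bg_f, _lam = expected_profile_reads_per_peak(config, fc)
    peaks = world.truth.factor_peaks[factor]
    strengths = world.truth.factor_strengths[factor][:len(peaks)]
    n_peak_reads = int(round(m_per_peak * len(peaks)))
    n_bg = fc.n_reads - n_peak_reads

    # family bookkeeping for multi-mapping
    fam_regions: dict[tuple, list] = {}
    for reg in world.repeats:
        fam_regions.setdefault((reg.repeat_class, reg.repeat_family),
                               []).append(reg)
    fam_by_region = {}
    for key, regs in fam_regions.items():
        for reg in regs:
            fam_by_region[id(reg)] = key
    fam_copies = {}
    for rc in config.repeat_classes:
        fam_copies[(rc.repeat_class, rc.family)] = min(rc.n_regions,
                                                       rc.multi_map_n)
    # slabs of extra background density over repeat regions
    slab_regions, slab_weights = [], []
    region_index = 0
    bound_set = set(world.truth.repeat_bound)
    offset = 0
    for rc in config.repeat_classes:
        boost = fc.repeat_boost.get(rc.repeat_class, 1.0)
        for j in range(rc.n_regions):
            reg = world.repeats[offset + j]
            mult = boost * (rc.bound_boost if (offset + j) in bound_set
                            else 1.0)
            if mult > 1.0:
                slab_regions.append(reg)
                slab_weights.append((mult - 1.0) * reg.interval.length)
        offset += rc.n_regions
    g_eff = config.genome_length + float(np.sum(slab_weights))

    reads: list[AlignedRead] = []
    sources: list[int] = []
    region_lookup = _SimpleRegionLookup(world.repeats)
    read_no = 0

    def emit(chrom: str, pos: int, source: int):
        nonlocal read_no
        pos = min(max(pos, 0), chrom_lengths[chrom] - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        rid = f"{factor}_r{read_no:07d}"
        read_no += 1
        reg = region_lookup.lookup(chrom, pos)
        if reg is not None:
            key = fam_by_region[id(reg)]
            k = fam_copies[key]
            if k > 1:
                regs = fam_regions[key]
                off_in = pos - reg.interval.start
                others = [r for r in regs if r is not reg]
                pick = rng.choice(len(others), size=k - 1, replace=False)
                copies = [reg] + [others[int(p)] for p in sorted(pick.tolist())]
                for cp in copies:
                    reads.append(AlignedRead(cp.interval.chrom,
                                             cp.interval.start + off_in,
                                             strand, n_hits=k, read_id=rid))
                sources.append(source)
                return
        reads.append(AlignedRead(chrom, pos, strand, n_hits=1, read_id=rid))
        sources.append(source)

    # peak reads: multinomial over peaks by strength, normal around summits
    if n_peak_reads > 0 and len(peaks) > 0:
        probs = strengths / strengths.sum()
        per_peak = rng.multinomial(n_peak_reads, probs)
        for i, n_i in enumerate(per_peak):
            if n_i == 0:
                continue
            offs = np.round(rng.normal(0.0, sd, size=int(n_i))).astype(int)
            for off in offs:
                emit(peaks[i].chrom, peaks[i].summit + int(off), i)

    # background reads: uniform genome plus boosted repeat slabs
    slab_w = np.array(slab_weights, dtype=float)
    p_slab = slab_w.sum() / g_eff if g_eff > 0 else 0.0
    for _ in range(n_bg):
        if slab_w.size and rng.random() < p_slab:
            j = int(rng.choice(slab_w.size, p=slab_w / slab_w.sum()))
            reg = slab_regions[j]
            pos = int(rng.integers(reg.interval.start, reg.interval.end))
            emit(reg.interval.chrom, pos, -1)
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            emit(chrom, int(rng.integers(0, chrom_lengths[chrom])), -1)
    return reads, np.array(sources)


class _SimpleRegionLookup:
    """Point lookup into non-overlapping repeat regions."""

    def __init__(self, regions: Sequence[RepeatRegion]):
        self._by_chrom: dict[str, tuple] = {}
        tmp: dict[str, list] = {}
        for reg in regions:
            tmp.setdefault(reg.interval.chrom, []).append(reg)
        for chrom, regs in tmp.items():
            regs.sort(key=lambda r: r.interval.start)
            self._by_chrom[chrom] = (
                np.array([r.interval.start for r in regs]), regs)

    def lookup(self, chrom: str, pos: int):
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, regs = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < regs[i].interval.end:
            return regs[i]
        return None


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(world: SyntheticWorld):
    """Per-exon RNA-seq counts consistent with the planted expression.

    For each isoform, the expected count is share x true RPKM x exonic kb x
    depth in tens of millions (primary isoform share 0.8 when a second
    isoform exists); counts are Poisson and spread over exons by length.
    Returns ``(long-format counts DataFrame, total_mapped_reads)``.
    """
    config = world.config
    rng = _stream(config, 9)
    ec = config.expression
    depth_m = ec.total_reads / 1e6
    rows = []
    for g in world.genes:
        level, _on = world.truth.expression_true[g.gene_id]
        n_iso = len(g.isoforms)
        shares = [1.0] if n_iso == 1 else [0.8] + [0.2 / (n_iso - 1)] * (n_iso - 1)
        for (tx_id, exons), share in zip(g.isoforms, shares):
            exonic_len = sum(e.length for e in exons)
            mean = share * level * (exonic_len / 1e3) * depth_m
            total = int(rng.poisson(mean)) if mean > 0 else 0
            if total > 0:
                lens = np.array([e.length for e in exons], dtype=float)
                per_exon = rng.multinomial(total, lens / lens.sum())
            else:
                per_exon = np.zeros(len(exons), dtype=int)
            for j, cnt in enumerate(per_exon):
                rows.append({"gene_id": g.gene_id, "transcript_id": tx_id,
                             "exon_index": j, "count": int(cnt)})
    return pd.DataFrame(rows), float(ec.total_reads)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, outdir, write_reads: bool = True):
    """Emit the world in the pipeline's file dialects plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genes(world.genes, outdir / "genes.gtf")
    write_repeats(world.repeats, outdir / "repeats.bed")
    write_fasta(world.promoter_sequences, outdir / "promoters.fa")
    for name, peaks in world.truth.factor_peaks.items():
        write_bed(peaks, outdir / f"peaks_{name}.bed", "peak_bed")
    if write_reads:
        for fc in world.config.factors:
            reads, _ = simulate_reads(world, fc.name)
            write_bed(reads, outdir / f"reads_{fc.name}.bed", "aln_bed",
                      read_length=world.config.read_len)
    counts, total = simulate_expression(world)
    write_table(counts, outdir / "expression_counts.tsv")
    write_table(pd.DataFrame({"gene_id": world.truth.de_genes}),
                outdir / "de_genes.tsv")
    truth = {
        "seed": world.config.seed,
        "chrom_lengths": world.chrom_lengths,
        "total_rna_reads": total,
        "bound_genes": sorted(world.truth.bound_genes),
        "de_genes": world.truth.de_genes,
        "motif_planted": {k: bool(v)
                          for k, v in world.truth.motif_planted.items()},
        "expression_true": {k: {"rpkm": v[0], "on": v[1]}
                            for k, v in world.truth.expression_true.items()},
        "repeat_bound_indices": world.truth.repeat_bound,
        "factor_anchor_gene": world.truth.factor_anchor_gene,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return outdir
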