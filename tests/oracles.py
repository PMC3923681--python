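"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (quadratic scans, exhaustive
enumeration, direct formula evaluation) and shares no code with the
package's optimized paths.
"""

from __future__ import annotations

import math
from itertools import combinations

from cohesichip.annotation_expression import (PEAK_EXTENSION,
                                              REGION_PRIORITY, region_windows)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def oracle_classify(peak, genes, chrom_lengths=None):
    """O(genes) scan: best (priority, |summit - tss|, gene_id) label."""
    s = max(0, peak.interval.start - PEAK_EXTENSION)
    e = peak.interval.end + PEAK_EXTENSION
    best = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        for cat, (ws, we) in region_windows(g, clen).items():
            if we > ws and s < we and ws < e:
                key = (REGION_PRIORITY[cat], abs(peak.summit - g.tss),
                       g.gene_id)
                if best is None or key < best[0]:
                    best = (key, cat, g.gene_id)
    if best is None:
        return "intergenic", None
    return best[1], best[2]


def oracle_overlap_mask(setA, setB, mode, window):
    out = []
    for a in setA:
        hit = False
        for b in setB:
            if a.chrom != b.chrom:
                continue
            if mode == "interval":
                if (a.interval.start < b.interval.end
                        and b.interval.start < a.interval.end):
                    hit = True
                    break
            else:
                if abs(a.summit - b.summit) <= window:
                    hit = True
                    break
        out.append(hit)
    return out


def oracle_nearest(peaksA, peaksB):
    """For each A: (signed distance to nearest B summit, ties negative),
    or None when no B shares the chromosome."""
    out = []
    for a in peaksA:
        cands = [a.summit - b.summit for b in peaksB if b.chrom == a.chrom]
        if not cands:
            out.append(None)
            continue
        out.append(min(cands, key=lambda d: (abs(d), d)))
    return out


def oracle_scan(seq, consensus):
    """Exhaustive sliding-window IUPAC match on both strands."""
    seq = seq.upper()
    rc = "".join(_COMP[c] for c in reversed(consensus.upper()))
    hits = []
    for cons, strand in ((consensus.upper(), "+"), (rc, "-")):
        m = len(cons)
        for i in range(len(seq) - m + 1):
            if all(seq[i + k] in IUPAC_SETS[cons[k]] for k in range(m)):
                hits.append((i, strand))
    return sorted(hits)


def oracle_rpk10m(reads, regions, total_aligned):
    """Per-read scan over all regions; returns {class_or_family: rpk10m}."""
    lengths, counts = {}, {}
    for reg in regions:
        for key in (reg.repeat_class, f"{reg.repeat_class}/{reg.repeat_family}"):
            lengths[key] = lengths.get(key, 0) + reg.interval.length
            counts.setdefault(key, 0.0)
    for read in reads:
        for reg in regions:
            if (reg.interval.chrom == read.chrom
                    and reg.interval.start <= read.five_prime_pos
                    < reg.interval.end):
                counts[reg.repeat_class] += 1.0 / read.n_hits
                counts[f"{reg.repeat_class}/{reg.repeat_family}"] += (
                    1.0 / read.n_hits)
                break  # regions are non-overlapping
    return {
        key: counts[key] / ((lengths[key] / 1e3) * (total_aligned / 1e7))
        for key in lengths
    }


def oracle_fisher_two_sided(a, b, c, d):
    """Exact two-sided Fisher p: enumerate all tables with the observed
    margins and sum the probabilities of tables no more likely than the
    observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):  # hypergeometric pmf at a = x
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = table_prob(a)
    tol = p_obs * (1 + 1e-9)
    return sum(table_prob(x) for x in range(0, min(r1, c1) + 1)
               if table_prob(x) <= tol)


def oracle_overlap_p_by_enumeration(universe, query_size, reference):
    """Distribution of |draw & reference| over ALL query_size-subsets of the
    universe, by explicit enumeration. Returns {overlap: probability}."""
    ref = set(reference)
    counts = {}
    total = 0
    for draw in combinations(sorted(universe), query_size):
        k = len(ref.intersection(draw))
        counts[k] = counts.get(k, 0) + 1
        total += 1
    return {k: v / total for k, v in counts.items()}


def oracle_assign_genes(peaks, genes, window):
    out = set()
    for g in genes:
        lo, hi = g.start - window, g.end + window
        for pk in peaks:
            if (pk.chrom == g.chrom and pk.interval.start < hi
                    and lo < pk.interval.end):
                out.add(g.gene_id)
                break
    return sorted(out)
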