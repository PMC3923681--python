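"""Motif scanning and Fisher-test enrichment with resampled nulls.

Two enrichment designs are implemented: motif preference at bound CpG-island
promoters versus an equal-size random draw of CpG-island promoters, and the
overlap of a peak-derived gene list with a reference gene list against a
hypergeometric / resampled null.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .formats_io import GeneModel, Peak

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A motif given as an IUPAC consensus or a position-weight matrix.

    For a PWM (rows = positions, columns = A,C,G,T probabilities summing
    to 1), a window matches where its log-odds-free additive probability
    score reaches ``threshold`` x the maximum attainable score. Matching
    always considers both strands; N in the target sequence never matches.
    """

    name: str
    consensus: Optional[str] = None
    pwm: Optional[tuple] = None  # tuple of 4-tuples, ACGT order
    threshold: float = 0.8

    def __post_init__(self):
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("specify exactly one of consensus or pwm")
        if self.consensus is not None:
            if len(self.consensus) < 4:
                raise ValueError("consensus length must be >= 4")
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC codes {sorted(bad)}")
        else:
            for row in self.pwm:
                if len(row) != 4 or abs(sum(row) - 1.0) > 1e-6:
                    raise ValueError("each PWM row needs 4 values summing to 1")
            if len(self.pwm) < 4:
                raise ValueError("PWM length must be >= 4")

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus else len(self.pwm)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@lru_cache(maxsize=256)
def _consensus_regex(consensus: str):
    # lookahead makes overlapping matches visible
    parts = []
    for ch in consensus.upper():
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile(f"(?={''.join(parts)})")


def _consensus_hits(seq: str, consensus: str) -> list:
    return [m.start() for m in _consensus_regex(consensus).finditer(seq)]


def _pwm_hits(seq: str, pwm, threshold: float) -> list:
    mat = np.asarray(pwm)
    m, n = len(mat), len(seq)
    max_score = float(mat.max(axis=1).sum())
    cut = threshold * max_score
    hits = []
    for i in range(n - m + 1):
        window = seq[i:i + m]
        score = 0.0
        ok = True
        for k, base in enumerate(window):
            j = _BASE_INDEX.get(base)
            if j is None:  # N never matches
                ok = False
                break
            score += mat[k, j]
        if ok and score >= cut:
            hits.append(i)
    return hits


def scan_motif(sequence: str, motif: MotifSpec) -> list:
    """All motif matches on both strands of a sequence.

    Returns a list of ``(position, strand)`` where ``position`` is the
    0-based offset of the match start on the forward strand. The sequence
    alphabet is {A,C,G,T,N}; N never matches.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    if motif.consensus is not None:
        fwd = _consensus_hits(seq, motif.consensus)
        rev = _consensus_hits(seq, _revcomp(motif.consensus))
    else:
        fwd = _pwm_hits(seq, motif.pwm, motif.threshold)
        # reverse-complement PWM: reverse positions, swap A<->T and C<->G
        rc = tuple(tuple(row) for row in np.asarray(motif.pwm)[::-1, ::-1])
        rev = _pwm_hits(seq, rc, motif.threshold)
    hits = [(i, "+") for i in fwd] + [(i, "-") for i in rev]
    # a palindromic match at one position on both strands stays two hits
    return sorted(hits)


def motif_site_fraction(sequences: Sequence[str], motif: MotifSpec,
                        ci_level: float = 0.95):
    """Fraction of sites carrying >=1 motif hit, with a binomial CI.

    Presence is binary per site; returns ``(fraction, (lo, hi), n_hits)``.
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    k = sum(1 for s in sequences if scan_motif(s, motif))
    n = len(sequences)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=ci_level,
                                             method="wilson")
    return k / n, (ci.low, ci.high), k


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment test: counts, odds ratio, p-value and provenance.

    Table layout: a = group1 with property, b = group1 without,
    c = group2 with, d = group2 without.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    test: str
    alternative: str
    seed: Optional[int] = None
    n_resamples: int = 0
    empirical_p: Optional[float] = None
    empirical_p_ci: Optional[tuple] = None
    p_values_redraws: Optional[list] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "odds_ratio": self.odds_ratio, "p_value": self.p_value,
            "test": self.test, "alternative": self.alternative,
            "seed": self.seed, "n_resamples": self.n_resamples,
            "empirical_p": self.empirical_p,
            "empirical_p_ci": self.empirical_p_ci,
        }
        d.update(self.extra)
        return d


def fisher_2x2(a: int, b: int, c: int, d: int,
               alternative: str = "two-sided") -> tuple:
    """Exact Fisher test on a 2x2 table; returns (odds_ratio, p)."""
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(odds), float(p)


def motif_enrichment_vs_random_promoters(
        bound: Mapping[str, str], all_promoters: Mapping[str, str],
        motif: MotifSpec, seed: int, alternative: str = "two-sided",
        n_redraws: int = 1) -> EnrichmentResult:
    """Motif enrichment at bound promoters vs an equal-count random draw.

    ``bound`` and ``all_promoters`` map promoter id -> sequence (e.g. all
    CpG-island promoters); the random control of size ``|bound|`` is drawn
    without replacement from ``all_promoters`` excluding the bound ids.
    With ``n_redraws > 1`` the control is redrawn and the Fisher test
    repeated; the reported table and p come from the first draw and the
    full p distribution is attached.
    """
    if not bound:
        raise ValueError("empty bound promoter set")
    pool = [pid for pid in all_promoters if pid not in bound]
    if len(pool) < len(bound):
        raise ValueError(
            f"need >= {len(bound)} non-bound promoters to draw from, "
            f"have {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    bound_ids = list(bound)
    a = sum(1 for pid in bound_ids if scan_motif(bound[pid], motif))
    b = len(bound_ids) - a

    ps, tables = [], []
    for _ in range(n_redraws):
        draw = rng.choice(len(pool), size=len(bound_ids), replace=False)
        c = sum(1 for k in draw if scan_motif(all_promoters[pool[k]], motif))
        d = len(bound_ids) - c
        odds, p = fisher_2x2(a, b, c, d, alternative)
        ps.append(p)
        tables.append((a, b, c, d, odds))
    a_, b_, c_, d_, odds = tables[0]
    return EnrichmentResult(
        a_, b_, c_, d_, odds, ps[0], test="fisher_exact",
        alternative=alternative, seed=seed, n_resamples=n_redraws,
        p_values_redraws=ps if n_redraws > 1 else None,
        extra={"motif": motif.name, "n_per_arm": len(bound_ids)},
    )


def gene_list_overlap_test(query_genes: Sequence[str],
                           reference_list: Sequence[str],
                           universe: Sequence[str], seed: int = 0,
                           n_resamples: int = 1000,
                           alternative: str = "two-sided"
                           ) -> EnrichmentResult:
    """Overlap of a gene list with a reference list against random lists.

    Exact p from the Fisher test on (overlap, query-only, reference-only,
    neither) over the gene universe, plus an empirical one-sided p from
    ``n_resamples`` random query-size draws from the universe (fraction of
    draws with overlap >= observed, with the +1/(R+1) correction). Fold =
    observed / expected overlap under the hypergeometric null.
    """
    uni = set(universe)
    query = set(query_genes)
    ref = set(reference_list)
    offenders = sorted((query | ref) - uni)
    if offenders:
        raise ValueError(f"genes outside the universe: {offenders[:10]}")
    n_uni, n_q, n_r = len(uni), len(query), len(ref)
    obs = len(query & ref)
    a, b = obs, n_q - obs
    c, d = n_r - obs, n_uni - n_q - n_r + obs
    odds, p = fisher_2x2(a, b, c, d, alternative)
    expected = n_q * n_r / n_uni
    fold = obs / expected if expected > 0 else float("nan")

    emp_p = emp_ci = None
    if n_resamples >= 1:
        rng = np.random.default_rng(seed)
        uni_arr = np.array(sorted(uni))
        ref_mask = np.isin(uni_arr, np.array(sorted(ref)))
        hits = 0
        for _ in range(n_resamples):
            draw = rng.choice(n_uni, size=n_q, replace=False)
            if int(ref_mask[draw].sum()) >= obs:
                hits += 1
        emp_p = (hits + 1) / (n_resamples + 1)
        lo, hi = stats.binomtest(hits, n_resamples).proportion_ci(
            confidence_level=0.95, method="wilson")
        emp_ci = (float(lo), float(hi))
    return EnrichmentResult(
        a, b, c, d, odds, p, test="fisher_exact", alternative=alternative,
        seed=seed, n_resamples=n_resamples, empirical_p=emp_p,
        empirical_p_ci=emp_ci,
        extra={"observed_overlap": obs, "expected_overlap": expected,
               "fold": fold, "universe_size": n_uni,
               "query_size": n_q, "reference_size": n_r},
    )


def assign_genes_to_peaks(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                          window: int = 2000) -> list:
    """Unique ids of genes whose span, extended by ``window`` bp on both
    sides, intersects at least one peak interval. Sorted for determinism."""
    import bisect

    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append(
            (pk.interval.start, pk.interval.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    out = []
    for g in genes:
        ivs = by_chrom.get(g.chrom)
        if not ivs:
            continue
        lo, hi = max(0, g.start - window), g.end + window
        starts = [s for s, _ in ivs]
        i = bisect.bisect_left(starts, hi)
        for k in range(i - 1, -1, -1):
            s, e = ivs[k]
            if e > lo:
                out.append(g.gene_id)
                break
            # peaks are short; stop once starts fall far below the window
            if s < lo - 1_000_000:
                break
        else:
            continue
    return sorted(set(out))
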