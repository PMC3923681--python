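"""Summit-centered read-density profiles, peak-set overlap and distances.

The central object is the :class:`SignalMatrix`: peaks x position-bins,
holding multi-mapping-weighted 5'-end counts in bins around each peak
summit, normalized per 10 million mapped reads and ordered by the caller's
significance score with the strongest peaks at the bottom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import AlignedRead, Peak


@dataclass
class SignalMatrix:
    """Weighted 5'-end counts in bins of width ``bin_size`` spanning
    +/-``flank`` around each peak summit.

    ``values`` is normalized per 10 million mapped reads
    (raw counts x 1e7 / total_reads); ``raw`` keeps the unnormalized
    weighted counts. Rows are ordered by peak score ascending, so the
    strongest peaks are the last rows (bottom of a rendered heatmap).
    """

    values: np.ndarray
    raw: np.ndarray
    peak_names: list
    scores: np.ndarray
    flank: int
    bin_size: int
    total_reads: float
    factor: str = ""

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size

    @property
    def bin_offsets(self) -> np.ndarray:
        """Left edge of each bin, relative to the summit."""
        return -self.flank + self.bin_size * np.arange(self.n_bins)

    def column_profile(self) -> np.ndarray:
        """Aggregate profile: column means of the normalized matrix."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values,
                          columns=[str(o) for o in self.bin_offsets])
        df.insert(0, "peak", self.peak_names)
        df.insert(1, "score", self.scores)
        return df


def signal_profile(peaks: Sequence[Peak], reads: Sequence[AlignedRead],
                   flank: int = 200, bin_size: int = 10,
                   total_reads: Optional[float] = None,
                   factor: str = "") -> SignalMatrix:
    """Count weighted read 5' ends in bins around each peak summit.

    ``value(i, j)`` is the sum of 1/N weights of reads whose 5' end falls
    in bin j of peak i, scaled by 1e7 / total_reads. ``total_reads``
    defaults to the summed weight of the supplied reads (the number of
    distinct mapped reads when every alignment of each read is present).
    """
    if (2 * flank) % bin_size != 0:
        raise ValueError(f"bin size {bin_size} does not divide window {2 * flank}")
    if total_reads is None:
        total_reads = float(sum(r.weight for r in reads))
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")

    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].score, i))
    n_bins = 2 * flank // bin_size
    raw = np.zeros((len(peaks), n_bins))

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = sorted({r.chrom for r in reads})
    for chrom in chroms:
        sub = [(r.five_prime_pos, r.weight) for r in reads if r.chrom == chrom]
        sub.sort()
        pos = np.array([p for p, _ in sub], dtype=np.int64)
        wts = np.array([w for _, w in sub])
        by_chrom[chrom] = (pos, np.concatenate([[0.0], np.cumsum(wts)]), wts)

    for row, i in enumerate(order):
        pk = peaks[i]
        if pk.chrom not in by_chrom:
            continue
        pos, _, wts = by_chrom[pk.chrom]
        lo = np.searchsorted(pos, pk.summit - flank, side="left")
        hi = np.searchsorted(pos, pk.summit + flank, side="left")
        if hi > lo:
            offsets = pos[lo:hi] - (pk.summit - flank)
            np.add.at(raw[row], offsets // bin_size, wts[lo:hi])

    values = raw * (1e7 / total_reads)
    return SignalMatrix(
        values=values, raw=raw,
        peak_names=[peaks[i].name for i in order],
        scores=np.array([peaks[i].score for i in order], dtype=float),
        flank=flank, bin_size=bin_size, total_reads=total_reads, factor=factor,
    )


def top_n_heatmap(peaks: Sequence[Peak], reads: Sequence[AlignedRead],
                  n: int, flank: int = 500, bin_size: int = 10,
                  total_reads: Optional[float] = None,
                  factor: str = "") -> SignalMatrix:
    """signal_profile restricted to the n strongest peaks by score."""
    if n > len(peaks):
        raise ValueError(f"n={n} exceeds the number of peaks ({len(peaks)})")
    strongest = sorted(peaks, key=lambda p: p.score, reverse=True)[:n]
    return signal_profile(strongest, reads, flank, bin_size, total_reads, factor)


def coloc_score(matrix: SignalMatrix, center_halfwidth: int = 100) -> float:
    """Center-to-flank signal ratio of the aggregate profile.

    (mean normalized signal in bins fully within +/-center_halfwidth of the
    summit) / (mean in the remaining outer bins). Background-only data give
    ~1; NaN with a warning when the outer flanks carry no signal.
    """
    if center_halfwidth >= matrix.flank:
        raise ValueError("center_halfwidth must be < flank")
    prof = matrix.column_profile()
    left = matrix.bin_offsets
    right = left + matrix.bin_size
    center = (left >= -center_halfwidth) & (right <= center_halfwidth)
    outer = ~center
    outer_mean = prof[outer].mean()
    if outer_mean == 0:
        warnings.warn("zero signal in outer flanks; colocalization score "
                      "undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(prof[center].mean() / outer_mean)


# ---------------------------------------------------------------------------
# Peak-set overlap and conservation
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    set_names: list
    set_sizes: list
    #: pairwise[(i, j)] = number of peaks of set i overlapped by >=1 peak of set j
    pairwise: dict
    #: per set: number of its peaks overlapped by >=1 peak in EVERY other set
    conserved_counts: list
    kway: int  # conserved count of the first set
    mode: str
    summit_window: Optional[int] = None

    @property
    def conserved_fractions(self) -> list:
        return [c / s if s else float("nan")
                for c, s in zip(self.conserved_counts, self.set_sizes)]

    def to_dict(self) -> dict:
        return {
            "sets": self.set_names, "sizes": self.set_sizes,
            "pairwise": {f"{self.set_names[i]}|{self.set_names[j]}": v
                         for (i, j), v in self.pairwise.items()},
            "conserved_counts": self.conserved_counts,
            "conserved_fractions": self.conserved_fractions,
            "kway": self.kway, "mode": self.mode,
            "summit_window": self.summit_window,
        }


def _overlap_mask(setA: Sequence[Peak], setB: Sequence[Peak], mode: str,
                  summit_window: int) -> np.ndarray:
    """Boolean array: A-peaks having >=1 qualifying B-peak."""
    mask = np.zeros(len(setA), dtype=bool)
    by_chrom: dict[str, list[Peak]] = {}
    for pk in setB:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    if mode == "interval":
        index = {}
        for c, pks in by_chrom.items():
            pks = sorted(pks, key=lambda p: p.interval.start)
            starts = np.array([p.interval.start for p in pks])
            maxlen = max(p.interval.length for p in pks)
            index[c] = (starts, pks, maxlen)
        for i, pk in enumerate(setA):
            if pk.chrom not in index:
                continue
            starts, pks, maxlen = index[pk.chrom]
            # candidates start before A ends and can reach A only if they
            # start within maxlen of A's start
            hi = np.searchsorted(starts, pk.interval.end, side="left")
            for k in range(hi - 1, -1, -1):
                b = pks[k]
                if b.interval.end > pk.interval.start:
                    mask[i] = True
                    break
                if b.interval.start < pk.interval.start - maxlen:
                    break
    elif mode == "summit_window":
        index = {c: np.array(sorted(p.summit for p in pks))
                 for c, pks in by_chrom.items()}
        for i, pk in enumerate(setA):
            summits = index.get(pk.chrom)
            if summits is None or len(summits) == 0:
                continue
            j = np.searchsorted(summits, pk.summit)
            best = min(
                abs(int(summits[k]) - pk.summit)
                for k in (j - 1, j) if 0 <= k < len(summits)
            )
            mask[i] = best <= summit_window
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return mask


def peak_overlap(setA: Sequence[Peak], setB: Sequence[Peak],
                 mode: str = "interval", summit_window: int = 200,
                 names=("A", "B")) -> OverlapSummary:
    """Pairwise overlap between two peak sets.

    ``interval`` mode requires >=1 bp intersection of the peak intervals;
    ``summit_window`` mode requires summit distance <= ``summit_window``.
    """
    maskA = _overlap_mask(setA, setB, mode, summit_window)
    maskB = _overlap_mask(setB, setA, mode, summit_window)
    return OverlapSummary(
        set_names=list(names), set_sizes=[len(setA), len(setB)],
        pairwise={(0, 1): int(maskA.sum()), (1, 0): int(maskB.sum())},
        conserved_counts=[int(maskA.sum()), int(maskB.sum())],
        kway=int(maskA.sum()), mode=mode,
        summit_window=summit_window if mode == "summit_window" else None,
    )


def conservation(sets: Sequence[Sequence[Peak]], names: Optional[list] = None,
                 mode: str = "interval", summit_window: int = 200
                 ) -> OverlapSummary:
    """All pairwise overlaps plus the k-way intersection of >=2 peak sets.

    The k-way count is the number of first-set peaks overlapped by a peak
    in every other set; per-set conserved counts apply the same rule to
    each set in turn.
    """
    if len(sets) < 2:
        raise ValueError("conservation requires >= 2 peak sets")
    if names is None:
        names = [f"set{i + 1}" for i in range(len(sets))]
    pairwise = {}
    masks = {}
    for i, si in enumerate(sets):
        for j, sj in enumerate(sets):
            if i == j:
                continue
            m = _overlap_mask(si, sj, mode, summit_window)
            masks[(i, j)] = m
            pairwise[(i, j)] = int(m.sum())
    conserved = []
    for i in range(len(sets)):
        everywhere = np.ones(len(sets[i]), dtype=bool)
        for j in range(len(sets)):
            if i != j:
                everywhere &= masks[(i, j)]
        conserved.append(int(everywhere.sum()))
    return OverlapSummary(
        set_names=list(names), set_sizes=[len(s) for s in sets],
        pairwise=pairwise, conserved_counts=conserved, kway=conserved[0],
        mode=mode,
        summit_window=summit_window if mode == "summit_window" else None,
    )


# ---------------------------------------------------------------------------
# Nearest-peak distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceRecord:
    peak_a: str
    distance: int  # signed; negative = A is 5' of B in the orientation frame
    score_a: float
    score_b: float


def nearest_peak_distances(peaksA: Sequence[Peak], peaksB: Sequence[Peak],
                           orientation: str = "reference",
                           strands_a: Optional[Sequence[str]] = None,
                           hist_halfwidth: int = 500,
                           hist_bin: int = 50):
    """Signed distance from each A summit to the nearest B summit.

    ``distance = summit_A - summit_B`` in the reference frame (negative =
    A lies at a lower coordinate, i.e. 5' of B); with
    ``orientation="gene"`` the sign is flipped for A peaks on - strand
    genes (``strands_a`` supplies one strand per A peak, e.g. from a
    promoter annotation), so negative always means "A upstream of B".
    Ties in |distance| break toward the negative side. A peaks on
    chromosomes with no B peak are dropped and counted.

    Returns ``(records, summary)``; the summary reports the median
    |distance|, the modal histogram bin of the signed distance and the
    fraction of negative (upstream) distances.
    """
    if orientation not in ("reference", "gene"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "gene":
        if strands_a is None or len(strands_a) != len(peaksA):
            raise ValueError("gene orientation requires one strand per A peak")

    by_chrom: dict[str, list] = {}
    for pk in peaksB:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    index = {}
    for chrom, pks in by_chrom.items():
        pks.sort(key=lambda p: p.summit)
        index[chrom] = (np.array([p.summit for p in pks], dtype=np.int64), pks)

    records = []
    dropped = 0
    for i, pk in enumerate(peaksA):
        if pk.chrom not in index:
            dropped += 1
            continue
        summits, pks = index[pk.chrom]
        j = np.searchsorted(summits, pk.summit)
        cands = [k for k in (j - 1, j) if 0 <= k < len(summits)]
        # minimal |d|; ties toward negative d (lower-coordinate B... a B at
        # +d and one at -d tie: pick the one giving negative signed distance)
        best = min(
            cands,
            key=lambda k: (abs(pk.summit - int(summits[k])),
                           pk.summit - int(summits[k])),
        )
        d = pk.summit - int(summits[best])
        if orientation == "gene" and strands_a[i] == "-":
            d = -d
        records.append(DistanceRecord(pk.name, d, pk.score, pks[best].score))

    dists = np.array([r.distance for r in records], dtype=np.int64)
    if len(dists):
        edges = np.arange(-hist_halfwidth, hist_halfwidth + hist_bin, hist_bin)
        hist, _ = np.histogram(dists, bins=edges)
        k = int(np.argmax(hist))
        modal_bin = (int(edges[k]), int(edges[k + 1]))
        summary = {
            "n": len(dists), "dropped_no_b_on_chrom": dropped,
            "median_abs_distance": float(np.median(np.abs(dists))),
            "modal_bin": modal_bin, "modal_bin_count": int(hist[k]),
            "upstream_fraction": float((dists < 0).mean()),
            "orientation": orientation,
        }
    else:
        summary = {"n": 0, "dropped_no_b_on_chrom": dropped,
                   "median_abs_distance": float("nan"), "modal_bin": None,
                   "modal_bin_count": 0, "upstream_fraction": float("nan"),
                   "orientation": orientation}
    return records, summary
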