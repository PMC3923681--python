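"""Readers and writers for the file dialects the pipeline touches.

All internal coordinates are 0-based half-open; GTF ingestion is the only
1-based boundary. Chromosome names are compared as exact strings (no "chr"
normalization) so that overlaps are reproducible across inputs.

Dialects
--------
``bed6``
    chrom, start, end, name, score, strand.
``peak_bed``
    BED6 plus column 7 = summit offset relative to ``start``.
``aln_bed``
    BED6 plus column 7 = number of genomic alignments of the read (N);
    each alignment record carries weight 1/N. The name column holds the
    read identifier, shared by all alignments of one read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A located feature on one chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp intersection under half-open arithmetic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding site with its maximum-signal position (summit).

    ``score`` is the peak caller's significance score; higher = stronger.
    ``summit_imputed`` flags peaks whose input lacked an explicit summit
    (the interval midpoint, rounded down, is substituted).
    """

    interval: GenomicInterval
    summit: int
    score: float
    summit_imputed: bool = False

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if not math.isfinite(self.score):
            raise ValueError("peak score must be finite")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def name(self) -> str:
        return self.interval.name


@dataclass(frozen=True)
class AlignedRead:
    """One alignment of a sequencing read.

    ``five_prime_pos`` is the 0-based genomic position of the read's 5' end
    (= BED start on the + strand, BED end - 1 on the - strand). ``n_hits``
    is the read's total number of genomic alignments N; every alignment of
    an N-times matched read carries weight 1/N, so a read's alignments
    collectively sum to one read.
    """

    chrom: str
    five_prime_pos: int
    strand: str
    n_hits: int = 1
    read_id: str = "."

    def __post_init__(self):
        if self.n_hits < 1:
            raise ValueError(f"n_hits must be >= 1, got {self.n_hits}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits


@dataclass(frozen=True)
class GeneModel:
    """A gene with its isoform structure and promoter attributes.

    ``tss`` is the 0-based position of the first transcribed base: the gene
    start on the + strand and the last base (``end - 1``) on the - strand.
    ``cpg_promoter`` flags promoters overlapping a CpG island.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    isoforms: tuple  # of (transcript_id, tuple of GenomicInterval exons)
    cpg_promoter: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id} has no isoforms")
        for tx_id, exons in self.isoforms:
            for ex in exons:
                if ex.start < self.start or ex.end > self.end:
                    raise ValueError(
                        f"exon [{ex.start},{ex.end}) of {tx_id} outside "
                        f"gene span [{self.start},{self.end}) of {self.gene_id}"
                    )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def gene_end(self) -> int:
        """Position of the last transcribed base (3' end)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand,
                               self.gene_id)


@dataclass(frozen=True)
class RepeatRegion:
    """An annotated repeat element instance with its class and family."""

    interval: GenomicInterval
    repeat_class: str
    repeat_family: str

    def __post_init__(self):
        if not self.repeat_class or not self.repeat_family:
            raise ValueError("repeat class and family must be non-empty")


# ---------------------------------------------------------------------------
# BED dialects
# ---------------------------------------------------------------------------

_BED_DIALECTS = ("bed6", "peak_bed", "aln_bed")


def _parse_bed_fields(line: str, lineno: int, min_cols: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise FormatError(
            f"line {lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    chrom, start_s, end_s = fields[0], fields[1], fields[2]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer coordinates") from exc
    if start >= end:
        raise FormatError(f"start >= end at line {lineno}")
    if start < 0:
        raise FormatError(f"negative start at line {lineno}")
    name = fields[3] if len(fields) > 3 else "."
    try:
        score = float(fields[4]) if len(fields) > 4 else 0.0
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric score") from exc
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in STRANDS:
        raise FormatError(f"line {lineno}: bad strand {strand!r}")
    return fields, chrom, start, end, name, score, strand


def read_bed(path, dialect: str = "bed6"):
    """Read a BED-dialect file into domain objects.

    Returns a list of :class:`GenomicInterval` (``bed6``), :class:`Peak`
    (``peak_bed``) or :class:`AlignedRead` (``aln_bed``). Peaks in a
    ``peak_bed`` file missing the summit column get the interval midpoint
    (rounded down) and are flagged ``summit_imputed``.
    """
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {_BED_DIALECTS}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            min_cols = 6 if dialect != "bed6" else 3
            fields, chrom, start, end, name, score, strand = _parse_bed_fields(
                line, lineno, min_cols
            )
            if dialect == "bed6":
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            elif dialect == "peak_bed":
                if len(fields) > 6 and fields[6] not in ("", "."):
                    try:
                        offset = int(fields[6])
                    except ValueError as exc:
                        raise FormatError(
                            f"line {lineno}: non-integer summit offset"
                        ) from exc
                    summit = start + offset
                    imputed = False
                else:
                    summit = start + (end - start) // 2
                    imputed = True
                if not (start <= summit < end):
                    raise FormatError(f"line {lineno}: summit outside interval")
                out.append(
                    Peak(GenomicInterval(chrom, start, end, strand, name, score),
                         summit, score, summit_imputed=imputed)
                )
            else:  # aln_bed
                try:
                    n_hits = int(fields[6]) if len(fields) > 6 else 1
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-integer n_hits") from exc
                if n_hits < 1:
                    raise FormatError(f"line {lineno}: n_hits < 1")
                if strand not in ("+", "-"):
                    raise FormatError(
                        f"line {lineno}: read strand must be + or -"
                    )
                pos = start if strand == "+" else end - 1
                out.append(AlignedRead(chrom, pos, strand, n_hits, read_id=name))
    return out


def write_bed(records: Sequence, path, dialect: str = "bed6",
              read_length: int = 36) -> None:
    """Write domain objects back to a BED dialect (inverse of read_bed).

    Aligned reads are written as ``read_length`` bp intervals anchored at
    the 5' end (clipped at 0 on the - strand).
    """
    with open(path, "w") as fh:
        for rec in records:
            if dialect == "bed6":
                iv = rec
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                         f"{iv.score!r}\t{iv.strand}\n")
            elif dialect == "peak_bed":
                iv = rec.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                         f"{rec.score!r}\t{iv.strand}\t{rec.summit - iv.start}\n")
            elif dialect == "aln_bed":
                if rec.strand == "+":
                    start, end = rec.five_prime_pos, rec.five_prime_pos + read_length
                else:
                    start = max(0, rec.five_prime_pos - read_length + 1)
                    end = rec.five_prime_pos + 1
                fh.write(f"{rec.chrom}\t{start}\t{end}\t{rec.read_id}\t0\t"
                         f"{rec.strand}\t{rec.n_hits}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def read_repeats(path):
    """Read a repeat annotation BED (column 4 = ``class:family``)."""
    out = []
    for iv in read_bed(path, "bed6"):
        if ":" not in iv.name:
            raise FormatError(
                f"repeat name {iv.name!r} is not of the form class:family"
            )
        cls, fam = iv.name.split(":", 1)
        out.append(RepeatRegion(iv, cls, fam))
    return out


def write_repeats(regions: Sequence[RepeatRegion], path) -> None:
    ivs = [
        GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end,
                        r.interval.strand, f"{r.repeat_class}:{r.repeat_family}",
                        r.interval.score)
        for r in regions
    ]
    write_bed(ivs, path, "bed6")


# ---------------------------------------------------------------------------
# GTF-lite gene models
# ---------------------------------------------------------------------------

def _gtf_attributes(raw: str, lineno: int) -> dict:
    attrs = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            key, value = part.split(" ", 1)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed attribute {part!r}") from exc
        attrs[key] = value.strip().strip('"')
    return attrs


def read_genes(path, cpg_flag_attr: str = "cpg_promoter"):
    """Read a GTF-lite file (gene/transcript/exon rows) into GeneModels.

    GTF coordinates are 1-based inclusive; they are converted here to the
    internal 0-based half-open convention. Transcripts are grouped under
    their parent gene; the TSS is derived from the strand. A gene row may
    carry a ``cpg_promoter "true"`` attribute to flag CpG-island promoters.
    """
    genes: dict[str, dict] = {}
    tx_to_gene: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_raw = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(f"line {lineno}: bad 1-based span {start1}..{end1}")
            start, end = start1 - 1, end1  # to 0-based half-open
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: gene features need +/- strand")
            attrs = _gtf_attributes(attr_raw, lineno)
            if feature == "gene":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise FormatError(f"line {lineno}: gene row without gene_id")
                if gid in genes:
                    raise FormatError(f"line {lineno}: duplicate gene_id {gid!r}")
                genes[gid] = {
                    "chrom": chrom, "strand": strand, "start": start, "end": end,
                    "cpg": attrs.get(cpg_flag_attr, "false").lower()
                    in ("true", "1", "yes"),
                    "isoforms": {},
                }
                order.append(gid)
            elif feature == "transcript":
                gid, tid = attrs.get("gene_id"), attrs.get("transcript_id")
                if gid is None or gid not in genes:
                    raise FormatError(
                        f"line {lineno}: transcript without parent gene"
                    )
                genes[gid]["isoforms"].setdefault(tid, [])
                tx_to_gene[tid] = gid
            elif feature == "exon":
                tid = attrs.get("transcript_id")
                if tid is None or tid not in tx_to_gene:
                    raise FormatError(
                        f"line {lineno}: exon without parent transcript"
                    )
                gid = tx_to_gene[tid]
                g = genes[gid]
                if start < g["start"] or end > g["end"]:
                    raise FormatError(
                        f"line {lineno}: exon outside span of gene {gid!r}"
                    )
                g["isoforms"][tid].append(
                    GenomicInterval(chrom, start, end, g["strand"])
                )
            # other feature types ignored
    models = []
    for gid in order:
        g = genes[gid]
        isoforms = tuple(
            (tid, tuple(sorted(exons, key=lambda e: e.start)))
            for tid, exons in g["isoforms"].items()
        )
        if not isoforms:  # gene with no transcript: single-isoform stand-in
            isoforms = (
                (f"{gid}.t1",
                 (GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"]),)),
            )
        models.append(
            GeneModel(gid, g["chrom"], g["strand"], g["start"], g["end"],
                      isoforms, cpg_promoter=g["cpg"])
        )
    return models


def write_genes(genes: Iterable[GeneModel], path) -> None:
    """Write GeneModels as GTF-lite (1-based inclusive), inverse of read_genes."""
    with open(path, "w") as fh:
        for g in genes:
            cpg = "true" if g.cpg_promoter else "false"
            attrs = f'gene_id "{g.gene_id}"; cpg_promoter "{cpg}";'
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for tid, exons in g.isoforms:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                fh.write(f"{g.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{tattrs}\n")
                for ex in exons:
                    fh.write(f"{g.chrom}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                             f"{g.strand}\t.\t{tattrs}\n")


# ---------------------------------------------------------------------------
# FASTA and tables
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an ``{id: uppercase sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_table(records, path, columns=None) -> None:
    """Write records (DataFrame, list of dicts, or list of tuples) as a TSV
    with header and deterministic column order."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=columns)
    if columns is not None:
        df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
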