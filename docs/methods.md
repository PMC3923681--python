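# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; overlap means ≥ 1 bp of
intersection under half-open arithmetic. GTF ingestion is the only 1-based
boundary. Chromosome names are compared as exact strings — no "chr"
aliasing — because silent normalization makes overlap counts
irreproducible across annotation sources. A read's 5′ end is its BED start
on the + strand and `end − 1` on the − strand.

## Peak annotation

Each gene defines four strand-oriented windows anchored at the TSS and the
gene end: promoter = TSS ± 1000 bp, upstream = the 4 kb immediately 5′ of
the promoter (to −5000), gene body = from TSS + 1000 to the gene end,
downstream = the 5 kb past the gene end. Windows are clipped at chromosome
bounds; a gene shorter than 1 kb has an empty gene body (allowed). The
peak interval is extended by 150 bp on both sides and assigned the single
intersected window highest in the preference order promoter → gene body →
upstream → downstream; peaks intersecting nothing are *intergenic*, kept
as an explicit fifth label so that label counts always partition the peak
set. The preference order fixes conflicts *between* categories; within one
category the tie goes to the gene whose TSS is nearest the summit, then to
the lexicographically smallest gene id, so annotation is deterministic.
Windows never overlap within one gene because the body starts at
TSS + 1 kb by construction.

The reported `distance_to_tss` is strand-oriented (negative = upstream of
transcription). Fractions of promoter-bound peaks at CpG-island promoters
and at expressed genes are computed over promoter-labeled peaks only and
are NA when there are none.

## Expression

Per isoform, RPKM = (summed exon read counts) / (exonic length in kb ×
total mapped reads in millions); the gene value is the maximum over
isoforms and a gene is called expressed iff RPKM > 0.6, strictly — a gene
at exactly 0.6 is not expressed. RPKM is linear in counts and
inverse-linear in depth, which the suite checks by scaling both.

## Signal matrices and colocalization

`signal_profile` counts 1/N-weighted read 5′ ends in bins of width *b*
(default 10 bp, fine enough to resolve 100–200 bp offset structure)
spanning ± flank around each summit, scaled by 10⁷ / total mapped reads;
raw counts are kept alongside. Rows are ordered by caller score ascending
so rendered heatmaps put the strongest peaks at the bottom. Row mass is
conserved: (row sum) × total/10⁷ equals the summed weight of reads in the
window, and the matrix is invariant under joint translation of reads and
summits.

`coloc_score` is the mean normalized signal in bins fully inside
± `center_halfwidth` divided by the mean over the remaining outer bins;
background-only data score ≈ 1, and a zero outer mean yields NaN with a
warning. To read the score as the planted peak/background density ratio
the outer bins must be essentially background — i.e. the flank should
extend well past the read spread (we use flank 1000 with center 200 for a
fragment length of 200; with flank equal to the signal window the outer
bins still contain summit-spread reads and the expected score is smaller,
computable from the normal spread in closed form).

Peak-set overlap supports two definitions, both recorded in output
metadata: `interval` (≥ 1 bp intersection of peak intervals, the default)
and `summit_window` (summit distance ≤ w, default 200 bp). Conservation of
k sets reports all pairwise overlap counts, per-set conserved counts (the
set's peaks overlapped in *every* other set) and the k-way count of the
first set; the pairwise and k-way readings of "conserved" are both
reported because the headline "80% conserved" style statistic is ambiguous
between them.

Nearest-summit distances are signed, `d = summit_A − summit_B`, negative
meaning A is 5′ of B in the reference frame; with `orientation="gene"` the
sign is flipped for A peaks on − strand genes so negative always means
upstream of transcription. Gene orientation is only meaningful for
promoter-assigned A peaks, so the pipeline restricts the distance analysis
to those. Ties in |d| break toward the negative (upstream) side for
reproducibility. The summary reports the median |d|, the modal bin of a
±500 bp histogram with 100 bp bins (wide enough that a planted −150 bp
offset sits inside one bin rather than on an edge) and the fraction of
negative distances.

## Repeat enrichment

Alignments of reads matching N genomic locations carry weight 1/N each, so
one read's alignments sum to one; reads with N > 10 are discarded before
any counting. An alignment is assigned to a repeat class iff its 5′ end
lies inside a region of that class — single assignment by position, the
same convention as the profile module. Per class and per class/family,
rpk10m = weighted count / (class length in kb × total aligned reads in
units of 10⁷); "total aligned reads" counts distinct retained reads
(summed weights), not alignment records, so depth normalization is
independent of the multi-mapping structure. Fold = chip rpk10m / input
rpk10m, NA when the input is empty; it is invariant to splitting regions
and to common depth scaling.

`bound_repeat_regions` calls a region bound when its ChIP/input fold
exceeds a threshold (default 5). The input expectation is smoothed at the
class level (class-wide input density × region length) rather than using
the per-region observed input count: at realistic depths a region's input
count is Poisson with single-digit mean and dividing by it would dominate
the fold noise.

## Enrichment statistics

Motif scanning honors IUPAC degenerate codes, scans both strands (reverse
complement hits are reported at their forward-strand offset), never
matches N, and supports PWMs with a threshold expressed as a fraction of
the maximum attainable score. Site-level presence is binary (≥ 1 hit).

Motif enrichment contrasts bound CpG-island promoters with an equal-count
random draw from the non-bound CpG-island promoters — the draw is without
replacement and excludes the bound set so a bound promoter cannot dilute
the control arm — tested with the exact Fisher test (two-sided by default;
one-sided available and recorded). The draw is seeded; optional repeated
draws report the p-value distribution. Gene-list overlap tests report the
exact Fisher p on the 2×2 table over the gene universe, the
hypergeometric expectation and fold, and an empirical one-sided p from
seeded equal-size random draws with the (hits + 1)/(R + 1) correction and
a Monte-Carlo CI. When several motifs are tested in one run, Bonferroni-
adjusted p-values accompany the raw ones.

## Synthetic data generator

The generator emulates the structure of a promoter-factor ChIP study; its
defaults are the study conditions the analyses are validated against:

| parameter | default | meaning |
|---|---|---|
| genome | 10 × 10 Mb | chromosome count × length |
| n_genes | 2500 | non-overlapping genes, 1.5–4 kb, 1–3 exons, 1–2 isoforms |
| promoter_fraction (loading factor) | 0.8 | share of its 1000 peaks at promoters |
| offset μ, σ | −150, 40 bp | summit position vs TSS, strand-oriented |
| polymerase | 1500 peaks at the TSS, 95 % sharing with the loading factor |
| enrichment e | 10 | 5′-end density in summit ± 200 bp over background |
| fragment_len | 200 bp | read 5′ spread: normal, sd = fragment_len/2 |
| n_reads | 10⁵ per factor | one uniform-background input sample included |
| repeats | rRNA: 250 LSU + 217 SSU copies, 500 bp, 5-way multi-mapping, 10× ChIP boost |
| CpG fraction | 0.9 bound / 0.6 background | promoter CpG-island flags |
| expressed fraction | 0.98 bound / 0.6 background | on/off mixture, lognormal "on" level floored at 2 RPKM |
| motif occupancy | 0.8 bound / 0.4 unbound | CCAAT consensus in 101 bp promoter windows |
| DE list | 300 genes, 60 % drawn from bound genes |

Key mechanisms and the reasoning behind them:

- **Streams.** Every component (genome, repeats, each factor's peaks, each
  factor's reads, expression, motif sequences, DE list) has its own
  generator stream spawned from the master seed, so changing one
  component's size never perturbs another — outputs are bit-exact under a
  fixed config, with no time-based entropy.
- **Gene layout** uses one jittered slot per gene, giving guaranteed
  capacity (an explicit error when the genome is too small) and
  non-overlapping genes by construction.
- **Read budget.** The enrichment e is defined as the expected 5′-end
  density inside summit ± 200 bp divided by the background density; the
  per-peak read count follows in closed form from e, the normal spread and
  the background rate, with per-peak counts multinomial over lognormal
  peak strengths. Peak scores are strength × lognormal noise so score
  ranking correlates with true strength (needed for meaningful top-N
  heatmaps).
- **Background peaks avoid promoter neighborhoods** (≥ 1.5 kb from any
  TSS), so the planted promoter fraction is identifiable: the recovered
  promoter-label fraction is exactly Binomial(n_peaks, f)/n_peaks rather
  than f plus a genome-density-dependent inflation.
- **Colocalization** pairs (A, B, shared fraction) anchor a fraction of
  B's peaks to a sample of A's: at the same gene (with B's own TSS offset)
  when A's peak is promoter-anchored, at A's summit ± 20 bp otherwise.
  Planting three "cell lines" where lines 2 and 3 each share 80 % of line
  1's sites gives pairwise conservation 0.8 and, by independence of the
  two samples, a three-way intersection of 0.64.
- **Multi-mapping** is modeled by copy count, not re-alignment: copies of
  one repeat family are interchangeable, and a read from a family with k
  effective copies (`min(n_regions, multi_map_n)`) is emitted as k
  alignment records at the same offset in k distinct copies, each with
  n_hits = k — so retained weights sum to distinct reads, and ChIP/input
  folds are unaffected by the convention. Note that multi-mapping smears
  region-level signal across a family; per-region bound-detection
  scenarios therefore use uniquely mapping repeat variants.
- **Expression** is an on/off mixture; the "on" level is lognormal floored
  at 2 RPKM so the RPKM > 0.6 call survives Poisson counting noise at the
  default 10⁷-read depth, making the configured expressed fraction
  recoverable to ± binomial noise. Exon counts are Poisson with
  length-proportional multinomial spread; isoform shares are 0.8/0.2 when
  a second isoform exists. The configured total mapped reads is the
  normalization constant the counts are scaled to.
- **Motif sequences** are generated motif-free by rejection before
  planting consensus occurrences (random offset and strand), so the
  planted occupancy equals the expected site fraction exactly. Real
  promoters of course contain chance motif matches; this simplification
  trades that realism for an exactly identifiable occupancy parameter.

### What the generator does not model

Sequencing errors, GC bias, mappability structure, paired-end fragments,
diploid genomes, bimodal strand-split 5′-end pileups around summits,
overlapping genes, enhancer annotation and chromatin states. Passing
recovery tests therefore demonstrates the correctness of the estimators
under the stated statistical model, not robustness to every artifact of
real sequencing data.

## Problem sizes

The default study uses a 100 Mb genome, 2500 genes, 10⁵ reads per factor
and 1000–1500 peaks per factor; recovery checks run on one such world,
power and null-calibration checks use 100–200 seeded replicates of the
promoter-sequence arm (692 promoters per arm, matching the bound-CpG
design size). These sizes put every planted parameter several standard
errors inside its acceptance band while keeping a full run in seconds.

## Pipeline and reporting

`run_all` executes simulate → annotate → profile/distances → repeats →
motif → gene overlap, writes per-stage TSVs and a consolidated
`report.json`/`report.txt`, and serializes the exact config alongside.
The report contains no timestamps, so a rerun with the same config is
byte-identical; logging goes to stderr only. Reported percentages round
to the nearest integer with ties away from zero (912/1138 → 80 %,
122/1118 → 11 %). Stage failures abort with the stage name; outputs
already written are retained.

## Known limitations

- The interval-overlap scan is O(n · k) in the local peak density; it is
  exact but not the asymptotically optimal sweep.
- PWM scanning is pure Python and intended for promoter-scale inputs, not
  genome-wide scans.
- The Fisher test's two-sided p on discrete tables is conservative at
  small counts, as for any exact test.
- SAM/BAM ingestion is out of scope; alignments enter as the BED dialect
  with an n_hits column (the NH-tag equivalent).
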