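# cohesichip

Downstream analysis of transcription-factor ChIP-seq experiments of the kind
used to characterize promoter-bound chromatin factors (e.g. the cohesin
loading factor NIPBL versus cohesin/CTCF and RNA polymerase II), packaged
with a synthetic-data generator so every statistic is testable end to end
without any external download.

The package is aimed at computational biologists who have peak calls, read
alignments, gene models and repeat annotations and want the classic battery
of summary analyses:

- **Peak annotation** into five categories by a priority scheme. Each gene
  defines four strand-oriented windows — promoter (TSS ± 1 kb), upstream
  (−5 kb … −1 kb of the TSS), gene body (TSS + 1 kb … gene end) and
  downstream (gene end + 5 kb). A peak extended by ±150 bp is assigned the
  highest-priority window it intersects
  (promoter → gene body → upstream → downstream), else *intergenic*.
- **Summit-centered signal matrices**: weighted read 5′-end counts in bins
  around each peak summit, normalized per 10⁷ mapped reads, rows ordered by
  caller score (strongest peaks at the bottom), with top-N variants, an
  aggregate profile, and a center/flank colocalization score.
- **Peak-set overlap and conservation** across samples (pairwise and k-way),
  and signed nearest-summit distances (negative = upstream), e.g. to show a
  factor sits 100–200 bp upstream of RNA Pol II.
- **Repeat-class enrichment** with multi-mapping awareness: an alignment of
  a read matching N genomic locations carries weight 1/N; reads with N > 10
  are discarded. Per repeat class, reads per kilobase per **10 million**
  aligned reads (rpk10m) and the ChIP/input fold, plus per-region bound
  calls.
- **Expression classification**: RPKM of the most highly expressed isoform
  (summed exon coverage as the numerator); a gene is *expressed* iff
  RPKM > 0.6.
- **Enrichment statistics**: IUPAC/PWM motif scanning on both strands,
  motif enrichment at bound CpG-island promoters versus an equal-count
  random draw of CpG-island promoters (exact Fisher test, seeded draw), and
  gene-list overlap tests against hypergeometric and resampled nulls.

The synthetic generator (`cohesichip.synthetic_data`) plants all of these
signals — promoter-biased peaks with TSS offsets, colocalizing factor
pairs, reads enriched over a uniform background, multi-mapping repeat
families, CpG/expression bias at bound promoters, CCAAT-box occupancy — and
records the ground truth, so each module is validated by parameter
recovery and by brute-force oracles.

## Worked example

```python
from cohesichip import (annotate_peaks, default_config, generate_world,
                        report_fractions)

world = generate_world(default_config(seed=1))
peaks = world.truth.factor_peaks["nipbl"]
table, summary = annotate_peaks(peaks, world.genes, world.chrom_lengths)
print(summary)
prom = int(summary.loc[summary.label == "promoter", "count"].iloc[0])
print("promoter-localized:", report_fractions(prom, len(peaks)))
```

prints

```
        label  count  fraction
0    promoter    797     0.797
1   gene_body      7     0.007
2    upstream     19     0.019
3  downstream     26     0.026
4  intergenic    151     0.151
promoter-localized: 80%
```

797 of the 1000 simulated loading-factor peaks fall in promoter windows —
the generator planted a promoter fraction of 0.8, and the annotation module
recovers it; the percentage formatter rounds to the nearest integer the way
such fractions are conventionally reported. The same world supports the
rest of the pipeline (`cohesichip run-all --seed 1 --outdir out/` writes a
consolidated JSON + text report with colocalization scores, nearest-Pol-II
distances, repeat folds, motif and gene-overlap statistics).

A CLI mirrors the library: `cohesichip
simulate|annotate|profile|overlap|distances|repeats|motif-enrich|gene-overlap|run-all`
(see `--help` for each).

## Documentation

`docs/methods.md` describes the models, the generator's assumptions and
simplifications, parameter defaults and numerical conventions.
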