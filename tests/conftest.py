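import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cohesichip.formats_io import GenomicInterval, GeneModel, Peak
from cohesichip.synthetic_data import (ColocPair, FactorConfig,
                                       RepeatClassConfig, SimConfig,
                                       default_config, generate_world)


def make_peak(chrom, start, end, summit=None, score=1.0, name="p"):
    if summit is None:
        summit = (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end, ".", name, score),
                summit, score)


def make_gene(gene_id, chrom, strand, start, end, cpg=False):
    exons = (GenomicInterval(chrom, start, end, strand),)
    return GeneModel(gene_id, chrom, strand, start, end,
                     ((f"{gene_id}.t1", exons),), cpg_promoter=cpg)


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=100_000,
                 width=(150, 500)):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        w = int(rng.integers(*width))
        start = int(rng.integers(0, span - w))
        summit = int(rng.integers(start, start + w))
        peaks.append(make_peak(chrom, start, start + w, summit,
                               float(rng.random() * 100), f"p{i}"))
    return peaks


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    genes = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span - 6000))
        end = start + int(rng.integers(1200, 6000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i}", chrom, strand, start, end))
    return genes


def small_config(seed=0, **overrides):
    """A scaled-down world for fast unit tests."""
    cfg = SimConfig(
        seed=seed, n_chroms=2, chrom_length=1_000_000, n_genes=300,
        cpg_fraction=0.6, cpg_fraction_bound=0.9,
        factors=[
            FactorConfig("tf", n_peaks=100, promoter_fraction=0.8,
                         offset_mu=-150.0, offset_sigma=40.0,
                         n_reads=20_000, enrichment=10.0,
                         repeat_boost={"rRNA": 10.0}),
            FactorConfig("pol", n_peaks=120, promoter_fraction=0.9,
                         n_reads=20_000, enrichment=10.0),
            FactorConfig("input", n_peaks=0, n_reads=20_000),
        ],
        coloc_pairs=[ColocPair("tf", "pol", 0.9)],
        repeat_classes=[
            RepeatClassConfig("rRNA", "LSU", n_regions=20, region_len=400,
                              multi_map_n=5),
        ],
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def small_world():
    return generate_world(small_config(seed=7))


@pytest.fixture(scope="session")
def study_world():
    """The full-size default world used by the acceptance checks."""
    return generate_world(default_config(seed=11))
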