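import numpy as np
import pytest

from cckit.ccio import InsertionRecord, InsertionSet, TTAAIndex
from cckit.peaks import CallerConfig, Peak, PeakSet
from cckit.simdata import SimConfig, simulate_genome, simulate_insertions


def make_insertions(positions, chrom="chr1", reads=1, strand="+", barcodes=None):
    """InsertionSet from bare start positions (end = start + 4)."""
    recs = []
    for i, p in enumerate(positions):
        bc = barcodes[i] if barcodes is not None else None
        recs.append(InsertionRecord(chrom, int(p), int(p) + 4, reads, strand, bc))
    return InsertionSet(recs)


def make_peak(chrom="chr1", start=100, end=200, pvalue=1e-5, n_exp=10):
    return Peak(chrom, start, end, n_exp, 0, max((end - start) // 10, 1),
                1.0, pvalue, pvalue, (start + end) // 2)


@pytest.fixture
def uniform_ttaa():
    """TTAA every 100 bp over 1 Mb on chr1."""
    return TTAAIndex({"chr1": list(range(0, 1_000_000, 100))})


@pytest.fixture
def planted_dataset():
    """Standard planted-peak benchmark: 10 sites, enrichment 50, seed 11."""
    cfg = SimConfig(seed=11, n_true_peaks=10, enrichment=50.0, n_background=2000)
    ttaa = simulate_genome(cfg)
    exp, bkg, truth = simulate_insertions(cfg, ttaa)
    return cfg, ttaa, exp, bkg, truth
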