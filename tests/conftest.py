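import numpy as np
import pandas as pd
import pytest

from ribocoord.models import CountMatrix, TranscriptModel
from ribocoord.simdata import SimulationConfig, simulate_dataset


@pytest.fixture
def plus_gene():
    """Two-exon + strand gene: 5'UTR 10 nt, CDS 30 nt, 3'UTR 8 nt."""
    return TranscriptModel(
        gene_id="gplus", chrom="chr1", strand="+",
        exons=((100, 130), (200, 218)),  # 30 + 18 = 48 nt
        utr5_len=10, cds_len=30, utr3_len=8,
    )


@pytest.fixture
def minus_gene():
    """Two-exon - strand gene with the same region lengths."""
    return TranscriptModel(
        gene_id="gminus", chrom="chr1", strand="-",
        exons=((500, 530), (400, 418)),  # transcript order: rightmost first
        utr5_len=10, cds_len=30, utr3_len=8,
    )


def make_alignment(chrom, five_prime, strand, length=28, name="r1"):
    """One BED-style alignment row with the given 5'-end genomic position."""
    if strand == "+":
        start, end = five_prime, five_prime + length
    else:
        start, end = five_prime - length + 1, five_prime + 1
    return pd.DataFrame(
        [{"chrom": chrom, "start": start, "end": end, "name": name,
          "length": length, "strand": strand}]
    )


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(n_genes=60, n_rpf_reads=6000, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def toy_counts():
    """5 genes x 4 samples with a 2-condition design, for normalization tests."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(5)]
    samples = ["s1", "s2", "s3", "s4"]
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(5, 4)), index=genes, columns=samples
    )
    design = pd.DataFrame(
        {
            "layer": ["mRNA"] * 4,
            "condition": ["control", "control", "stress", "stress"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    lengths = pd.Series(rng.integers(500, 3000, size=5), index=genes)
    return CountMatrix(counts=counts, design=design, lengths=lengths)
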