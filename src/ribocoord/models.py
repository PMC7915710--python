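"""Core containers shared across the pipeline.

Coordinate conventions
----------------------
All in-memory genomic intervals are 0-based half-open (``[start, end)``),
as in BED.  GFF3 on disk is 1-based inclusive; conversion happens at the
I/O boundary.  Transcript coordinates run 5'->3' in the orientation of the
gene, so position 0 is the first transcribed nucleotide regardless of
genomic strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LAYERS = ("mRNA", "Poly", "RPF")
CONDITIONS = ("control", "stress")


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's strand-aware 5'UTR / CDS / 3'UTR structure.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    chrom : str
        Chromosome name.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Genomic exon intervals (0-based half-open), ordered 5'->3' in
        transcript orientation.  For a minus-strand gene the first exon is
        the genomically rightmost one.
    utr5_len, cds_len, utr3_len : int
        Lengths (nt) of the three transcript regions; they tile the
        transcript exactly and the CDS length is a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_len} not a multiple of 3")
        exon_total = sum(e - s for s, e in self.exons)
        if exon_total != self.transcript_length:
            raise ValueError(
                f"{self.gene_id}: exon lengths sum to {exon_total}, "
                f"expected {self.transcript_length}"
            )
        genomic_order = sorted(self.exons)
        if self.strand == "+" and list(self.exons) != genomic_order:
            raise ValueError(f"{self.gene_id}: + strand exons not in ascending order")
        if self.strand == "-" and list(self.exons) != genomic_order[::-1]:
            raise ValueError(f"{self.gene_id}: - strand exons not in descending order")
        for (s1, e1), (s2, e2) in zip(genomic_order, genomic_order[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def transcript_length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_span(self) -> tuple:
        """CDS interval in transcript coordinates, half-open."""
        return (self.utr5_len, self.utr5_len + self.cds_len)

    @property
    def utr5_span(self) -> tuple:
        return (0, self.utr5_len)

    @property
    def utr3_span(self) -> tuple:
        return (self.utr5_len + self.cds_len, self.transcript_length)

    @property
    def genomic_span(self) -> tuple:
        """Total genomic footprint (0-based half-open)."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return (min(starts), max(ends))

    def to_genomic(self, tpos: int) -> int:
        """Map a transcript position to its genomic coordinate."""
        if not 0 <= tpos < self.transcript_length:
            raise IndexError(f"transcript position {tpos} outside [0, {self.transcript_length})")
        off = 0
        for s, e in self.exons:
            n = e - s
            if tpos < off + n:
                d = tpos - off
                return s + d if self.strand == "+" else e - 1 - d
            off += n
        raise AssertionError("unreachable")

    def to_transcript(self, gpos: int):
        """Map a genomic coordinate to a transcript position, or None if intronic/outside."""
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    def region_of(self, tpos: int) -> str:
        """Region label ('utr5' / 'cds' / 'utr3') containing a transcript position."""
        if tpos < self.utr5_len:
            return "utr5"
        if tpos < self.utr5_len + self.cds_len:
            return "cds"
        return "utr3"

    def region_genomic_intervals(self, region: str):
        """Genomic intervals (half-open, ascending) covered by a transcript region."""
        span = {"utr5": self.utr5_span, "cds": self.cds_span, "utr3": self.utr3_span}[region]
        t0, t1 = span
        out = []
        off = 0
        for s, e in self.exons:
            n = e - s
            lo = max(t0, off)
            hi = min(t1, off + n)
            if lo < hi:
                if self.strand == "+":
                    out.append((s + lo - off, s + hi - off))
                else:
                    out.append((e - (hi - off), e - (lo - off)))
            off += n
        return sorted(out)


@dataclass
class CountMatrix:
    """Integer gene x sample counts with the sample design and feature lengths.

    ``counts`` is a DataFrame (genes x samples, non-negative ints),
    ``design`` is indexed by sample id with columns ``layer`` (mRNA/Poly/RPF),
    ``condition`` (control/stress) and ``replicate``, and ``lengths`` holds
    the transcript length (nt) per gene.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive feature length")
        self.lengths = self.lengths.astype(np.int64)

    @property
    def gene_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[list(sample_ids)],
            design=self.design.loc[list(sample_ids)],
            lengths=self.lengths,
        )


@dataclass
class NormalizedMatrix:
    """RPKM or TPM values on the same axes as the source CountMatrix."""

    values: pd.DataFrame
    unit: str  # "RPKM" or "TPM"

    def __post_init__(self):
        if self.unit not in ("RPKM", "TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized values must be non-negative")


@dataclass
class RegionFractionSummary:
    """Where assigned footprints land: 5'UTR / CDS / 3'UTR / other."""

    utr5: float
    cds: float
    utr3: float
    other: float
    total: int
    length_filtered: int = 0
    ambiguous: int = 0

    @property
    def fractions(self):
        return {"utr5": self.utr5, "cds": self.cds, "utr3": self.utr3, "other": self.other}


@dataclass
class MetageneProfile:
    """Summed 5'-end counts at positions relative to the start or stop codon.

    Position 0 is the first nucleotide of the anchor codon; positions run
    from ``-window`` to ``+window`` inclusive.
    """

    anchor: str  # "start" or "stop"
    window: int
    counts: np.ndarray  # length 2*window + 1
    n_genes: int
    n_reads: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"anchor": self.anchor, "position": self.positions, "count": self.counts}
        )


@dataclass
class FrameDistribution:
    """Fractions of CDS-internal footprint 5' ends by reading frame."""

    f0: float
    f1: float
    f2: float
    n_reads: int

    def as_tuple(self):
        return (self.f0, self.f1, self.f2)


@dataclass
class Thresholds:
    """Significance gates for differential-expression and TE calls."""

    rpkm_min: float = 1.0
    abs_log2fc_min: float = 1.0
    padj_max: float = 0.05
    te_z_min: float = 1.5

    def __post_init__(self):
        for name in ("rpkm_min", "abs_log2fc_min", "padj_max", "te_z_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
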