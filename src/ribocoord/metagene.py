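"""Metagene profiles around start/stop codons, reading-frame periodicity,
and stall-peak detection.

Position 0 is the first nucleotide of the anchor codon (ATG for the start
anchor, the stop triplet for the stop anchor).  Profiles are raw 5'-end
counts summed over genes; an optional per-gene mean normalization is
available for cross-library comparison.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import FrameDistribution, MetageneProfile, TranscriptModel
from .quantify import DEFAULT_LENGTH_RANGE, assign_reads


def _anchor_tpos(m: TranscriptModel, anchor: str) -> int:
    if anchor == "start":
        return m.utr5_len
    if anchor == "stop":
        return m.utr5_len + m.cds_len - 3
    raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")


def metagene_profile(
    alignments: pd.DataFrame,
    models: Sequence[TranscriptModel],
    anchor: str = "start",
    window: int = 100,
    length_range: Optional[Tuple[int, int]] = DEFAULT_LENGTH_RANGE,
    per_gene_normalize: bool = False,
) -> MetageneProfile:
    """Sum footprint 5'-end counts at each position around the anchor codon.

    Each uniquely assigned read contributes at its transcript position
    minus the anchor position; positions outside [-window, +window] are
    ignored.  With ``per_gene_normalize`` each gene's contribution is
    divided by its mean per-position count before summation.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    assigned, _ = assign_reads(alignments, models, layer="RPF", length_range=length_range)
    anchors = {m.gene_id: _anchor_tpos(m, anchor) for m in models}
    rel = assigned["tpos"] - assigned["gene_id"].map(anchors)
    in_win = rel.abs() <= window
    rel_in = rel[in_win]
    genes_in = assigned["gene_id"][in_win]

    size = 2 * window + 1
    if per_gene_normalize:
        counts = np.zeros(size, dtype=float)
        for _, grp in rel_in.groupby(genes_in):
            gene_counts = np.bincount((grp + window).to_numpy(), minlength=size)[:size]
            mean = gene_counts.mean()
            if mean > 0:
                counts += gene_counts / mean
    else:
        counts = np.bincount((rel_in + window).to_numpy(), minlength=size)[:size]
    return MetageneProfile(
        anchor=anchor,
        window=window,
        counts=counts,
        n_genes=int(genes_in.nunique()),
        n_reads=int(in_win.sum()),
    )


def frame_distribution(
    alignments: pd.DataFrame,
    models: Sequence[TranscriptModel],
    length_range: Optional[Tuple[int, int]] = DEFAULT_LENGTH_RANGE,
) -> FrameDistribution:
    """Fractions of CDS-internal 5' ends in frames 0/1/2 relative to the start.

    Only 5' ends strictly inside the CDS and upstream of the stop codon
    qualify; frame = (transcript position - CDS start) mod 3.  With zero
    qualifying reads the fractions are NaN and n_reads is 0.
    """
    assigned, _ = assign_reads(alignments, models, layer="RPF", length_range=length_range)
    info = {m.gene_id: (m.utr5_len, m.utr5_len + m.cds_len - 3) for m in models}
    cds_start = assigned["gene_id"].map(lambda g: info[g][0])
    stop_start = assigned["gene_id"].map(lambda g: info[g][1])
    ok = (assigned["tpos"] >= cds_start) & (assigned["tpos"] < stop_start)
    n = int(ok.sum())
    if n == 0:
        return FrameDistribution(np.nan, np.nan, np.nan, 0)
    frames = ((assigned["tpos"] - cds_start)[ok] % 3).to_numpy()
    f = np.bincount(frames, minlength=3) / n
    return FrameDistribution(float(f[0]), float(f[1]), float(f[2]), n)


def detect_stall_peaks(
    profile: MetageneProfile,
    flank_exclusion: int = 3,
    min_enrichment: float = 2.0,
) -> list:
    """Upstream positions enriched over the upstream median count.

    A position p < 0 is a peak when its count is positive and at least
    ``min_enrichment`` times the median of the other upstream counts
    (excluding p and its ±``flank_exclusion`` neighbours).
    """
    positions = profile.positions
    counts = np.asarray(profile.counts, dtype=float)
    upstream = positions < 0
    peaks = []
    for p in positions[upstream]:
        here = counts[positions == p][0]
        if here <= 0:
            continue
        others = upstream & (np.abs(positions - p) > flank_exclusion)
        if not others.any():
            continue
        med = float(np.median(counts[others]))
        if here >= min_enrichment * med:
            peaks.append(int(p))
    return peaks
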