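"""Footprint-to-gene assignment, region fractions, and RPKM/TPM normalization.

Reads are assigned by the transcript-coordinate position of their 5' end
(leftmost aligned base on the + strand, rightmost on the -), which is the
same primitive the metagene profiles use.  A read counts for a gene iff
its 5' end falls in an exon of exactly one gene on the matching strand;
5' ends overlapping exons of more than one gene are discarded as
ambiguous.  Footprint (RPF) reads outside the 20-40 nt size-selection
window are dropped before assignment.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import (
    CountMatrix,
    NormalizedMatrix,
    RegionFractionSummary,
    TranscriptModel,
)

DEFAULT_LENGTH_RANGE = (20, 40)


class AnnotationError(ValueError):
    pass


def load_annotation(gff3_path: str):
    """Parse a GFF3 annotation into :class:`TranscriptModel` objects.

    Expects gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR features
    (1-based inclusive on disk; converted to 0-based half-open in memory).
    Genes violating the model invariants — CDS length not a multiple of 3,
    or UTR+CDS lengths not tiling the exons — are skipped with a warning.
    """
    try:
        db = gffutils.create_db(
            gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps parse errors
        raise AnnotationError(f"failed to parse {gff3_path}: {exc}") from exc

    models = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds_len = sum(f.end - f.start + 1 for f in db.children(gene, featuretype="CDS"))
        utr5_len = sum(
            f.end - f.start + 1 for f in db.children(gene, featuretype="five_prime_UTR")
        )
        utr3_len = sum(
            f.end - f.start + 1 for f in db.children(gene, featuretype="three_prime_UTR")
        )
        if cds_len == 0:
            warnings.warn(f"{gene_id}: no CDS feature; gene skipped")
            continue
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        if gene.strand == "-":
            exons = exons[::-1]
        try:
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    exons=tuple(exons),
                    utr5_len=utr5_len,
                    cds_len=cds_len,
                    utr3_len=utr3_len,
                )
            )
        except ValueError as exc:
            warnings.warn(f"{gene_id}: invalid model skipped ({exc})")
    return models


# ---------------------------------------------------------------------------
# read assignment


class _ExonIndex:
    """Point-query index: genomic position -> overlapping genes' exons."""

    def __init__(self, models: Sequence[TranscriptModel]):
        self.models = {m.gene_id: m for m in models}
        self.trees: Dict[tuple, IntervalTree] = {}
        for m in models:
            tree = self.trees.setdefault((m.chrom, m.strand), IntervalTree())
            for s, e in m.exons:
                tree[s:e] = m.gene_id

    def genes_at(self, chrom: str, strand: str, pos: int):
        tree = self.trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree[pos]})


def five_prime_end(start: int, end: int, strand: str) -> int:
    """Genomic coordinate of a read's 5' end (half-open interval)."""
    return start if strand == "+" else end - 1


def assign_reads(
    alignments: pd.DataFrame,
    models: Sequence[TranscriptModel],
    layer: str = "RPF",
    length_range: Optional[Tuple[int, int]] = DEFAULT_LENGTH_RANGE,
) -> Tuple[pd.DataFrame, dict]:
    """Assign each alignment to a gene by its 5'-end transcript position.

    Returns ``(assigned, stats)``: ``assigned`` has one row per uniquely
    assigned read with columns gene_id, tpos (transcript coordinate of the
    5' end) and region; ``stats`` tallies total / length_filtered /
    ambiguous / unassigned reads.  The size filter applies only when
    ``layer == "RPF"`` and ``length_range`` is not None.
    """
    if not models:
        raise ValueError("need at least one transcript model")
    index = _ExonIndex(models)
    known_chroms = {m.chrom for m in models}
    stats = {"total": len(alignments), "length_filtered": 0, "ambiguous": 0,
             "unassigned": 0}
    aln = alignments
    if layer == "RPF" and length_range is not None:
        lo, hi = length_range
        keep = (aln["length"] >= lo) & (aln["length"] <= hi)
        stats["length_filtered"] = int((~keep).sum())
        aln = aln[keep]

    genes, tposs, regions = [], [], []
    unknown_chrom_seen = False
    for chrom, start, end, strand in zip(
        aln["chrom"], aln["start"], aln["end"], aln["strand"]
    ):
        if chrom not in known_chroms and not unknown_chrom_seen:
            warnings.warn(f"alignments on unknown chromosome {chrom!r} counted as other")
            unknown_chrom_seen = True
        pos = five_prime_end(start, end, strand)
        hits = index.genes_at(chrom, strand, pos)
        if len(hits) == 0:
            stats["unassigned"] += 1
            continue
        if len(hits) > 1:
            stats["ambiguous"] += 1
            continue
        m = index.models[hits[0]]
        t = m.to_transcript(pos)
        assert t is not None
        genes.append(m.gene_id)
        tposs.append(t)
        regions.append(m.region_of(t))
    assigned = pd.DataFrame({"gene_id": genes, "tpos": tposs, "region": regions})
    return assigned, stats


def count_reads(
    alignments: pd.DataFrame,
    models: Sequence[TranscriptModel],
    layer: str = "RPF",
    length_range: Optional[Tuple[int, int]] = DEFAULT_LENGTH_RANGE,
) -> Tuple[pd.Series, Dict[str, int], dict]:
    """Gene-level counts plus per-region totals from one sample's alignments.

    Returns ``(gene_counts, region_counts, stats)``.  ``region_counts``
    covers utr5/cds/utr3 for assigned reads and "other" for reads whose 5'
    end matched no gene; ambiguous and length-filtered reads appear only
    in ``stats``.
    """
    assigned, stats = assign_reads(alignments, models, layer, length_range)
    gene_ids = [m.gene_id for m in models]
    gene_counts = (
        assigned["gene_id"].value_counts().reindex(gene_ids, fill_value=0).astype(np.int64)
    )
    gene_counts.index.name = "gene_id"
    region_counts = {
        r: int((assigned["region"] == r).sum()) for r in ("utr5", "cds", "utr3")
    }
    region_counts["other"] = stats["unassigned"]
    return gene_counts, region_counts, stats


def region_fractions(
    region_counts: Dict[str, int], stats: Optional[dict] = None
) -> RegionFractionSummary:
    """Fractions of (non-discarded) reads per feature region."""
    if any(v < 0 for v in region_counts.values()):
        raise ValueError("region counts must be non-negative")
    total = sum(region_counts.get(r, 0) for r in ("utr5", "cds", "utr3", "other"))
    stats = stats or {}
    if total == 0:
        return RegionFractionSummary(
            0.0, 0.0, 0.0, 0.0, total=0,
            length_filtered=stats.get("length_filtered", 0),
            ambiguous=stats.get("ambiguous", 0),
        )
    return RegionFractionSummary(
        utr5=region_counts.get("utr5", 0) / total,
        cds=region_counts.get("cds", 0) / total,
        utr3=region_counts.get("utr3", 0) / total,
        other=region_counts.get("other", 0) / total,
        total=total,
        length_filtered=stats.get("length_filtered", 0),
        ambiguous=stats.get("ambiguous", 0),
    )


# ---------------------------------------------------------------------------
# normalization


def _check_columns(cm: CountMatrix):
    colsums = cm.counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero total counts in sample(s): {list(zero.index)}")
    return colsums


def compute_rpkm(cm: CountMatrix) -> NormalizedMatrix:
    """Reads Per Kilobase of transcript per Million mapped reads.

    RPKM_gj = count_gj * 1e9 / (length_g * total_j), with total_j the
    assigned-read total of sample j.
    """
    colsums = _check_columns(cm)
    values = cm.counts * 1e9
    values = values.div(cm.lengths, axis=0).div(colsums, axis=1)
    return NormalizedMatrix(values=values, unit="RPKM")


def compute_tpm(cm: CountMatrix) -> NormalizedMatrix:
    """Transcripts Per Million: length-normalized rates rescaled so every
    sample column sums to 1e6."""
    _check_columns(cm)
    rate = cm.counts.div(cm.lengths, axis=0)
    values = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return NormalizedMatrix(values=values, unit="TPM")


def filter_expressed(
    rpkm: NormalizedMatrix, threshold: float = 1.0, min_samples: int = 1
) -> pd.Index:
    """Genes with RPKM >= threshold in at least ``min_samples`` samples."""
    if rpkm.unit != "RPKM":
        raise ValueError(f"expression filter expects RPKM values, got {rpkm.unit}")
    ok = (rpkm.values >= threshold).sum(axis=1) >= min_samples
    return rpkm.values.index[ok]
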