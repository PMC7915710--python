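"""Readers and writers for the plain-text formats the pipeline exchanges.

GFF3 is written 1-based inclusive; BED6 is 0-based half-open with the read
length carried in the score column.  All writers are deterministic: the
same in-memory objects always produce the same bytes.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import CountMatrix, TranscriptModel

BED_COLUMNS = ["chrom", "start", "end", "name", "length", "strand"]

_FEATURE_TYPES = {
    "utr5": "five_prime_UTR",
    "cds": "CDS",
    "utr3": "three_prime_UTR",
}


def write_gff3(models: Iterable[TranscriptModel], path: str) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    lines = ["##gff-version 3"]
    for m in models:
        g0, g1 = m.genomic_span
        base = (m.chrom, "ribocoord", g0 + 1, g1, m.strand)

        def row(ftype, s, e, attrs):
            return f"{base[0]}\t{base[1]}\t{ftype}\t{s}\t{e}\t.\t{base[4]}\t.\t{attrs}"

        lines.append(row("gene", g0 + 1, g1, f"ID={m.gene_id}"))
        mrna_id = f"{m.gene_id}.1"
        lines.append(row("mRNA", g0 + 1, g1, f"ID={mrna_id};Parent={m.gene_id}"))
        for i, (s, e) in enumerate(sorted(m.exons), 1):
            lines.append(row("exon", s + 1, e, f"ID={mrna_id}.exon{i};Parent={mrna_id}"))
        for region in ("utr5", "cds", "utr3"):
            for i, (s, e) in enumerate(m.region_genomic_intervals(region), 1):
                ftype = _FEATURE_TYPES[region]
                lines.append(row(ftype, s + 1, e, f"ID={mrna_id}.{region}{i};Parent={mrna_id}"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_bed(alignments: pd.DataFrame, path: str) -> None:
    """Write footprint alignments as BED6 (score column = read length)."""
    alignments[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    """Read BED6 footprint alignments (score column = read length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["length"] = df["length"].astype(np.int64)
    return df


def write_counts(cm: CountMatrix, path: str) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id").astype(np.int64)


def write_design(design: pd.DataFrame, path: str) -> None:
    out = design.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_design(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_lengths(lengths: pd.Series, path: str) -> None:
    out = lengths.rename("length").to_frame()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_lengths(path: str) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="gene_id")["length"].astype(np.int64)


def write_table(df: pd.DataFrame, path: str, index: bool = True) -> None:
    """Deterministic TSV writer used for all result tables."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_table(path: str, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
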