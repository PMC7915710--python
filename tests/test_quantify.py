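"""Read assignment, region fractions, and RPKM/TPM normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribocoord import io as rcio
from ribocoord.models import CountMatrix
from ribocoord.quantify import (
    compute_rpkm,
    compute_tpm,
    count_reads,
    filter_expressed,
    load_annotation,
    region_fractions,
)
from ribocoord.simdata import SimulationConfig, generate_annotation, generate_rpf_alignments

from conftest import make_alignment


# ---------------------------------------------------------------------------
# annotation loading


def test_gff3_coordinates_convert_to_half_open(tmp_path, plus_gene):
    path = tmp_path / "one.gff3"
    rcio.write_gff3([plus_gene], path)
    text = path.read_text()
    assert "\t101\t130\t" in text  # first exon 1-based inclusive on disk
    (model,) = load_annotation(str(path))
    assert model.exons[0] == (100, 130)
    assert model == plus_gene


def test_gene_with_bad_cds_skipped_with_warning(tmp_path):
    lines = [
        "##gff-version 3",
        "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=bad",
        "chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=bad.1;Parent=bad",
        "chr1\t.\texon\t101\t200\t.\t+\t.\tID=bad.1.e1;Parent=bad.1",
        "chr1\t.\tCDS\t101\t200\t.\t+\t.\tID=bad.1.c1;Parent=bad.1",  # 100 nt CDS
    ]
    path = tmp_path / "bad.gff3"
    path.write_text("\n".join(lines) + "\n")
    with pytest.warns(UserWarning, match="bad"):
        models = load_annotation(str(path))
    assert models == []


def test_gene_without_cds_skipped(tmp_path):
    lines = [
        "##gff-version 3",
        "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=nocds",
        "chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=nocds.1;Parent=nocds",
        "chr1\t.\texon\t101\t200\t.\t+\t.\tID=nocds.1.e1;Parent=nocds.1",
    ]
    path = tmp_path / "nocds.gff3"
    path.write_text("\n".join(lines) + "\n")
    with pytest.warns(UserWarning, match="no CDS"):
        assert load_annotation(str(path)) == []


# ---------------------------------------------------------------------------
# read assignment


def test_single_read_in_cds_counted(plus_gene):
    aln = make_alignment("chr1", 115, "+")  # tpos 15, inside CDS
    counts, regions, stats = count_reads(aln, [plus_gene])
    assert counts["gplus"] == 1
    assert regions == {"utr5": 0, "cds": 1, "utr3": 0, "other": 0}


def test_minus_strand_read_uses_rightmost_base(minus_gene):
    # 5' end at genomic 529 = transcript position 0 (5'UTR)
    aln = make_alignment("chr1", 529, "-")
    counts, regions, _ = count_reads(aln, [minus_gene])
    assert counts["gminus"] == 1
    assert regions["utr5"] == 1


def test_length_filter_applies_only_to_rpf(plus_gene):
    aln = make_alignment("chr1", 115, "+", length=19)
    counts, _, stats = count_reads(aln, [plus_gene], layer="RPF")
    assert counts.sum() == 0 and stats["length_filtered"] == 1
    counts, _, stats = count_reads(aln, [plus_gene], layer="mRNA")
    assert counts["gplus"] == 1 and stats["length_filtered"] == 0


def test_ambiguous_read_discarded(plus_gene):
    twin = plus_gene.__class__(
        gene_id="gtwin", chrom="chr1", strand="+",
        exons=((110, 158),), utr5_len=10, cds_len=30, utr3_len=8,
    )
    aln = make_alignment("chr1", 115, "+")
    counts, regions, stats = count_reads(aln, [plus_gene, twin])
    assert counts.sum() == 0
    assert stats["ambiguous"] == 1


def test_wrong_strand_read_unassigned(plus_gene):
    aln = make_alignment("chr1", 115, "-")
    counts, regions, stats = count_reads(aln, [plus_gene])
    assert counts.sum() == 0 and regions["other"] == 1


def test_unknown_chromosome_counted_as_other(plus_gene):
    aln = make_alignment("chrX", 115, "+")
    with pytest.warns(UserWarning, match="unknown chromosome"):
        _, regions, _ = count_reads(aln, [plus_gene])
    assert regions["other"] == 1


def test_read_conservation_invariant(small_dataset):
    counts, regions, stats = count_reads(small_dataset.alignments, small_dataset.models)
    assigned = int(counts.sum())
    assert (
        assigned + regions["other"] + stats["ambiguous"] + stats["length_filtered"]
        == stats["total"]
    )


def test_strand_symmetry_of_assignment(small_dataset):
    """Mirroring all coordinates and strands leaves gene counts unchanged."""
    models = small_dataset.models
    aln = small_dataset.alignments
    M = max(m.genomic_span[1] for m in models) + 1000
    flip = {"+": "-", "-": "+"}
    mirrored_models = [
        m.__class__(
            gene_id=m.gene_id, chrom=m.chrom, strand=flip[m.strand],
            exons=tuple((M - e, M - s) for s, e in m.exons),
            utr5_len=m.utr5_len, cds_len=m.cds_len, utr3_len=m.utr3_len,
        )
        for m in models
    ]
    mirrored_aln = aln.assign(
        start=M - aln["end"], end=M - aln["start"],
        strand=aln["strand"].map(flip),
    )
    c1, r1, _ = count_reads(aln, models)
    c2, r2, _ = count_reads(mirrored_aln, mirrored_models)
    assert (c1 == c2).all()
    assert r1 == r2


# ---------------------------------------------------------------------------
# region fractions


def test_region_fraction_arithmetic():
    frac = region_fractions({"utr5": 5, "cds": 90, "utr3": 5, "other": 0})
    assert (frac.utr5, frac.cds, frac.utr3, frac.other) == (0.05, 0.90, 0.05, 0.0)
    assert abs(sum(frac.fractions.values()) - 1.0) < 1e-12
    all_cds = region_fractions({"utr5": 0, "cds": 50, "utr3": 0, "other": 0})
    assert all_cds.cds == 1.0
    empty = region_fractions({"utr5": 0, "cds": 0, "utr3": 0, "other": 0})
    assert empty.total == 0 and empty.cds == 0.0


def test_region_probability_recovery():
    cfg = SimulationConfig(
        n_genes=150, seed=17,
        region_probs=(0.05, 0.75, 0.05, 0.15),
        stall_offsets=(), stall_weights=(),
    )
    models = generate_annotation(cfg)
    aln = generate_rpf_alignments(models, 100_000, cfg)
    _, regions, stats = count_reads(aln, models)
    frac = region_fractions(regions, stats)
    for got, want in zip(
        (frac.utr5, frac.cds, frac.utr3, frac.other), cfg.region_probs
    ):
        assert abs(got - want) <= 0.02


# ---------------------------------------------------------------------------
# normalization


def brute_force_rpkm(cm):
    out = {}
    for j in cm.counts.columns:
        total = cm.counts[j].sum()
        out[j] = {
            g: cm.counts.at[g, j] * 1e9 / (cm.lengths[g] * total)
            for g in cm.counts.index
        }
    return pd.DataFrame(out)


def brute_force_tpm(cm):
    out = {}
    for j in cm.counts.columns:
        rates = {g: cm.counts.at[g, j] / cm.lengths[g] for g in cm.counts.index}
        denom = sum(rates.values())
        out[j] = {g: r * 1e6 / denom for g, r in rates.items()}
    return pd.DataFrame(out)


def test_rpkm_matches_brute_force_oracle(toy_counts):
    got = compute_rpkm(toy_counts).values
    pd.testing.assert_frame_equal(got, brute_force_rpkm(toy_counts), rtol=1e-12)


def test_tpm_matches_brute_force_oracle(toy_counts):
    got = compute_tpm(toy_counts).values
    pd.testing.assert_frame_equal(got, brute_force_tpm(toy_counts), atol=1e-9, rtol=0)


def test_rpkm_worked_example():
    cm = CountMatrix(
        counts=pd.DataFrame({"s": [100, 999_900]}, index=["a", "filler"]),
        design=pd.DataFrame(
            {"layer": ["mRNA"], "condition": ["control"], "replicate": [1]},
            index=pd.Index(["s"], name="sample_id"),
        ),
        lengths=pd.Series([2000, 1000], index=["a", "filler"]),
    )
    rpkm = compute_rpkm(cm)
    assert rpkm.values.at["a", "s"] == pytest.approx(50.0)


def test_tpm_symmetry_three_equal_genes():
    cm = CountMatrix(
        counts=pd.DataFrame({"s": [7, 7, 7]}, index=list("abc")),
        design=pd.DataFrame(
            {"layer": ["mRNA"], "condition": ["control"], "replicate": [1]},
            index=pd.Index(["s"], name="sample_id"),
        ),
        lengths=pd.Series([500, 500, 500], index=list("abc")),
    )
    tpm = compute_tpm(cm)
    np.testing.assert_allclose(tpm.values["s"], 1e6 / 3)


def test_zero_column_sum_raises(toy_counts):
    counts = toy_counts.counts.copy()
    counts["s1"] = 0
    cm = CountMatrix(counts=counts, design=toy_counts.design, lengths=toy_counts.lengths)
    with pytest.raises(ValueError, match="s1"):
        compute_rpkm(cm)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_tpm_columns_sum_to_a_million_and_match_rpkm(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 12)
    genes = [f"g{i}" for i in range(n)]
    counts = pd.DataFrame(
        rng.integers(0, 1000, size=(n, 3)) + np.eye(n, 3, dtype=int),
        index=genes, columns=["s1", "s2", "s3"],
    )
    design = pd.DataFrame(
        {"layer": ["mRNA"] * 3, "condition": ["control", "control", "stress"],
         "replicate": [1, 2, 1]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    cm = CountMatrix(
        counts=counts, design=design,
        lengths=pd.Series(rng.integers(200, 5000, size=n), index=genes),
    )
    tpm = compute_tpm(cm).values
    np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)
    # RPKM -> TPM consistency identity
    rpkm = compute_rpkm(cm).values
    np.testing.assert_allclose(tpm, rpkm * 1e6 / rpkm.sum(axis=0), rtol=1e-9)


def test_filter_expressed_boundaries(toy_counts):
    rpkm = compute_rpkm(toy_counts)
    values = pd.DataFrame(
        {"s1": [0.2, 0.99, 0.0], "s2": [0.4, 0.99, 0.0], "s3": [1.0, 0.99, 0.0]},
        index=list("abc"),
    )
    nm = rpkm.__class__(values=values, unit="RPKM")
    kept = filter_expressed(nm)
    assert list(kept) == ["a"]  # 1.0 passes the >= boundary, 0.99 does not
    assert list(filter_expressed(nm, threshold=0)) == ["a", "b", "c"]
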