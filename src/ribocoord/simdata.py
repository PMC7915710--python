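"""Synthetic tri-layer expression data with known ground truth.

The generator emulates the statistical structure of a paired total-mRNA /
polysomal-mRNA / ribosome-footprint (RPF) stress experiment:

* negative-binomial counts for 3 layers x 2 conditions x ``n_reps``
  replicates, with per-sample library-size variation;
* mRNA-level effects on a fraction of genes, propagated to the RPF and
  polysomal layers through a coupling coefficient plus independent noise
  (so the correlation between mRNA and RPF fold changes is tunable);
* a separate gene subset regulated only at the ribosome-loading level
  (translational-efficiency-only genes);
* footprint alignments with tunable reading-frame periodicity, region
  placement (5'UTR/CDS/3'UTR/intergenic) and stall peaks at fixed offsets
  from the start/stop codons.

Everything is a pure function of the configuration (including its seed):
the same config always produces byte-identical outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as rcio
from .coordination import classify_direction_pair
from .models import CONDITIONS, LAYERS, CountMatrix, TranscriptModel

CHROM = "chrS"
REGIONS = ("utr5", "cds", "utr3", "intergenic")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Length fields are inclusive ``(lo, hi)`` ranges in nucleotides; the CDS
    draw is constrained to multiples of 3 of at least 60 nt.  Effect sizes
    are on the log2 scale.  ``rpf_coupling`` (gamma) multiplies the true
    mRNA log2 fold change to give the coupled part of the RPF fold change;
    ``rpf_noise_sd`` adds an independent normal effect on top, so the
    population correlation between the two layers' true fold changes is
    tunable.  ``region_probs`` defaults mirror the footprint region split
    typical of plant ribosome-profiling control libraries (about 2/3 of
    footprints in the CDS, a few percent in each UTR).
    """

    n_genes: int = 2000
    utr5_len: tuple = (20, 300)
    cds_len: tuple = (300, 1800)
    utr3_len: tuple = (50, 400)
    n_exons: tuple = (1, 3)
    intergenic_gap: tuple = (200, 800)
    n_reps: int = 3
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.0
    de_fraction: float = 0.2
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    rpf_coupling: float = 0.8
    rpf_noise_sd: float = 0.5
    poly_coupling: float = 0.9
    poly_noise_sd: float = 0.3
    te_only_fraction: float = 0.05
    dispersion: float = 0.05
    frame_probs: tuple = (0.7, 0.2, 0.1)
    region_probs: tuple = (0.035, 0.674, 0.030, 0.261)
    stall_offsets: tuple = (("start", -12), ("stop", -15))
    stall_weights: tuple = (0.04, 0.02)
    n_rpf_reads: int = 100_000
    library_scale_range: tuple = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2 (DE requires replication)")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        for name in ("frame_probs", "region_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be probabilities summing to 1")
        if len(self.frame_probs) != 3 or len(self.region_probs) != 4:
            raise ConfigurationError("frame_probs needs 3 entries, region_probs 4")
        if not 0 <= self.de_fraction + self.te_only_fraction <= 1:
            raise ConfigurationError("de_fraction + te_only_fraction must be in [0, 1]")
        w = np.asarray(self.stall_weights, dtype=float)
        if len(w) != len(self.stall_offsets) or (w < 0).any() or w.sum() > 1:
            raise ConfigurationError("stall_weights must match stall_offsets and sum to <= 1")
        lo, hi = self.cds_len
        if self._cds_codon_range() is None:
            raise ConfigurationError(
                f"cds_len range ({lo}, {hi}) admits no multiple of 3 that is >= 60 nt"
            )

    def _cds_codon_range(self):
        """Range of codon counts compatible with the CDS length range, or None."""
        lo, hi = self.cds_len
        lo_c = max(20, math.ceil(lo / 3))  # >= 60 nt
        hi_c = hi // 3
        if lo_c > hi_c:
            return None
        return lo_c, hi_c

    def normalized_stall_offsets(self):
        """Stall peaks as (anchor, offset) pairs; bare ints are start-anchored."""
        out = []
        for item in self.stall_offsets:
            if isinstance(item, (int, np.integer)):
                out.append(("start", int(item)))
            else:
                anchor, off = item
                if anchor not in ("start", "stop"):
                    raise ConfigurationError(f"stall anchor must be start/stop, got {anchor!r}")
                out.append((anchor, int(off)))
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stall_offsets"] = [list(x) if not isinstance(x, int) else x
                              for x in self.normalized_stall_offsets()]
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("utr5_len", "cds_len", "utr3_len", "n_exons", "intergenic_gap",
                    "frame_probs", "region_probs", "stall_weights", "library_scale_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "stall_offsets" in d:
            d["stall_offsets"] = tuple(
                tuple(x) if isinstance(x, (list, tuple)) else int(x)
                for x in d["stall_offsets"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([int(config.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimulationConfig) -> list:
    """Place ``n_genes`` non-overlapping gene models on one synthetic chromosome.

    Strands alternate; each gene gets 5'UTR/CDS/3'UTR lengths drawn from the
    configured ranges (CDS a multiple of 3, >= 60 nt) and 1-3 exons with
    introns of 60-200 nt.  Deterministic in the config seed.
    """
    rng = _rng(config, 0)
    lo_c, hi_c = config._cds_codon_range()
    models = []
    cursor = 1000
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:05d}"
        strand = "+" if i % 2 == 0 else "-"
        utr5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        cds = 3 * int(rng.integers(lo_c, hi_c + 1))
        utr3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        L = utr5 + cds + utr3
        k = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
        k = min(k, max(1, L // 30))
        # split transcript into k exon segments of >= 30 nt each
        extra = L - 30 * k
        w = rng.random(k)
        lens = (30 + np.floor(w / w.sum() * extra)).astype(int)
        lens[0] += L - lens.sum()
        introns = rng.integers(60, 201, size=max(k - 1, 0))
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        start = cursor + gap
        genomic_lens = lens if strand == "+" else lens[::-1]
        exons_genomic = []
        p = start
        for j, n in enumerate(genomic_lens):
            exons_genomic.append((p, p + int(n)))
            p += int(n)
            if j < k - 1:
                p += int(introns[j])
        cursor = exons_genomic[-1][1]
        exons = tuple(exons_genomic) if strand == "+" else tuple(exons_genomic[::-1])
        models.append(
            TranscriptModel(
                gene_id=gene_id, chrom=CHROM, strand=strand, exons=exons,
                utr5_len=utr5, cds_len=cds, utr3_len=utr3,
            )
        )
    return models


# ---------------------------------------------------------------------------
# footprint alignments


def generate_rpf_alignments(
    models: Sequence[TranscriptModel], n_reads: int, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate ribosome-footprint alignments as a BED6-style DataFrame.

    Each read draws a length from 20-40 nt and a placement category: one of
    the configured stall peaks (5' end exactly at the anchor offset) or a
    transcript region by ``region_probs``.  CDS placements draw a codon
    uniformly and a frame offset from ``frame_probs``, so the 5'-end frame
    distribution inside the CDS matches the configuration.  Intergenic
    reads fall uniformly outside gene loci.  The genomic interval is the
    read's exon-projected span; the score column carries the footprint
    length.
    """
    if not models:
        raise ValueError("need at least one transcript model")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = _rng(config, 1)
    stalls = config.normalized_stall_offsets()
    w = np.asarray(config.stall_weights, dtype=float)
    region_p = np.asarray(config.region_probs, dtype=float) * (1.0 - w.sum())
    probs = np.concatenate([w, region_p])
    n_stall = len(stalls)
    cats = rng.choice(len(probs), size=n_reads, p=probs / probs.sum())
    lengths = rng.integers(20, 41, size=n_reads)

    # eligible genes per stall peak (5' end must land inside the transcript)
    def anchor_tpos(m: TranscriptModel, anchor: str) -> int:
        return m.utr5_len if anchor == "start" else m.utr5_len + m.cds_len - 3

    stall_eligible = []
    for anchor, off in stalls:
        idx = [i for i, m in enumerate(models)
               if 0 <= anchor_tpos(m, anchor) + off < m.transcript_length]
        if not idx:
            raise ConfigurationError(f"no gene can host stall peak ({anchor}, {off})")
        stall_eligible.append(np.asarray(idx))

    span_lo = min(m.genomic_span[0] for m in models)
    span_hi = max(m.genomic_span[1] for m in models)
    gene_blocks = sorted(m.genomic_span for m in models)
    intergenic = []
    prev = max(span_lo - 500, 0)
    for s, e in gene_blocks:
        if s > prev:
            intergenic.append((prev, s))
        prev = max(prev, e)
    intergenic.append((prev, span_hi + 500))
    ig_lens = np.array([e - s for s, e in intergenic], dtype=float)

    recs = {k: [] for k in ("chrom", "start", "end", "name", "length", "strand")}

    def emit(i, chrom, start, end, strand):
        recs["chrom"].append(chrom)
        recs["start"].append(int(start))
        recs["end"].append(int(end))
        recs["name"].append(f"read{i + 1:07d}")
        recs["length"].append(int(lengths[i]))
        recs["strand"].append(strand)

    n_models = len(models)
    for i in range(n_reads):
        c = int(cats[i])
        if c < n_stall:
            anchor, off = stalls[c]
            m = models[int(rng.choice(stall_eligible[c]))]
            t = anchor_tpos(m, anchor) + off
        else:
            region = REGIONS[c - n_stall]
            if region == "intergenic":
                blk = int(rng.choice(len(intergenic), p=ig_lens / ig_lens.sum()))
                s, e = intergenic[blk]
                g = int(rng.integers(s, e))
                strand = "+" if rng.random() < 0.5 else "-"
                emit(i, CHROM, g, min(g + int(lengths[i]), e), strand)
                continue
            m = models[int(rng.integers(0, n_models))]
            if region == "utr5":
                t = int(rng.integers(0, m.utr5_len)) if m.utr5_len > 0 else m.utr5_len
            elif region == "cds":
                codon = int(rng.integers(0, m.cds_len // 3))
                f = int(rng.choice(3, p=np.asarray(config.frame_probs, dtype=float)))
                t = m.utr5_len + 3 * codon + f
            else:  # utr3
                t = int(rng.integers(m.utr5_len + m.cds_len, m.transcript_length))
        g5 = m.to_genomic(t)
        t3 = min(t + int(lengths[i]) - 1, m.transcript_length - 1)
        g3 = m.to_genomic(t3)
        emit(i, m.chrom, min(g5, g3), max(g5, g3) + 1, m.strand)

    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# counts + ground truth


def generate_count_matrices(
    config: SimulationConfig, models: Optional[Sequence[TranscriptModel]] = None
):
    """Draw NB counts for the three layers and return them with the truth table.

    Counts follow NB(mean = library_scale * baseline * 2^(effect if stress),
    variance = mu + alpha*mu^2).  The true RPF log2FC is
    ``gamma * mRNA_log2FC + Normal(0, rpf_noise_sd)`` except for the
    TE-only subset, whose mRNA effect is zero and whose RPF (and polysomal)
    effect is drawn fresh from the effect distribution.

    Returns ``(counts, truth)`` where ``counts`` maps layer name to a
    :class:`CountMatrix` and ``truth`` is a per-gene DataFrame of true
    effects and labels.
    """
    if models is None:
        models = generate_annotation(config)
    rng = _rng(config, 2)
    n = len(models)
    gene_ids = pd.Index([m.gene_id for m in models], name="gene_id")
    lengths = pd.Series([m.transcript_length for m in models], index=gene_ids)

    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
    perm = rng.permutation(n)
    n_de = int(round(config.de_fraction * n))
    n_te = int(round(config.te_only_fraction * n))
    de_idx = perm[:n_de]
    te_idx = perm[n_de:n_de + n_te]

    def effect_draw(size):
        mag = np.abs(rng.normal(config.effect_mean, config.effect_sd, size))
        sign = rng.choice([-1.0, 1.0], size=size)
        return mag * sign

    fc_mrna = np.zeros(n)
    fc_mrna[de_idx] = effect_draw(n_de)
    eps_rpf = rng.normal(0.0, config.rpf_noise_sd, n)
    eps_poly = rng.normal(0.0, config.poly_noise_sd, n)
    fc_rpf = config.rpf_coupling * fc_mrna + eps_rpf
    fc_poly = config.poly_coupling * fc_mrna + eps_poly
    te_effect = effect_draw(n_te)
    fc_mrna[te_idx] = 0.0
    fc_rpf[te_idx] = te_effect
    fc_poly[te_idx] = te_effect
    if n_de + n_te < n:
        # unaffected genes carry no effect at any layer
        null_idx = perm[n_de + n_te:]
        fc_mrna[null_idx] = 0.0
        fc_rpf[null_idx] = 0.0
        fc_poly[null_idx] = 0.0

    effects = {"mRNA": fc_mrna, "Poly": fc_poly, "RPF": fc_rpf}
    lo, hi = config.library_scale_range
    counts = {}
    design_rows = {layer: [] for layer in LAYERS}
    for layer in LAYERS:
        cols = {}
        for cond in CONDITIONS:
            for rep in range(1, config.n_reps + 1):
                sid = f"{layer}_{cond}_{rep}"
                scale = math.exp(rng.uniform(math.log(lo), math.log(hi)))
                mu = scale * baseline * np.where(cond == "stress", 2.0 ** effects[layer], 1.0)
                if config.dispersion < 1e-8:
                    col = rng.poisson(mu)
                else:
                    r = 1.0 / config.dispersion
                    col = rng.negative_binomial(r, r / (r + mu))
                cols[sid] = col
                design_rows[layer].append(
                    {"sample_id": sid, "layer": layer, "condition": cond, "replicate": rep}
                )
        counts[layer] = CountMatrix(
            counts=pd.DataFrame(cols, index=gene_ids),
            design=pd.DataFrame(design_rows[layer]).set_index("sample_id"),
            lengths=lengths,
        )

    def truth_direction(effect):
        return np.where(effect >= 1.0, "up", np.where(effect <= -1.0, "down", "ns"))

    m_dir = truth_direction(fc_mrna)
    r_dir = truth_direction(fc_rpf)
    reg_type = [classify_direction_pair(a, b) for a, b in zip(m_dir, r_dir)]
    de_mask = np.zeros(n, dtype=bool)
    de_mask[de_idx] = True
    te_mask = np.zeros(n, dtype=bool)
    te_mask[te_idx] = True
    truth = pd.DataFrame(
        {
            "log2fc_mrna": fc_mrna,
            "log2fc_poly": fc_poly,
            "log2fc_rpf": fc_rpf,
            "log2fc_te": fc_rpf - fc_mrna,
            "de_mrna": de_mask,
            "te_only": te_mask,
            "regulation_type": [0 if t is None else t for t in reg_type],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return counts, truth


def true_effect_variance(config: SimulationConfig) -> float:
    """Population variance of the true mRNA log2 fold changes.

    Effects are symmetric-sign draws of magnitude |N(effect_mean,
    effect_sd)| on a ``de_fraction`` subset, hence mean 0 and variance
    ``de_fraction * (effect_mean^2 + effect_sd^2)`` (the half-normal fold
    of the magnitude does not change the second moment).
    """
    return config.de_fraction * (config.effect_mean**2 + config.effect_sd**2)


def rpf_noise_sd_for_correlation(config: SimulationConfig, target_r: float) -> float:
    """Noise sd giving a target population correlation between mRNA and RPF effects.

    With RPF effect = gamma*m + eps, corr(m, RPF) = gamma*sd(m) /
    sqrt(gamma^2 var(m) + sigma^2); solving for sigma gives
    ``gamma * sd(m) * sqrt(1/r^2 - 1)``.  Assumes no TE-only subset.
    """
    if not 0 < target_r <= 1:
        raise ValueError("target_r must be in (0, 1]")
    var_m = true_effect_variance(config)
    if var_m <= 0:
        raise ValueError("no mRNA effects: set de_fraction > 0")
    return config.rpf_coupling * math.sqrt(var_m) * math.sqrt(1.0 / target_r**2 - 1.0)


def config_for_truth_correlation(
    target_r: float, seed: int, n_genes: int = 5000, **overrides
) -> SimulationConfig:
    """A coupling experiment: every gene carries an mRNA effect and the RPF
    noise sd is solved so the population corr(mRNA_FC, RPF_FC) equals
    ``target_r``."""
    base = SimulationConfig(
        n_genes=n_genes, de_fraction=1.0, te_only_fraction=0.0,
        baseline_log_mean=5.5, dispersion=0.02, seed=seed, **overrides
    )
    sigma = rpf_noise_sd_for_correlation(base, target_r)
    return replace(base, rpf_noise_sd=sigma)


# ---------------------------------------------------------------------------
# dataset bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    models: list
    alignments: pd.DataFrame
    counts: dict
    truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all three generators under one config."""
    models = generate_annotation(config)
    alignments = generate_rpf_alignments(models, config.n_rpf_reads, config)
    counts, truth = generate_count_matrices(config, models)
    return SimulatedDataset(config, models, alignments, counts, truth)


def write_dataset(dataset: SimulatedDataset, directory: str) -> None:
    """Write the full dataset as plain-text files (GFF3/BED/TSV/YAML)."""
    rcio.ensure_dir(directory)
    j = lambda name: os.path.join(directory, name)
    rcio.write_gff3(dataset.models, j("annotation.gff3"))
    rcio.write_bed(dataset.alignments, j("rpf_alignments.bed"))
    designs = []
    for layer, cm in dataset.counts.items():
        rcio.write_counts(cm, j(f"counts_{layer}.tsv"))
        designs.append(cm.design)
    rcio.write_design(pd.concat(designs), j("design.tsv"))
    rcio.write_lengths(dataset.counts["mRNA"].lengths, j("lengths.tsv"))
    truth = dataset.truth.copy()
    rcio.write_table(truth, j("truth.tsv"))
    dataset.config.to_yaml(j("config.yaml"))


def read_dataset(directory: str) -> SimulatedDataset:
    """Inverse of :func:`write_dataset` (models re-parsed from the GFF3)."""
    from .quantify import load_annotation

    j = lambda name: os.path.join(directory, name)
    config = SimulationConfig.from_yaml(j("config.yaml"))
    models = load_annotation(j("annotation.gff3"))
    alignments = rcio.read_bed(j("rpf_alignments.bed"))
    design = rcio.read_design(j("design.tsv"))
    lengths = rcio.read_lengths(j("lengths.tsv"))
    counts = {}
    for layer in LAYERS:
        tab = rcio.read_counts(j(f"counts_{layer}.tsv"))
        counts[layer] = CountMatrix(
            counts=tab, design=design.loc[tab.columns], lengths=lengths
        )
    truth = rcio.read_table(j("truth.tsv"))
    truth["de_mrna"] = truth["de_mrna"].astype(bool)
    truth["te_only"] = truth["te_only"].astype(bool)
    return SimulatedDataset(config, models, alignments, counts, truth)
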