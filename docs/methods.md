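# Methods

This note documents the models, conventions, and numerical choices behind
`ribocoord`, and what the synthetic-data tests do and do not demonstrate
about real sequencing data.

## Coordinate conventions and read assignment

In-memory intervals are 0-based half-open; GFF3 on disk is 1-based
inclusive and BED is 0-based half-open, converted at the I/O boundary.
Transcript coordinates run 5′→3′ in gene orientation, so position 0 is the
first transcribed nucleotide on either strand.

A read is represented by its 5′ end (leftmost aligned base on the +
strand, rightmost on the −). It is assigned to a gene iff that single
position falls inside an exon of exactly one gene on the matching strand;
5′ ends overlapping exons of two or more genes are discarded as ambiguous,
mirroring a uniquely-mapped-reads policy at the assignment level. Point
assignment (rather than whole-read overlap, as featureCounts would do) was
chosen because it is unambiguous for footprints spanning region
boundaries and is the same primitive the metagene profiles use; counts on
real data will differ slightly from a featureCounts-based workflow.
Footprints (the RPF layer only) outside the 20–40 nt size-selection window
are dropped before assignment; the mRNA and polysomal layers accept any
length. No P-site offset is applied anywhere: all downstream statistics
are defined on raw 5′ ends.

Region fractions are computed over all non-discarded reads: assigned
reads contribute to 5′UTR/CDS/3′UTR by the region containing their 5′-end
transcript position, and reads matching no gene (intergenic, antisense,
unknown chromosome) form the "other" class.

## Normalization and the expression gate

RPKM_gj = count_gj · 10⁹ / (length_g · total_j) and
TPM_gj = (count_gj/length_g) · 10⁶ / Σ_g (count_gj/length_g), where
total_j is the assigned-read total of sample j (the pipeline starts from
assigned counts, so no separate mapped-library size exists). Every
downstream significance call is gated on RPKM ≥ 1 in at least one sample
of the layer(s) involved; for TE and correlations the gate is the union
of the mRNA and RPF gates.

## Differential expression

The NB model uses variance μ + αμ². Per layer:

1. **Size factors** — median-of-ratios: sf_j = median over reference
   genes of count_gj / geometric-mean_g; the reference excludes genes
   with any zero count (a pseudo-reference flag relaxes this to genes
   with a positive geometric mean over their nonzero samples).
2. **Dispersion** — method of moments on size-factor-normalized counts,
   (s² − μ̄)/μ̄² averaged across the two conditions, floored at 10⁻⁸, then
   shrunk by a half-weight geometric mean with the across-gene median.
   On simulated data with α = 0.1 (2,000 genes, 10 replicates) the median
   estimate lands within [0.07, 0.13].
3. **Wald test** — log₂FC = log₂((μ̂_s + c)/(μ̂_c + c)) with pseudocount
   c = 0.5 on the condition means (prevents infinite fold changes at zero
   counts); the delta-method standard error treats each normalized count
   as NB(μ̂, α), Var(μ̂) = (μ̂ + αμ̂²)/n per condition. This form is exactly
   invariant to rescaling any sample's counts together with its size
   factor.
4. **Reference distribution** — the Wald statistic is referred to a t
   distribution with df = 2·(n₁ + n₂ − 2) rather than the normal. The
   dispersion entering the standard error is itself estimated, which
   makes normal tails anti-conservative at typical replicate numbers
   (empirically, type-I error ≈ 0.10 at nominal 0.05 for 3 vs 3). The df
   follows moderated-t logic: n₁ + n₂ − 2 residual degrees of freedom,
   plus an equal prior share contributed by the half-weight shrinkage of
   the dispersion toward the across-gene median. At 3 vs 3 this gives
   df = 8 and an empirical null type-I error of ≈ 0.055; the reference
   converges to the normal as replication grows.
5. **BH adjustment** (via statsmodels) and the triple gate:
   max-RPKM ≥ 1, |log₂FC| ≥ 1, padj ≤ 0.05, with direction by sign.

This is a deliberately transparent stand-in for a DESeq2-style analysis:
no independent filtering, no LFC shrinkage, no outlier refitting, no
multi-factor designs. Results on real data will differ from DESeq2; the
validation surface here is simulation calibration (type-I error in
[0.03, 0.07], ≥ 90% power on |log₂FC| = 2 at base mean ≥ 100), not DESeq2
equality. Genes with zero counts in all samples are dropped before
testing.

## Translational efficiency

TE per condition is the ratio of size-factor-normalized RPF and mRNA
condition means with pseudocount 0.5 on both numerator and denominator;
the TE fold change is log₂ of the ratio of ratios. z-scores are computed
over the RPKM-gated gene universe (gate-then-standardize, so unexpressed
genes do not dilute the null pool): z = (x − μ)/σ with μ, σ the mean and
population sd of the gated log₂(TE_FC) values; significant iff |z| ≥ 1.5.
By construction the gated z-scores have mean 0 and sd 1, and for
normally distributed fold changes the significant fraction approaches
2·(1 − Φ(1.5)) ≈ 0.134 regardless of the fold-change scale.

## Regulation types

Genes significant at ≥ 1 of the two levels (mRNA, RPF) are classified by
their direction pair: (up,up)→1, (up,ns)→2, (ns,up)→3, (down,down)→4,
(down,ns)→5, (ns,down)→6, (up,down)→7, (down,up)→8; (ns,ns) is excluded.
Type 1 — coordinate up-regulation at both levels — is the canonical
amplified stress-response class; the numbering of types 2–8 is a fixed
package convention covering the remaining pairs. Type counts partition
the classified set exactly. Pairwise and three-way homodirectional
overlaps (Venn counts) are reported when polysomal calls are available,
and type-1 sets from multiple stresses can be intersected
(`core_responsive_genes`) to find genes induced at both levels by ≥ K
stresses.

## Metagene profiles

Position 0 is the first nucleotide of the start codon (start anchor) or
of the stop codon (stop anchor); profiles cover −window..+window
(default 100 nt) and sum raw 5′-end counts over genes, with an optional
per-gene mean normalization for cross-library comparison. Genes shorter
than the window simply contribute nothing at out-of-range positions.
Frame fractions use only 5′ ends strictly inside the CDS and upstream of
the stop codon; frame = (transcript position − CDS start) mod 3. Stall
peaks are upstream positions whose count is ≥ 2× the median of the other
upstream counts (excluding a ±3 nt flank around the candidate); on
strongly periodic data every frame-0 position upstream of the stop codon
can exceed that threshold, so the detector is best read as "positions
enriched over the upstream background", with the configured stall
position expected to be the profile argmax.

## Enrichment

One-sided over-representation only: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), with the background universe an explicit
required argument (recommended: the RPKM-gated gene set) and BH
correction across sets. No ontology structure is used; gene sets come
from a user-supplied GMT file.

## The synthetic experiment

The generator is the package's study-condition definition, not a tuning
surface. Defaults: 2,000 genes on one chromosome (alternating strands,
1–3 exons, CDS ≥ 60 nt and a multiple of 3), 3 replicates per condition,
log-normal baselines (log-mean 4.5, log-sd 1 → median ≈ 90 counts),
per-sample library scales log-uniform over ±30%, NB dispersion 0.05, 20%
of genes with an mRNA effect of magnitude |N(2, 0.5)| and random sign, 5%
TE-only genes (RPF and polysomal effect without an mRNA effect,
emulating genes whose ribosome loading changes while the transcript does
not), RPF coupling γ = 0.8 with effect noise sd 0.5, polysomal coupling
0.9 with noise sd 0.3. Footprints: 100,000 reads of 20–40 nt; region
placement (5′UTR/CDS/3′UTR/intergenic) = (0.035, 0.674, 0.030, 0.261),
matching the region split typical of plant ribosome-profiling control
libraries; frame probabilities (0.7, 0.2, 0.1) for strong but not
degenerate 3-nt periodicity; stall peaks 12 nt upstream of the start and
15 nt upstream of the stop codon with 4% and 2% of reads. True direction
labels in the ground truth use the same |log₂FC| ≥ 1 cutoff as the
significance gate, so truth types and detected types are on the same
scale. For correlation experiments,
`config_for_truth_correlation(target_r, ...)` puts an effect on every
gene and solves the RPF noise sd analytically from
corr(m, γm + ε) = γ·sd(m)/√(γ²var(m) + σ²).

What the generator does **not** emulate: alternative isoforms, sequencing
error and adapter artifacts, rRNA contamination, gene-specific dispersion
trends, GC/length biases, P-site geometry, and real codon-level pausing.
Passing tests therefore demonstrate that the statistical machinery is
correct and calibrated under the assumed NB/placement model — not that
any particular biological dataset will show these effect sizes.

## Problem sizes and determinism

Calibration checks use 2,000 genes (null and power), 5,000 genes
(correlation recovery), and 100,000 footprints over 150 genes (metagene
recovery) — sizes at which Monte-Carlo noise is comfortably below the
stated tolerances while the whole suite stays quick. All generators and
analysis stages are pure functions of their configuration (including the
seed); the full pipeline is byte-identical across runs with the same
seed, which the test suite and the acceptance script both verify.

## Known limitations

* The Wald t-reference df rule is a pragmatic calibration device; it is
  exact in neither the NB likelihood nor the moderated-t senses.
* Dispersion shrinkage is global (no mean-dispersion trend), which
  over-shrinks genes whose true dispersion is far from the median.
* Ambiguous-read discarding loses signal in overlapping-gene regions;
  there is no multimapper rescue.
* TE inference uses condition means only; replicate-level TE variance is
  not modeled (no interaction-term NB GLM as DESeq2 would fit for TE).
* The regulation-type numbering for types 2–8 is a package convention;
  only type 1 has a field-standard identity.
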