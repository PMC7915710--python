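# ribocoord

Coordination analysis of the transcriptome and the translatome for paired
ribosome-profiling experiments.

When a stress hits a cell, transcript levels change — but ribosomes do not
necessarily follow. `ribocoord` is for researchers who profile the same
samples at three layers — total mRNA (RNA-seq), polysome-associated mRNA,
and ribosome-protected fragments (RPFs, Ribo-seq) — and want to know, per
gene, whether transcription and translation move together. It takes a GFF3
annotation, footprint alignments in BED, and gene × sample count tables,
and produces:

* **footprint QC**: region fractions (5′UTR / CDS / 3′UTR / other),
  metagene profiles of footprint 5′ ends around start and stop codons,
  3-nt reading-frame periodicity, and detection of stall peaks;
* **per-layer differential expression**: a negative-binomial Wald test
  with median-of-ratios size factors, moderated dispersion, and the
  triple significance gate RPKM ≥ 1 (in ≥ 1 sample), |log₂FC| ≥ 1,
  padj ≤ 0.05;
* **translational efficiency (TE)**: TE = RPF abundance / mRNA abundance
  per condition; its fold change is the ratio of ratios

  ```
  TE_FC = (RPF_stress / mRNA_stress) / (RPF_control / mRNA_control)
  ```

  with significance called by z-score, z = (x − μ)/σ over all expressed
  genes' log₂(TE_FC), significant iff |z| ≥ 1.5;
* **regulation typing**: each gene significant at ≥ 1 layer is classified
  by its (mRNA, RPF) direction pair into types 1–8 — type 1 (up, up) is
  the coordinately amplified, typically stress-specific class;
* **cross-layer Pearson correlations** of log₂ fold changes (mRNA vs RPF,
  mRNA vs Poly, Poly vs RPF, mRNA vs TE) over the expression-gated gene
  set, and intersection of type-1 sets across multiple stresses ("core
  responsive genes");
* **gene-set enrichment**: hypergeometric over-representation over GMT
  sets with an explicit background universe and BH correction.

A first-class synthetic-data generator (`ribocoord.simdata`) emulates the
whole input structure with known ground truth — negative-binomial counts
across 3 layers × 2 conditions × n replicates with a tunable coupling
between mRNA and RPF fold changes, a TE-only regulated gene subset, and
footprint alignments with tunable frame periodicity, region placement and
stall peaks — so every stage of the pipeline is verifiable without any
sequencing data.

## Worked example

```bash
ribocoord pipeline --out demo --seed 7
```

runs the full chain (simulate → quantify → metagene → DE ×3 → TE →
classify → correlate → enrich) on the default synthetic experiment
(2,000 genes, 3 replicates, 100,000 footprints) and prints:

```
              pair         r    n
 mRNA_FC vs RPF_FC  0.713707 2000
mRNA_FC vs Poly_FC  0.748537 2000
 Poly_FC vs RPF_FC  0.850924 2000
  mRNA_FC vs TE_FC -0.379683 2000
all outputs in demo
```

Read: with the default RPF coupling γ = 0.8 (ribosome loading follows
only 80% of each mRNA change, plus independent noise), the estimated
mRNA–RPF fold-change correlation is moderate (r ≈ 0.71), the polysomal
layer tracks mRNA more closely, and — because loading lags transcription —
mRNA changes anti-correlate with TE changes (r ≈ −0.38). `demo/` contains
the per-stage TSVs: `de_<layer>.tsv`, `te.tsv` (with z-scores),
`regulation_types.tsv`, `type_summary.tsv` (type-1 genes are ~32% of the
classified set under the defaults), `metagene_profile.tsv` (argmax at the
injected stall position −12), `correlations.tsv` and `enrichment.tsv`
(the detected type-1 set is strongly enriched for the true type-1 set).

Each stage is also exposed separately (`ribocoord simulate / quantify /
metagene / diffexp / te / classify / correlate / core / enrich`) and as
plain library functions.

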