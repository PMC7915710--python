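"""End-to-end orchestration: simulate -> quantify -> metagene -> DE (x3
layers) -> TE -> classification -> correlations -> enrichment.

Each stage writes deterministic TSVs into the output directory, so two
runs with the same configuration produce byte-identical trees.
"""

from __future__ import annotations

import os
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as rcio
from .coordination import (
    compute_te_table,
    classify_regulation,
    layer_correlations,
    summarize_types,
    venn_counts,
)
from .diffexpr import condition_means, run_de, size_factors
from .enrichment import GeneSetCollection, hypergeom_enrich
from .metagene import detect_stall_peaks, frame_distribution, metagene_profile
from .models import LAYERS, Thresholds
from .quantify import compute_rpkm, compute_tpm, count_reads, filter_expressed, region_fractions
from .simdata import SimulatedDataset, SimulationConfig, simulate_dataset, write_dataset


def truth_gene_sets(truth: pd.DataFrame) -> GeneSetCollection:
    """Gene sets derived from the simulation truth, for enrichment runs.

    One set per true regulation type present, plus the TE-only subset.
    """
    sets, desc = {}, {}
    for t in sorted(truth["regulation_type"].unique()):
        if t == 0:
            continue
        members = frozenset(truth.index[truth["regulation_type"] == t])
        if members:
            sets[f"true_type{t}"] = members
            desc[f"true_type{t}"] = f"genes with true regulation type {t}"
    te_only = frozenset(truth.index[truth["te_only"]])
    if te_only:
        sets["true_te_only"] = te_only
        desc["true_te_only"] = "genes regulated only at the ribosome-loading level"
    return GeneSetCollection(sets=sets, descriptions=desc)


def run_pipeline(
    config: Optional[SimulationConfig] = None,
    outdir: str = "ribocoord_out",
    dataset: Optional[SimulatedDataset] = None,
    thresholds: Optional[Thresholds] = None,
) -> Dict[str, object]:
    """Run the full analysis on a (simulated) dataset and write all outputs.

    Returns a dict of the in-memory results keyed by stage.
    """
    thresholds = thresholds or Thresholds()
    if dataset is None:
        dataset = simulate_dataset(config or SimulationConfig())
    rcio.ensure_dir(outdir)
    sim_dir = os.path.join(outdir, "sim")
    write_dataset(dataset, sim_dir)
    j = lambda name: os.path.join(outdir, name)
    results: Dict[str, object] = {"dataset": dataset}

    # --- quantify -----------------------------------------------------
    gene_counts, region_counts, stats = count_reads(
        dataset.alignments, dataset.models, layer="RPF"
    )
    frac = region_fractions(region_counts, stats)
    rcio.write_table(
        pd.DataFrame([{**frac.fractions, "total": frac.total,
                       "length_filtered": frac.length_filtered,
                       "ambiguous": frac.ambiguous}]),
        j("region_fractions.tsv"), index=False,
    )
    results["region_fractions"] = frac
    rpkm, tpm = {}, {}
    for layer in LAYERS:
        cm = dataset.counts[layer]
        rpkm[layer] = compute_rpkm(cm)
        tpm[layer] = compute_tpm(cm)
        rcio.write_table(rpkm[layer].values, j(f"rpkm_{layer}.tsv"))
        rcio.write_table(tpm[layer].values, j(f"tpm_{layer}.tsv"))
    results["rpkm"] = rpkm
    results["tpm"] = tpm

    # --- metagene -----------------------------------------------------
    profiles = {
        anchor: metagene_profile(dataset.alignments, dataset.models, anchor=anchor)
        for anchor in ("start", "stop")
    }
    rcio.write_table(
        pd.concat([p.to_frame() for p in profiles.values()]),
        j("metagene_profile.tsv"), index=False,
    )
    frames = frame_distribution(dataset.alignments, dataset.models)
    rcio.write_table(
        pd.DataFrame([{"f0": frames.f0, "f1": frames.f1, "f2": frames.f2,
                       "n_reads": frames.n_reads}]),
        j("frame_distribution.tsv"), index=False,
    )
    peaks = {a: detect_stall_peaks(p) for a, p in profiles.items()}
    rcio.write_table(
        pd.DataFrame(
            [{"anchor": a, "position": p} for a, ps in peaks.items() for p in ps]
        ),
        j("stall_peaks.tsv"), index=False,
    )
    results["metagene"] = profiles
    results["frames"] = frames
    results["stall_peaks"] = peaks

    # --- differential expression per layer ----------------------------
    de: Dict[str, pd.DataFrame] = {}
    for layer in LAYERS:
        de[layer] = run_de(dataset.counts[layer], thresholds)
        rcio.write_table(de[layer], j(f"de_{layer}.tsv"))
    results["de"] = de

    # --- translational efficiency -------------------------------------
    gate = filter_expressed(rpkm["mRNA"], thresholds.rpkm_min).union(
        filter_expressed(rpkm["RPF"], thresholds.rpkm_min)
    )
    rpf_cm, mrna_cm = dataset.counts["RPF"], dataset.counts["mRNA"]
    rpf_means = condition_means(rpf_cm, size_factors(rpf_cm))
    mrna_means = condition_means(mrna_cm, size_factors(mrna_cm))
    te_table, te_stats = compute_te_table(
        rpf_means, mrna_means, gate, z_min=thresholds.te_z_min
    )
    rcio.write_table(te_table, j("te.tsv"))
    results["te"] = te_table
    results["te_stats"] = te_stats

    # --- classification ------------------------------------------------
    types = classify_regulation(de["mRNA"]["direction"], de["RPF"]["direction"])
    rcio.write_table(types.rename("regulation_type").to_frame(), j("regulation_types.tsv"))
    summary = summarize_types(types)
    rcio.write_table(summary, j("type_summary.tsv"))
    venn = venn_counts(
        {"mRNA": de["mRNA"]["direction"], "Poly": de["Poly"]["direction"],
         "RPF": de["RPF"]["direction"]}
    )
    rcio.write_table(venn, j("venn_counts.tsv"), index=False)
    results["types"] = types
    results["type_summary"] = summary
    results["venn"] = venn

    # --- correlations --------------------------------------------------
    fc = {layer: de[layer]["log2fc"] for layer in LAYERS}
    fc["TE"] = te_table["log2_te_fc"]
    corr = layer_correlations(
        fc, gate,
        pairs=[("mRNA", "RPF"), ("mRNA", "Poly"), ("Poly", "RPF"), ("mRNA", "TE")],
    )
    rcio.write_table(corr, j("correlations.tsv"), index=False)
    results["correlations"] = corr

    # --- enrichment ----------------------------------------------------
    sets = truth_gene_sets(dataset.truth)
    type1 = sorted(types.index[types == 1])
    if type1 and len(sets):
        enr = hypergeom_enrich(type1, sets, universe=sorted(gate))
        rcio.write_table(enr, j("enrichment.tsv"), index=False)
        results["enrichment"] = enr
    return results
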