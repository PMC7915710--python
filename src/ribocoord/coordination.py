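"""Transcriptome-translatome coordination: translational efficiency,
z-score significance calls, regulation-type classification, cross-layer
correlations and multi-stress core gene intersection.

Translational efficiency (TE) for a gene is the ratio of its normalized
RPF abundance to its normalized mRNA abundance; the TE fold change between
conditions is the ratio of ratios

    TE_FC = (RPF_stress / mRNA_stress) / (RPF_control / mRNA_control)

and significance of log2(TE_FC) is called by z-score against the mean and
standard deviation of all expressed genes' log2(TE_FC) values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Direction-pair -> regulation type.  Type 1 (coordinately upregulated
#: mRNA and RPF) is the canonical stress-responsive class; the remaining
#: numbering is a fixed package convention covering all direction pairs
#: with at least one significant level.
REGULATION_TYPES: Dict[tuple, int] = {
    ("up", "up"): 1,
    ("up", "ns"): 2,
    ("ns", "up"): 3,
    ("down", "down"): 4,
    ("down", "ns"): 5,
    ("ns", "down"): 6,
    ("up", "down"): 7,
    ("down", "up"): 8,
}

_DIRECTIONS = ("up", "down", "ns")


def classify_direction_pair(mrna_direction: str, rpf_direction: str) -> Optional[int]:
    """Regulation type for one (mRNA, RPF) direction pair.

    Returns None for (ns, ns) — genes with no significant change at either
    level are excluded from the classification.
    """
    if mrna_direction not in _DIRECTIONS or rpf_direction not in _DIRECTIONS:
        raise ValueError(
            f"directions must be one of {_DIRECTIONS}, "
            f"got ({mrna_direction!r}, {rpf_direction!r})"
        )
    return REGULATION_TYPES.get((mrna_direction, rpf_direction))


@dataclass
class TEStats:
    """Mean/sd of log2 TE fold changes over the included gene universe."""

    mu: float
    sigma: float
    n: int


def compute_te(
    rpf_norm_means: pd.Series, mrna_norm_means: pd.Series, pseudocount: float = 0.5
) -> pd.Series:
    """TE = (RPF mean + c) / (mRNA mean + c) from normalized condition means."""
    rpf = rpf_norm_means.astype(float)
    mrna = mrna_norm_means.reindex(rpf.index).astype(float)
    if (rpf < 0).any() or (mrna < 0).any():
        raise ValueError("normalized means must be non-negative")
    return (rpf + pseudocount) / (mrna + pseudocount)


def te_fold_change(te_stress, te_control):
    """log2 of the ratio of ratios (stress TE over control TE)."""
    te_stress = np.asarray(te_stress, dtype=float)
    te_control = np.asarray(te_control, dtype=float)
    if (te_stress <= 0).any() or (te_control <= 0).any():
        raise ValueError("TE values must be positive")
    out = np.log2(te_stress / te_control)
    return float(out) if out.ndim == 0 else out


def te_significance(
    log2_te_fc: pd.Series,
    gated_genes: Iterable[str],
    z_min: float = 1.5,
) -> tuple:
    """z-score TE calls over the expression-gated gene universe.

    The mean and sd are computed over genes passing the RPKM gate
    (``gated_genes``); z = (x - mu) / sigma.  A gene is significant iff it
    is in the gate and |z| >= ``z_min``; direction follows the sign of z.
    Returns ``(table, stats)`` where the table has columns log2_te_fc, z,
    significant, direction (genes outside the gate get z = NaN, ns).
    """
    gate = pd.Index(sorted(set(gated_genes))).intersection(log2_te_fc.index)
    x = log2_te_fc.loc[gate].dropna()
    if len(x) < 3:
        raise ValueError("need at least 3 gated genes with finite log2 TE fold change")
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma == 0:
        raise ValueError("zero variance in log2 TE fold changes; z-scores undefined")
    z = pd.Series(np.nan, index=log2_te_fc.index)
    z.loc[x.index] = (x - mu) / sigma
    significant = z.abs() >= z_min
    significant = significant.fillna(False)
    direction = pd.Series("ns", index=log2_te_fc.index)
    direction[significant & (z > 0)] = "up"
    direction[significant & (z < 0)] = "down"
    table = pd.DataFrame(
        {
            "log2_te_fc": log2_te_fc,
            "z": z,
            "significant": significant.astype(bool),
            "direction": direction,
        }
    )
    return table, TEStats(mu=mu, sigma=sigma, n=int(len(x)))


def compute_te_table(
    rpf_means: pd.DataFrame,
    mrna_means: pd.DataFrame,
    gated_genes: Iterable[str],
    pseudocount: float = 0.5,
    z_min: float = 1.5,
) -> tuple:
    """Full TE pipeline from per-condition normalized means of both layers.

    ``rpf_means`` / ``mrna_means`` are gene x {control, stress} frames of
    size-factor-normalized condition means.  Returns (table, stats) with
    te_control / te_stress columns prepended to the z-score table.
    """
    te_c = compute_te(rpf_means["control"], mrna_means["control"], pseudocount)
    te_s = compute_te(rpf_means["stress"], mrna_means["stress"], pseudocount)
    x = pd.Series(te_fold_change(te_s.to_numpy(), te_c.to_numpy()), index=te_c.index)
    table, te_stats = te_significance(x, gated_genes, z_min=z_min)
    table.insert(0, "te_control", te_c)
    table.insert(1, "te_stress", te_s)
    return table, te_stats


def classify_regulation(
    mrna_direction: pd.Series, rpf_direction: pd.Series
) -> pd.Series:
    """Per-gene regulation type (1-8) from DE direction labels.

    Genes not significant at either level ((ns, ns)) get type 0 and are
    excluded from summaries.
    """
    idx = mrna_direction.index.intersection(rpf_direction.index)
    out = pd.Series(0, index=idx, dtype=int)
    for g in idx:
        t = classify_direction_pair(mrna_direction[g], rpf_direction[g])
        out[g] = 0 if t is None else t
    return out


def summarize_types(types: pd.Series) -> pd.DataFrame:
    """Counts and proportions per regulation type (excluded genes dropped)."""
    kept = types[types > 0]
    counts = kept.value_counts().reindex(range(1, 9), fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "type": counts.index,
            "n_genes": counts.to_numpy(),
            "proportion": counts.to_numpy() / total if total else 0.0,
        }
    ).set_index("type")


def venn_counts(direction_tables: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise homodirectional overlap counts between layers.

    For every layer pair and each direction (up/down), reports the number
    of genes significant in that direction in both layers, plus per-layer
    totals.
    """
    layers = list(direction_tables)
    rows = []
    for direction in ("up", "down"):
        sets = {
            layer: set(d.index[d == direction]) for layer, d in direction_tables.items()
        }
        for layer in layers:
            rows.append({"comparison": layer, "direction": direction,
                         "n_genes": len(sets[layer])})
        for i, a in enumerate(layers):
            for b in layers[i + 1:]:
                rows.append({"comparison": f"{a}&{b}", "direction": direction,
                             "n_genes": len(sets[a] & sets[b])})
        if len(layers) >= 3:
            inter = set.intersection(*sets.values())
            rows.append({"comparison": "&".join(layers), "direction": direction,
                         "n_genes": len(inter)})
    return pd.DataFrame(rows)


def layer_correlations(
    fc_tables: Mapping[str, pd.Series],
    gene_subset: Iterable[str],
    pairs: Optional[Sequence[tuple]] = None,
) -> pd.DataFrame:
    """Pearson correlations between fold-change vectors over a gated gene set.

    ``fc_tables`` maps a label (e.g. "mRNA", "RPF", "TE") to a per-gene
    log2 fold-change Series.  Pairwise-complete genes within the subset are
    used; fewer than 3 raises.
    """
    subset = pd.Index(sorted(set(gene_subset)))
    if pairs is None:
        labels = list(fc_tables)
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    rows = []
    for a, b in pairs:
        xa = fc_tables[a].reindex(subset)
        xb = fc_tables[b].reindex(subset)
        ok = xa.notna() & xb.notna()
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"pair {a} vs {b}: fewer than 3 pairwise-complete genes")
        r, _ = stats.pearsonr(xa[ok], xb[ok])
        rows.append({"pair": f"{a}_FC vs {b}_FC", "r": float(r), "n": n})
    return pd.DataFrame(rows)


def core_responsive_genes(
    type1_sets: Mapping[str, Iterable[str]], min_stresses: int = 2
) -> pd.DataFrame:
    """Genes coordinately upregulated (type 1) under at least ``min_stresses``
    of the supplied stress conditions.

    Returns a DataFrame indexed by gene with the membership count and a
    comma-joined list of the stresses each core gene responds to.
    """
    if min_stresses > len(type1_sets):
        raise ValueError(
            f"min_stresses={min_stresses} exceeds the {len(type1_sets)} supplied sets"
        )
    if len(type1_sets) < 2:
        raise ValueError("need at least 2 stress gene sets")
    membership: Dict[str, list] = {}
    for stress, genes in type1_sets.items():
        for g in set(genes):
            membership.setdefault(g, []).append(stress)
    rows = [
        {"gene_id": g, "n_stresses": len(ss), "stresses": ",".join(sorted(ss))}
        for g, ss in membership.items()
        if len(ss) >= min_stresses
    ]
    out = pd.DataFrame(rows, columns=["gene_id", "n_stresses", "stresses"])
    return out.sort_values(["n_stresses", "gene_id"], ascending=[False, True]).set_index(
        "gene_id"
    )
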