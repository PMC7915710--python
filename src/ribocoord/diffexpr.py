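"""Negative-binomial differential expression per expression layer.

A deliberately transparent NB pipeline: median-of-ratios size factors,
method-of-moments dispersion with half-weight shrinkage toward the
across-gene median, a Wald test on the log2 ratio of pseudocounted
condition means (delta-method standard error from the NB variance
mu + alpha*mu^2), Benjamini-Hochberg adjustment, and the triple
significance gate (max RPKM >= 1 in the layer, |log2FC| >= 1,
padj <= 0.05).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CountMatrix, NormalizedMatrix, Thresholds

ALPHA_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


def size_factors(cm: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    sf_j = median over reference genes of count_gj / geomean_g, where the
    reference excludes genes with any zero count.  With ``pseudo_reference``
    the reference instead keeps every gene with a positive geometric mean
    computed over its nonzero samples (a fallback for sparse data).
    """
    counts = cm.counts.to_numpy(dtype=float)
    logc = np.full(counts.shape, np.nan)
    np.log(counts, out=logc, where=counts > 0)
    if pseudo_reference:
        loggeo = np.nanmean(logc, axis=1)
        ok = np.isfinite(loggeo)
    else:
        ok = (counts > 0).all(axis=1)
        if not ok.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        loggeo = np.full(counts.shape[0], np.nan)
        loggeo[ok] = logc[ok].mean(axis=1)
    ratios = np.exp(logc[ok] - loggeo[ok, None])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sf = np.nanmedian(ratios, axis=0)
    if not np.isfinite(sf).all() or (sf <= 0).any():
        raise ValueError("size-factor estimation failed (non-positive factor)")
    return pd.Series(sf, index=cm.counts.columns, name="size_factor")


def _condition_groups(design: pd.DataFrame):
    conds = design["condition"].unique().tolist()
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, found {conds}")
    # stress-vs-control orientation when those labels are present
    if set(conds) == {"control", "stress"}:
        conds = ["control", "stress"]
    groups = {c: design.index[design["condition"] == c].tolist() for c in conds}
    for c, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")
    return conds, groups


def estimate_dispersions(
    cm: CountMatrix, sf: pd.Series, design: Optional[pd.DataFrame] = None
) -> pd.Series:
    """Per-gene NB dispersion, method-of-moments with median shrinkage.

    On size-factor-normalized counts, each condition contributes
    (s^2 - mean)/mean^2; the per-gene estimate is their average floored at
    1e-8, and the final value is the geometric mean of the gene estimate
    and the across-gene median (half-weight shrinkage).
    """
    design = cm.design if design is None else design
    _, groups = _condition_groups(design)
    norm = cm.counts.div(sf, axis=1)
    per_cond = []
    for samples in groups.values():
        sub = norm[samples]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / mu**2
        per_cond.append(a.replace([np.inf, -np.inf], np.nan))
    raw = pd.concat(per_cond, axis=1).mean(axis=1)
    raw = raw.fillna(ALPHA_FLOOR).clip(lower=ALPHA_FLOOR)
    med = float(raw.median())
    shrunk = np.sqrt(raw * med)
    return pd.Series(shrunk, index=cm.counts.index, name="dispersion")


def nb_wald_test(
    cm: CountMatrix,
    sf: pd.Series,
    dispersions: pd.Series,
    design: Optional[pd.DataFrame] = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Wald test of the stress/control log2 ratio of normalized means.

    log2FC = log2((mu_stress + c)/(mu_control + c)) with c = 0.5; the
    standard error comes from the delta method, treating each normalized
    count as NB with mean mu_hat and dispersion alpha:
    Var(mu_hat_cond) = (mu_hat + alpha*mu_hat^2) / n.

    The Wald statistic is referred to a t distribution rather than the
    normal: the dispersion entering the standard error is estimated, so
    normal tails are anti-conservative at typical replicate numbers.  The
    residual degrees of freedom are n1 + n2 - 2, and the half-weight
    shrinkage of the dispersion toward the across-gene median contributes
    an equal prior share (moderated-t logic), giving df = 2*(n1 + n2 - 2).
    As replication grows this converges to the normal reference.

    Returns base_mean, log2fc, se, stat and the two-sided p per gene.
    """
    design = cm.design if design is None else design
    missing = set(cm.counts.columns) - set(design.index)
    if missing:
        raise ValueError(f"design missing samples: {sorted(missing)}")
    conds, groups = _condition_groups(design.loc[cm.counts.columns])
    ref, alt = conds  # ref = control-like baseline
    norm = cm.counts.div(sf, axis=1)
    alpha = dispersions.reindex(cm.counts.index).to_numpy()

    def cond_stats(samples):
        sub = norm[samples]
        mu = sub.mean(axis=1).to_numpy()
        n = len(samples)
        var = (mu + alpha * mu**2) / n
        return mu, var

    mu_ref, var_ref = cond_stats(groups[ref])
    mu_alt, var_alt = cond_stats(groups[alt])
    c = pseudocount
    log2fc = np.log2((mu_alt + c) / (mu_ref + c))
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_alt / ((mu_alt + c) * ln2) ** 2 + var_ref / ((mu_ref + c) * ln2) ** 2
    )
    se = np.maximum(se, 1e-12)
    stat = log2fc / se
    df = 2 * (len(groups[ref]) + len(groups[alt]) - 2)
    p = 2.0 * stats.t.sf(np.abs(stat), df)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
        },
        index=cm.counts.index,
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    de: pd.DataFrame, rpkm: NormalizedMatrix, thresholds: Optional[Thresholds] = None
) -> pd.DataFrame:
    """Apply the triple gate and label each gene up/down/ns.

    A gene is significant when its largest RPKM across the layer's samples
    is >= rpkm_min, |log2FC| >= abs_log2fc_min, and padj <= padj_max;
    direction follows the sign of the fold change.
    """
    thresholds = thresholds or Thresholds()
    out = de.copy()
    if "padj" not in out:
        out["padj"] = adjust_bh(out["p"].to_numpy())
    out["max_rpkm"] = rpkm.values.reindex(out.index).max(axis=1)
    sig = (
        (out["max_rpkm"] >= thresholds.rpkm_min)
        & (out["log2fc"].abs() >= thresholds.abs_log2fc_min)
        & (out["padj"] <= thresholds.padj_max)
    )
    out["significant"] = sig.fillna(False)
    out["direction"] = np.where(
        out["significant"] & (out["log2fc"] > 0),
        "up",
        np.where(out["significant"] & (out["log2fc"] < 0), "down", "ns"),
    )
    return out


def run_de(
    cm: CountMatrix,
    thresholds: Optional[Thresholds] = None,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Full DE pipeline for one layer's CountMatrix.

    Drops all-zero genes, estimates size factors and dispersions, runs the
    Wald test, BH-adjusts, and applies the significance gate using the
    layer's own RPKM values.  Returns the per-gene result table.
    """
    nonzero = cm.counts.sum(axis=1) > 0
    cm_used = CountMatrix(
        counts=cm.counts[nonzero],
        design=cm.design,
        lengths=cm.lengths[nonzero],
    )
    sf = size_factors(cm_used, pseudo_reference=pseudo_reference)
    disp = estimate_dispersions(cm_used, sf)
    de = nb_wald_test(cm_used, sf, disp)
    de["padj"] = adjust_bh(de["p"].to_numpy())
    from .quantify import compute_rpkm

    rpkm = compute_rpkm(cm_used)
    return call_significant(de, rpkm, thresholds)


def condition_means(cm: CountMatrix, sf: Optional[pd.Series] = None) -> pd.DataFrame:
    """Size-factor-normalized mean count per condition (genes x conditions)."""
    sf = size_factors(cm) if sf is None else sf
    norm = cm.counts.div(sf, axis=1)
    out = {}
    for cond in cm.design["condition"].unique():
        samples = cm.design.index[cm.design["condition"] == cond]
        out[cond] = norm[[s for s in samples if s in norm.columns]].mean(axis=1)
    return pd.DataFrame(out)
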