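"""Variant-effect statistics on model-predicted ref/alt accessibility counts.

Given per-fold predicted read counts for the reference and alternative allele
of each variant in each cell type, the scheme is:

1. fold-averaged effect size: mean over folds of log2(alt/ref);
2. per-cell-type significance: one-sided Poisson test of the fold-averaged
   alternative count with rate equal to the fold-averaged reference count,
   taking the tail in the direction of the observed change;
3. per-variant significance: Fisher combination of the per-cell-type p-values
   (chi-square with 2k df);
4. Benjamini-Hochberg adjustment across variants;
5. a variant is *high effect* iff max |fold-averaged log2FC| over cell types
   exceeds 0.25 and FDR is below 0.01 (both strict).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

P_FLOOR = 1e-300


def fold_average_log2fc(pred_counts: pd.DataFrame) -> pd.DataFrame:
    """Mean over folds of log2(alt/ref) per (variant, cell type).

    ``pred_counts`` has columns rsid, cell_type, fold, ref_count, alt_count.
    Counts must be strictly positive and each (variant, cell type) needs >= 2
    folds.
    """
    df = pred_counts
    if (df["ref_count"] <= 0).any() or (df["alt_count"] <= 0).any():
        raise ValidationError("predicted counts must be strictly positive")
    fold_counts = df.groupby(["rsid", "cell_type"])["fold"].nunique()
    if (fold_counts < 2).any():
        raise ValidationError("each (variant, cell type) needs >= 2 folds")
    l2 = np.log2(df["alt_count"].to_numpy() / df["ref_count"].to_numpy())
    out = (
        df.assign(log2fc=l2)
        .groupby(["rsid", "cell_type"], as_index=False)
        .agg(
            log2fc=("log2fc", "mean"),
            ref_mean=("ref_count", "mean"),
            alt_mean=("alt_count", "mean"),
        )
    )
    return out


def poisson_one_sided(alt_count: float, ref_rate: float) -> float:
    """One-sided Poisson tail for the alternative count at the reference rate.

    Upper tail P(X >= alt) when alt >= ref_rate, else lower tail P(X <= alt),
    X ~ Poisson(ref_rate). Continuous counts are rounded to the nearest
    integer before the tail sum.
    """
    if ref_rate <= 0:
        raise ValidationError("ref_rate must be positive")
    if alt_count < 0:
        raise ValidationError("alt_count must be nonnegative")
    k = int(round(alt_count))
    if alt_count >= ref_rate:
        # P(X >= k) = sf(k - 1)
        return float(stats.poisson.sf(k - 1, ref_rate))
    return float(stats.poisson.cdf(k, ref_rate))


def fisher_combine(p_values: Sequence[float], p_floor: float = P_FLOOR) -> float:
    """Fisher's method: X^2 = -2 sum(ln p); upper chi-square tail at 2k df."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("need >= 1 p-value to combine")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn(f"zero p-values clipped to {p_floor}", stacklevel=2)
        p = np.maximum(p, p_floor)
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def score_variants(pred_counts: pd.DataFrame) -> pd.DataFrame:
    """Full variant-effect scoring on a prediction table.

    Returns one row per variant with columns: rsid, max_abs_log2fc,
    combined_p, fdr, high_effect, plus per-cell-type log2fc/p in long-form
    companion columns via ``per_cell_type`` attribute-free design: the
    per-cell-type table is available from :func:`fold_average_log2fc`.
    """
    per_ct = fold_average_log2fc(pred_counts)
    per_ct["p_value"] = [
        poisson_one_sided(alt, ref)
        for alt, ref in zip(per_ct["alt_mean"], per_ct["ref_mean"])
    ]
    rows = []
    for rsid, grp in per_ct.groupby("rsid"):
        rows.append(
            {
                "rsid": rsid,
                "max_abs_log2fc": float(np.abs(grp["log2fc"]).max()),
                "combined_p": fisher_combine(grp["p_value"].to_numpy()),
            }
        )
    res = pd.DataFrame(rows).sort_values("rsid").reset_index(drop=True)
    res["fdr"] = bh_adjust(res["combined_p"].to_numpy())
    res["high_effect"] = (res["max_abs_log2fc"] > 0.25) & (res["fdr"] < 0.01)
    return res


def call_high_effect(
    results: pd.DataFrame, fc_min: float = 0.25, fdr_max: float = 0.01
) -> set:
    """High-effect variant set: |log2FC| > fc_min AND FDR < fdr_max (strict)."""
    mask = (results["max_abs_log2fc"] > fc_min) & (results["fdr"] < fdr_max)
    return set(results.loc[mask, "rsid"])
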