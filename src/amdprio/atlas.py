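"""Peak-space operations on the single-cell chromatin atlas.

Cell QC, promoter windows, variant/peak intersection, merged unique-base
enrichment, and the generic thresholded rank-sum group comparison used for
marker peaks/genes and differential accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .catalog import round_half_away
from .core import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    ValidationError,
    VariantRecord,
)
from .effects import bh_adjust

QC_COLUMNS = [
    "n_rna_transcripts",
    "pct_mito",
    "pct_ribo",
    "tss_enrichment",
    "n_atac_fragments",
]


def qc_filter_cells(metrics: pd.DataFrame) -> List[str]:
    """Cell barcodes passing all five multiome QC gates.

    Kept iff 200 <= RNA transcripts <= 10,000 (inclusive), mitochondrial
    fraction < 1%, ribosomal fraction < 5%, TSS enrichment > 4 and
    > 1,000 ATAC fragments (strict bounds exactly as stated).
    """
    missing = [c for c in QC_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValidationError(f"QC metrics table missing columns {missing}")
    keep = (
        metrics["n_rna_transcripts"].between(200, 10_000)
        & (metrics["pct_mito"] < 1.0)
        & (metrics["pct_ribo"] < 5.0)
        & (metrics["tss_enrichment"] > 4.0)
        & (metrics["n_atac_fragments"] > 1_000)
    )
    return list(metrics.index[keep])


PROMOTER_UPSTREAM = 2_000
PROMOTER_DOWNSTREAM = 100


def make_promoters(
    gene_models: Sequence[GeneModel],
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Tuple[PeakSet, Dict[str, GenomicInterval]]:
    """Promoter windows: 2,000 bp upstream to 100 bp downstream of each TSS.

    On the + strand with TSS t the window is [t-2000, t+101); on the - strand
    it is [t-100, t+2001) (downstream of a - gene runs leftward). Windows are
    clipped at chromosome boundaries.

    Returns the promoter PeakSet plus a gene_id -> window map.
    """
    windows: Dict[str, GenomicInterval] = {}
    for g in gene_models:
        if g.strand == "+":
            start, end = g.tss - PROMOTER_UPSTREAM, g.tss + PROMOTER_DOWNSTREAM + 1
        else:
            start, end = g.tss - PROMOTER_DOWNSTREAM, g.tss + PROMOTER_UPSTREAM + 1
        start = max(0, start)
        if chrom_sizes is not None and g.chrom in chrom_sizes:
            end = min(end, chrom_sizes[g.chrom])
        windows[g.gene_id] = GenomicInterval(g.chrom, start, end, g.strand)
    return PeakSet("promoters", windows.values()), windows


def build_point_index(peakset: PeakSet) -> Dict[str, IntervalTree]:
    """Per-chromosome interval trees for containment/overlap queries."""
    trees: Dict[str, IntervalTree] = {}
    for iv in peakset:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


@dataclass
class AccessibilityCall:
    rsid: str
    cell_type: str
    accessible: bool
    containing_peak: Optional[GenomicInterval] = None


def intersect_variants_peaks(
    variants: Sequence[VariantRecord],
    peaksets: Mapping[str, PeakSet],
) -> Tuple[List[AccessibilityCall], Dict[str, int]]:
    """Point-intersect variant positions with each cell type's peaks.

    A variant is accessible in a cell type iff its position lies inside at
    least one peak (half-open containment). Returns all calls plus the
    per-variant count of cell types in which it is accessible.
    """
    trees = {label: build_point_index(ps) for label, ps in peaksets.items()}
    calls: List[AccessibilityCall] = []
    n_accessible: Dict[str, int] = {v.rsid: 0 for v in variants}
    for v in variants:
        for label in peaksets:
            tree = trees[label].get(v.chrom)
            hits = sorted(tree[v.pos]) if tree is not None else []
            if hits:
                calls.append(
                    AccessibilityCall(v.rsid, label, True, hits[0].data)
                )
                n_accessible[v.rsid] += 1
            else:
                calls.append(AccessibilityCall(v.rsid, label, False))
    return calls, n_accessible


def containing_peaks(
    variants: Sequence[VariantRecord], peaksets: Mapping[str, PeakSet]
) -> Dict[str, List[GenomicInterval]]:
    """All peaks (across cell types, deduplicated) containing each variant."""
    out: Dict[str, List[GenomicInterval]] = {}
    trees = {label: build_point_index(ps) for label, ps in peaksets.items()}
    for v in variants:
        found = set()
        for label in peaksets:
            tree = trees[label].get(v.chrom)
            if tree is None:
                continue
            for hit in tree[v.pos]:
                found.add(hit.data)
        if found:
            out[v.rsid] = sorted(found)
    return out


def merge_unique_bases(peakset: PeakSet) -> Tuple[PeakSet, int]:
    """Merge overlapping intervals; return merged set and total unique bp."""
    merged: List[GenomicInterval] = []
    for iv in peakset:  # already sorted by (chrom, start)
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end
                )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    total = sum(len(iv) for iv in merged)
    return PeakSet(peakset.label + "_merged", merged), total


@dataclass
class EnrichmentResult:
    tissue: str
    n_accessible_variants: int
    unique_bases: int
    raw_rate: float
    normalized_enrichment: Optional[float] = None


def variant_enrichment(
    variants: Sequence[VariantRecord],
    tissue_peaksets: Mapping[str, PeakSet],
    target_tissues: Sequence[str],
    baseline_tissues: Sequence[str],
) -> Dict[str, EnrichmentResult]:
    """Accessible-variant density per tissue, normalized to the baseline mean.

    Raw rate = accessible variants / unique merged peak bases; normalized
    enrichment divides by the mean raw rate over the baseline tissues.
    """
    if not baseline_tissues:
        raise ValidationError("need >= 1 baseline tissue")
    results: Dict[str, EnrichmentResult] = {}
    for tissue in list(target_tissues) + list(baseline_tissues):
        ps = tissue_peaksets[tissue]
        merged, total_bp = merge_unique_bases(ps)
        if total_bp == 0:
            raise ValidationError(f"{tissue}: zero unique peak bases")
        trees = build_point_index(merged)
        n_acc = sum(
            1
            for v in variants
            if v.chrom in trees and trees[v.chrom][v.pos]
        )
        results[tissue] = EnrichmentResult(
            tissue, n_acc, total_bp, n_acc / total_bp
        )
    baseline_mean = float(
        np.mean([results[t].raw_rate for t in baseline_tissues])
    )
    if baseline_mean == 0:
        raise ValidationError("baseline mean rate is zero")
    for res in results.values():
        res.normalized_enrichment = res.raw_rate / baseline_mean
    return results


def group_differential(
    values: pd.DataFrame,
    group_labels: Mapping[str, str],
    target_group: str,
    log2fc_min: float,
    fdr_max: float,
    min_fraction: Optional[float] = None,
    other_group: Optional[str] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Thresholded rank-sum group comparison (marker/differential features).

    Per feature: Wilcoxon rank-sum of the target group against the rest (or
    against ``other_group`` for pairwise mode) with mid-rank tie handling,
    normal approximation and continuity correction; Benjamini-Hochberg FDR
    across features; log2FC of pseudocounted group means. A feature is
    returned iff log2FC >= log2fc_min, FDR <= fdr_max and (when set) the
    fraction of target-group samples with nonzero signal >= min_fraction.
    """
    labels = pd.Series({s: group_labels[s] for s in values.columns})
    if labels.value_counts().min() < 3:
        raise ValidationError("every group needs >= 3 samples")
    target_cols = labels.index[labels == target_group]
    if other_group is not None:
        rest_cols = labels.index[labels == other_group]
    else:
        rest_cols = labels.index[labels != target_group]
    if len(target_cols) < 3 or len(rest_cols) < 3:
        raise ValidationError("comparison groups need >= 3 samples each")

    tgt = values[target_cols].to_numpy(dtype=float)
    rest = values[rest_cols].to_numpy(dtype=float)
    log2fc = np.log2(
        (tgt.mean(axis=1) + pseudocount) / (rest.mean(axis=1) + pseudocount)
    )
    pvals = np.ones(values.shape[0])
    for i in range(values.shape[0]):
        if np.ptp(np.concatenate([tgt[i], rest[i]])) == 0:
            continue  # identical values: p stays 1
        pvals[i] = stats.mannwhitneyu(
            tgt[i], rest[i], alternative="two-sided",
            use_continuity=True, method="asymptotic",
        ).pvalue
    fdr = bh_adjust(pvals)
    frac = (tgt > 0).mean(axis=1)
    out = pd.DataFrame(
        {
            "feature_id": values.index,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "fraction": frac,
        }
    )
    keep = (out["log2fc"] >= log2fc_min) & (out["fdr"] <= fdr_max)
    if min_fraction is not None:
        keep &= out["fraction"] >= min_fraction
    return out[keep].reset_index(drop=True)


# Threshold presets quoted for the atlas comparisons.
DIFFERENTIAL_PRESETS = {
    "marker_peaks": {"log2fc_min": 0.5, "fdr_max": 0.1},
    "diff_accessibility": {"log2fc_min": 0.5, "fdr_max": 0.25},
    "marker_genes": {"log2fc_min": 1.0, "fdr_max": 0.1, "min_fraction": 0.6},
    "subpop_genes": {"log2fc_min": 0.5, "fdr_max": 0.1, "min_fraction": 0.3},
}
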