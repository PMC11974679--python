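"""The four enhancer-linking strategies and their summaries.

1. co-accessibility: correlated accessibility between peak pairs, routed to
   genes through peaks inside promoter windows;
2. peak-gene correlation: peak accessibility vs gene expression;
3. loop overlap: a variant/peak in one loop anchor, the gene's promoter/TSS
   in the partner anchor;
4. Activity-by-Contact: element activity (geometric mean of ATAC and H3K27ac
   signal) times 3D contact, normalized per gene over its candidate elements.

Correlations are Pearson on untransformed pseudo-bulk signal, and the cutoff
applies to the signed value (negative correlations never pass); an
absolute-value mode is available via ``use_absolute``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .atlas import build_point_index, make_promoters
from .core import (
    ContactMap,
    FeatureMatrix,
    GeneModel,
    GenomicInterval,
    LoopSet,
    PeakSet,
    ValidationError,
    VariantRecord,
)

DEFAULT_CORR_CUTOFF = 0.3
DEFAULT_MAX_DIST = 250_000
ABC_SCORE_MIN = 0.025
ABC_MIN_TSS_DIST = 500


@dataclass(frozen=True)
class PeakPeakLink:
    peak_a: GenomicInterval
    peak_b: GenomicInterval
    correlation: float


@dataclass(frozen=True)
class PeakGeneLink:
    peak: GenomicInterval
    gene_id: str
    correlation: float
    distance_to_tss: int


@dataclass(frozen=True)
class ABCConnection:
    element: GenomicInterval
    gene_id: str
    activity: float
    contact: float
    abc_score: float
    distance_to_tss: int


def _standardize_rows(mat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-standardize; returns (z, constant_row_mask)."""
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    const = sd[:, 0] == 0
    sd[const] = 1.0
    return (mat - mu) / sd, const


def coaccessibility_links(
    accessibility: FeatureMatrix,
    peaks: PeakSet,
    window_bp: int = DEFAULT_MAX_DIST,
    cutoff: float = DEFAULT_CORR_CUTOFF,
    use_absolute: bool = False,
) -> List[PeakPeakLink]:
    """Correlated same-chromosome peak pairs within a genomic window.

    Peak accessibility profiles over pseudo-bulk samples are Pearson-
    correlated for every pair of peaks whose midpoints lie within
    ``window_bp``; a link is kept iff the (signed) correlation exceeds
    ``cutoff``. Constant profiles are skipped with a warning.
    """
    if accessibility.shape[1] < 10:
        raise ValidationError("co-accessibility needs >= 10 pseudo-bulk samples")
    order = [iv.key() for iv in peaks]
    mat = accessibility.values.loc[order].to_numpy(dtype=float)
    z, const = _standardize_rows(mat)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant peak profiles skipped", stacklevel=2
        )
    n = mat.shape[1]
    key_to_row = {k: i for i, k in enumerate(order)}
    links: List[PeakPeakLink] = []
    for ci, chrom_ivs in peaks.by_chrom().items():
        chrom_ivs = sorted(chrom_ivs, key=lambda iv: iv.midpoint)
        idx = [key_to_row[iv.key()] for iv in chrom_ivs]
        mids = np.array([iv.midpoint for iv in chrom_ivs])
        for a in range(len(chrom_ivs)):
            for b in range(a + 1, len(chrom_ivs)):
                if mids[b] - mids[a] > window_bp:
                    break  # midpoints sorted: later pairs only get farther
                ia, ib = idx[a], idx[b]
                if const[ia] or const[ib]:
                    continue
                r = float(z[ia] @ z[ib] / n)
                stat = abs(r) if use_absolute else r
                if stat > cutoff:
                    links.append(PeakPeakLink(chrom_ivs[a], chrom_ivs[b], r))
    return links


def promoter_coaccessible(
    links: Sequence[PeakPeakLink],
    gene_models: Sequence[GeneModel],
) -> Tuple[Set[Tuple[str, str]], Dict[str, object]]:
    """Route peak-peak links to genes through promoter-window peaks.

    A peak is co-accessible with gene g iff it is linked to at least one peak
    overlapping g's promoter window. Returns the set of (peak key, gene_id)
    pairs plus summary stats including the fraction of link-bearing peaks
    with >= 1 co-accessible promoter.
    """
    _, windows = make_promoters(gene_models)
    win_ps = PeakSet("promoter_windows", windows.values())
    trees = build_point_index(win_ps)
    window_to_gene = {windows[g].key(): g for g in windows}

    def genes_overlapping(iv: GenomicInterval) -> Set[str]:
        tree = trees.get(iv.chrom)
        if tree is None:
            return set()
        return {
            window_to_gene[
                GenomicInterval(iv.chrom, hit.begin, hit.end).key()
            ]
            for hit in tree.overlap(iv.start, iv.end)
        }

    pairs: Set[Tuple[str, str]] = set()
    peaks_with_promoter: Set[str] = set()
    all_link_peaks: Set[str] = set()
    for link in links:
        for peak, other in (
            (link.peak_a, link.peak_b),
            (link.peak_b, link.peak_a),
        ):
            all_link_peaks.add(peak.key())
            for g in genes_overlapping(other):
                pairs.add((peak.key(), g))
                peaks_with_promoter.add(peak.key())
    summary = {
        "n_pairs": len(pairs),
        "n_peaks_with_promoter": len(peaks_with_promoter),
        "n_link_peaks": len(all_link_peaks),
    }
    return pairs, summary


def peak_gene_links(
    accessibility: FeatureMatrix,
    expression: FeatureMatrix,
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    max_dist: int = DEFAULT_MAX_DIST,
    cutoff: float = DEFAULT_CORR_CUTOFF,
    use_absolute: bool = False,
) -> List[PeakGeneLink]:
    """Correlate peak accessibility with expression of genes within max_dist.

    Distance is |peak midpoint - TSS|; a link is retained iff the (signed)
    Pearson correlation exceeds the cutoff.
    """
    if accessibility.sample_ids != expression.sample_ids:
        raise ValidationError(
            "accessibility and expression matrices must share sample IDs"
        )
    acc_order = [iv.key() for iv in peaks]
    acc = accessibility.values.loc[acc_order].to_numpy(dtype=float)
    expr = expression.values.to_numpy(dtype=float)
    gene_row = {g: i for i, g in enumerate(expression.feature_ids)}
    za, ca = _standardize_rows(acc)
    ze, ce = _standardize_rows(expr)
    n = acc.shape[1]
    links: List[PeakGeneLink] = []
    by_chrom = peaks.by_chrom()
    key_to_row = {k: i for i, k in enumerate(acc_order)}
    for g in genes:
        if g.gene_id not in gene_row:
            continue
        gi = gene_row[g.gene_id]
        if ce[gi]:
            continue
        for iv in by_chrom.get(g.chrom, []):
            dist = abs(iv.midpoint - g.tss)
            if dist > max_dist:
                continue
            pi = key_to_row[iv.key()]
            if ca[pi]:
                continue
            r = float(za[pi] @ ze[gi] / n)
            stat = abs(r) if use_absolute else r
            if stat > cutoff:
                links.append(PeakGeneLink(iv, g.gene_id, r, dist))
    return links


@dataclass
class LoopOverlapResult:
    linked_pairs: Set[Tuple[str, str]]  # (target_id, gene_id)
    anchor_peak_fraction: Optional[float] = None


def loop_overlap(
    loopset: LoopSet,
    gene_models: Sequence[GeneModel],
    variant_positions: Optional[Mapping[str, Tuple[str, int]]] = None,
    target_intervals: Optional[Mapping[str, GenomicInterval]] = None,
    peaksets: Optional[Mapping[str, PeakSet]] = None,
) -> LoopOverlapResult:
    """Loop-mediated target-gene links plus anchor/peak overlap fraction.

    A target (a variant position or an interval) is loop-linked to a gene iff
    the target overlaps one anchor and the gene's promoter window or TSS
    overlaps the *other* anchor of the same loop. Anchor overlap means >= 1
    shared base; a point overlaps an anchor iff it lies inside it (half-open).

    When ``peaksets`` is given, also reports the fraction of loops with at
    least one anchor overlapping a peak of any supplied set.
    """
    _, promoter_windows = make_promoters(gene_models)

    def anchor_genes(anchor: GenomicInterval) -> Set[str]:
        out = set()
        for g in gene_models:
            win = promoter_windows[g.gene_id]
            if anchor.overlaps(win) or anchor.contains(g.chrom, g.tss):
                out.add(g.gene_id)
        return out

    def anchor_targets(anchor: GenomicInterval) -> Set[str]:
        out = set()
        if variant_positions:
            for rsid, (chrom, pos) in variant_positions.items():
                if anchor.contains(chrom, pos):
                    out.add(rsid)
        if target_intervals:
            for tid, iv in target_intervals.items():
                if anchor.overlaps(iv):
                    out.add(tid)
        return out

    pairs: Set[Tuple[str, str]] = set()
    for lp in loopset:
        for a, b in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            targets = anchor_targets(a)
            if not targets:
                continue
            genes = anchor_genes(b)
            pairs.update((t, g) for t in targets for g in genes)

    frac = None
    if peaksets:
        n_overlap = 0
        for lp in loopset:
            hit = False
            for ps in peaksets.values():
                trees = build_point_index(ps)
                for anchor in (lp.anchor1, lp.anchor2):
                    tree = trees.get(anchor.chrom)
                    if tree is not None and tree.overlap(
                        anchor.start, anchor.end
                    ):
                        hit = True
            n_overlap += hit
        frac = n_overlap / len(loopset) if len(loopset) else 0.0
    return LoopOverlapResult(pairs, frac)


def abc_scores(
    candidate_elements: PeakSet,
    atac_signal: Mapping[str, float],
    h3k27ac_signal: Mapping[str, float],
    contact_map: ContactMap,
    genes: Sequence[GeneModel],
    score_min: float = ABC_SCORE_MIN,
    min_tss_dist: int = ABC_MIN_TSS_DIST,
    max_candidate_dist: int = 5_000_000,
) -> List[ABCConnection]:
    """Activity-by-Contact enhancer-gene connections.

    Activity A_e = sqrt(ATAC_e * H3K27ac_e); contact C_eg is the map value
    between the element's bin and the TSS's bin (diagonal entry for same-bin
    pairs, distance-decay expectation for bins outside the map). Per gene,
    scores are A.C normalized to sum to 1 over the candidate set (elements
    within ``max_candidate_dist`` of the TSS). A connection is reported iff
    its score exceeds ``score_min`` and |element midpoint - TSS| is at least
    ``min_tss_dist``. Genes whose candidates all have zero A.C are skipped
    with a warning.
    """
    elements = list(candidate_elements)
    activity = {}
    for iv in elements:
        k = iv.key()
        a, h = atac_signal.get(k, 0.0), h3k27ac_signal.get(k, 0.0)
        if a < 0 or h < 0:
            raise ValidationError(f"{k}: negative signal")
        activity[k] = float(np.sqrt(a * h))
    by_chrom = candidate_elements.by_chrom()
    connections: List[ABCConnection] = []
    skipped_genes: List[str] = []
    for g in genes:
        tss_bin = contact_map.bin_of(g.tss)
        cands = [
            iv
            for iv in by_chrom.get(g.chrom, [])
            if abs(iv.midpoint - g.tss) <= max_candidate_dist
        ]
        if not cands:
            continue
        weights, contacts = [], []
        for iv in cands:
            e_bin = contact_map.bin_of(iv.midpoint)
            c = contact_map.contact(g.chrom, e_bin, tss_bin)
            if c is None:
                if g.chrom in contact_map.matrices:
                    c = contact_map.expected_at_distance(
                        g.chrom, abs(e_bin - tss_bin)
                    )
                else:
                    c = 0.0
            contacts.append(c)
            weights.append(activity[iv.key()] * c)
        total = float(sum(weights))
        if total <= 0:
            skipped_genes.append(g.gene_id)
            continue
        for iv, w, c in zip(cands, weights, contacts):
            score = w / total
            dist = abs(iv.midpoint - g.tss)
            if score > score_min and dist >= min_tss_dist:
                connections.append(
                    ABCConnection(
                        iv, g.gene_id, activity[iv.key()], c, score, dist
                    )
                )
    if skipped_genes:
        warnings.warn(
            f"{len(skipped_genes)} gene(s) skipped (no candidate with positive "
            f"activity x contact), e.g. {skipped_genes[:3]}",
            stacklevel=2,
        )
    return connections


def connection_summaries(
    link_collections: Mapping[str, Set[Tuple[str, str]]],
    distances: Optional[Mapping[str, Sequence[int]]] = None,
) -> Dict[str, object]:
    """Per-strategy link counts, enhancers-per-gene medians and overlaps.

    ``link_collections`` maps strategy name -> set of (element key, gene_id).
    Overlap between two strategies = |intersection| / |smaller set|.
    """
    if not link_collections:
        raise ValidationError("need >= 1 strategy")
    out: Dict[str, object] = {"strategies": {}}
    for name, pairs in link_collections.items():
        per_gene: Dict[str, int] = {}
        for _, gene in pairs:
            per_gene[gene] = per_gene.get(gene, 0) + 1
        entry = {
            "n_links": len(pairs),
            "n_genes": len(per_gene),
            "enhancers_per_gene_median": (
                float(np.median(list(per_gene.values()))) if per_gene else 0.0
            ),
        }
        if distances and name in distances and len(distances[name]):
            entry["distance_median"] = float(np.median(distances[name]))
        out["strategies"][name] = entry
    overlaps: Dict[str, float] = {}
    names = sorted(link_collections)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = link_collections[a], link_collections[b]
            smaller = min(len(sa), len(sb))
            overlaps[f"{a}|{b}"] = (
                len(sa & sb) / smaller if smaller else 0.0
            )
    out["pairwise_overlap"] = overlaps
    return out


def marker_gene_enrichment(
    target_genes: Set[str],
    marker_gene_sets: Mapping[str, Sequence[str]],
    baseline_tissues: Sequence[str],
    n_sample: int = 457,
    n_draws: int = 100,
    seed: int = 0,
) -> Dict[str, Dict[str, float]]:
    """Fraction of sampled marker genes found among enhancer target genes.

    For each tissue's marker set, ``n_sample`` genes are drawn without
    replacement (or the whole set if smaller), the fraction inside
    ``target_genes`` recorded, and the mean over ``n_draws`` draws reported;
    fractions are normalized to the mean over ``baseline_tissues``.
    """
    rng = np.random.default_rng(seed)
    if not target_genes:
        warnings.warn("empty enhancer target set; fractions are 0", stacklevel=2)
    fractions: Dict[str, float] = {}
    for tissue, markers in marker_gene_sets.items():
        markers = list(markers)
        k = min(n_sample, len(markers))
        draws = []
        for _ in range(n_draws):
            sample = rng.choice(markers, size=k, replace=False)
            draws.append(
                sum(1 for m in sample if m in target_genes) / k if k else 0.0
            )
        fractions[tissue] = float(np.mean(draws))
    baseline_mean = float(np.mean([fractions[t] for t in baseline_tissues]))
    out = {}
    for tissue, frac in fractions.items():
        out[tissue] = {
            "fraction": frac,
            "normalized": frac / baseline_mean if baseline_mean > 0 else np.nan,
        }
    return out
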