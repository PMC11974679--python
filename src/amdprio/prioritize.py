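"""Integration of the eight regulatory-evidence criteria and the >=3-of-8 rule.

The criteria matrix has one row per accessible variant (accessible in at
least one RPE/choroid cell type) and eight boolean columns:

1. coaccessible_with_promoter — the variant's containing peak has a
   promoter-co-accessibility link;
2. accessibility_correlated_with_gene — the containing peak has a peak-gene
   correlation link;
3. hichip_linked — the variant lies in a loop anchor whose partner anchor
   overlaps a gene promoter/TSS;
4. abc_connected — the containing peak has an Activity-by-Contact connection;
5. in_starrseq_enhancer — the variant's oligo is a STARR-seq enhancer;
6. functional_snp — significant allelic STARR-seq effect inside an enhancer;
7. significant_eqtl — eQTL FDR <= 0.05 in macular or non-macular tissue;
8. chrombpnet_high_effect — high predicted accessibility effect.

A variant in more than one peak inherits the union of its peaks' links.
Variants meeting at least three criteria are *prioritized*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .catalog import round_half_away
from .core import GenomicInterval, ValidationError, VariantRecord

CRITERIA = [
    "coaccessible_with_promoter",
    "accessibility_correlated_with_gene",
    "hichip_linked",
    "abc_connected",
    "in_starrseq_enhancer",
    "functional_snp",
    "significant_eqtl",
    "chrombpnet_high_effect",
]

K_MIN_DEFAULT = 3


def eqtl_significant(
    eqtl_table: pd.DataFrame,
    variants: Optional[Sequence[str]] = None,
    fdr_max: float = 0.05,
) -> Set[str]:
    """Variants with eQTL FDR <= fdr_max (inclusive) in either tissue region."""
    bad = set(eqtl_table["tissue_region"]) - {"macular", "non_macular"}
    if bad:
        raise ValidationError(f"unknown tissue_region values {bad}")
    sig = set(eqtl_table.loc[eqtl_table["fdr"] <= fdr_max, "rsid"])
    if variants is not None:
        sig &= set(variants)
    return sig


def build_criteria_matrix(
    accessible_variants: Sequence[str],
    variant_peaks: Mapping[str, Sequence[GenomicInterval]],
    promoter_links: Set[Tuple[str, str]],
    peak_gene_links: Set[Tuple[str, str]],
    loop_links: Set[Tuple[str, str]],
    abc_links: Set[Tuple[str, str]],
    enhancer_set: Set[str],
    functional_set: Set[str],
    eqtl_set: Set[str],
    high_effect_set: Set[str],
) -> pd.DataFrame:
    """Assemble the accessible-variant x 8-criterion boolean matrix.

    Peak-level link sets (criteria 1, 2, 4) are keyed by (peak key, gene_id);
    the loop-link set (criterion 3) by (rsid, gene_id); the remaining four by
    rsid membership. ``variant_peaks`` maps each accessible variant to its
    containing peak(s).
    """
    peak_keys_with = {
        "coaccessible_with_promoter": {p for p, _ in promoter_links},
        "accessibility_correlated_with_gene": {p for p, _ in peak_gene_links},
        "abc_connected": {p for p, _ in abc_links},
    }
    loop_variants = {v for v, _ in loop_links}
    rows = []
    for rsid in accessible_variants:
        peaks = variant_peaks.get(rsid)
        if not peaks:
            raise ValidationError(
                f"accessible variant {rsid} has no containing peak"
            )
        keys = {iv.key() for iv in peaks}
        row = {
            "rsid": rsid,
            "coaccessible_with_promoter": bool(
                keys & peak_keys_with["coaccessible_with_promoter"]
            ),
            "accessibility_correlated_with_gene": bool(
                keys & peak_keys_with["accessibility_correlated_with_gene"]
            ),
            "hichip_linked": rsid in loop_variants,
            "abc_connected": bool(keys & peak_keys_with["abc_connected"]),
            "in_starrseq_enhancer": rsid in enhancer_set,
            "functional_snp": rsid in functional_set,
            "significant_eqtl": rsid in eqtl_set,
            "chrombpnet_high_effect": rsid in high_effect_set,
        }
        rows.append(row)
    matrix = pd.DataFrame(rows, columns=["rsid"] + CRITERIA)
    if matrix.empty:
        matrix = pd.DataFrame(columns=["rsid"] + CRITERIA)
    matrix = matrix.set_index("rsid")
    matrix[CRITERIA] = matrix[CRITERIA].astype(bool)
    matrix["n_criteria_met"] = matrix[CRITERIA].sum(axis=1).astype(int)
    return matrix


@dataclass
class PrioritizationResult:
    prioritized: Set[str]
    n_accessible: int
    pct_of_accessible: float
    pct_of_catalog: Optional[float] = None


def call_prioritized(
    matrix: pd.DataFrame,
    k_min: int = K_MIN_DEFAULT,
    n_catalog_noncoding: Optional[int] = None,
) -> PrioritizationResult:
    """Variants meeting at least ``k_min`` of the eight criteria.

    Percentages (half-away-from-zero, one decimal) are reported relative to
    the accessible-variant universe and, when given, the noncoding/synonymous
    catalog size.
    """
    chosen = set(matrix.index[matrix["n_criteria_met"] >= k_min])
    n_acc = len(matrix)
    pct_acc = round_half_away(100.0 * len(chosen) / n_acc) if n_acc else 0.0
    pct_cat = (
        round_half_away(100.0 * len(chosen) / n_catalog_noncoding)
        if n_catalog_noncoding
        else None
    )
    return PrioritizationResult(chosen, n_acc, pct_acc, pct_cat)


def upset_summary(matrix: pd.DataFrame) -> Dict[str, object]:
    """Counts per exact criterion combination plus column marginals.

    Combination counts partition the accessible variants (they sum to the
    number of rows); marginals equal column sums.
    """
    combos: Dict[str, int] = {}
    for _, row in matrix[CRITERIA].iterrows():
        key = "+".join(c for c in CRITERIA if row[c]) or "(none)"
        combos[key] = combos.get(key, 0) + 1
    marginals = {c: int(matrix[c].sum()) for c in CRITERIA}
    n = len(matrix)
    marginal_pct = {
        c: round_half_away(100.0 * marginals[c] / n) if n else 0.0
        for c in CRITERIA
    }
    return {
        "combination_counts": combos,
        "marginals": marginals,
        "marginal_pct": marginal_pct,
        "n_rows": n,
    }


@dataclass
class LocusReport:
    locus_id: int
    index_variants: List[Dict[str, object]]
    candidates: List[Dict[str, object]]
    prioritized: List[str]
    index_inaccessible_with_alternative: bool


def locus_report(
    locus_id: int,
    catalog: Sequence[VariantRecord],
    matrix: pd.DataFrame,
    allelic_log2fc: Optional[Mapping[str, float]] = None,
    linked_genes: Optional[Mapping[str, Mapping[str, Sequence[str]]]] = None,
    k_min: int = K_MIN_DEFAULT,
) -> LocusReport:
    """Per-locus summary: index accessibility, ranked candidates, links.

    Candidates are the locus's accessible variants ranked by criteria met,
    ties broken by |allelic log2FC| (descending) then rsid. The report flags
    the pattern where every index variant is inaccessible but a non-index
    variant is prioritized.
    """
    locus_variants = [v for v in catalog if v.locus_id == locus_id]
    if not locus_variants:
        raise ValidationError(f"unknown locus {locus_id}")
    allelic_log2fc = allelic_log2fc or {}
    linked_genes = linked_genes or {}
    accessible = set(matrix.index)
    index_rows = [
        {"rsid": v.rsid, "accessible": v.rsid in accessible}
        for v in locus_variants
        if v.is_index
    ]
    cands = []
    for v in locus_variants:
        if v.rsid not in accessible:
            continue
        n_met = int(matrix.loc[v.rsid, "n_criteria_met"])
        cands.append(
            {
                "rsid": v.rsid,
                "n_criteria_met": n_met,
                "prioritized": n_met >= k_min,
                "abs_allelic_log2fc": abs(allelic_log2fc.get(v.rsid, 0.0)),
                "criteria": [
                    c for c in CRITERIA if bool(matrix.loc[v.rsid, c])
                ],
                "linked_genes": {
                    k: sorted(vv)
                    for k, vv in linked_genes.get(v.rsid, {}).items()
                },
            }
        )
    cands.sort(
        key=lambda d: (-d["n_criteria_met"], -d["abs_allelic_log2fc"], d["rsid"])
    )
    prioritized = [c["rsid"] for c in cands if c["prioritized"]]
    flag = bool(
        index_rows
        and not any(r["accessible"] for r in index_rows)
        and any(
            p not in {r["rsid"] for r in index_rows} for p in prioritized
        )
    )
    return LocusReport(locus_id, index_rows, cands, prioritized, flag)
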