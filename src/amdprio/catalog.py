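"""Risk-variant catalog construction: LD expansion, credible-set merging,
consequence classification, AlphaMissense binning and summary arithmetic.

The catalog starts from GWAS index variants. LD expansion collects every
variant whose genotype dosages are correlated (R^2 above a strict threshold,
default 0.5) with at least one index variant; the union with an externally
supplied credible set, deduplicated on (chrom, pos, ref, alt), forms the final
catalog. Each variant is classed as protein-altering, synonymous or noncoding,
and missense variants carry an AlphaMissense pathogenicity bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ValidationError, VariantRecord


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def compute_r2(dosages_a: Sequence[float], dosages_b: Sequence[float]) -> float:
    """Squared sample correlation of two dosage vectors."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("dosage vectors must be equal-length, size >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("R^2 undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LDHit:
    """A variant retained by LD expansion, with its best index assignment."""

    rsid: str
    best_r2: float
    index_rsid: str
    locus_id: Optional[int]


def ld_expand(
    index_variants: Sequence[Tuple[str, Optional[int]]],
    genotypes: pd.DataFrame,
    r2_threshold: float = 0.5,
    substitutions: Optional[Dict[str, str]] = None,
) -> List[LDHit]:
    """Expand index variants to all LD partners with R^2 strictly above threshold.

    Parameters
    ----------
    index_variants : list of (rsid, locus_id)
        GWAS lead variants. An index absent from the genotype matrix must have
        an entry in ``substitutions`` (caller-supplied replacement rsid).
    genotypes : DataFrame, variants x individuals, dosage values 0/1/2.
    r2_threshold : retained iff R^2 > threshold (strict) to >= 1 index.

    Returns one ``LDHit`` per retained variant, annotated with the maximal R^2
    and the locus of the index achieving it. Index variants themselves are
    always included (R^2 = 1 to self by convention, independent of threshold).
    """
    substitutions = substitutions or {}
    resolved: List[Tuple[str, Optional[int]]] = []
    for rsid, locus in index_variants:
        if rsid not in genotypes.index:
            sub = substitutions.get(rsid)
            if sub is None or sub not in genotypes.index:
                raise ValidationError(
                    f"index variant {rsid} absent from genotypes and no "
                    "substitute provided"
                )
            rsid = sub
        resolved.append((rsid, locus))

    geno = genotypes.to_numpy(dtype=float)
    variant_ids = list(genotypes.index)
    # standardize rows; constant rows get NaN correlation -> never pass
    mu = geno.mean(axis=1, keepdims=True)
    sd = geno.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (geno - mu) / sd
    n = geno.shape[1]

    best: Dict[str, LDHit] = {}
    for idx_rsid, locus in resolved:
        row = genotypes.index.get_loc(idx_rsid)
        if sd[row, 0] == 0:
            raise ValidationError(
                f"index variant {idx_rsid} is monomorphic; R^2 undefined"
            )
        with np.errstate(invalid="ignore"):
            r = z @ z[row] / n
        r2 = r * r
        for i, rsid in enumerate(variant_ids):
            if rsid == idx_rsid:
                continue
            if np.isnan(r2[i]) or r2[i] <= r2_threshold:
                continue
            prev = best.get(rsid)
            if prev is None or r2[i] > prev.best_r2:
                best[rsid] = LDHit(rsid, float(r2[i]), idx_rsid, locus)
    for idx_rsid, locus in resolved:
        best[idx_rsid] = LDHit(idx_rsid, 1.0, idx_rsid, locus)
    return sorted(best.values(), key=lambda h: h.rsid)


def merge_credible_set(
    expanded: Sequence[VariantRecord], credible_set: Sequence[VariantRecord]
) -> List[VariantRecord]:
    """Union of LD-expanded and credible-set variants, keyed on alleles.

    The union is keyed on (chrom, pos, ref, alt); when both lists carry the
    same key, the expanded list's record wins (it holds the R^2 annotation).
    The same rsid appearing with different alleles is a conflict.
    """
    merged: Dict[Tuple, VariantRecord] = {}
    rsid_key: Dict[str, Tuple] = {}

    def _add(v: VariantRecord, overwrite: bool) -> None:
        key = v.allele_key()
        if v.rsid in rsid_key and rsid_key[v.rsid] != key:
            raise ValidationError(
                f"rsid {v.rsid} appears with conflicting alleles/positions"
            )
        rsid_key[v.rsid] = key
        if overwrite or key not in merged:
            merged[key] = v

    for v in expanded:
        _add(v, overwrite=True)
    for v in credible_set:
        _add(v, overwrite=False)
    return sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.rsid))


# Controlled vocabulary of raw consequence labels -> the three catalog classes.
# Splice-altering labels route to protein_altering: they change the protein
# product even though the base change sits outside the codon (judgment call,
# see docs/methods.md).
CONSEQUENCE_VOCABULARY: Dict[str, str] = {
    "missense": "protein_altering",
    "stop_gained": "protein_altering",
    "stop_lost": "protein_altering",
    "start_lost": "protein_altering",
    "frameshift": "protein_altering",
    "inframe_insertion": "protein_altering",
    "inframe_deletion": "protein_altering",
    "splice_acceptor": "protein_altering",
    "splice_donor": "protein_altering",
    "splice_region": "protein_altering",
    "synonymous": "synonymous",
    "intronic": "noncoding",
    "intergenic": "noncoding",
    "UTR": "noncoding",
    "5_prime_UTR": "noncoding",
    "3_prime_UTR": "noncoding",
    "upstream": "noncoding",
    "downstream": "noncoding",
    "regulatory": "noncoding",
    "non_coding_transcript": "noncoding",
    # already-classified labels are accepted unchanged (idempotence)
    "protein_altering": "protein_altering",
    "noncoding": "noncoding",
}


def classify_consequence(raw_label: str) -> str:
    """Map a raw consequence label to {protein_altering, synonymous, noncoding}.

    Unknown labels raise; nothing is ever silently called noncoding.
    """
    try:
        return CONSEQUENCE_VOCABULARY[raw_label]
    except KeyError:
        raise ValidationError(
            f"unknown consequence label {raw_label!r}; known labels: "
            f"{sorted(CONSEQUENCE_VOCABULARY)}"
        ) from None


def alphamissense_bin(am_score: float) -> str:
    """AlphaMissense pathogenicity bin.

    Likely benign below 0.34, likely pathogenic above 0.565, ambiguous in
    between (both inequalities strict).
    """
    if not 0.0 <= am_score <= 1.0:
        raise ValidationError(f"am_score must be in [0,1], got {am_score}")
    if am_score < 0.34:
        return "likely_benign"
    if am_score > 0.565:
        return "likely_pathogenic"
    return "ambiguous"


@dataclass
class CatalogSummary:
    n_total: int
    n_noncoding_or_synonymous: int
    pct_noncoding_or_synonymous: float
    n_protein_altering: int
    n_snps: int
    pct_snps: float
    am_class_counts: Dict[str, int] = field(default_factory=dict)
    n_am_scored: int = 0
    pct_am_likely_benign: Optional[float] = None


def summarize_catalog(variants: Sequence[VariantRecord]) -> CatalogSummary:
    """Headline counts/percentages for a variant catalog.

    Percentages are 100 * count / total rounded half-away-from-zero to one
    decimal, matching how such figures are conventionally printed.
    """
    variants = list(variants)
    if not variants:
        raise ValidationError("cannot summarize an empty catalog")
    n = len(variants)
    n_noncod = sum(v.consequence in {"noncoding", "synonymous"} for v in variants)
    n_prot = sum(v.consequence == "protein_altering" for v in variants)
    n_snps = sum(v.is_snp for v in variants)
    am_counts = {"likely_benign": 0, "ambiguous": 0, "likely_pathogenic": 0}
    n_scored = 0
    for v in variants:
        if v.am_score is not None:
            n_scored += 1
            am_counts[alphamissense_bin(v.am_score)] += 1
    pct_benign = (
        round_half_away(100.0 * am_counts["likely_benign"] / n_scored)
        if n_scored
        else None
    )
    return CatalogSummary(
        n_total=n,
        n_noncoding_or_synonymous=n_noncod,
        pct_noncoding_or_synonymous=round_half_away(100.0 * n_noncod / n),
        n_protein_altering=n_prot,
        n_snps=n_snps,
        pct_snps=round_half_away(100.0 * n_snps / n),
        am_class_counts=am_counts,
        n_am_scored=n_scored,
        pct_am_likely_benign=pct_benign,
    )
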