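"""Allele-specific STARR-seq analysis.

Amplicon reads carry an insert (the oligo, one allele of a SNP in fixed
genomic context), a constant adapter and a 10-nt degenerate barcode. The
pipeline parses reads, counts unique barcodes per oligo per sample, discards
oligos with <5 barcodes in any replicate, size-factor normalizes
(median-of-ratios), calls enhancer oligos against the input library
(|log2FC| > 0.585, BH-adjusted p < 0.05), tests allelic activity per SNP
(paired replicate log-ratios, moderated one-sample t with empirical-Bayes
variance shrinkage), and designates functional SNPs as significant allelic
effects inside enhancers exceeding the control-SNP 80th-percentile |log2FC|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import ValidationError
from .effects import bh_adjust

ADAPTER = "GCTAGCCATTGCGTGTAGAG"
BARCODE_LENGTH = 10
MIN_BARCODES = 5
ENHANCER_LOG2FC = float(np.log2(1.5))  # 0.585
ENHANCER_PADJ = 0.05
FUNCTIONAL_PADJ = 0.05
CONTROL_PERCENTILE = 0.80
LOG_PSEUDOCOUNT = 0.5


@dataclass
class SampleInfo:
    """Role of one sequencing library: input plasmid or output per condition."""

    sample_id: str
    role: str  # "input" | "output"
    condition: Optional[str] = None  # "naive" | "complement" for outputs

    def __post_init__(self):
        if self.role not in {"input", "output"}:
            raise ValidationError(f"role must be input/output, got {self.role}")


class OligoCounts:
    """Unique-barcode counts per oligo (SNP x allele) per sample."""

    def __init__(
        self,
        counts: pd.DataFrame,
        oligo_meta: pd.DataFrame,
        samples: Sequence[SampleInfo],
    ):
        # counts: index oligo_id, columns sample_id, integer values
        # oligo_meta: oligo_id, snp_id, allele (ref/alt), is_control
        if not (counts.to_numpy() >= 0).all():
            raise ValidationError("counts must be nonnegative")
        if not np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
            raise ValidationError("counts must be integer-valued")
        self.counts = counts.astype(float)
        self.oligo_meta = oligo_meta.set_index("oligo_id") if (
            oligo_meta.index.name != "oligo_id"
        ) else oligo_meta
        self.samples = {s.sample_id: s for s in samples}
        pairs = self.oligo_meta.groupby("snp_id")["allele"].nunique()
        if (pairs != 2).any():
            bad = list(pairs.index[pairs != 2])
            raise ValidationError(f"SNPs without exactly 2 allele rows: {bad}")

    def sample_ids(self, role: str, condition: Optional[str] = None) -> List[str]:
        return [
            sid
            for sid, s in self.samples.items()
            if s.role == role and (condition is None or s.condition == condition)
        ]

    def subset(self, oligo_ids: Sequence[str]) -> "OligoCounts":
        ids = list(oligo_ids)
        return OligoCounts(
            self.counts.loc[ids],
            self.oligo_meta.loc[ids].reset_index(),
            list(self.samples.values()),
        )


def parse_amplicon(
    read_sequence: str,
    oligo_lookup: Mapping[str, str],
    adapter: str = ADAPTER,
    barcode_length: int = BARCODE_LENGTH,
):
    """Parse one merged amplicon read into (oligo_id, barcode).

    The read layout is insert + adapter + barcode. Returns the tuple on
    success or a rejection reason string: ``no_adapter`` (adapter absent),
    ``bad_barcode_length`` (sequence after the adapter is not exactly 10 nt),
    ``unknown_insert`` (insert not in the oligo reference).
    """
    pos = read_sequence.find(adapter)
    if pos < 0:
        return "no_adapter"
    barcode = read_sequence[pos + len(adapter) :]
    if len(barcode) != barcode_length:
        return "bad_barcode_length"
    insert = read_sequence[:pos]
    oligo_id = oligo_lookup.get(insert)
    if oligo_id is None:
        return "unknown_insert"
    return oligo_id, barcode


def count_unique_barcodes(
    parsed: Iterable[Tuple[str, str]]
) -> Dict[str, int]:
    """Distinct barcodes per oligo; PCR duplicates (same pair) count once."""
    seen: Dict[str, Set[str]] = {}
    for oligo_id, barcode in parsed:
        seen.setdefault(oligo_id, set()).add(barcode)
    return {oligo: len(bcs) for oligo, bcs in seen.items()}


def qc_filter_oligos(
    counts: OligoCounts, min_barcodes: int = MIN_BARCODES
) -> Tuple[Set[str], Set[str]]:
    """Oligos with >= min_barcodes in EVERY replicate, paired by SNP.

    Returns (retained oligo IDs, retained SNP IDs). A SNP survives only if
    both of its allele oligos survive; a surviving oligo whose partner failed
    is excluded from allelic analysis with its SNP.
    """
    ok = (counts.counts >= min_barcodes).all(axis=1)
    kept_oligos = set(counts.counts.index[ok])
    meta = counts.oligo_meta
    kept_snps = set()
    for snp_id, grp in meta.groupby("snp_id"):
        if set(grp.index) <= kept_oligos:
            kept_snps.add(snp_id)
    paired_oligos = {
        oid for oid in kept_oligos if meta.loc[oid, "snp_id"] in kept_snps
    }
    return paired_oligos, kept_snps


def size_factor_normalize(
    counts: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization.

    Size factor s_j = median over oligos (with positive counts in all
    samples) of count_ij / geometric-mean_i; normalized count = count / s_j.
    """
    if counts.shape[1] < 2:
        raise ValidationError("need >= 2 samples to normalize")
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError("no oligo has nonzero counts in every sample")
    ref = np.exp(np.log(mat[all_pos]).mean(axis=1, keepdims=True))
    ratios = mat[all_pos] / ref
    factors = np.median(ratios, axis=0)
    normalized = counts / factors
    return normalized, pd.Series(factors, index=counts.columns)


def _squeeze_var(s2: np.ndarray, df: float) -> Tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-feature variances (limma-style).

    Models s2 ~ scaled F; estimates prior df d0 and prior variance s0^2 by
    matching moments of log(s2), then returns posterior variances
    (d*s2 + d0*s0^2)/(d+d0) and the total df d+d0. Infinite d0 (no excess
    spread) shrinks fully to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        pooled = float(s2.mean()) if s2.size else 0.0
        return np.full_like(s2, pooled), float("inf")
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        s0_sq = float(np.exp(e_mean))
        post = np.full_like(s2, s0_sq)
        return post, float("inf")
    # solve trigamma(d0/2) = excess for d0 by Newton iteration
    x = 0.5 + 1.0 / excess
    for _ in range(50):
        tri = special.polygamma(1, x)
        tetra = special.polygamma(2, x)
        delta = tri * (1.0 - tri / excess) / tetra
        x = max(x + delta, 1e-8)
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_sq = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    post = (df * s2 + d0 * s0_sq) / (df + d0)
    return post, df + d0


def moderated_one_sample_t(log_ratios: np.ndarray) -> pd.DataFrame:
    """Moderated one-sample t-test of each row's replicate log-ratios vs 0.

    Residual variances are shrunk toward a prior estimated across rows;
    two-sided p-values from the t distribution with augmented df.
    """
    x = np.asarray(log_ratios, dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValidationError("need >= 2 replicates")
    mean = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    df = n - 1
    post_var, total_df = _squeeze_var(s2, df)
    se = np.sqrt(np.maximum(post_var, 1e-300) / n)
    tstat = mean / se
    if np.isinf(total_df):
        pvals = 2 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2 * stats.t.sf(np.abs(tstat), df=total_df)
    return pd.DataFrame(
        {"estimate": mean, "t": tstat, "p_value": pvals, "df": total_df}
    )


def _normalized_log2(
    counts: OligoCounts,
) -> Tuple[pd.DataFrame, pd.Series]:
    normalized, factors = size_factor_normalize(counts.counts)
    return np.log2(normalized + LOG_PSEUDOCOUNT), factors


def call_enhancers(
    counts: OligoCounts,
    condition: str,
    log2fc_min: float = ENHANCER_LOG2FC,
    padj_max: float = ENHANCER_PADJ,
    enrichment_only: bool = False,
) -> pd.DataFrame:
    """Enhancer calls per SNP: combined ref+alt output vs input activity.

    Ref and alt raw counts are summed per SNP, the combined matrix is
    size-factor normalized, and each output replicate's log2 ratio to the
    normalized-input reference (geometric mean over input replicates) feeds a
    moderated one-sample t-test. Enhancers have |log2FC| > log2fc_min and
    BH-adjusted p < padj_max; ``enrichment_only`` restricts to positive
    log2FC, and depleted oligos are flagged either way.
    """
    out_cols = counts.sample_ids("output", condition)
    in_cols = counts.sample_ids("input")
    if len(out_cols) < 2:
        raise ValidationError("need >= 2 output replicates")
    if not in_cols:
        raise ValidationError("need >= 1 input replicate")
    combined = counts.counts.groupby(
        counts.oligo_meta["snp_id"].reindex(counts.counts.index)
    ).sum()
    normalized, _ = size_factor_normalize(combined[in_cols + out_cols])
    log2n = np.log2(normalized + LOG_PSEUDOCOUNT)
    if len(in_cols) == len(out_cols):
        # pair output replicate r with input replicate r so input sampling
        # noise enters the replicate-wise variance
        ratios = pd.DataFrame(
            log2n[out_cols].to_numpy() - log2n[in_cols].to_numpy(),
            index=log2n.index,
        )
    else:
        input_ref = log2n[in_cols].mean(axis=1)
        ratios = log2n[out_cols].sub(input_ref, axis=0)
    res = moderated_one_sample_t(ratios.to_numpy())
    res.index = combined.index
    res = res.rename(columns={"estimate": "log2fc"})
    res["padj"] = bh_adjust(res["p_value"].to_numpy())
    effect = res["log2fc"] if enrichment_only else res["log2fc"].abs()
    res["is_enhancer"] = (effect > log2fc_min) & (res["padj"] < padj_max)
    res["depleted"] = res["is_enhancer"] & (res["log2fc"] < 0)
    res["snp_id"] = res.index
    is_control = (
        counts.oligo_meta.groupby("snp_id")["is_control"].first().astype(bool)
    )
    res["is_control"] = is_control.reindex(res.index).to_numpy()
    return res.reset_index(drop=True)


def allelic_activity(counts: OligoCounts, condition: str) -> pd.DataFrame:
    """Per-SNP allelic activity: alt vs ref, paired by output replicate.

    For each output replicate the log2 ratio of normalized alt to normalized
    ref counts is formed; a moderated one-sample t-test against zero with
    empirical-Bayes variance shrinkage gives the p-value, BH-adjusted across
    SNPs.
    """
    out_cols = counts.sample_ids("output", condition)
    if len(out_cols) < 2:
        raise ValidationError("need >= 2 output replicates")
    in_cols = counts.sample_ids("input")
    log2n, _ = _normalized_log2(counts)
    meta = counts.oligo_meta
    snp_ids = sorted(meta["snp_id"].unique())
    ref_rows, alt_rows = [], []
    for snp in snp_ids:
        grp = meta[meta["snp_id"] == snp]
        ref_rows.append(grp.index[grp["allele"] == "ref"][0])
        alt_rows.append(grp.index[grp["allele"] == "alt"][0])
    ratios = (
        log2n.loc[alt_rows, out_cols].to_numpy()
        - log2n.loc[ref_rows, out_cols].to_numpy()
    )
    res = moderated_one_sample_t(ratios)
    res.insert(0, "snp_id", snp_ids)
    res = res.rename(columns={"estimate": "log2fc"})
    res["padj"] = bh_adjust(res["p_value"].to_numpy())
    is_control = meta.groupby("snp_id")["is_control"].first().astype(bool)
    res["is_control"] = is_control.reindex(snp_ids).to_numpy()
    res["condition"] = condition
    return res


def empirical_threshold(
    control_abs_log2fc: Sequence[float], q: float = CONTROL_PERCENTILE
) -> float:
    """q-th percentile of control |log2FC| by linear interpolation.

    Uses the h = q*(n-1) convention (numpy's default 'linear' method).
    """
    vals = np.asarray(list(control_abs_log2fc), dtype=float)
    if vals.size == 0:
        raise ValidationError("need >= 1 control value")
    if vals.size < 10:
        warnings.warn("fewer than 10 control SNPs; threshold is noisy", stacklevel=2)
    return float(np.percentile(vals, q * 100.0, method="linear"))


def call_functional_snps(
    allelic_results: pd.DataFrame,
    enhancer_snps: Set[str],
    threshold: float,
    padj_max: float = FUNCTIONAL_PADJ,
) -> Set[str]:
    """Functional SNPs: in an enhancer, adjusted p < 0.05, |log2FC| > threshold."""
    res = allelic_results
    mask = (
        res["snp_id"].isin(enhancer_snps)
        & (res["padj"] < padj_max)
        & (res["log2fc"].abs() > threshold)
    )
    return set(res.loc[mask, "snp_id"])


def qq_abs_log2fc(
    test_values: Sequence[float],
    control_values: Sequence[float],
    n_points: int = 357,
) -> pd.DataFrame:
    """Paired quantiles of |log2FC| in test vs control SNPs (QQ table).

    Quantiles are evaluated at probabilities (k - 0.5)/n_points; identical
    distributions fall on the diagonal.
    """
    test = np.abs(np.asarray(list(test_values), dtype=float))
    ctrl = np.abs(np.asarray(list(control_values), dtype=float))
    if test.size == 0 or ctrl.size == 0:
        raise ValidationError("both groups must be non-empty")
    probs = (np.arange(1, n_points + 1) - 0.5) / n_points
    return pd.DataFrame(
        {
            "prob": probs,
            "control_quantile": np.quantile(ctrl, probs),
            "test_quantile": np.quantile(test, probs),
        }
    )
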