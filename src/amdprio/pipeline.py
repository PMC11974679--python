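"""End-to-end orchestration: synthetic data in, prioritized variants out.

A single :class:`RunConfig` carries every stage threshold (with the
documented defaults) plus the synthetic-study generator block and a seed.
``run_pipeline`` writes a report directory containing the catalog, the
criteria matrix, the prioritized set, locus reports, summaries, the truth
ledger and a structured log; re-running with the same config reproduces the
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import containing_peaks, intersect_variants_peaks, variant_enrichment
from .catalog import summarize_catalog
from .connectome import (
    abc_scores,
    coaccessibility_links,
    connection_summaries,
    loop_overlap,
    peak_gene_links,
    promoter_coaccessible,
)
from .core import PeakSet
from .effects import call_high_effect, score_variants
from .io import write_json, write_variant_table
from .prioritize import (
    CRITERIA,
    build_criteria_matrix,
    call_prioritized,
    eqtl_significant,
    locus_report,
    upset_summary,
)
from .simulate import StudyConfig, SyntheticStudy, simulate_study
from .starrseq import (
    allelic_activity,
    call_enhancers,
    call_functional_snps,
    empirical_threshold,
    qc_filter_oligos,
)


@dataclass
class Thresholds:
    """Every stage threshold, with the documented defaults."""

    r2_threshold: float = 0.5
    correlation_cutoff: float = 0.3
    max_peak_gene_dist: int = 250_000
    coaccessibility_window: int = 250_000
    abc_score_min: float = 0.025
    abc_min_tss_dist: int = 500
    abc_max_candidate_dist: int = 1_000_000
    starr_fc_threshold: float = 1.5
    starr_padj_max: float = 0.05
    starr_control_percentile: float = 0.80
    starr_min_barcodes: int = 5
    effect_log2fc_min: float = 0.25
    effect_fdr_max: float = 0.01
    eqtl_fdr_max: float = 0.05
    k_min: int = 3


@dataclass
class RunConfig:
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    synthetic: StudyConfig = field(default_factory=StudyConfig)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: Dict) -> "RunConfig":
        thr = Thresholds(**d.get("thresholds", {}))
        syn_d = dict(d.get("synthetic", {}))
        for key in ("cell_types", "effect_cell_types", "conditions"):
            if key in syn_d:
                syn_d[key] = tuple(syn_d[key])
        syn = StudyConfig(**syn_d)
        return RunConfig(seed=int(d.get("seed", 0)), thresholds=thr, synthetic=syn)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(config: RunConfig) -> List[str]:
    """Every violated constraint, reported with its config key."""
    errors: List[str] = []
    t = config.thresholds
    if not 0.0 <= t.r2_threshold <= 1.0:
        errors.append("thresholds.r2_threshold: must be in [0,1]")
    if not -1.0 <= t.correlation_cutoff <= 1.0:
        errors.append("thresholds.correlation_cutoff: must be in [-1,1]")
    if t.max_peak_gene_dist <= 0:
        errors.append("thresholds.max_peak_gene_dist: must be positive")
    if not 0.0 <= t.abc_score_min <= 1.0:
        errors.append("thresholds.abc_score_min: must be in [0,1]")
    if t.abc_min_tss_dist < 0:
        errors.append("thresholds.abc_min_tss_dist: must be >= 0")
    if t.starr_fc_threshold <= 0:
        errors.append("thresholds.starr_fc_threshold: must be positive")
    if not 0.0 < t.starr_padj_max <= 1.0:
        errors.append("thresholds.starr_padj_max: must be in (0,1]")
    if not 0.0 <= t.starr_control_percentile <= 1.0:
        errors.append("thresholds.starr_control_percentile: must be in [0,1]")
    if t.starr_min_barcodes < 0:
        errors.append("thresholds.starr_min_barcodes: must be >= 0")
    if not 0.0 < t.eqtl_fdr_max <= 1.0:
        errors.append("thresholds.eqtl_fdr_max: must be in (0,1]")
    if t.k_min < 0:
        errors.append("thresholds.k_min: must be >= 0")
    s = config.synthetic
    if s.n_loci < 1:
        errors.append("synthetic.n_loci: must be >= 1")
    if not 0.3 < s.link_corr <= 1.0:
        errors.append("synthetic.link_corr: must be in (0.3, 1]")
    if s.n_reps < 2:
        errors.append("synthetic.n_reps: must be >= 2")
    if s.n_individuals < 20:
        errors.append("synthetic.n_individuals: must be >= 20")
    return errors


@dataclass
class StudyResults:
    """All stage outputs of one analysis run."""

    catalog_summary: object
    accessible_variants: List[str]
    criteria_matrix: pd.DataFrame
    prioritized: Set[str]
    pct_of_accessible: float
    pct_of_catalog: Optional[float]
    upset: Dict
    promoter_pairs: Set[Tuple[str, str]]
    promoter_summary: Dict
    peak_gene_pairs: Set[Tuple[str, str]]
    loop_pairs: Set[Tuple[str, str]]
    abc_pairs: Set[Tuple[str, str]]
    enhancer_snps: Set[str]
    functional_snps: Set[str]
    eqtl_snps: Set[str]
    high_effect: Set[str]
    allelic_results: pd.DataFrame
    enhancer_results: pd.DataFrame
    effect_results: pd.DataFrame
    starr_threshold: float
    n_qc_snps: int
    n_starr_snps: int
    enrichment: Dict
    connection_summary: Dict
    locus_reports: List
    timings: Dict[str, float] = field(default_factory=dict)


def analyze_study(
    study: SyntheticStudy, thresholds: Optional[Thresholds] = None
) -> StudyResults:
    """Run every analysis stage on a (synthetic or assembled) study."""
    t = thresholds or Thresholds()
    timings: Dict[str, float] = {}

    def _tick(name, t0):
        timings[name] = round(time.perf_counter() - t0, 3)
        return time.perf_counter()

    t0 = time.perf_counter()
    catalog_summary = summarize_catalog(study.catalog)

    # accessibility of catalog variants in RPE/choroid cell types
    _, n_acc = intersect_variants_peaks(study.catalog, study.peaksets)
    accessible = sorted(r for r, n in n_acc.items() if n > 0)
    variant_peaks = containing_peaks(study.catalog, study.peaksets)
    t0 = _tick("accessibility", t0)

    # enhancer-linking strategies
    links = coaccessibility_links(
        study.accessibility,
        study.union_peaks,
        window_bp=t.coaccessibility_window,
        cutoff=t.correlation_cutoff,
    )
    promoter_pairs, promoter_summary = promoter_coaccessible(links, study.genes)
    t0 = _tick("coaccessibility", t0)

    pg_links = peak_gene_links(
        study.accessibility,
        study.expression,
        study.union_peaks,
        study.genes,
        max_dist=t.max_peak_gene_dist,
        cutoff=t.correlation_cutoff,
    )
    peak_gene_pairs = {(l.peak.key(), l.gene_id) for l in pg_links}
    t0 = _tick("peak_gene", t0)

    variant_positions = {v.rsid: (v.chrom, v.pos) for v in study.catalog}
    loop_res = loop_overlap(
        study.loops,
        study.genes,
        variant_positions=variant_positions,
        peaksets=study.peaksets,
    )
    t0 = _tick("loops", t0)

    abc = abc_scores(
        study.union_peaks,
        study.atac_signal,
        study.h3k27ac_signal,
        study.contact_map,
        study.genes,
        score_min=t.abc_score_min,
        min_tss_dist=t.abc_min_tss_dist,
        max_candidate_dist=t.abc_max_candidate_dist,
    )
    abc_pairs = {(c.element.key(), c.gene_id) for c in abc}
    t0 = _tick("abc", t0)

    # STARR-seq
    kept_oligos, kept_snps = qc_filter_oligos(
        study.starr_counts, min_barcodes=t.starr_min_barcodes
    )
    n_total_snps = study.starr_counts.oligo_meta["snp_id"].nunique()
    sub = study.starr_counts.subset(sorted(kept_oligos))
    condition = study.config.conditions[0]
    enh = call_enhancers(
        sub,
        condition,
        log2fc_min=float(np.log2(t.starr_fc_threshold)),
        padj_max=t.starr_padj_max,
    )
    allelic = allelic_activity(sub, condition)
    controls = allelic.loc[allelic["is_control"], "log2fc"].abs()
    threshold = empirical_threshold(controls, q=t.starr_control_percentile)
    enhancer_snp_all = set(enh.loc[enh["is_enhancer"], "snp_id"])
    functional_all = call_functional_snps(
        allelic, enhancer_snp_all, threshold, padj_max=t.starr_padj_max
    )
    is_ctrl = study.starr_counts.oligo_meta.groupby("snp_id")["is_control"].first()
    enhancer_snps = {s for s in enhancer_snp_all if not is_ctrl.get(s, False)}
    functional_snps = {s for s in functional_all if not is_ctrl.get(s, False)}
    t0 = _tick("starrseq", t0)

    # predicted variant effects
    effect_results = score_variants(study.predicted_counts)
    high_effect = call_high_effect(
        effect_results, fc_min=t.effect_log2fc_min, fdr_max=t.effect_fdr_max
    )
    t0 = _tick("variant_effect", t0)

    eqtl_snps = eqtl_significant(study.eqtl_table, fdr_max=t.eqtl_fdr_max)

    # integration
    matrix = build_criteria_matrix(
        accessible,
        variant_peaks,
        promoter_pairs,
        peak_gene_pairs,
        loop_res.linked_pairs,
        abc_pairs,
        enhancer_snps,
        functional_snps,
        eqtl_snps,
        high_effect,
    )
    prio = call_prioritized(
        matrix,
        k_min=t.k_min,
        n_catalog_noncoding=catalog_summary.n_noncoding_or_synonymous,
    )
    upset = upset_summary(matrix)
    t0 = _tick("prioritize", t0)

    # auxiliary summaries
    tissue_sets = dict(study.baseline_peaksets)
    tissue_sets["RPE_choroid"] = PeakSet(
        "RPE_choroid",
        {iv for ps in study.peaksets.values() for iv in ps},
    )
    enrichment = {
        name: dataclasses.asdict(res)
        for name, res in variant_enrichment(
            study.catalog,
            tissue_sets,
            ["RPE_choroid"],
            list(study.baseline_peaksets),
        ).items()
    }
    for entry in enrichment.values():
        entry.pop("tissue", None)
    conn_summary = connection_summaries(
        {
            "coaccessibility": promoter_pairs,
            "peak_gene": peak_gene_pairs,
            "hichip": loop_res.linked_pairs,
            "abc": abc_pairs,
        }
    )
    allelic_map = dict(zip(allelic["snp_id"], allelic["log2fc"]))
    reports = [
        locus_report(
            locus_id,
            study.catalog,
            matrix,
            allelic_log2fc=allelic_map,
            k_min=t.k_min,
        )
        for locus_id in sorted({v.locus_id for v in study.catalog})
    ]
    _tick("summaries", t0)

    return StudyResults(
        catalog_summary=catalog_summary,
        accessible_variants=accessible,
        criteria_matrix=matrix,
        prioritized=prio.prioritized,
        pct_of_accessible=prio.pct_of_accessible,
        pct_of_catalog=prio.pct_of_catalog,
        upset=upset,
        promoter_pairs=promoter_pairs,
        promoter_summary=promoter_summary,
        peak_gene_pairs=peak_gene_pairs,
        loop_pairs=loop_res.linked_pairs,
        abc_pairs=abc_pairs,
        enhancer_snps=enhancer_snps,
        functional_snps=functional_snps,
        eqtl_snps=eqtl_snps,
        high_effect=high_effect,
        allelic_results=allelic,
        enhancer_results=enh,
        effect_results=effect_results,
        starr_threshold=threshold,
        n_qc_snps=len(kept_snps),
        n_starr_snps=int(n_total_snps),
        enrichment=enrichment,
        connection_summary=conn_summary,
        locus_reports=reports,
        timings=timings,
    )


def run_pipeline(config: RunConfig, out_dir) -> StudyResults:
    """Simulate, analyze and write the report directory."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    config_hash = hashlib.sha256(config_yaml.encode()).hexdigest()[:16]

    study = simulate_study(config.synthetic, seed=config.seed)
    results = analyze_study(study, config.thresholds)

    write_variant_table(study.catalog, out / "catalog.tsv")
    results.criteria_matrix.reset_index().to_csv(
        out / "criteria_matrix.tsv", sep="\t", index=False
    )
    pd.DataFrame({"rsid": sorted(results.prioritized)}).to_csv(
        out / "prioritized.tsv", sep="\t", index=False
    )
    write_json(results.upset, out / "upset.json")
    write_json(study.truth.to_dict(), out / "truth_ledger.json")
    write_json(
        {
            "catalog": dataclasses.asdict(results.catalog_summary),
            "n_accessible": len(results.accessible_variants),
            "n_prioritized": len(results.prioritized),
            "pct_of_accessible": results.pct_of_accessible,
            "pct_of_catalog": results.pct_of_catalog,
            "starr": {
                "n_snps": results.n_starr_snps,
                "n_qc_snps": results.n_qc_snps,
                "n_enhancer_snps": len(results.enhancer_snps),
                "n_functional_snps": len(results.functional_snps),
                "control_threshold": results.starr_threshold,
            },
            "enrichment": results.enrichment,
            "connections": results.connection_summary,
        },
        out / "summary.json",
    )
    write_json(
        [dataclasses.asdict(r) for r in results.locus_reports],
        out / "locus_reports.json",
    )
    log_lines = [
        f"amdprio {__version__}",
        f"config_hash {config_hash}",
        f"seed {config.seed}",
        f"n_catalog {len(study.catalog)}",
        f"n_accessible {len(results.accessible_variants)}",
        f"n_prioritized {len(results.prioritized)}",
    ] + [f"stage {name} {sec}s" for name, sec in results.timings.items()]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
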