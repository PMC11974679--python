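"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of its arguments including ``seed``; every
generated dataset passes the corresponding reader's validation after a
write/read round trip. The toy genome is two chromosomes of 10 Mb — large
enough to exercise cross-chromosome logic while staying desk-scale.

``simulate_study`` composes the individual generators into one coherent
scenario: an LD-expanded variant catalog, a chromatin atlas with planted
peak-gene regulatory links, loops and contacts, STARR-seq barcode counts with
planted enhancers and allelic effects, predicted-count variant effects and an
eQTL table — with a truth ledger recording which of the eight prioritization
criteria each accessible variant was planted to satisfy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import (
    ContactMap,
    FeatureMatrix,
    GeneModel,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
    ValidationError,
    VariantRecord,
)
from .starrseq import OligoCounts, SampleInfo

TOY_GENOME: Dict[str, int] = {"chr1": 10_000_000, "chr2": 10_000_000}

CRITERION_NAMES = {
    1: "coaccessible_with_promoter",
    2: "accessibility_correlated_with_gene",
    3: "hichip_linked",
    4: "abc_connected",
    5: "in_starrseq_enhancer",
    6: "functional_snp",
    7: "significant_eqtl",
    8: "chrombpnet_high_effect",
}


class GenerationError(ValueError):
    pass


@dataclass
class TruthLedger:
    """Ground truth planted by the generators, keyed by generated IDs."""

    seed: int
    true_ld_partners: Dict[str, Dict[str, float]] = field(default_factory=dict)
    true_peak_gene_links: Set[Tuple[str, str]] = field(default_factory=set)
    true_promoter_links: Set[Tuple[str, str]] = field(default_factory=set)
    true_loops: Set[Tuple[str, int, int]] = field(default_factory=set)
    true_enhancer_oligos: Dict[str, float] = field(default_factory=dict)
    true_allelic_effects: Dict[str, float] = field(default_factory=dict)
    true_high_effect_variants: Dict[str, Dict[str, float]] = field(
        default_factory=dict
    )
    true_eqtl_variants: Set[str] = field(default_factory=set)
    accessible_variants: Set[str] = field(default_factory=set)
    planted_criteria: Dict[str, Set[str]] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {
            "seed": self.seed,
            "true_ld_partners": self.true_ld_partners,
            "true_peak_gene_links": sorted(map(list, self.true_peak_gene_links)),
            "true_promoter_links": sorted(map(list, self.true_promoter_links)),
            "true_loops": sorted(map(list, self.true_loops)),
            "true_enhancer_oligos": self.true_enhancer_oligos,
            "true_allelic_effects": self.true_allelic_effects,
            "true_high_effect_variants": self.true_high_effect_variants,
            "true_eqtl_variants": sorted(self.true_eqtl_variants),
            "accessible_variants": sorted(self.accessible_variants),
            "planted_criteria": {
                k: sorted(v) for k, v in self.planted_criteria.items()
            },
        }


def _nb_sample(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial with variance mu + dispersion*mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# genotypes


def sim_genotypes(
    n_individuals: int,
    block_spec: Sequence[Tuple[int, float]],
    seed: int,
    maf: float = 0.5,
) -> Tuple[pd.DataFrame, TruthLedger]:
    """LD-block genotype dosages (variants x individuals, values 0/1/2).

    Each block copies a latent pair of index haplotypes and flips partner
    alleles independently with probability eps = (1 - sqrt(r2))/2, giving
    haplotype correlation sqrt(r2) and hence dosage R^2 = r2 in expectation.
    The first variant of each block is the block's index.
    """
    if n_individuals < 20:
        raise GenerationError("n_individuals must be >= 20")
    rng = np.random.default_rng(seed)
    ledger = TruthLedger(seed=seed)
    rows, rsids = [], []
    for bi, (n_variants, r2) in enumerate(block_spec):
        if not 0.0 <= r2 <= 1.0:
            raise GenerationError(f"block {bi}: r2 must be in [0,1]")
        h1 = rng.random(n_individuals) < maf
        h2 = rng.random(n_individuals) < maf
        index_rsid = f"rs_b{bi}_v0"
        if r2 > 0 and np.unique(h1.astype(int) + h2.astype(int)).size == 1:
            raise GenerationError(
                f"block {bi}: monomorphic index with r2 > 0"
            )
        rows.append(h1.astype(int) + h2.astype(int))
        rsids.append(index_rsid)
        ledger.true_ld_partners[index_rsid] = {}
        eps = (1.0 - np.sqrt(r2)) / 2.0
        for j in range(1, n_variants):
            f1 = rng.random(n_individuals) < eps
            f2 = rng.random(n_individuals) < eps
            g1 = np.where(f1, ~h1, h1)
            g2 = np.where(f2, ~h2, h2)
            rsid = f"rs_b{bi}_v{j}"
            rows.append(g1.astype(int) + g2.astype(int))
            rsids.append(rsid)
            ledger.true_ld_partners[index_rsid][rsid] = r2
    geno = pd.DataFrame(
        np.vstack(rows),
        index=rsids,
        columns=[f"ind{i}" for i in range(n_individuals)],
    )
    return geno, ledger


# ---------------------------------------------------------------------------
# chromatin atlas


def _lognormal_signal(z: np.ndarray, sigma: float = 0.3, scale: float = 10.0):
    return scale * np.exp(sigma * z)


def sim_atlas(
    n_cell_types: int,
    n_peaks: int,
    n_genes: int,
    n_planted_links: int,
    link_corr: float,
    seed: int,
    n_samples: int = 200,
    genome: Optional[Mapping[str, int]] = None,
    max_link_dist: int = 250_000,
) -> Tuple[
    Dict[str, PeakSet],
    List[GeneModel],
    FeatureMatrix,
    FeatureMatrix,
    TruthLedger,
]:
    """Cell-type peak sets with planted peak-gene regulatory links.

    Planted (peak, gene) pairs share a latent Gaussian factor at correlation
    ``link_corr``; unlinked pairs are generated independently. Observed signal
    is a lognormal transform of the latent factor (nonnegative), which
    attenuates the Pearson correlation slightly below ``link_corr``.
    """
    if not 0.3 < link_corr <= 1.0:
        raise GenerationError("link_corr must be in (0.3, 1]")
    genome = dict(genome or TOY_GENOME)
    rng = np.random.default_rng(seed)
    ledger = TruthLedger(seed=seed)
    chroms = sorted(genome)

    genes: List[GeneModel] = []
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        tss = 500_000 + (i // len(chroms)) * (
            (genome[chrom] - 1_000_000) // max(1, n_genes // len(chroms))
        )
        genes.append(GeneModel(f"gene{i}", chrom, tss, "+"))

    peaks: List[GenomicInterval] = []
    planted: List[Tuple[int, int]] = []  # (peak index, gene index)
    width = 500
    for i in range(n_planted_links):
        g = genes[i % len(genes)]
        offset = int(rng.integers(5_000, min(max_link_dist, 200_000)))
        sign = 1 if i % 2 == 0 else -1
        start = max(0, g.tss + sign * offset - width // 2)
        iv = GenomicInterval(g.chrom, start, start + width)
        if abs(iv.midpoint - g.tss) > max_link_dist:
            raise GenerationError("planted link farther than the link window")
        planted.append((len(peaks), i % len(genes)))
        peaks.append(iv)
    while len(peaks) < n_peaks:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, genome[chrom] - width))
        peaks.append(GenomicInterval(chrom, start, start + width))

    z_genes = rng.standard_normal((n_genes, n_samples))
    z_peaks = rng.standard_normal((n_peaks, n_samples))
    for pi, gi in planted:
        noise = rng.standard_normal(n_samples)
        z_peaks[pi] = link_corr * z_genes[gi] + np.sqrt(
            max(0.0, 1 - link_corr**2)
        ) * noise

    sample_ids = [f"pb{j}" for j in range(n_samples)]
    expr = FeatureMatrix(
        pd.DataFrame(
            _lognormal_signal(z_genes),
            index=[g.gene_id for g in genes],
            columns=sample_ids,
        ),
        "expression",
    )
    peak_keys = [iv.key() for iv in peaks]
    acc = FeatureMatrix(
        pd.DataFrame(_lognormal_signal(z_peaks), index=peak_keys, columns=sample_ids),
        "accessibility",
    )
    peaksets = {}
    for c in range(n_cell_types):
        members = [iv for i, iv in enumerate(peaks) if i % n_cell_types == c]
        # planted peaks present in every cell type so links are attributable
        members += [peaks[pi] for pi, _ in planted]
        peaksets[f"celltype{c}"] = PeakSet(f"celltype{c}", set(members))
    for pi, gi in planted:
        ledger.true_peak_gene_links.add((peak_keys[pi], genes[gi].gene_id))
    return peaksets, genes, acc, expr, ledger


# ---------------------------------------------------------------------------
# contacts and loops


def sim_contacts(
    genome: Mapping[str, int],
    loop_spec: Sequence[Tuple[GenomicInterval, GenomicInterval, float]],
    gamma: float = 1.0,
    resolution_bp: int = 5_000,
    seed: int = 0,
    base: float = 50.0,
) -> Tuple[ContactMap, LoopSet, TruthLedger]:
    """Power-law contact maps with planted focal loops.

    Background contact between bins at distance d (in bins) is
    base * max(d, 1)^(-gamma); the diagonal holds the d=0 value ``base``.
    Each planted loop multiplies its anchor-bin pair by its enrichment.
    """
    if gamma < 0:
        raise GenerationError("gamma must be >= 0")
    ledger = TruthLedger(seed=seed)
    matrices: Dict[str, np.ndarray] = {}
    for chrom, size in genome.items():
        n = int(np.ceil(size / resolution_bp))
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        matrices[chrom] = base * np.maximum(d, 1).astype(float) ** (-gamma)
        np.fill_diagonal(matrices[chrom], base)
    loops = []
    for a, b, enrichment in loop_spec:
        if a.chrom not in genome or b.chrom not in genome:
            raise GenerationError(f"loop anchor off the genome: {a} / {b}")
        if a.end > genome[a.chrom] or b.end > genome[b.chrom]:
            raise GenerationError("loop anchor beyond chromosome end")
        loops.append(Loop.make(a, b, enrichment))
        if a.chrom == b.chrom:
            bi = a.midpoint // resolution_bp
            bj = b.midpoint // resolution_bp
            matrices[a.chrom][bi, bj] *= enrichment
            if bi != bj:
                matrices[a.chrom][bj, bi] *= enrichment
        ledger.true_loops.add((a.chrom, a.midpoint, b.midpoint))
    return ContactMap(resolution_bp, matrices), LoopSet(loops), ledger


# ---------------------------------------------------------------------------
# STARR-seq


@dataclass
class SnpSpec:
    """Planted truth for one STARR-seq SNP."""

    snp_id: str
    is_control: bool = False
    activity_log2fc: float = 0.0  # output/input enrichment of both alleles
    allelic_log2fc: float = 0.0  # alt minus ref, in output libraries
    low_quality: bool = False  # under-represented oligo that should fail QC


def make_starrseq_counts(
    snp_specs: Sequence[SnpSpec],
    bc_mean_input: float = 3_000.0,
    bc_mean_output: float = 300.0,
    dispersion: float = 0.005,
    n_reps: int = 4,
    conditions: Sequence[str] = ("naive",),
    seed: int = 0,
    baseline_sigma: float = 0.3,
) -> Tuple[OligoCounts, TruthLedger]:
    """Negative-binomially dispersed barcode counts from explicit SNP specs."""
    if n_reps < 2:
        raise GenerationError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    ledger = TruthLedger(seed=seed)
    samples = [SampleInfo(f"input_{r+1}", "input") for r in range(n_reps)]
    for cond in conditions:
        samples += [
            SampleInfo(f"output_{cond}_{r+1}", "output", cond)
            for r in range(n_reps)
        ]
    oligo_ids, meta_rows, count_rows = [], [], []
    depth_ratio = bc_mean_output / bc_mean_input
    for spec in snp_specs:
        baseline = bc_mean_input * float(
            np.exp(baseline_sigma * rng.standard_normal())
        )
        if spec.low_quality:
            baseline = 2.0  # mean below the 5-barcode QC floor
        if spec.activity_log2fc != 0 and not spec.is_control:
            ledger.true_enhancer_oligos[spec.snp_id] = spec.activity_log2fc
        if spec.allelic_log2fc != 0 and not spec.is_control:
            ledger.true_allelic_effects[spec.snp_id] = spec.allelic_log2fc
        for allele in ("ref", "alt"):
            oligo_id = f"{spec.snp_id}_{allele}"
            half = spec.allelic_log2fc / 2.0
            allele_shift = half if allele == "alt" else -half
            out_mean = (
                baseline
                * depth_ratio
                * 2.0 ** (spec.activity_log2fc + allele_shift)
            )
            counts = list(
                _nb_sample(rng, np.full(n_reps, baseline), dispersion)
            )
            for _ in conditions:
                counts += list(
                    _nb_sample(rng, np.full(n_reps, out_mean), dispersion)
                )
            oligo_ids.append(oligo_id)
            meta_rows.append(
                {
                    "oligo_id": oligo_id,
                    "snp_id": spec.snp_id,
                    "allele": allele,
                    "is_control": spec.is_control,
                }
            )
            count_rows.append(counts)
    counts_df = pd.DataFrame(
        np.asarray(count_rows, dtype=float),
        index=oligo_ids,
        columns=[s.sample_id for s in samples],
    )
    return OligoCounts(counts_df, pd.DataFrame(meta_rows), samples), ledger


def sim_starrseq(
    n_test_snps: int,
    n_control_snps: int,
    frac_enhancer: float,
    effect_grid: Sequence[float],
    bc_mean_input: float = 3_000.0,
    bc_mean_output: float = 300.0,
    dispersion: float = 0.005,
    n_reps: int = 4,
    seed: int = 0,
    enhancer_log2fc: float = 1.5,
    frac_allelic_among_enhancers: float = 0.5,
    frac_low_quality: float = 0.0,
    conditions: Sequence[str] = ("naive",),
) -> Tuple[OligoCounts, TruthLedger]:
    """STARR-seq counts with a planted fraction of enhancers/allelic effects.

    The first round(frac_enhancer * n_test_snps) test SNPs are enhancers with
    output/input log2FC ``enhancer_log2fc``; among those, the first
    round(frac_allelic * n_enh) carry allelic log2FCs cycled from
    ``effect_grid``. Controls are null.
    """
    if not 0.0 <= frac_enhancer <= 1.0:
        raise GenerationError("frac_enhancer must be in [0,1]")
    n_enh = round(frac_enhancer * n_test_snps)
    n_allelic = round(frac_allelic_among_enhancers * n_enh)
    if n_allelic > 0 and not effect_grid:
        raise GenerationError("effect_grid empty while allelic fraction > 0")
    n_low = round(frac_low_quality * n_test_snps)
    specs = []
    for i in range(n_test_snps):
        activity = enhancer_log2fc if i < n_enh else 0.0
        allelic = effect_grid[i % len(effect_grid)] if i < n_allelic else 0.0
        low = i >= n_test_snps - n_low  # trailing (null) SNPs are low quality
        specs.append(SnpSpec(f"snp{i}", False, activity, allelic, low))
    for i in range(n_control_snps):
        specs.append(SnpSpec(f"ctrl{i}", True))
    return make_starrseq_counts(
        specs,
        bc_mean_input=bc_mean_input,
        bc_mean_output=bc_mean_output,
        dispersion=dispersion,
        n_reps=n_reps,
        conditions=conditions,
        seed=seed,
    )


def sim_amplicon_reads(
    n_snps: int,
    barcodes_per_oligo: int,
    reads_per_barcode: int,
    seed: int = 0,
    adapter: str = "GCTAGCCATTGCGTGTAGAG",
    barcode_length: int = 10,
    insert_length: int = 30,
) -> Tuple[List[str], pd.DataFrame, Dict[str, int]]:
    """Plain-text amplicon reads with a known unique-barcode count per oligo.

    Returns (reads, oligo reference table, expected unique counts). PCR
    duplicates are emulated by emitting each (oligo, barcode) pair
    ``reads_per_barcode`` times.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def seq(n):
        return "".join(rng.choice(bases, size=n))

    ref_rows, reads, expected = [], [], {}
    seen_inserts = set()
    for i in range(n_snps):
        for allele in ("ref", "alt"):
            insert = seq(insert_length)
            while insert in seen_inserts or adapter in insert:
                insert = seq(insert_length)
            seen_inserts.add(insert)
            oligo_id = f"snp{i}_{allele}"
            ref_rows.append(
                {
                    "oligo_id": oligo_id,
                    "snp_id": f"snp{i}",
                    "allele": allele,
                    "insert_sequence": insert,
                    "is_control": False,
                }
            )
            barcodes = {seq(barcode_length) for _ in range(barcodes_per_oligo)}
            expected[oligo_id] = len(barcodes)
            for bc in barcodes:
                reads.extend([insert + adapter + bc] * reads_per_barcode)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, pd.DataFrame(ref_rows), expected


# ---------------------------------------------------------------------------
# predicted counts and eQTLs


def sim_predicted_counts(
    variant_ids: Sequence[str],
    cell_types: Sequence[str],
    n_folds: int = 5,
    frac_high_effect: float = 0.1,
    effect_size: float = 1.0,
    base_count_range: Tuple[float, float] = (200.0, 800.0),
    seed: int = 0,
    jitter_sd: float = 0.02,
    effects: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> Tuple[pd.DataFrame, TruthLedger]:
    """Per-fold predicted ref/alt counts with planted high-effect variants.

    The first round(frac_high_effect * n) variants carry a |log2FC| of
    ``effect_size`` in one cell type (sign alternating); fold-to-fold jitter
    is multiplicative lognormal noise of scale ``jitter_sd``. An explicit
    ``effects`` map (rsid -> {cell_type: log2fc}) overrides the fraction.
    """
    if n_folds < 2:
        raise GenerationError("n_folds must be >= 2")
    if effects is None and frac_high_effect > 0 and effect_size <= 0.25:
        warnings.warn(
            "planted effect_size <= 0.25 sits below the high-effect calling "
            "threshold",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    ledger = TruthLedger(seed=seed)
    if effects is None:
        n_high = round(frac_high_effect * len(variant_ids))
        effects = {}
        for i, rsid in enumerate(variant_ids):
            if i < n_high:
                ct = cell_types[i % len(cell_types)]
                sign = 1.0 if i % 2 == 0 else -1.0
                effects[rsid] = {ct: sign * effect_size}
    rows = []
    lo, hi = base_count_range
    for rsid in variant_ids:
        planted = effects.get(rsid, {})
        if planted:
            ledger.true_high_effect_variants[rsid] = dict(planted)
        for ct in cell_types:
            base = float(rng.uniform(lo, hi))
            l2fc = planted.get(ct, 0.0)
            for fold in range(n_folds):
                jr = float(np.exp(jitter_sd * rng.standard_normal()))
                ja = float(np.exp(jitter_sd * rng.standard_normal()))
                rows.append(
                    {
                        "rsid": rsid,
                        "cell_type": ct,
                        "fold": fold,
                        "ref_count": base * jr,
                        "alt_count": base * (2.0**l2fc) * ja,
                    }
                )
    return pd.DataFrame(rows), ledger


def sim_eqtl_table(
    variant_ids: Sequence[str],
    gene_ids: Sequence[str],
    frac_significant: float,
    seed: int = 0,
    significant_variants: Optional[Set[str]] = None,
) -> Tuple[pd.DataFrame, TruthLedger]:
    """eQTL rows per variant per tissue region with a planted significant set.

    Exactly round(frac_significant * n) variants (or the explicit set) have
    FDR <= 0.05 in at least one region.
    """
    if not 0.0 <= frac_significant <= 1.0:
        raise GenerationError("frac_significant must be in [0,1]")
    rng = np.random.default_rng(seed)
    ledger = TruthLedger(seed=seed)
    if significant_variants is None:
        k = round(frac_significant * len(variant_ids))
        significant_variants = set(list(variant_ids)[:k])
    ledger.true_eqtl_variants = set(significant_variants)
    rows = []
    for i, rsid in enumerate(variant_ids):
        gene = gene_ids[i % len(gene_ids)] if gene_ids else "gene0"
        sig = rsid in significant_variants
        sig_region = "macular" if rng.random() < 0.5 else "non_macular"
        for region in ("macular", "non_macular"):
            if sig and region == sig_region:
                fdr = float(rng.uniform(0.0, 0.05))
            else:
                fdr = float(rng.uniform(0.0500001, 1.0))
            rows.append(
                {
                    "rsid": rsid,
                    "gene_id": gene,
                    "tissue_region": region,
                    "fdr": fdr,
                }
            )
    return pd.DataFrame(rows), ledger


# ---------------------------------------------------------------------------
# integrated study


@dataclass
class StudyConfig:
    """Generator settings for the integrated synthetic study."""

    n_loci: int = 8
    block_size: int = 10
    within_block_r2: float = 0.9
    n_individuals: int = 500
    n_credible_extra: int = 2
    accessible_per_locus: int = 5
    n_samples: int = 200
    link_corr: float = 0.9
    cell_types: Tuple[str, ...] = (
        "RPE",
        "fibroblast",
        "macrophage",
        "endothelial",
        "melanocyte",
    )
    effect_cell_types: Tuple[str, ...] = ("RPE", "fibroblast", "macrophage")
    resolution_bp: int = 5_000
    gamma: float = 1.0
    loop_enrichment: float = 5.0
    n_control_snps: int = 350
    n_reps: int = 4
    bc_mean_input: float = 3_000.0
    bc_mean_output: float = 300.0
    dispersion: float = 0.005
    starr_activity_log2fc: float = 2.0
    starr_allelic_log2fc: float = 2.0
    predicted_effect: float = 1.0
    n_folds: int = 5
    background_peak_spacing: int = 20_000
    conditions: Tuple[str, ...] = ("naive",)


# cycle of planted criteria profiles; 6 (functional SNP) always implies 5
_CRITERIA_PLAN: List[Set[int]] = [
    set(),
    {5},
    {7},
    {8},
    {1},
    {2},
    {3},
    {4},
    {5, 7},
    {1, 2},
    {3, 8},
    {2, 5},
    {1, 2, 3},
    {5, 6, 7},
    {1, 4, 7},
    {2, 5, 8},
    {3, 4, 7},
    {1, 2, 5, 6},
    {1, 2, 3, 4, 5, 6, 7, 8},
    {4, 5, 6, 7, 8},
]


@dataclass
class SyntheticStudy:
    """All pipeline inputs for one synthetic run, plus ground truth."""

    config: StudyConfig
    genome: Dict[str, int]
    catalog: List[VariantRecord]
    genotypes: pd.DataFrame
    index_variants: List[Tuple[str, int]]
    peaksets: Dict[str, PeakSet]  # RPE/choroid cell types
    union_peaks: PeakSet  # all peaks across cell types
    baseline_peaksets: Dict[str, PeakSet]  # non-ocular tissues
    genes: List[GeneModel]
    accessibility: FeatureMatrix
    expression: FeatureMatrix
    loops: LoopSet
    contact_map: ContactMap
    atac_signal: Dict[str, float]
    h3k27ac_signal: Dict[str, float]
    starr_counts: OligoCounts
    predicted_counts: pd.DataFrame
    eqtl_table: pd.DataFrame
    truth: TruthLedger


def simulate_study(
    config: Optional[StudyConfig] = None, seed: int = 0
) -> SyntheticStudy:
    """Generate every input of the prioritization pipeline with planted truth.

    Each locus holds an LD block (index + partners at the configured R^2),
    a handful of independent low-LD variants and a credible-set supplement.
    A subset of catalog variants per locus is made accessible (each inside
    its own 500 bp peak) and assigned a planted profile of the eight
    criteria, realized with strong effects so every planted criterion is
    recoverable at the stated thresholds:

    - criteria 1/2 through latent-factor correlations (promoter peak or gene
      expression) at ``link_corr``;
    - criterion 3 through a loop between the variant and its gene's TSS;
    - criterion 4 by giving the variant's peak H3K27ac signal (only planted
      enhancer elements carry the active mark, so per-gene ABC normalization
      assigns them the full score mass);
    - criteria 5/6 through planted STARR-seq activity/allelic log2FCs;
    - criterion 7 through eQTL rows at FDR <= 0.05;
    - criterion 8 through planted predicted-count effects.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    genome = dict(TOY_GENOME)
    chroms = sorted(genome)
    truth = TruthLedger(seed=seed)

    # --- loci, genotypes, LD catalog -------------------------------------
    locus_centers: List[Tuple[str, int]] = []
    per_chrom = int(np.ceil(cfg.n_loci / len(chroms)))
    for li in range(cfg.n_loci):
        chrom = chroms[li % len(chroms)]
        slot = li // len(chroms)
        center = 1_200_000 + slot * ((genome[chrom] - 2_400_000) // max(1, per_chrom - 1) if per_chrom > 1 else 0)
        locus_centers.append((chrom, center))

    block_spec = []
    for _ in range(cfg.n_loci):
        block_spec.append((cfg.block_size, cfg.within_block_r2))
        block_spec.append((4, 0.0))  # independent low-LD variants
    genotypes, geno_truth = sim_genotypes(
        cfg.n_individuals, block_spec, seed=int(rng.integers(2**31))
    )
    truth.true_ld_partners = geno_truth.true_ld_partners

    # map generated rsids onto loci with deterministic positions
    catalog: List[VariantRecord] = []
    index_variants: List[Tuple[str, int]] = []
    rsid_pos: Dict[str, Tuple[str, int]] = {}
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    for li in range(cfg.n_loci):
        chrom, center = locus_centers[li]
        locus_id = li + 1
        ld_block = 2 * li  # block index in block_spec
        indep_block = 2 * li + 1
        # LD block variants: index at center, partners alternating outward
        for j in range(cfg.block_size):
            rsid = f"rs_b{ld_block}_v{j}"
            if j == 0:
                pos = center
            else:
                sign = 1 if j % 2 == 1 else -1
                pos = center + sign * 1_500 * ((j + 1) // 2)
            ref, alt = alleles[j % len(alleles)]
            catalog.append(
                VariantRecord(
                    rsid, chrom, pos, ref, alt,
                    locus_id=locus_id, is_index=(j == 0),
                    consequence="noncoding",
                )
            )
            rsid_pos[rsid] = (chrom, pos)
            if j == 0:
                index_variants.append((rsid, locus_id))
        # independent variants exist in the genotype matrix but fall below
        # the R^2 threshold; they are NOT part of the catalog
        # credible-set supplement (not in the genotype panel)
        for j in range(cfg.n_credible_extra):
            rsid = f"rs_cs_l{locus_id}_v{j}"
            pos = center - 40_000 - j * 1_500
            ref, alt = alleles[j % len(alleles)]
            catalog.append(
                VariantRecord(
                    rsid, chrom, pos, ref, alt,
                    locus_id=locus_id, consequence="noncoding",
                )
            )
            rsid_pos[rsid] = (chrom, pos)

    # sprinkle consequences: one synonymous per locus, missense at locus 1
    by_locus: Dict[int, List[VariantRecord]] = {}
    for v in catalog:
        by_locus.setdefault(v.locus_id, []).append(v)
    for locus_id, vs in by_locus.items():
        vs[-1].consequence = "synonymous"
        if locus_id == 1 and len(vs) >= 3:
            vs[-2].consequence = "protein_altering"
            vs[-2].am_score = 0.2  # likely benign missense

    # --- accessible variants and criteria plan ---------------------------
    accessible: List[VariantRecord] = []
    plan: Dict[str, Set[int]] = {}
    k = 0
    for locus_id in sorted(by_locus):
        vs = [v for v in by_locus[locus_id] if v.consequence == "noncoding"]
        for v in vs[: cfg.accessible_per_locus]:
            profile = set(_CRITERIA_PLAN[k % len(_CRITERIA_PLAN)])
            if 6 in profile:
                profile.add(5)
            plan[v.rsid] = profile
            accessible.append(v)
            k += 1
    truth.accessible_variants = {v.rsid for v in accessible}
    truth.planted_criteria = {
        rsid: {CRITERION_NAMES[c] for c in profile}
        for rsid, profile in plan.items()
    }

    # --- genes ------------------------------------------------------------
    genes: List[GeneModel] = []
    target_gene: Dict[str, GeneModel] = {}
    per_locus_counter: Dict[int, int] = {}
    for v in accessible:
        i = per_locus_counter.get(v.locus_id, 0)
        per_locus_counter[v.locus_id] = i + 1
        sign = 1 if i % 2 == 0 else -1
        tss = v.pos + sign * (20_000 + 3_000 * i)
        g = GeneModel(f"gene_{v.rsid}", v.chrom, tss, "+")
        genes.append(g)
        target_gene[v.rsid] = g
    for i in range(10):  # background genes away from the loci
        chrom = chroms[i % len(chroms)]
        genes.append(
            GeneModel(f"bg_gene{i}", chrom, 9_000_000 + (i // 2) * 150_000, "+")
        )

    # --- peaks ------------------------------------------------------------
    peak_width = 500
    variant_peak: Dict[str, GenomicInterval] = {}
    all_peaks: List[GenomicInterval] = []
    for v in accessible:
        iv = GenomicInterval(v.chrom, v.pos - 250, v.pos + 250)
        variant_peak[v.rsid] = iv
        all_peaks.append(iv)
    promoter_peak: Dict[str, GenomicInterval] = {}
    for g in [target_gene[v.rsid] for v in accessible]:
        iv = GenomicInterval(g.chrom, g.tss - 200, g.tss + 300)
        promoter_peak[g.gene_id] = iv
        all_peaks.append(iv)
    background_peaks: List[GenomicInterval] = []
    # keep background peaks clear of every catalog variant (accessible or
    # not) and of promoter windows, so accessibility is exactly as planted
    occupied = sorted(
        [(iv.chrom, iv.start, iv.end) for iv in all_peaks]
        + [(v.chrom, v.pos - 250, v.pos + 250) for v in catalog]
    )
    for chrom in chroms:
        for start in range(
            50_000, genome[chrom] - peak_width, cfg.background_peak_spacing
        ):
            iv = GenomicInterval(chrom, start, start + peak_width)
            if any(
                c == chrom and start < e + 2_000 and s - 2_000 < iv.end
                for c, s, e in occupied
            ):
                continue
            background_peaks.append(iv)
    all_peaks.extend(background_peaks)
    union_peaks = PeakSet("union", all_peaks)

    # --- latent factors and signal matrices -------------------------------
    n_samples = cfg.n_samples
    sample_ids = [f"pb{j}" for j in range(n_samples)]
    z_expr = {
        g.gene_id: rng.standard_normal(n_samples) for g in genes
    }
    z_prom = {
        gid: rng.standard_normal(n_samples) for gid in promoter_peak
    }
    lc = cfg.link_corr
    peak_latent: Dict[str, np.ndarray] = {}
    for gid, iv in promoter_peak.items():
        peak_latent[iv.key()] = z_prom[gid]
    for v in accessible:
        iv = variant_peak[v.rsid]
        g = target_gene[v.rsid]
        profile = plan[v.rsid]
        noise = rng.standard_normal(n_samples)
        if 1 in profile and 2 in profile:
            w = lc / np.sqrt(2.0)
            resid = max(0.0, 1.0 - 2 * w * w)
            z = w * z_prom[g.gene_id] + w * z_expr[g.gene_id] + np.sqrt(resid) * noise
        elif 1 in profile:
            z = lc * z_prom[g.gene_id] + np.sqrt(1 - lc * lc) * noise
        elif 2 in profile:
            z = lc * z_expr[g.gene_id] + np.sqrt(1 - lc * lc) * noise
        else:
            z = noise
        peak_latent[iv.key()] = z
        if 1 in profile:
            truth.true_promoter_links.add((iv.key(), g.gene_id))
        if 2 in profile:
            truth.true_peak_gene_links.add((iv.key(), g.gene_id))
    for iv in background_peaks:
        peak_latent[iv.key()] = rng.standard_normal(n_samples)

    acc_rows = {k: _lognormal_signal(z) for k, z in peak_latent.items()}
    accessibility = FeatureMatrix(
        pd.DataFrame.from_dict(acc_rows, orient="index", columns=sample_ids)
        .loc[[iv.key() for iv in union_peaks]],
        "accessibility",
    )
    expression = FeatureMatrix(
        pd.DataFrame.from_dict(
            {gid: _lognormal_signal(z) for gid, z in z_expr.items()},
            orient="index",
            columns=sample_ids,
        ).loc[[g.gene_id for g in genes]],
        "expression",
    )

    # --- cell-type peak sets ----------------------------------------------
    peaksets: Dict[str, PeakSet] = {}
    cts = list(cfg.cell_types)
    members: Dict[str, List[GenomicInterval]] = {ct: [] for ct in cts}
    for i, v in enumerate(accessible):
        for j in range(1 + i % 2):  # accessible in 1 or 2 cell types
            members[cts[(i + j) % len(cts)]].append(variant_peak[v.rsid])
    for i, iv in enumerate(promoter_peak.values()):
        members[cts[i % len(cts)]].append(iv)
    for i, iv in enumerate(background_peaks):
        members[cts[i % len(cts)]].append(iv)
    for ct in cts:
        peaksets[ct] = PeakSet(ct, set(members[ct]))

    # baseline (non-ocular) tissues: background peaks plus a couple of
    # variant-containing peaks so baseline rates are nonzero
    baseline_peaksets: Dict[str, PeakSet] = {}
    for bi, name in enumerate(("tissueA", "tissueB")):
        ivs = background_peaks[bi::3][:200]
        ivs = ivs + [variant_peak[accessible[bi].rsid]]
        baseline_peaksets[name] = PeakSet(name, set(ivs))

    # --- loops and contacts ------------------------------------------------
    def _vg_anchors(v: VariantRecord):
        g = target_gene[v.rsid]
        a = GenomicInterval(v.chrom, v.pos - 250, v.pos + 250)
        b = GenomicInterval(g.chrom, g.tss - 250, g.tss + 250)
        return a, b

    hichip_spec = [
        (*_vg_anchors(v), cfg.loop_enrichment)
        for v in accessible
        if 3 in plan[v.rsid]
    ]
    # focal contact enrichment also planted at ABC-only pairs (not loop calls)
    abc_only_spec = [
        (*_vg_anchors(v), cfg.loop_enrichment)
        for v in accessible
        if 4 in plan[v.rsid] and 3 not in plan[v.rsid]
    ]
    contact_map, _, _ = sim_contacts(
        genome,
        hichip_spec + abc_only_spec,
        gamma=cfg.gamma,
        resolution_bp=cfg.resolution_bp,
        seed=int(rng.integers(2**31)),
    )
    hichip_loops = LoopSet([Loop.make(a, b, e) for a, b, e in hichip_spec])
    truth.true_loops = {
        (a.chrom, a.midpoint, b.midpoint) for a, b, _ in hichip_spec
    }

    # --- ABC signal tracks --------------------------------------------------
    atac_signal = {
        iv.key(): float(np.mean(acc_rows[iv.key()])) for iv in union_peaks
    }
    h3k27ac_signal = {iv.key(): 0.0 for iv in union_peaks}
    for v in accessible:
        if 4 in plan[v.rsid]:
            h3k27ac_signal[variant_peak[v.rsid].key()] = 1.0

    # --- STARR-seq ----------------------------------------------------------
    specs: List[SnpSpec] = []
    for v in catalog:
        profile = plan.get(v.rsid, set())
        activity = cfg.starr_activity_log2fc if 5 in profile else 0.0
        allelic = cfg.starr_allelic_log2fc if 6 in profile else 0.0
        specs.append(SnpSpec(v.rsid, False, activity, allelic))
    for i in range(cfg.n_control_snps):
        specs.append(SnpSpec(f"ctrl{i}", True))
    starr_counts, starr_truth = make_starrseq_counts(
        specs,
        bc_mean_input=cfg.bc_mean_input,
        bc_mean_output=cfg.bc_mean_output,
        dispersion=cfg.dispersion,
        n_reps=cfg.n_reps,
        conditions=cfg.conditions,
        seed=int(rng.integers(2**31)),
    )
    truth.true_enhancer_oligos = starr_truth.true_enhancer_oligos
    truth.true_allelic_effects = starr_truth.true_allelic_effects

    # --- predicted counts ----------------------------------------------------
    effects_map = {
        v.rsid: {cfg.effect_cell_types[0]: cfg.predicted_effect}
        for v in accessible
        if 8 in plan[v.rsid]
    }
    predicted_counts, pred_truth = sim_predicted_counts(
        [v.rsid for v in accessible],
        list(cfg.effect_cell_types),
        n_folds=cfg.n_folds,
        frac_high_effect=0.0,
        effect_size=cfg.predicted_effect,
        seed=int(rng.integers(2**31)),
        effects=effects_map,
    )
    truth.true_high_effect_variants = pred_truth.true_high_effect_variants

    # --- eQTLs ----------------------------------------------------------------
    sig = {v.rsid for v in accessible if 7 in plan[v.rsid]}
    eqtl_table, eqtl_truth = sim_eqtl_table(
        [v.rsid for v in catalog],
        [target_gene[v.rsid].gene_id if v.rsid in target_gene else "gene0" for v in catalog],
        frac_significant=0.0,
        seed=int(rng.integers(2**31)),
        significant_variants=sig,
    )
    truth.true_eqtl_variants = eqtl_truth.true_eqtl_variants

    return SyntheticStudy(
        config=cfg,
        genome=genome,
        catalog=catalog,
        genotypes=genotypes,
        index_variants=index_variants,
        peaksets=peaksets,
        union_peaks=union_peaks,
        baseline_peaksets=baseline_peaksets,
        genes=genes,
        accessibility=accessibility,
        expression=expression,
        loops=hichip_loops,
        contact_map=contact_map,
        atac_signal=atac_signal,
        h3k27ac_signal=h3k27ac_signal,
        starr_counts=starr_counts,
        predicted_counts=predicted_counts,
        eqtl_table=eqtl_table,
        truth=truth,
    )
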