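"""Generator contracts: determinism, planted-truth fidelity, limits."""

import numpy as np
import pandas as pd
import pytest

from amdprio.catalog import compute_r2
from amdprio.core import GenomicInterval
from amdprio.io import read_bed, read_variant_table, write_bed, write_variant_table
from amdprio.simulate import (
    GenerationError,
    SnpSpec,
    make_starrseq_counts,
    sim_amplicon_reads,
    sim_atlas,
    sim_contacts,
    sim_eqtl_table,
    sim_genotypes,
    sim_predicted_counts,
    sim_starrseq,
    simulate_study,
)
from amdprio.starrseq import count_unique_barcodes, parse_amplicon


class TestSimGenotypes:
    def test_r2_one_duplicates_columns(self):
        geno, _ = sim_genotypes(100, [(3, 1.0)], seed=0)
        assert (geno.loc["rs_b0_v0"] == geno.loc["rs_b0_v1"]).all()
        assert compute_r2(geno.loc["rs_b0_v0"], geno.loc["rs_b0_v2"]) == 1.0

    def test_realized_r2_near_target(self):
        geno, _ = sim_genotypes(500, [(6, 0.8), (6, 0.5)], seed=1)
        for block, target in ((0, 0.8), (1, 0.5)):
            for j in range(1, 6):
                r2 = compute_r2(
                    geno.loc[f"rs_b{block}_v0"], geno.loc[f"rs_b{block}_v{j}"]
                )
                assert abs(r2 - target) < 0.15

    def test_cross_block_independence(self):
        n_high = 0
        for seed in range(100):
            geno, _ = sim_genotypes(500, [(2, 0.9), (2, 0.9)], seed=seed)
            r2 = compute_r2(geno.loc["rs_b0_v0"], geno.loc["rs_b1_v0"])
            n_high += r2 >= 0.5
        assert n_high == 0  # P(cross-block R^2 >= 0.5) < 0.01 at n = 500

    def test_seed_determinism(self):
        a, _ = sim_genotypes(60, [(4, 0.7)], seed=42)
        b, _ = sim_genotypes(60, [(4, 0.7)], seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(GenerationError):
            sim_genotypes(10, [(3, 0.5)], seed=0)


class TestSimAtlas:
    def test_planted_links_detectable_and_recorded(self):
        peaksets, genes, acc, expr, truth = sim_atlas(
            3, 60, 10, 10, link_corr=0.95, seed=2
        )
        assert len(truth.true_peak_gene_links) == 10
        for peak_key, gene_id in truth.true_peak_gene_links:
            r = np.corrcoef(
                acc.values.loc[peak_key], expr.values.loc[gene_id]
            )[0, 1]
            assert r > 0.3

    def test_no_planted_links_few_false_positives(self):
        fp = []
        for seed in range(10):
            _, genes, acc, expr, _ = sim_atlas(2, 40, 10, 0, 0.9, seed=seed)
            z_acc = acc.values.to_numpy()
            z_expr = expr.values.to_numpy()
            r = np.corrcoef(np.vstack([z_acc, z_expr]))[: len(z_acc), len(z_acc):]
            fp.append((r > 0.3).mean())
        assert np.mean(fp) < 0.02

    def test_seed_determinism(self):
        _, _, a1, e1, _ = sim_atlas(2, 30, 5, 3, 0.9, seed=7)
        _, _, a2, e2, _ = sim_atlas(2, 30, 5, 3, 0.9, seed=7)
        pd.testing.assert_frame_equal(a1.values, a2.values)
        pd.testing.assert_frame_equal(e1.values, e2.values)

    def test_link_corr_below_cutoff_rejected(self):
        with pytest.raises(GenerationError):
            sim_atlas(2, 30, 5, 3, link_corr=0.2, seed=0)


class TestSimContacts:
    GENOME = {"chr1": 500_000}

    def test_gamma_zero_flat_contacts(self):
        cmap, _, _ = sim_contacts(self.GENOME, [], gamma=0.0, seed=0)
        m = cmap.matrices["chr1"]
        assert np.allclose(m, m[0, 0])

    def test_planted_loop_is_focal_enrichment_maximum(self):
        a = GenomicInterval("chr1", 100_000, 100_500)
        b = GenomicInterval("chr1", 400_000, 400_500)
        cmap, loops, truth = sim_contacts(self.GENOME, [(a, b, 5.0)], gamma=1.0, seed=0)
        m = cmap.matrices["chr1"]
        n = m.shape[0]
        bi, bj = 100_250 // 5_000, 400_250 // 5_000
        # relative to the power-law background, the loop's bin pair is the
        # row maximum (raw contact is dominated by near-diagonal decay)
        d = np.abs(np.arange(n) - bi)
        expected = 50.0 * np.maximum(d, 1) ** -1.0
        ratio = m[bi] / expected
        ratio[bi] = 0
        assert int(np.argmax(ratio)) == bj
        assert ratio[bj] == pytest.approx(5.0)
        assert ("chr1", 100_250, 400_250) in truth.true_loops

    def test_symmetric_output(self):
        a = GenomicInterval("chr1", 50_000, 50_500)
        b = GenomicInterval("chr1", 300_000, 300_500)
        cmap, _, _ = sim_contacts(self.GENOME, [(a, b, 3.0)], seed=0)
        m = cmap.matrices["chr1"]
        assert np.allclose(m, m.T)

    def test_anchor_off_genome_rejected(self):
        a = GenomicInterval("chr1", 499_000, 501_000)
        with pytest.raises(GenerationError):
            sim_contacts(self.GENOME, [(a, a, 2.0)], seed=0)


class TestSimStarrseq:
    def test_zero_dispersion_null_ratio_concentrates_at_one(self):
        counts, _ = make_starrseq_counts(
            [SnpSpec(f"s{i}") for i in range(50)],
            dispersion=0.0, seed=3, baseline_sigma=0.0,
        )
        in_cols = counts.sample_ids("input")
        out_cols = counts.sample_ids("output", "naive")
        depth = 3_000.0 / 300.0
        ratio = (
            counts.counts[out_cols].mean(axis=1)
            / counts.counts[in_cols].mean(axis=1)
            * depth
        )
        assert ratio.to_numpy() == pytest.approx(1.0, abs=0.15)

    def test_planted_allelic_fold_change(self):
        counts, truth = sim_starrseq(
            100, 0, 1.0, [1.0], frac_allelic_among_enhancers=1.0,
            n_reps=4, seed=4,
        )
        out_cols = counts.sample_ids("output", "naive")
        ratios = []
        for snp in truth.true_allelic_effects:
            alt = counts.counts.loc[f"{snp}_alt", out_cols].mean()
            ref = counts.counts.loc[f"{snp}_ref", out_cols].mean()
            ratios.append(alt / ref)
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.15)

    def test_low_quality_snps_fail_qc(self):
        from amdprio.starrseq import qc_filter_oligos

        counts, _ = sim_starrseq(
            40, 10, 0.0, [], frac_low_quality=0.25, seed=5
        )
        _, kept = qc_filter_oligos(counts)
        assert len(kept) == 40 + 10 - 10  # 10 test SNPs planted low quality

    def test_empty_effect_grid_with_allelic_fraction_rejected(self):
        with pytest.raises(GenerationError):
            sim_starrseq(10, 0, 1.0, [], frac_allelic_among_enhancers=1.0, seed=0)

    def test_seed_determinism(self):
        a, _ = sim_starrseq(20, 5, 0.5, [1.0], seed=6)
        b, _ = sim_starrseq(20, 5, 0.5, [1.0], seed=6)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestSimAmpliconReads:
    def test_counts_recovered_from_reads(self):
        reads, ref, expected = sim_amplicon_reads(5, 8, 3, seed=7)
        lookup = dict(zip(ref["insert_sequence"], ref["oligo_id"]))
        parsed = [parse_amplicon(r, lookup) for r in reads]
        assert all(not isinstance(p, str) for p in parsed)
        assert count_unique_barcodes(parsed) == expected


class TestSimPredictedCounts:
    def test_zero_jitter_exact_fold_change(self):
        pred, _ = sim_predicted_counts(
            ["rs1"], ["ct"], n_folds=5, frac_high_effect=1.0,
            effect_size=1.0, jitter_sd=0.0, seed=8,
        )
        assert (pred["alt_count"] / pred["ref_count"]).to_numpy() == pytest.approx(2.0)

    def test_effect_below_threshold_warns(self):
        with pytest.warns(UserWarning, match="0.25"):
            sim_predicted_counts(
                ["rs1"], ["ct"], frac_high_effect=0.5, effect_size=0.2, seed=0
            )

    def test_seed_determinism(self):
        a, _ = sim_predicted_counts(["rs1", "rs2"], ["ct"], seed=9)
        b, _ = sim_predicted_counts(["rs1", "rs2"], ["ct"], seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimEqtlTable:
    @pytest.mark.parametrize("frac", [0.0, 0.3, 1.0])
    def test_exact_significant_counts(self, frac):
        ids = [f"rs{i}" for i in range(40)]
        table, truth = sim_eqtl_table(ids, ["g"], frac, seed=10)
        sig = set(table.loc[table["fdr"] <= 0.05, "rsid"])
        assert len(sig) == round(frac * 40)
        assert sig == truth.true_eqtl_variants


class TestWriteReadRoundTrips:
    def test_generated_data_passes_readers(self, tmp_path, study):
        write_variant_table(study.catalog, tmp_path / "cat.tsv")
        again = read_variant_table(tmp_path / "cat.tsv")
        assert len(again) == len(study.catalog)
        assert again[0].rsid == study.catalog[0].rsid
        write_bed(study.peaksets["RPE"], tmp_path / "rpe.bed")
        ps = read_bed(tmp_path / "rpe.bed", label="RPE")
        assert ps == study.peaksets["RPE"]


def test_simulate_study_deterministic():
    a = simulate_study(seed=21)
    b = simulate_study(seed=21)
    pd.testing.assert_frame_equal(a.starr_counts.counts, b.starr_counts.counts)
    pd.testing.assert_frame_equal(a.accessibility.values, b.accessibility.values)
    assert a.truth.planted_criteria == b.truth.planted_criteria
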