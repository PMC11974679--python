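"""Reporter-assay analysis: parsing, counting, QC, normalization, tests."""

import numpy as np
import pandas as pd
import pytest

from amdprio.core import ValidationError
from amdprio.simulate import SnpSpec, make_starrseq_counts, sim_starrseq
from amdprio.starrseq import (
    ADAPTER,
    OligoCounts,
    SampleInfo,
    allelic_activity,
    call_enhancers,
    call_functional_snps,
    count_unique_barcodes,
    empirical_threshold,
    parse_amplicon,
    qc_filter_oligos,
    qq_abs_log2fc,
    size_factor_normalize,
)

LOOKUP = {"ACGTACGTACGTACGTACGT": "oligo1"}
INSERT = "ACGTACGTACGTACGTACGT"


class TestParseAmplicon:
    def test_constructed_read_parses(self):
        read = INSERT + ADAPTER + "AAAAACCCCC"
        assert parse_amplicon(read, LOOKUP) == ("oligo1", "AAAAACCCCC")

    @pytest.mark.parametrize(
        "read,reason",
        [
            (INSERT + ADAPTER + "AAAAACCCC", "bad_barcode_length"),  # 9 nt
            (INSERT + ADAPTER + "AAAAACCCCCG", "bad_barcode_length"),  # 11 nt
            (INSERT + "AAAAACCCCC", "no_adapter"),
            ("TTTT" + ADAPTER + "AAAAACCCCC", "unknown_insert"),
            ("", "no_adapter"),
        ],
    )
    def test_rejections(self, read, reason):
        assert parse_amplicon(read, LOOKUP) == reason


class TestCountUniqueBarcodes:
    def test_duplicates_count_once(self):
        parsed = [("o1", "A" * 10), ("o1", "A" * 10), ("o1", "C" * 10)]
        assert count_unique_barcodes(parsed) == {"o1": 2}

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        parsed = [(f"o{i % 3}", f"bc{rng.integers(5)}") for i in range(100)]
        shuffled = [parsed[i] for i in rng.permutation(len(parsed))]
        assert count_unique_barcodes(parsed) == count_unique_barcodes(shuffled)

    def test_idempotent_under_read_duplication(self):
        parsed = [("o1", "A" * 10), ("o2", "C" * 10)]
        assert count_unique_barcodes(parsed) == count_unique_barcodes(parsed * 3)


def _counts(rows, samples=None):
    """rows: {oligo_id: [counts]}, default 2 input + 2 output naive samples."""
    if samples is None:
        samples = [
            SampleInfo("input_1", "input"),
            SampleInfo("input_2", "input"),
            SampleInfo("output_naive_1", "output", "naive"),
            SampleInfo("output_naive_2", "output", "naive"),
        ]
    meta = []
    for oid in rows:
        snp, allele = oid.rsplit("_", 1)
        meta.append(
            {"oligo_id": oid, "snp_id": snp, "allele": allele, "is_control": False}
        )
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[s.sample_id for s in samples]
    )
    return OligoCounts(df, pd.DataFrame(meta), samples)


class TestQcFilterOligos:
    def test_boundary_five_retained(self):
        oc = _counts({"s1_ref": [5, 5, 5, 5], "s1_alt": [9, 9, 9, 9]})
        oligos, snps = qc_filter_oligos(oc)
        assert oligos == {"s1_ref", "s1_alt"} and snps == {"s1"}

    def test_any_replicate_below_floor_discards(self):
        oc = _counts({"s1_ref": [12, 4, 30, 20], "s1_alt": [9, 9, 9, 9]})
        oligos, snps = qc_filter_oligos(oc)
        assert oligos == set() and snps == set()

    def test_snp_excluded_if_one_allele_fails(self):
        oc = _counts(
            {"s1_ref": [9, 9, 9, 9], "s1_alt": [1, 9, 9, 9],
             "s2_ref": [9, 9, 9, 9], "s2_alt": [9, 9, 9, 9]}
        )
        oligos, snps = qc_filter_oligos(oc)
        assert snps == {"s2"} and "s1_ref" not in oligos


class TestSizeFactorNormalize:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, dtype=float)
        _, factors = size_factor_normalize(df)
        assert factors.tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_library_factor_ratio(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, dtype=float)
        _, factors = size_factor_normalize(df)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(100, size=(100, 5)).astype(float) + 1
        df = pd.DataFrame(mat, columns=list("abcde"))
        _, factors = size_factor_normalize(df)
        logs = np.log(mat)
        geo = np.exp(logs.mean(axis=1))
        expected = np.median(mat / geo[:, None], axis=0)
        assert factors.to_numpy() == pytest.approx(expected)

    def test_all_zero_row_everywhere_rejected(self):
        df = pd.DataFrame({"a": [0, 0], "b": [0, 5]}, dtype=float)
        with pytest.raises(ValidationError):
            size_factor_normalize(df)


class TestCallEnhancers:
    def test_output_equal_input_no_enhancers(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(300, size=(40, 1)).astype(float)
        rows = {}
        for i in range(20):
            rows[f"s{i}_ref"] = list(base[2 * i]) * 4
            rows[f"s{i}_alt"] = list(base[2 * i + 1]) * 4
        res = call_enhancers(_counts(rows), "naive")
        assert not res["is_enhancer"].any()

    def test_fold_change_gate(self):
        # deterministic 1.4x output enrichment: below the 1.5x threshold
        rows = {}
        for i in range(30):
            c = 300.0 + i
            rows[f"s{i}_ref"] = [c, c, round(1.4 * c), round(1.4 * c)]
            rows[f"s{i}_alt"] = [c, c, round(1.4 * c), round(1.4 * c)]
        res = call_enhancers(_counts(rows), "naive")
        assert not res["is_enhancer"].any()

    def test_rescaling_one_library_is_invariant(self):
        counts, _ = sim_starrseq(60, 20, 0.2, [1.0], seed=5, n_reps=4)
        res1 = call_enhancers(counts, "naive")
        scaled = counts.counts.copy()
        scaled["output_naive_1"] = np.round(scaled["output_naive_1"] * 3)
        counts2 = OligoCounts(
            scaled, counts.oligo_meta.reset_index(), list(counts.samples.values())
        )
        res2 = call_enhancers(counts2, "naive")
        assert (res1["is_enhancer"] == res2["is_enhancer"]).all()

    def test_planted_enhancers_recovered(self):
        counts, truth = sim_starrseq(
            300, 100, 0.2, [1.0], seed=6, n_reps=4, enhancer_log2fc=1.5
        )
        res = call_enhancers(counts, "naive")
        called = set(res.loc[res["is_enhancer"], "snp_id"])
        planted = set(truth.true_enhancer_oligos)
        sensitivity = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(1, len(called))
        assert sensitivity >= 0.9
        assert fdr <= 0.1


class TestAllelicActivity:
    def test_equal_alleles_zero_effect(self):
        rows = {}
        for i in range(20):
            c = 300.0 + 5 * i
            rows[f"s{i}_ref"] = [c, c, c, c]
            rows[f"s{i}_alt"] = [c, c, c, c]
        res = allelic_activity(_counts(rows), "naive")
        assert res["log2fc"].abs().max() == 0.0
        assert (res["p_value"] > 0.9).all()

    def test_allele_swap_negates_log2fc(self):
        counts, _ = sim_starrseq(50, 20, 0.4, [1.5], seed=7, n_reps=4)
        res = allelic_activity(counts, "naive")
        swapped_meta = counts.oligo_meta.reset_index().copy()
        swapped_meta["allele"] = swapped_meta["allele"].map(
            {"ref": "alt", "alt": "ref"}
        )
        swapped = OligoCounts(
            counts.counts, swapped_meta, list(counts.samples.values())
        )
        res2 = allelic_activity(swapped, "naive")
        assert res2["log2fc"].to_numpy() == pytest.approx(
            -res["log2fc"].to_numpy()
        )

    def test_planted_effect_estimates_accurate(self):
        counts, truth = sim_starrseq(
            100, 30, 1.0, [1.0], seed=8, n_reps=4,
            frac_allelic_among_enhancers=1.0,
        )
        res = allelic_activity(counts, "naive").set_index("snp_id")
        errs = [
            abs(res.loc[snp, "log2fc"] - effect)
            for snp, effect in truth.true_allelic_effects.items()
        ]
        frac_close = np.mean([e <= 0.2 for e in errs])
        assert frac_close >= 0.9


class TestEmpiricalThreshold:
    def test_interpolated_80th_percentile(self):
        controls = [round(0.1 * i, 1) for i in range(1, 11)]
        assert empirical_threshold(controls, 0.80) == pytest.approx(0.82)

    def test_constant_controls(self):
        assert empirical_threshold([0.3] * 12, 0.80) == pytest.approx(0.3)

    def test_q_one_is_maximum(self):
        assert empirical_threshold(list(range(15)), 1.0) == 14

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            empirical_threshold([])


class TestCallFunctionalSnps:
    def _results(self):
        return pd.DataFrame(
            {
                "snp_id": ["a", "b", "c", "d"],
                "log2fc": [1.0, 1.0, 0.5, -1.2],
                "padj": [0.01, 0.01, 0.01, 0.2],
            }
        )

    def test_conjunction(self):
        out = call_functional_snps(self._results(), {"a", "c", "d"}, 0.5)
        assert out == {"a"}  # b not in enhancer; c at threshold; d p too high

    def test_threshold_is_strict(self):
        res = pd.DataFrame(
            {"snp_id": ["x"], "log2fc": [0.5], "padj": [0.001]}
        )
        assert call_functional_snps(res, {"x"}, 0.5) == set()


class TestQqAbsLog2fc:
    def test_identical_groups_on_diagonal(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=500)
        qq = qq_abs_log2fc(vals, vals, n_points=357)
        assert len(qq) == 357
        assert qq["test_quantile"].to_numpy() == pytest.approx(
            qq["control_quantile"].to_numpy()
        )

    def test_shifted_distribution_above_diagonal(self):
        rng = np.random.default_rng(10)
        ctrl = np.abs(rng.normal(size=2000))
        test = ctrl + 0.7
        qq = qq_abs_log2fc(test, ctrl, n_points=100)
        diff = qq["test_quantile"] - qq["control_quantile"]
        assert diff.to_numpy() == pytest.approx(0.7, abs=1e-6)
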