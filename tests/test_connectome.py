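"""Enhancer-linking strategies: co-accessibility, peak-gene, loops, ABC."""

import numpy as np
import pandas as pd
import pytest

from amdprio.connectome import (
    abc_scores,
    coaccessibility_links,
    connection_summaries,
    loop_overlap,
    marker_gene_enrichment,
    peak_gene_links,
    promoter_coaccessible,
)
from amdprio.core import (
    ContactMap,
    FeatureMatrix,
    GeneModel,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
)


def _fm(rows, index, kind="accessibility"):
    n = len(rows[0])
    return FeatureMatrix(
        pd.DataFrame(rows, index=index, columns=[f"s{i}" for i in range(n)]),
        kind,
    )


class TestCoaccessibility:
    def test_scaled_profiles_perfectly_linked(self):
        rng = np.random.default_rng(0)
        base = rng.random(50) * 10
        peaks = PeakSet("x", [GenomicInterval("chr1", 0, 500),
                              GenomicInterval("chr1", 10_000, 10_500)])
        fm = _fm([base, 3 * base], [iv.key() for iv in peaks])
        links = coaccessibility_links(fm, peaks)
        assert len(links) == 1
        assert links[0].correlation == pytest.approx(1.0)

    def test_window_gate(self):
        rng = np.random.default_rng(0)
        base = rng.random(50) * 10
        peaks = PeakSet("x", [GenomicInterval("chr1", 0, 500),
                              GenomicInterval("chr1", 400_000, 400_500)])
        fm = _fm([base, 3 * base], [iv.key() for iv in peaks])
        assert coaccessibility_links(fm, peaks, window_bp=250_000) == []

    def test_independent_noise_rarely_linked(self):
        rng = np.random.default_rng(1)
        n_pairs, n_linked = 0, 0
        for trial in range(20):
            peaks = PeakSet(
                "x",
                [GenomicInterval("chr1", i * 10_000, i * 10_000 + 500) for i in range(10)],
            )
            fm = _fm(rng.random((10, 200)) * 10, [iv.key() for iv in peaks])
            links = coaccessibility_links(fm, peaks)
            n_linked += len(links)
            n_pairs += 45
        assert n_linked / n_pairs < 0.01


class TestPromoterCoaccessible:
    def test_link_through_promoter_peak(self, study, study_results):
        planted = study.truth.true_promoter_links
        recovered = len(planted & study_results.promoter_pairs) / len(planted)
        assert recovered >= 0.9

    def test_boundary_peak_outside_window_not_linked(self):
        gene = GeneModel("g", "chr1", 100_000, "+")
        inside = GenomicInterval("chr1", 99_000, 99_500)  # inside [98000,100101)
        outside = GenomicInterval("chr1", 100_101, 100_601)  # 1 bp past window
        distal = GenomicInterval("chr1", 50_000, 50_500)
        from amdprio.connectome import PeakPeakLink

        pairs_in, _ = promoter_coaccessible(
            [PeakPeakLink(distal, inside, 0.9)], [gene]
        )
        pairs_out, _ = promoter_coaccessible(
            [PeakPeakLink(distal, outside, 0.9)], [gene]
        )
        assert (distal.key(), "g") in pairs_in
        assert (distal.key(), "g") not in pairs_out


class TestPeakGeneLinks:
    def _inputs(self, offset, corr_sign=1):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(100)
        peaks = PeakSet("x", [GenomicInterval("chr1", 500_000, 500_500)])
        gene = GeneModel("g", "chr1", 500_250 + offset, "+")
        acc = _fm([10 + 2 * corr_sign * z], [peaks.intervals[0].key()])
        expr = _fm([10 + 2 * z], ["g"], kind="expression")
        return acc, expr, peaks, [gene]

    def test_strong_link_retained(self):
        acc, expr, peaks, genes = self._inputs(10_000)
        links = peak_gene_links(acc, expr, peaks, genes)
        assert len(links) == 1 and links[0].correlation > 0.99

    def test_distance_gate(self):
        acc, expr, peaks, genes = self._inputs(251_000)
        assert peak_gene_links(acc, expr, peaks, genes) == []

    def test_anticorrelated_not_retained_under_signed_cutoff(self):
        acc, expr, peaks, genes = self._inputs(10_000, corr_sign=-1)
        assert peak_gene_links(acc, expr, peaks, genes) == []
        assert len(
            peak_gene_links(acc, expr, peaks, genes, use_absolute=True)
        ) == 1


class TestLoopOverlap:
    def test_variant_and_tss_across_anchors(self):
        loop = Loop.make(GenomicInterval("chr1", 1_000, 1_500),
                         GenomicInterval("chr1", 50_000, 50_500))
        genes = [GeneModel("g", "chr1", 50_250, "+")]
        res = loop_overlap(
            LoopSet([loop]), genes, variant_positions={"rs1": ("chr1", 1_200)}
        )
        assert ("rs1", "g") in res.linked_pairs

    def test_same_anchor_not_linked(self):
        loop = Loop.make(GenomicInterval("chr1", 1_000, 1_500),
                         GenomicInterval("chr1", 50_000, 50_500))
        genes = [GeneModel("g", "chr1", 1_100, "+")]  # TSS in anchor1 too
        res = loop_overlap(
            LoopSet([loop]), genes, variant_positions={"rs1": ("chr1", 1_200)}
        )
        # promoter window of g spills outside anchor1 but never reaches anchor2
        assert ("rs1", "g") not in res.linked_pairs

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        loops, genes, variants = [], [], {}
        for i in range(30):
            a = int(rng.integers(0, 900_000))
            b = int(rng.integers(0, 900_000))
            loops.append(Loop.make(GenomicInterval("chr1", a, a + 2_000),
                                   GenomicInterval("chr1", b, b + 2_000)))
        for i in range(20):
            genes.append(GeneModel(f"g{i}", "chr1", int(rng.integers(0, 900_000)), "+"))
        for i in range(50):
            variants[f"rs{i}"] = ("chr1", int(rng.integers(0, 900_000)))
        res = loop_overlap(LoopSet(loops), genes, variant_positions=variants)

        from amdprio.atlas import make_promoters

        _, windows = make_promoters(genes)
        expected = set()
        for lp in LoopSet(loops):
            for a, b in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
                for rsid, (chrom, pos) in variants.items():
                    if not a.contains(chrom, pos):
                        continue
                    for g in genes:
                        w = windows[g.gene_id]
                        if b.overlaps(w) or b.contains(g.chrom, g.tss):
                            expected.add((rsid, g.gene_id))
        assert res.linked_pairs == expected

    def test_anchor_peak_fraction(self):
        loops = LoopSet([
            Loop.make(GenomicInterval("chr1", 0, 1_000),
                      GenomicInterval("chr1", 10_000, 11_000)),
            Loop.make(GenomicInterval("chr1", 20_000, 21_000),
                      GenomicInterval("chr1", 30_000, 31_000)),
        ])
        ps = {"ct": PeakSet("ct", [GenomicInterval("chr1", 500, 700)])}
        res = loop_overlap(loops, [], peaksets=ps)
        assert res.anchor_peak_fraction == pytest.approx(0.5)


def _uniform_map(n_bins=200, value=1.0, resolution=5_000):
    return ContactMap(resolution, {"chr1": np.full((n_bins, n_bins), value)})


class TestAbcScores:
    def test_two_candidate_normalization(self):
        peaks = PeakSet("x", [GenomicInterval("chr1", 100_000, 100_500),
                              GenomicInterval("chr1", 200_000, 200_500)])
        k1, k2 = (iv.key() for iv in peaks)
        genes = [GeneModel("g", "chr1", 150_000, "+")]
        conns = abc_scores(
            peaks, {k1: 9.0, k2: 1.0}, {k1: 1.0, k2: 1.0},
            _uniform_map(), genes,
        )
        scores = {c.element.key(): c.abc_score for c in conns}
        assert scores[k1] == pytest.approx(0.75)
        assert scores[k2] == pytest.approx(0.25)

    def test_min_tss_distance_excludes_close_elements(self):
        peaks = PeakSet("x", [GenomicInterval("chr1", 149_900, 150_400)])
        k = peaks.intervals[0].key()
        genes = [GeneModel("g", "chr1", 150_000, "+")]
        conns = abc_scores(peaks, {k: 9.0}, {k: 9.0}, _uniform_map(), genes)
        assert conns == []  # midpoint 150,150 is 150 bp from the TSS

    def test_matches_brute_force_and_scores_conserve(self):
        rng = np.random.default_rng(4)
        ivs, atac, h3k = [], {}, {}
        for i in range(50):
            s = int(rng.integers(0, 800_000))
            iv = GenomicInterval("chr1", s, s + 500)
            ivs.append(iv)
            atac[iv.key()] = float(rng.random() * 10)
            h3k[iv.key()] = float(rng.random() * 5)
        peaks = PeakSet("x", set(ivs))
        genes = [GeneModel(f"g{i}", "chr1", int(rng.integers(0, 800_000)), "+")
                 for i in range(10)]
        n = 200
        m = rng.random((n, n))
        cmap = ContactMap(5_000, {"chr1": (m + m.T) / 2})
        conns = abc_scores(peaks, atac, h3k, cmap, genes,
                           score_min=0.0, min_tss_dist=0)
        got = {(c.element.key(), c.gene_id): c.abc_score for c in conns}
        for g in genes:
            weights = {}
            for iv in set(ivs):
                a = np.sqrt(atac[iv.key()] * h3k[iv.key()])
                c = cmap.matrices["chr1"][iv.midpoint // 5_000, g.tss // 5_000]
                weights[iv.key()] = a * c
            total = sum(weights.values())
            gene_scores = [
                got[(k, g.gene_id)] for k in weights if (k, g.gene_id) in got
            ]
            assert sum(gene_scores) == pytest.approx(1.0, abs=1e-12)
            for k, w in weights.items():
                if (k, g.gene_id) in got:
                    assert got[(k, g.gene_id)] == pytest.approx(w / total)

    def test_gene_with_zero_activity_skipped_with_warning(self):
        peaks = PeakSet("x", [GenomicInterval("chr1", 100_000, 100_500)])
        k = peaks.intervals[0].key()
        genes = [GeneModel("g", "chr1", 150_000, "+")]
        with pytest.warns(UserWarning, match="skipped"):
            conns = abc_scores(peaks, {k: 5.0}, {k: 0.0}, _uniform_map(), genes)
        assert conns == []


class TestConnectionSummaries:
    def test_enhancers_per_gene_median(self):
        links = {"s": {("p1", "g"), ("p2", "g"), ("p3", "g")}}
        out = connection_summaries(links)
        assert out["strategies"]["s"]["enhancers_per_gene_median"] == 3

    def test_overlap_extremes(self):
        same = {("p1", "g1"), ("p2", "g2")}
        out = connection_summaries({"a": same, "b": set(same)})
        assert out["pairwise_overlap"]["a|b"] == 1.0
        out = connection_summaries({"a": same, "b": {("x", "y")}})
        assert out["pairwise_overlap"]["a|b"] == 0.0


class TestMarkerGeneEnrichment:
    def test_subset_and_disjoint(self):
        targets = {f"g{i}" for i in range(100)}
        res = marker_gene_enrichment(
            targets,
            {"eye": [f"g{i}" for i in range(50)],
             "other": [f"x{i}" for i in range(50)]},
            baseline_tissues=["eye"],
            n_sample=20, n_draws=10, seed=0,
        )
        assert res["eye"]["fraction"] == 1.0
        assert res["other"]["fraction"] == 0.0

    def test_half_overlap_close_to_expectation(self):
        targets = {f"g{i}" for i in range(500)}
        markers = [f"g{i}" for i in range(250)] + [f"x{i}" for i in range(250)]
        res = marker_gene_enrichment(
            targets, {"t": markers, "b": markers}, ["b"],
            n_sample=457, n_draws=100, seed=1,
        )
        # sampling 457 of 500 half-overlapping markers: hypergeometric mean 0.5
        assert res["t"]["fraction"] == pytest.approx(0.5, abs=0.02)
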