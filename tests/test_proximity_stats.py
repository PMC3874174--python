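"""Matched-pair proximity tests, rank sums and boundary enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import random_domains
from eqtldomains.eqtl_mapping import EqtlClass, attach_properties, \
    build_classes, filter_pairs
from eqtldomains.hic_graph import DomainSequence, total_frequencies
from eqtldomains.null_models import build_shuffle_set, sample_random_eqtls
from eqtldomains.proximity_stats import (
    boundary_window_enrichment,
    proximity_matched_test,
    regulatory_proximity_test,
    size_stratified_boundary_test,
    total_frequency_ranksum,
)
from eqtldomains.synthetic_data import SyntheticConfig, generate_dataset


def analysis_inputs(seed, **cfg_kw):
    cfg = SyntheticConfig(**cfg_kw)
    ds = generate_dataset(cfg, seed=seed)
    totals = total_frequencies(ds.graph)
    pairs = filter_pairs(ds.pairs)
    classes = attach_properties(build_classes(pairs, ds.graph), ds.graph,
                                totals)
    return ds, pairs, classes


class TestSignedRankExactness:
    def signed_rank_enumeration(self, x, y):
        d = x - y
        d = d[d != 0]
        r = stats.rankdata(np.abs(d))
        w = r[d > 0].sum()
        W = np.array([r[np.array(s, bool)].sum()
                      for s in itertools.product([0, 1], repeat=len(d))])
        return min(1.0, 2 * min(np.mean(W <= w), np.mean(W >= w)))

    def test_matches_enumeration_null(self, rng):
        for _ in range(5):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            if np.unique(np.abs(x - y)).size < 12:
                continue
            expected = self.signed_rank_enumeration(x, y)
            got = stats.wilcoxon(x, y, zero_method="wilcox",
                                 method="auto").pvalue
            assert got == pytest.approx(expected, rel=1e-12)

    def test_all_positive_differences_extreme(self, rng):
        x = np.arange(1.0, 13.0) + 100
        y = np.arange(1.0, 13.0)
        p = stats.wilcoxon(x, y, method="auto").pvalue
        assert p == pytest.approx(2 / 2 ** 12, rel=1e-12)


class TestProximityMatchedTest:
    def test_identical_proximities_give_p_one(self, rng):
        ds, pairs, classes = analysis_inputs(101, n_eqtls=40,
                                             chrom_length=8_000_000,
                                             n_genes=25)
        space = sample_random_eqtls(classes, pairs, ds.graph.chrom_length,
                                    ds.graph, n_p=5, seed=1)
        space.proximity = np.full(len(space), -1.0)
        for c in classes:
            c.properties.p = -1.0  # force elementwise equality after match
        t = proximity_matched_test(classes, space)
        assert t.p_value == 1.0 and t.direction == "none"

    def test_subset_restriction_reduces_pairs(self, rng):
        ds, pairs, classes = analysis_inputs(102, n_eqtls=60,
                                             chrom_length=8_000_000,
                                             n_genes=25)
        space = sample_random_eqtls(classes, pairs, ds.graph.chrom_length,
                                    ds.graph, n_p=8, seed=2)
        t_all = proximity_matched_test(classes, space)
        t_cross = proximity_matched_test(classes, space, subset="crossing",
                                         domains=ds.domains)
        t_non = proximity_matched_test(classes, space, subset="noncrossing",
                                       domains=ds.domains)
        assert t_cross.n_pairs + t_non.n_pairs == t_all.n_pairs
        assert sum(a for a, _ in t_all.per_bin_counts.values()) == t_all.n_pairs

    def test_planted_proximity_detected_null_calibrated(self):
        rejections = {0.0: 0, 3.0: 0}
        n_rep = 30
        for lam in rejections:
            for seed in range(n_rep):
                ds, pairs, classes = analysis_inputs(
                    2000 + seed, proximity_planting=lam)
                space = sample_random_eqtls(classes, pairs,
                                            ds.graph.chrom_length, ds.graph,
                                            n_p=20, seed=seed)
                t = proximity_matched_test(classes, space)
                rejections[lam] += t.p_value <= 0.01
        assert rejections[3.0] >= 0.9 * n_rep
        assert rejections[0.0] <= 0.2 * n_rep


class TestRankSum:
    def test_identical_groups_p_one(self):
        assert total_frequency_ranksum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_small_sample_exact_value(self):
        assert total_frequency_ranksum([1, 2, 3], [4, 5, 6]) == \
            pytest.approx(0.1, rel=1e-12)

    def test_matches_enumeration(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        ranks = stats.rankdata(np.concatenate([a, b]))
        u = ranks[:6].sum() - 6 * 7 / 2
        Us = np.array([ranks[list(cb)].sum() - 6 * 7 / 2
                       for cb in itertools.combinations(range(13), 6)])
        expected = min(1.0, 2 * min(np.mean(Us <= u), np.mean(Us >= u)))
        assert total_frequency_ranksum(a, b) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_large_shift_detected(self, rng):
        a = rng.normal(5, 1, size=400)
        b = rng.normal(0, 1, size=400)
        assert total_frequency_ranksum(a, b) < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            total_frequency_ranksum([], [1.0])


class TestBoundaryWindowEnrichment:
    def make_classes(self, positions):
        return [EqtlClass("chrR", int(p) // 40_000, f"g{i}", [0], 40_000)
                for i, p in enumerate(positions)]

    def test_dense_tiling_gives_fraction_one(self, rng):
        # domains with period <= 2 * window: every midpoint within window
        starts = np.arange(0, 4_000_000, 400_000)
        d = DomainSequence("chrR", starts, starts + 300_000, 4_000_000)
        classes = self.make_classes(rng.integers(0, 4_000_000, size=30))
        shuffles = build_shuffle_set(d, n_d=20, seed=0)
        frac, p = boundary_window_enrichment(classes, d, shuffles,
                                             window=250_000)
        assert frac == 1.0

    def test_far_snps_give_fraction_zero(self):
        d = DomainSequence("chrR", [0], [1_000_000], 8_000_000)
        classes = self.make_classes([4_000_000, 5_000_000])
        shuffles = build_shuffle_set(d, n_d=20, seed=0)
        frac, p = boundary_window_enrichment(classes, d, shuffles,
                                             window=250_000)
        assert frac == 0.0
        assert 1 / 21 <= p <= 1.0

    def test_planted_boundary_snps_enriched(self):
        sig, null = [], []
        for seed in range(15):
            ds, pairs, classes = analysis_inputs(3000 + seed,
                                                 boundary_planting=0.9)
            sh = build_shuffle_set(ds.domains, n_d=99, seed=seed)
            sig.append(boundary_window_enrichment(classes, ds.domains, sh)[1])
            ds, pairs, classes = analysis_inputs(4000 + seed)
            sh = build_shuffle_set(ds.domains, n_d=99, seed=seed)
            null.append(boundary_window_enrichment(classes, ds.domains, sh)[1])
        assert np.mean(np.array(sig) <= 0.01) >= 0.8
        assert np.mean(np.array(null) <= 0.05) <= 0.2


class TestSizeStratified:
    def test_uniform_offsets_calibrated(self, rng):
        # SNP midpoints uniform around boundaries of ~1 Mb domains
        starts = np.arange(0, 20_000_000, 2_000_000)
        d = DomainSequence("chrR", starts, starts + 1_000_000, 20_000_000)
        classes = [EqtlClass("chrR", int(b), "g", [0], 40_000)
                   for b in rng.integers(0, 500, size=300)]
        res = size_stratified_boundary_test(classes, d, sizes=[1_000_000],
                                            tolerance=0.1, n_bins=5)
        assert len(res) == 1 and res[0].p_bonferroni > 0.001

    def test_skewed_offsets_rejected(self):
        starts = np.arange(0, 20_000_000, 2_000_000)
        d = DomainSequence("chrR", starts, starts + 1_000_000, 20_000_000)
        # SNPs piled on the first bins after each boundary
        classes = [EqtlClass("chrR", int(s // 40_000) + (i % 2), f"g{i}",
                             [0], 40_000)
                   for i, s in enumerate(np.repeat(starts, 12))]
        res = size_stratified_boundary_test(classes, d, sizes=[1_000_000],
                                            tolerance=0.1, n_bins=5)
        assert res[0].p_raw < 1e-10

    def test_missing_size_class_flagged_underpowered(self, small_classes,
                                                     small_dataset):
        res = size_stratified_boundary_test(small_classes,
                                            small_dataset.domains,
                                            sizes=[5_000_000], tolerance=0.0,
                                            n_bins=5)
        assert res[0].underpowered and res[0].n_domains == 0

    def test_bonferroni_multiplies_by_size_count(self, rng):
        starts = np.arange(0, 20_000_000, 2_000_000)
        d = DomainSequence("chrR", starts, starts + 1_000_000, 20_000_000)
        classes = [EqtlClass("chrR", int(b), "g", [0], 40_000)
                   for b in rng.integers(0, 500, size=200)]
        res = size_stratified_boundary_test(classes, d,
                                            sizes=[1_000_000, 2_000_000],
                                            tolerance=0.1, n_bins=5)
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 2))


class TestRegulatoryProximity:
    def test_clear_separation_small_exact_p(self):
        reg = [EqtlClass("chrR", i, f"r{i}", [i + 5], 40_000)
               for i in range(4)]
        oth = [EqtlClass("chrR", i, f"o{i}", [i + 5], 40_000)
               for i in range(5)]
        for i, c in enumerate(reg):
            c.properties = _pv(p=50 + i)
        for i, c in enumerate(oth):
            c.properties = _pv(p=i)
        p = regulatory_proximity_test(reg, oth)
        # one-sided exact: most extreme arrangement of 4 vs 5
        assert p == pytest.approx(1 / 126, rel=1e-12)

    def test_identical_distribution_not_significant(self, rng):
        ps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            reg = [EqtlClass("chrR", i, f"r{i}", [i + 5], 40_000)
                   for i in range(8)]
            oth = [EqtlClass("chrR", i, f"o{i}", [i + 5], 40_000)
                   for i in range(8)]
            for c in reg + oth:
                c.properties = _pv(p=float(r.normal()))
            ps.append(regulatory_proximity_test(reg, oth))
        assert 0.2 < np.mean(ps) < 0.8

    def test_planted_regulatory_subset_detected(self):
        from eqtldomains.eqtl_mapping import classify_many, regulatory_subset
        from eqtldomains.synthetic_data import generate_regulatory_elements
        pvals = []
        n_rep = 15
        for seed in range(n_rep):
            ds, pairs, classes = analysis_inputs(5000 + seed,
                                                 proximity_planting=1.0)
            reg_iv = generate_regulatory_elements(pairs, ds.graph, ds.config,
                                                  seed=seed, planted=True)
            labels = classify_many(classes, ds.domains)
            noncross = [c for c, lab in zip(classes, labels)
                        if lab != "crossing"]
            reg_cls = regulatory_subset(noncross, reg_iv)
            reg_ids = {id(c) for c in reg_cls}
            other = [c for c in noncross if id(c) not in reg_ids]
            if len(reg_cls) < 5 or len(other) < 5:
                continue
            pvals.append(regulatory_proximity_test(reg_cls, other))
        assert len(pvals) >= 10
        assert np.mean(np.array(pvals) <= 0.01) >= 0.8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            regulatory_proximity_test([], [])


def _pv(p):
    from eqtldomains.eqtl_mapping import PropertyVector
    return PropertyVector(d=1.0, g=1.0, m=1.0, t_hat=1.0, p=p)
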