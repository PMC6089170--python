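import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import _oracles as orc
import germsoma as gs
from germsoma.enrichment import (
    assign_csgs,
    bh_adjust,
    build_regions,
    driver_proportion,
    hypergeom_enrichment,
    pathway_co_enrichment,
    per_snp_resident_genes,
    region_permutation_test,
    sample_matched_snps,
)
from germsoma.io import PathwayGeneSet, RiskSNP, SnpFeatures


def _snp(snp_id="rs1", pos=300_000, chrom="chr1", maf=0.2):
    return RiskSNP(snp_id, chrom, pos, "A", "G", maf)


def _genes(rows):
    return pd.DataFrame(
        rows, columns=["gene_symbol", "chrom", "start", "end", "coding"]
    )


class TestRegions:
    def test_flank_window(self):
        r = build_regions([_snp(pos=300_000)], flank_kb=200)[0]
        assert (r.start, r.end) == (100_000, 500_000)

    def test_clipped_at_one(self):
        r = build_regions([_snp(pos=10_000)], flank_kb=50)[0]
        assert (r.start, r.end) == (1, 60_000)

    def test_one_region_per_snp(self):
        snps = [_snp(snp_id=f"rs{i}", pos=10**6 + i) for i in range(11)]
        assert len(build_regions(snps, 200)) == 11

    def test_nonpositive_flank_rejected(self):
        with pytest.raises(ValueError):
            build_regions([_snp()], 0)


class TestCsgs:
    GENES = _genes(
        [
            ("G1", "chr1", 150_000, 160_000, True),
            ("G2", "chr1", 600_000, 700_000, True),
            ("G3", "chr1", 90_000, 99_000, False),  # non-coding
        ]
    )

    def test_overlapping_coding_gene_included(self):
        regions = build_regions([_snp(pos=300_000)], 200)
        csgs = assign_csgs(regions, self.GENES)
        assert csgs == frozenset({"G1"})

    def test_eqtl_genes_added_even_if_unannotated(self):
        regions = build_regions([_snp(pos=300_000)], 200)
        csgs = assign_csgs(regions, self.GENES, eqtl_genes=["GX"])
        assert csgs == frozenset({"G1", "GX"})

    def test_no_overlap_no_eqtl_is_empty(self):
        regions = build_regions([_snp(pos=2_000_000)], 50)
        assert assign_csgs(regions, self.GENES) == frozenset()


class TestDriverProportion:
    def test_fraction_of_resident_genes(self):
        genes = _genes(
            [(f"G{i}", "chr1", 100_000 + i * 10_000, 105_000 + i * 10_000, True)
             for i in range(3)]
        )
        regions = build_regions([_snp(pos=120_000)], 200)
        assert driver_proportion(regions, genes, {"G1"}) == pytest.approx(1 / 3)

    def test_zero_when_no_driver_overlap(self):
        genes = _genes([("G1", "chr1", 100, 200, True)])
        regions = build_regions([_snp(pos=150)], 50)
        assert driver_proportion(regions, genes, {"OTHER"}) == 0.0

    def test_decreases_with_flank_when_drivers_planted_near_snps(self):
        """Planted drivers sit within +/-50 kb, so wider flanks dilute them."""
        props = {50: [], 500: []}
        for seed in range(8):
            cfg = gs.SimConfig(
                seed=seed, n_pool_snps=50, n_genes=1500, n_drivers=60,
                driver_planting_rate=1.0, planted_drivers_per_snp=2,
            )
            sets = gs.simulate_annotation_and_sets(cfg)
            for fk in (50, 500):
                props[fk].append(
                    driver_proportion(
                        build_regions(sets.risk_snps, fk), sets.genes, sets.drivers
                    )
                )
        assert np.mean(props[50]) > np.mean(props[500])


class TestMatchedSampling:
    def _features(self, n, maf=0.2, ld=10, dist=20_000, dens=10, prefix="p"):
        return [
            SnpFeatures(f"{prefix}{i}", maf, ld, dist, dens) for i in range(n)
        ]

    def test_clone_pool_always_matches(self):
        targets = self._features(3, prefix="t")
        pool = self._features(40)
        sets = sample_matched_snps(targets, pool, n_sets=20, seed=0)
        assert len(sets) == 20 and all(len(s) == 3 for s in sets)

    def test_maf_window_rule(self):
        targets = [SnpFeatures("t0", 0.10, 10, 20_000, 10)]
        pool = [SnpFeatures("bad", 0.16, 10, 20_000, 10)] + self._features(30, maf=0.10)
        sets = sample_matched_snps(targets, pool, n_sets=30, seed=1)
        assert all("bad" not in s for s in sets)  # |0.16 - 0.10| > 0.05

    def test_deterministic_under_seed(self):
        targets = self._features(2, prefix="t")
        pool = self._features(50)
        a = sample_matched_snps(targets, pool, n_sets=10, seed=7)
        b = sample_matched_snps(targets, pool, n_sets=10, seed=7)
        c = sample_matched_snps(targets, pool, n_sets=10, seed=8)
        assert a == b and a != c

    def test_without_replacement_within_set(self):
        targets = self._features(4, prefix="t")
        pool = self._features(40)
        for s in sample_matched_snps(targets, pool, n_sets=50, seed=3):
            assert len(set(s)) == len(s)

    def test_no_match_errors_name_the_snp(self):
        targets = [SnpFeatures("lonely", 0.5, 10, 20_000, 10)]
        pool = self._features(30, maf=0.1)
        with pytest.raises(ValueError, match="lonely"):
            sample_matched_snps(targets, pool, n_sets=10, seed=0)

    def test_insufficient_matches_suggest_wider_tolerances(self):
        targets = self._features(1, prefix="t")
        pool = self._features(5)
        with pytest.raises(ValueError, match="widen"):
            sample_matched_snps(targets, pool, n_sets=1000, seed=0)


class TestPermutationTest:
    def test_count_rule_with_ties(self):
        nulls = [0.6, 0.1, 0.2, 0.5, 0.3, 0.1, 0.1, 0.2, 0.1, 0.1]
        res = region_permutation_test(0.5, nulls)
        assert res.p == pytest.approx(0.2)
        assert res.null_count_ge == 2 and res.n_perm == 10

    def test_extremes(self):
        assert region_permutation_test(0.9, [0.1] * 10).p == 0.0
        assert region_permutation_test(0.05, [0.1] * 10).p == 1.0

    def test_zero_p_displayed_as_bound(self):
        res = region_permutation_test(0.9, [0.1] * 10)
        assert res.p_display() == "< 0.1"


class TestHypergeom:
    def test_direct_combinatorial_example(self):
        fold, p = hypergeom_enrichment(4, 4, 5, 10)
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap(self):
        fold, p = hypergeom_enrichment(0, 20, 5, 100)
        assert fold == 0.0 and p == 1.0

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(5, 4, 10, 100)
        with pytest.raises(ValueError):
            hypergeom_enrichment(1, 4, 200, 100)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_exact_enumeration_for_small_universes(self, data):
        N = data.draw(st.integers(1, 30))
        K = data.draw(st.integers(0, N))
        n_draw = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(K, n_draw)))
        _, p = hypergeom_enrichment(k, n_draw, K, N)
        assert p == pytest.approx(
            orc.hypergeom_upper_tail_oracle(k, n_draw, K, N), abs=1e-12
        )


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_tied_pvalues(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=100)
    )
    def test_matches_brute_force_and_statsmodels(self, p):
        ours = bh_adjust(p)
        np.testing.assert_allclose(ours, orc.bh_oracle(p), atol=1e-12)
        sm_adj = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, sm_adj, atol=1e-10)


class TestPathwayCoEnrichment:
    def test_pathway_equal_to_driver_list_is_extreme(self):
        drivers = frozenset(f"D{i}" for i in range(30))
        csgs = frozenset(f"C{i}" for i in range(10))
        pws = [PathwayGeneSet("drv", drivers), PathwayGeneSet("bg", frozenset({"C0", "X1"}))]
        res = pathway_co_enrichment(pws, csgs, drivers, universe_size=20_000)
        assert res.loc["drv", "driver_p"] < 1e-20

    def test_disjoint_pathway_prefiltered(self):
        pws = [
            PathwayGeneSet("hit", frozenset({"D0", "X"})),
            PathwayGeneSet("miss", frozenset({"Y", "Z"})),
        ]
        res = pathway_co_enrichment(pws, frozenset({"C0"}), frozenset({"D0"}), 1000)
        assert "miss" not in res.index

    def test_empty_pathway_list_is_error(self):
        with pytest.raises(ValueError):
            pathway_co_enrichment([], frozenset({"A"}), frozenset({"B"}), 100)

    def test_recovers_exactly_the_planted_key_pathways(self, planted_cohort):
        sets = planted_cohort.sets
        csgs = assign_csgs(build_regions(sets.risk_snps, 200), sets.genes, sets.eqtl_genes)
        res = pathway_co_enrichment(
            sets.pathways, csgs, sets.drivers,
            universe_size=planted_cohort.config.n_genes,
        )
        assert sorted(res.index[res["key"]]) == sorted(sets.key_pathway_names)
        assert len(sets.key_pathway_names) == 8


def _permutation_p(seed, planting_rate, n_perm=300):
    cfg = gs.SimConfig(
        seed=seed, n_pool_snps=6000, n_genes=1200, n_drivers=150,
        driver_planting_rate=planting_rate, planted_drivers_per_snp=1,
    )
    sets = gs.simulate_annotation_and_sets(cfg)
    per = per_snp_resident_genes(sets.pool_snps + sets.risk_snps, sets.genes, 100)
    drivers = sets.drivers

    def prop(ids):
        resident = frozenset().union(*[per[i] for i in ids])
        return len(resident & drivers) / len(resident) if resident else 0.0

    observed = prop([s.snp_id for s in sets.risk_snps])
    matched = sample_matched_snps(
        sets.target_features, sets.pool_features, n_sets=n_perm, seed=seed + 1
    )
    return region_permutation_test(observed, [prop(m) for m in matched]).p


def test_permutation_p_decreases_with_planting_enrichment():
    """Median permutation P falls monotonically as driver planting increases."""
    medians = []
    for rate in (0.0, 0.3, 1.0):
        ps = [_permutation_p(100 + r, rate) for r in range(7)]
        medians.append(np.median(ps))
    assert medians[0] > medians[1] > medians[2]
    assert medians[2] < 0.05
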