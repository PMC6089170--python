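import numpy as np
import pandas as pd
import pytest

import _oracles as orc
import germsoma as gs
from germsoma.association import (
    AssociationScanner,
    association_scan,
    fit_glm_additive,
    genotype_contingency,
    median_impute,
)
from germsoma.qc import GenotypeMatrix

# Published genotype-by-outcome counts for one risk SNP against a pathway
# truncation phenotype: (dosage, cases with / without mutation).
TABLE1_COUNTS = {0: (18, 131), 1: (10, 191), 2: (0, 64)}


def _table1_arrays():
    d, y = [], []
    for dose, (n1, n0) in TABLE1_COUNTS.items():
        d += [dose] * (n1 + n0)
        y += [1] * n1 + [0] * n0
    return np.array(d, float), np.array(y, float)


def _gm_from_dosage(d, snp="rs1"):
    dosages = pd.DataFrame({snp: d}, index=[f"S{i}" for i in range(len(d))])
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": 1000, "risk_allele": "A", "other_allele": "G", "info": 1.0},
        index=[snp],
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


class TestMedianImpute:
    def test_numeric_median(self):
        cov = pd.DataFrame({"age": [40.0, np.nan, 60.0]})
        assert median_impute(cov)["age"].tolist() == [40.0, 50.0, 60.0]

    def test_identity_when_complete(self):
        cov = pd.DataFrame({"age": [40.0, 60.0], "gender": ["F", "M"]})
        pd.testing.assert_frame_equal(median_impute(cov), cov)

    def test_ordinal_stage_lower_median(self):
        cov = pd.DataFrame({"stage": [1.0, 2.0, np.nan, 4.0]})
        assert median_impute(cov)["stage"].tolist() == [1.0, 2.0, 2.0, 4.0]

    def test_nominal_mode(self):
        cov = pd.DataFrame({"gender": ["F", "F", None, "M"]})
        assert median_impute(cov)["gender"].tolist() == ["F", "F", "F", "M"]

    def test_entirely_missing_column_is_error(self):
        with pytest.raises(ValueError, match="entirely missing"):
            median_impute(pd.DataFrame({"age": [np.nan, np.nan]}))


class TestFitGlmAdditive:
    def test_monomorphic_dosage_is_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fit_glm_additive(np.ones(20), np.r_[np.ones(10), np.zeros(10)])

    def test_dominant_collapse_equals_cross_product_ratio(self):
        """On a saturated 2x2, the logistic MLE odds ratio is the cross product."""
        d, y = _table1_arrays()
        carrier = (d >= 1).astype(float)
        res = fit_glm_additive(carrier, y, model="logistic")
        expected = (10 * 131) / (18 * 255)
        assert res.or_ == pytest.approx(expected, rel=1e-6)
        assert res.or_ == pytest.approx(0.285, abs=5e-4)

    def test_additive_fit_matches_grid_search_oracle(self):
        d, y = _table1_arrays()
        res = fit_glm_additive(d, y, model="logistic")
        beta_oracle = orc.grid_logistic_slope(d, y)
        assert res.beta == pytest.approx(beta_oracle, abs=1e-4)

    def test_logistic_matches_newton_oracle(self):
        rng = np.random.default_rng(11)
        for rep in range(20):
            n = 120
            X = np.column_stack(
                [np.ones(n), rng.binomial(2, 0.3, n), rng.normal(size=n)]
            )
            y = rng.binomial(1, 1 / (1 + np.exp(-X @ [-0.2, 0.4, -0.3]))).astype(float)
            cov = pd.DataFrame({"c1": X[:, 2]})
            res = fit_glm_additive(X[:, 1], y, covariates=cov, model="logistic")
            if res.flags:
                continue
            beta_orc = orc.newton_logistic(X, y, seed=rep)[1]
            assert res.beta == pytest.approx(beta_orc, abs=1e-6)

    def test_null_dosage_gives_small_beta_and_uniform_p(self):
        rng = np.random.default_rng(13)
        ps, betas = [], []
        for _ in range(30):
            d = rng.binomial(2, 0.3, 2000).astype(float)
            y = rng.binomial(1, 0.4, 2000).astype(float)
            res = fit_glm_additive(d, y, model="logistic")
            ps.append(res.p)
            betas.append(res.beta)
        assert abs(np.mean(betas)) < 0.05
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.17

    def test_linear_model_recovers_slope(self):
        rng = np.random.default_rng(15)
        d = rng.binomial(2, 0.3, 500).astype(float)
        yq = 1.0 + 0.3 * d + rng.normal(0, 0.3, 500)
        res = fit_glm_additive(d, yq, model="auto")
        assert res.model == "linear"
        assert res.beta == pytest.approx(0.3, abs=3 * res.se)
        assert res.ci95[0] < res.beta < res.ci95[1]

    def test_separation_flagged_not_raised(self):
        d = np.array([0.0] * 10 + [2.0] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10)
        res = fit_glm_additive(d, y, model="logistic")
        assert res.flags and (np.isnan(res.p) or "possible_separation" in res.flags)


class TestAssociationScan:
    def test_planted_effect_recovered_and_significant(self):
        """OR = 0.25 at MAF 0.4, n = 400: detected at FDR 0.1 in >= 80% of runs."""
        rng = np.random.default_rng(19)
        ors, hits = [], 0
        reps = 30
        for _ in range(reps):
            d = rng.binomial(2, 0.4, 400).astype(float)
            p = 1 / (1 + np.exp(-(np.log(0.4 / 0.6) + np.log(0.25) * d)))
            y = rng.binomial(1, p).astype(float)
            gm = _gm_from_dosage(d)
            pheno = pd.DataFrame({"trait": y}, index=gm.dosages.index)
            res = association_scan(gm, {"binary": pheno})
            ors.append(res["or"].iloc[0])
            hits += int(res["fdr"].iloc[0] <= 0.1)
        assert 0.18 <= np.median(ors) <= 0.35
        assert hits / reps >= 0.8

    def test_single_pair_fdr_equals_p(self):
        rng = np.random.default_rng(21)
        d = rng.binomial(2, 0.3, 200).astype(float)
        y = rng.binomial(1, 0.3, 200).astype(float)
        gm = _gm_from_dosage(d)
        res = association_scan(gm, {"fam": pd.DataFrame({"y": y}, index=gm.dosages.index)})
        assert res["fdr"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_all_null_scan_type_one_error(self):
        """11 SNPs x 130 mixed phenotypes, no effects: ~5% of P below .05."""
        rng = np.random.default_rng(25)
        n = 300
        d = rng.binomial(2, 0.3, size=(n, 11)).astype(float)
        dosages = pd.DataFrame(d, index=[f"S{i}" for i in range(n)],
                               columns=[f"rs{j}" for j in range(11)])
        variants = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(11) + 1, "risk_allele": "A",
             "other_allele": "G", "info": 1.0}, index=dosages.columns)
        gm = GenotypeMatrix(dosages=dosages, variants=variants)
        binary = pd.DataFrame(
            rng.binomial(1, 0.3, size=(n, 40)).astype(float),
            index=dosages.index, columns=[f"b{j}" for j in range(40)])
        quant = pd.DataFrame(
            rng.normal(size=(n, 90)), index=dosages.index,
            columns=[f"q{j}" for j in range(90)])
        res = association_scan(gm, {"binary": binary, "cn": quant})
        assert len(res) == 11 * 130
        frac = float((res["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_bh_never_beats_unadjusted_discoveries(self):
        rng = np.random.default_rng(27)
        n = 250
        d = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        dosages = pd.DataFrame(d, index=[f"S{i}" for i in range(n)],
                               columns=[f"rs{j}" for j in range(5)])
        variants = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(5) + 1, "risk_allele": "A",
             "other_allele": "G", "info": 1.0}, index=dosages.columns)
        gm = GenotypeMatrix(dosages=dosages, variants=variants)
        quant = pd.DataFrame(rng.normal(size=(n, 30)), index=dosages.index,
                             columns=[f"q{j}" for j in range(30)])
        res = association_scan(gm, {"cn": quant}, fdr=0.1)
        assert (res["fdr"] <= 0.1).sum() <= (res["p"] <= 0.1).sum()

    def test_empty_sample_intersection_is_error(self):
        rng = np.random.default_rng(29)
        gm = _gm_from_dosage(rng.binomial(2, 0.3, 50).astype(float))
        pheno = pd.DataFrame({"y": [0.0, 1.0]}, index=["X1", "X2"])
        with pytest.raises(ValueError, match="intersection"):
            association_scan(gm, {"fam": pheno})

    def test_scanner_is_sklearn_compatible(self):
        est = AssociationScanner(fdr=0.05, global_bh=True)
        params = est.get_params()
        assert params["fdr"] == 0.05 and params["global_bh"] is True
        est.set_params(fdr=0.2)
        assert est.fdr == 0.2


class TestCoverage:
    def test_ci_coverage_and_bias(self):
        """Planted log-OR recovered without bias; 95% CIs cover it ~95% of the time."""
        rng = np.random.default_rng(31)
        covered = []
        for b0 in (-1.35, 0.0, 0.7):
            betas = []
            for _ in range(60):
                d = rng.binomial(2, 0.3, 1000).astype(float)
                p = 1 / (1 + np.exp(-(-0.5 + b0 * d)))
                y = rng.binomial(1, p).astype(float)
                res = fit_glm_additive(d, y, model="logistic")
                betas.append(res.beta)
                covered.append(np.log(res.ci95[0]) <= b0 <= np.log(res.ci95[1]))
            assert abs(np.mean(betas) - b0) < 0.1
        assert 0.92 <= np.mean(covered) <= 0.98


class TestGenotypeContingency:
    def test_reproduces_published_margins(self):
        d, y = _table1_arrays()
        rep = genotype_contingency(d, y, risk_allele="A", other_allele="G")
        assert rep.loc["GG", "pct_with"] == pytest.approx(64.29, abs=0.01)
        assert rep.loc["GG", "pct_without"] == pytest.approx(33.94, abs=0.01)
        assert rep.loc["GA/AA", "n_with"] == 10
        assert rep.loc["GA/AA", "n_without"] == 255
        assert rep.loc["GA/AA", "or"] == pytest.approx((10 * 131) / (18 * 255), rel=1e-6)

    def test_genotype_without_carriers_has_absent_or(self):
        d, y = _table1_arrays()
        rep = genotype_contingency(d, y)
        assert rep.loc["AA", "n_with"] == 0
        assert np.isnan(rep.loc["AA", "or"])

    def test_renders_with_single_class_outcome(self):
        d = np.array([0, 1, 2, 1, 0], float)
        y = np.zeros(5)
        rep = genotype_contingency(d, y)
        assert (rep["n_with"].fillna(0) == 0).all()
        assert rep.loc["GA", "pct_without"] == pytest.approx(40.0)
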