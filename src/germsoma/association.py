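"""Additive-model association scans between risk-SNP dosages and somatic phenotypes.

Each SNP-phenotype pair is tested with a generalized linear model on the
additive genotype coding (risk-allele dosage in [0, 2]): logistic regression
for binary phenotypes, ordinary least squares for quantitative ones, always
with an intercept and optional covariates (age, gender, clinical stage and
genotype principal components, with missing clinical values median-imputed).
P-values are two-sided Wald tests on the dosage coefficient;
Benjamini-Hochberg adjustment is applied within each phenotype family
(driver mutations, key pathways, copy number, lesions, signatures) at an FDR
threshold of 0.1 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .enrichment import bh_adjust
from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "median_impute",
    "fit_glm_additive",
    "AssociationScanner",
    "association_scan",
    "genotype_contingency",
]

_Z95 = norm.ppf(0.975)


@dataclass
class AssociationResult:
    """One SNP-phenotype regression fit."""

    snp_id: str
    phenotype_id: str
    model: str  # "logistic" | "linear"
    beta: float
    se: float
    p: float
    n_used: int
    or_: float | None = None
    ci95: tuple[float, float] = (np.nan, np.nan)
    fdr: float | None = None
    flags: list[str] = field(default_factory=list)


def median_impute(cov: pd.DataFrame) -> pd.DataFrame:
    """Impute missing covariate values: column median (numeric/ordinal) or mode.

    Non-numeric columns (e.g. gender) take the most frequent observed level,
    with a log message.  A column with no observed values is an error.
    """
    out = cov.copy()
    for col in out.columns:
        s = out[col]
        if not s.isna().any():
            continue
        observed = s.dropna()
        if observed.empty:
            raise ValueError(f"covariate column {col!r} is entirely missing")
        if pd.api.types.is_numeric_dtype(s):
            fill = float(observed.median())
        else:
            fill = observed.mode().iloc[0]
            logger.info("median_impute: nominal column %r imputed with mode %r", col, fill)
        out[col] = s.fillna(fill)
    return out


def _design_columns(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    """Numeric design columns from a covariate table (gender dummy-coded)."""
    if covariates is None or covariates.empty:
        return None
    cols = {}
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            cols[col] = s.astype(float)
        else:
            levels = sorted(s.dropna().unique())
            if len(levels) < 2:
                continue  # constant nominal covariate carries no information
            for lev in levels[1:]:
                cols[f"{col}_{lev}"] = (s == lev).astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def fit_glm_additive(
    dosage: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    model: str = "auto",
    snp_id: str = "",
    phenotype_id: str = "",
) -> AssociationResult:
    """Fit one additive-model association and Wald-test the dosage term.

    ``model="auto"`` chooses logistic when the outcome takes only the values
    {0, 1}, linear otherwise.  Logistic fits use Newton iterations to a
    gradient tolerance of 1e-8; non-convergence or perfect separation is
    flagged (P set to missing) rather than raised.  A constant dosage is an
    error ("monomorphic").  For logistic fits with fewer than 10 samples in
    either outcome class the result is flagged "small_class".
    """
    d = np.asarray(dosage, dtype=float)
    yv = np.asarray(y, dtype=float)
    if np.ptp(d) == 0:
        raise ValueError(f"monomorphic dosage for SNP {snp_id!r}")
    X = pd.DataFrame({"dosage": d})
    if covariates is not None:
        design = _design_columns(covariates)
        if design is not None:
            X = pd.concat([X.reset_index(drop=True), design.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, prepend=True)
    is_binary = set(np.unique(yv)) <= {0.0, 1.0}
    if model == "auto":
        model = "logistic" if is_binary else "linear"
    if model == "logistic" and not is_binary:
        raise ValueError("logistic model requires a 0/1 outcome")

    flags: list[str] = []
    n_used = len(yv)
    if model == "logistic":
        n1 = int(yv.sum())
        if min(n1, n_used - n1) < 10:
            flags.append("small_class")
        try:
            res = sm.Logit(yv, X).fit(method="newton", tol=1e-10, maxiter=200, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res, converged = None, False
        if res is None or not converged or not np.isfinite(res.bse["dosage"]):
            flags.append("not_converged")
            return AssociationResult(
                snp_id=snp_id, phenotype_id=phenotype_id, model=model,
                beta=np.nan, se=np.nan, p=np.nan, n_used=n_used, flags=flags,
            )
        beta = float(res.params["dosage"])
        se = float(res.bse["dosage"])
        if abs(beta) > 15:
            flags.append("possible_separation")
        return AssociationResult(
            snp_id=snp_id, phenotype_id=phenotype_id, model=model,
            beta=beta, se=se, p=float(res.pvalues["dosage"]), n_used=n_used,
            or_=float(np.exp(beta)),
            ci95=(float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
            flags=flags,
        )

    res = sm.OLS(yv, X).fit()
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    return AssociationResult(
        snp_id=snp_id, phenotype_id=phenotype_id, model="linear",
        beta=beta, se=se, p=float(res.pvalues["dosage"]), n_used=n_used,
        ci95=(beta - _Z95 * se, beta + _Z95 * se), flags=flags,
    )


class AssociationScanner(BaseEstimator):
    """Scan every SNP against every somatic phenotype with covariate adjustment.

    Parameters
    ----------
    fdr : BH significance threshold applied within each phenotype family.
    model : "auto" (logistic for 0/1 phenotypes, linear otherwise),
        "logistic" or "linear".
    global_bh : adjust across all families jointly instead of per family.

    After :meth:`fit`, ``results_`` holds one row per (SNP, phenotype) with
    effect estimate, Wald P and family-wise BH FDR, sorted by P, and
    ``significant_`` the FDR <= threshold subset.
    """

    def __init__(self, fdr: float = 0.1, model: str = "auto", global_bh: bool = False):
        self.fdr = fdr
        self.model = model
        self.global_bh = global_bh

    def fit(
        self,
        gm: GenotypeMatrix,
        phenotypes: dict[str, pd.DataFrame],
        covariates: pd.DataFrame | None = None,
    ) -> "AssociationScanner":
        if gm.n_variants < 1 or not phenotypes:
            raise ValueError("need at least one SNP and one phenotype family")
        samples = set(gm.dosages.index)
        for fam, mat in phenotypes.items():
            samples &= set(mat.index)
        if covariates is not None:
            samples &= set(covariates.index)
        if not samples:
            raise ValueError("empty sample intersection across inputs")
        samples = sorted(samples)
        cov = median_impute(covariates.loc[samples]) if covariates is not None else None

        rows: list[AssociationResult] = []
        fam_of: list[str] = []
        for fam, mat in phenotypes.items():
            mat = mat.loc[samples]
            for snp in gm.dosages.columns:
                d = gm.dosages.loc[samples, snp]
                for pheno in mat.columns:
                    try:
                        r = fit_glm_additive(
                            d, mat[pheno], covariates=cov, model=self.model,
                            snp_id=str(snp), phenotype_id=str(pheno),
                        )
                    except ValueError as exc:
                        logger.warning("scan: skipped %s x %s (%s)", snp, pheno, exc)
                        continue
                    rows.append(r)
                    fam_of.append(fam)
        res = pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in rows],
                "phenotype_id": [r.phenotype_id for r in rows],
                "family": fam_of,
                "model": [r.model for r in rows],
                "beta": [r.beta for r in rows],
                "se": [r.se for r in rows],
                "or": [r.or_ if r.or_ is not None else np.nan for r in rows],
                "ci95_low": [r.ci95[0] for r in rows],
                "ci95_high": [r.ci95[1] for r in rows],
                "p": [r.p for r in rows],
                "n_used": [r.n_used for r in rows],
                "flags": [";".join(r.flags) for r in rows],
            }
        )
        res["fdr"] = np.nan
        groups = [res.index] if self.global_bh else [
            idx for _, idx in res.groupby("family").groups.items()
        ]
        for idx in groups:
            ok = res.loc[idx, "p"].notna()
            keep = res.loc[idx].index[ok]
            if len(keep):
                res.loc[keep, "fdr"] = bh_adjust(res.loc[keep, "p"].to_numpy())
        self.results_ = res.sort_values("p", kind="stable").reset_index(drop=True)
        self.significant_ = self.results_[self.results_["fdr"] <= self.fdr]
        self.samples_ = samples
        return self


def association_scan(
    gm: GenotypeMatrix,
    phenotypes: dict[str, pd.DataFrame],
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.1,
    model: str = "auto",
    global_bh: bool = False,
) -> pd.DataFrame:
    """One additive-model fit per SNP x phenotype with per-family BH FDR.

    Thin wrapper over :class:`AssociationScanner`; returns ``results_``.
    """
    return AssociationScanner(fdr=fdr, model=model, global_bh=global_bh).fit(
        gm, phenotypes, covariates
    ).results_


def _safe_logistic_or(
    x: np.ndarray, y: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[float, float, float, float]:
    """(OR, lo, hi, p) for a single-predictor logistic fit; NaNs when degenerate."""
    if np.ptp(x) == 0 or len(set(np.unique(y))) < 2:
        return (np.nan,) * 4
    try:
        r = fit_glm_additive(x, y, covariates=covariates, model="logistic")
    except ValueError:
        return (np.nan,) * 4
    if "not_converged" in r.flags or "possible_separation" in r.flags:
        return (np.nan,) * 4
    return r.or_, r.ci95[0], r.ci95[1], r.p


def genotype_contingency(
    dosage: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    risk_allele: str = "A",
    other_allele: str = "G",
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genotype-by-outcome contingency report with per-genotype odds ratios.

    Dosages are rounded to best-guess genotypes {0, 1, 2}; rows are the three
    genotypes (labelled from the alleles, reference homozygote first), the
    dominant collapse (het + hom carriers vs reference) and the additive
    model.  Columns give counts and within-column percentages of samples with
    and without the binary phenotype, plus OR, 95% CI and Wald P (logistic,
    optionally covariate-adjusted).  Cells whose genotype has no carriers in
    one outcome column are reported with an absent OR.
    """
    d = np.clip(np.round(np.asarray(dosage, dtype=float)), 0, 2).astype(int)
    yv = np.asarray(y, dtype=float)
    labels = [
        other_allele * 2,
        other_allele + risk_allele,
        risk_allele * 2,
    ]
    n_with = float((yv == 1).sum())
    n_without = float((yv == 0).sum())

    def pct(n, total):
        return round(100.0 * n / total, 2) if total > 0 else 0.0

    rows = []
    for g, label in enumerate(labels):
        cw = int(((d == g) & (yv == 1)).sum())
        cwo = int(((d == g) & (yv == 0)).sum())
        if g == 0:
            or_, lo, hi, p = 1.0, np.nan, np.nan, np.nan
        elif cw == 0 or cwo == 0:
            or_, lo, hi, p = (np.nan,) * 4  # no carriers in one column
        else:
            mask = (d == 0) | (d == g)
            cov = covariates.iloc[mask] if covariates is not None else None
            or_, lo, hi, p = _safe_logistic_or((d[mask] == g).astype(float), yv[mask], cov)
        rows.append((label, cw, pct(cw, n_with), cwo, pct(cwo, n_without), or_, lo, hi, p))

    carriers = (d >= 1).astype(float)
    cw = int(((d >= 1) & (yv == 1)).sum())
    cwo = int(((d >= 1) & (yv == 0)).sum())
    or_, lo, hi, p = _safe_logistic_or(carriers, yv, covariates)
    rows.append(
        (f"{labels[1]}/{labels[2]}", cw, pct(cw, n_with), cwo, pct(cwo, n_without),
         or_, lo, hi, p)
    )
    or_, lo, hi, p = _safe_logistic_or(d.astype(float), yv, covariates)
    rows.append(("Additive model", np.nan, np.nan, np.nan, np.nan, or_, lo, hi, p))

    return pd.DataFrame(
        rows,
        columns=["genotype", "n_with", "pct_with", "n_without", "pct_without",
                 "or", "ci95_low", "ci95_high", "p"],
    ).set_index("genotype")
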