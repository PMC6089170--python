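"""Variant-level genotype QC, LD pruning and genotype principal components.

Genotypes live in a :class:`GenotypeMatrix`: samples x variants additive
dosages in [0, 2] counted in risk alleles, with per-variant metadata
(alleles, imputation info score, folded MAF, exact Hardy-Weinberg P).

QC defaults follow array-imputation practice for association scans:
imputation info >= 0.5, MAF >= 0.01, HWE exact P >= 0.001.  The HWE test is
the exact (Wigginton-style) two-sided test on best-guess genotypes — dosages
are rounded to the nearest integer for the HWE test only; association uses
the raw dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .io import FormatError, RiskSNP

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "hwe_exact_test",
    "filter_variants",
    "ld_prune",
    "GenotypePCA",
    "genotype_pca",
]

_VARIANT_META_COLS = ["chrom", "pos", "risk_allele", "other_allele", "info"]


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix with per-variant QC metadata.

    ``dosages``: DataFrame indexed by sample id, one column per variant id,
    values in [0, 2] counted in risk alleles.
    ``variants``: DataFrame indexed by variant id with columns chrom, pos,
    risk_allele, other_allele, info, and (after :meth:`compute_qc_metrics`)
    maf and hwe_p.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        if not self.variants.empty and not self.variants.index.equals(
            self.dosages.columns
        ):
            self.variants = self.variants.loc[self.dosages.columns]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def hard_calls(self) -> pd.DataFrame:
        """Best-guess genotypes: dosages rounded to the nearest of {0, 1, 2}."""
        return self.dosages.round().clip(0, 2).astype(int)

    def compute_qc_metrics(self) -> "GenotypeMatrix":
        """Fill per-variant folded MAF and exact HWE P from the dosage data."""
        calls = self.hard_calls().to_numpy()
        n = calls.shape[0]
        freq = self.dosages.to_numpy(dtype=float).mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        hwe = np.empty(self.n_variants)
        for j in range(self.n_variants):
            counts = np.bincount(calls[:, j], minlength=3)
            n_aa, n_het, n_bb = int(counts[0]), int(counts[1]), int(counts[2])
            hwe[j] = hwe_exact_test(n_aa, n_het, n_bb) if n >= 1 else np.nan
        self.variants = self.variants.copy()
        self.variants["maf"] = maf
        self.variants["hwe_p"] = hwe
        return self

    def subset_variants(self, keep: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[keep].copy(), variants=self.variants.loc[keep].copy()
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages.loc[keep].copy(), variants=self.variants.copy()
        )

    # -- dosage matrix TSV: variants as rows, metadata then sample columns --

    def to_tsv(self, path: str | Path) -> None:
        meta = self.variants[[c for c in _VARIANT_META_COLS if c in self.variants]]
        out = pd.concat([meta, self.dosages.T], axis=1)
        out.rename_axis("snp_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="snp_id")
        meta_cols = [c for c in _VARIANT_META_COLS if c in df.columns]
        variants = df[meta_cols]
        dosages = df.drop(columns=meta_cols).T.astype(float)
        dosages.index.name = None
        dosages.columns.name = None
        variants.index.name = None
        if dosages.isna().any().any():
            raise FormatError(f"{path}: missing dosage values")
        return cls(dosages=dosages, variants=variants)


def hwe_exact_test(n_aa: int, n_het: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test from genotype counts.

    Enumerates every heterozygote count with the parity of the observed minor
    allele count, computes each configuration's probability conditional on the
    allele counts, and returns the sum of probabilities not exceeding the
    observed configuration's probability (the exact two-sided P).

    Parameters are the counts of the three genotype classes (either
    homozygote first; the test is symmetric).  Returns a P in (0, 1].
    """
    for c in (n_aa, n_het, n_bb):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_het + n_bb
    if n < 1:
        raise ValueError("at least one genotype observation is required")
    rare = min(2 * n_aa + n_het, 2 * n_bb + n_het)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het | n, rare) up to a shared constant:
    #   n! / (n_rr! n_het! n_cc!) * 2^het, with n_rr = (rare - het) / 2
    n_rr = (rare - hets) // 2
    n_cc = n - hets - n_rr
    logp = hets * np.log(2.0) - gammaln(n_rr + 1) - gammaln(hets + 1) - gammaln(n_cc + 1)
    logp -= logsumexp(logp)
    obs = logp[hets == n_het][0]
    p = float(np.exp(logp[logp <= obs + 1e-10]).sum())
    return min(p, 1.0)


def filter_variants(
    gm: GenotypeMatrix,
    info_min: float = 0.5,
    maf_min: float = 0.01,
    hwe_min: float = 0.001,
) -> GenotypeMatrix:
    """Keep variants with info >= info_min, MAF >= maf_min and HWE P >= hwe_min.

    All three thresholds are inclusive.  Removal counts per criterion are
    logged; an empty result is returned with a warning rather than an error.
    """
    for name, t in (("info_min", info_min), ("maf_min", maf_min), ("hwe_min", hwe_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    v = gm.variants
    if "maf" not in v.columns or "hwe_p" not in v.columns:
        gm = gm.compute_qc_metrics()
        v = gm.variants
    info = v["info"] if "info" in v.columns else pd.Series(1.0, index=v.index)
    ok_info = info >= info_min
    ok_maf = v["maf"] >= maf_min
    ok_hwe = v["hwe_p"] >= hwe_min
    keep = ok_info & ok_maf & ok_hwe
    logger.info(
        "filter_variants: removed %d (info), %d (maf), %d (hwe); kept %d/%d",
        int((~ok_info).sum()), int((~ok_maf).sum()), int((~ok_hwe).sum()),
        int(keep.sum()), len(v),
    )
    if not keep.any():
        logger.warning("filter_variants: no variants pass QC")
    return gm.subset_variants(list(v.index[keep]))


def ld_prune(
    snps: list[RiskSNP], r2: np.ndarray, r2_max: float = 0.8
) -> list[RiskSNP]:
    """Greedy LD pruning: one SNP per LD clump (r^2 >= r2_max).

    SNPs are visited in ascending GWAS P order (missing P last; ties broken by
    input order) and kept iff their r^2 with every already-kept SNP is below
    ``r2_max``.  The returned list preserves input order.
    """
    r2 = np.asarray(r2, dtype=float)
    if r2.shape != (len(snps), len(snps)):
        raise ValueError(
            f"r2 matrix shape {r2.shape} does not match {len(snps)} SNPs"
        )
    order = sorted(
        range(len(snps)),
        key=lambda i: (snps[i].gwas_p if snps[i].gwas_p is not None else np.inf, i),
    )
    kept: list[int] = []
    for i in order:
        if all(r2[i, j] < r2_max for j in kept):
            kept.append(i)
    return [snps[i] for i in sorted(kept)]


def _ld_prune_columns(x: np.ndarray, r2_max: float, window: int) -> np.ndarray:
    """Indices of columns kept by greedy within-window r^2 pruning of a dosage matrix."""
    kept: list[int] = []
    sd = x.std(axis=0)
    for j in range(x.shape[1]):
        if sd[j] == 0:
            continue
        ok = True
        for k in kept:
            if j - k > window:
                continue
            r = np.corrcoef(x[:, j], x[:, k])[0, 1]
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.array(kept, dtype=int)


class GenotypePCA(BaseEstimator):
    """Principal components of a standardized genotype dosage matrix.

    Variants are centred and scaled to unit variance; zero-variance variants
    are excluded with a warning.  By default the PCA is computed on an
    LD-pruned variant subset (pairwise r^2 < ``prune_r2`` within
    ``prune_window``-variant windows, estimated from the dosages themselves);
    set ``prune_r2=None`` to use all QC-passing variants.  Component signs
    follow a deterministic convention: the largest-magnitude variant loading
    of each component is positive.

    Attributes (after fit): ``components_`` (n_pcs x variants_used),
    ``explained_variance_ratio_``, ``variants_used_``, ``pcs_`` (the sample
    scores as a DataFrame with columns PC1..PCn).
    """

    def __init__(
        self,
        n_pcs: int = 10,
        prune_r2: float | None = 0.2,
        prune_window: int = 250,
    ):
        self.n_pcs = n_pcs
        self.prune_r2 = prune_r2
        self.prune_window = prune_window

    def fit(self, gm: GenotypeMatrix, y=None) -> "GenotypePCA":
        x = gm.dosages.to_numpy(dtype=float)
        cols = np.asarray(gm.dosages.columns)
        sd = x.std(axis=0)
        if (sd == 0).any():
            logger.warning(
                "genotype_pca: excluding %d zero-variance variants", int((sd == 0).sum())
            )
        nz = sd > 0
        x, cols = x[:, nz], cols[nz]
        if self.prune_r2 is not None:
            keep = _ld_prune_columns(x, self.prune_r2, self.prune_window)
            x, cols = x[:, keep], cols[keep]
        if x.shape[1] < self.n_pcs:
            raise ValueError(
                f"need >= {self.n_pcs} usable variants for {self.n_pcs} PCs, "
                f"have {x.shape[1]}"
            )
        self.mean_ = x.mean(axis=0)
        self.scale_ = x.std(axis=0)
        z = (x - self.mean_) / self.scale_
        pca = PCA(n_components=self.n_pcs, svd_solver="full")
        scores = pca.fit_transform(z)
        comps = pca.components_
        # deterministic sign: largest-|loading| entry of each component positive
        for k in range(comps.shape[0]):
            i = np.argmax(np.abs(comps[k]))
            if comps[k, i] < 0:
                comps[k] *= -1
                scores[:, k] *= -1
        self.components_ = comps
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.variants_used_ = list(cols)
        self.pcs_ = pd.DataFrame(
            scores,
            index=gm.dosages.index,
            columns=[f"PC{k + 1}" for k in range(self.n_pcs)],
        )
        return self

    def transform(self, gm: GenotypeMatrix) -> pd.DataFrame:
        x = gm.dosages[self.variants_used_].to_numpy(dtype=float)
        z = (x - self.mean_) / self.scale_
        scores = z @ self.components_.T
        return pd.DataFrame(
            scores, index=gm.dosages.index, columns=self.pcs_.columns
        )


def genotype_pca(gm: GenotypeMatrix, n_pcs: int = 10, **kwargs) -> pd.DataFrame:
    """Sample principal components (PC1..PCn) of a genotype matrix; see GenotypePCA."""
    return GenotypePCA(n_pcs=n_pcs, **kwargs).fit(gm).pcs_
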