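"""Susceptibility regions, matched-SNP permutation enrichment and gene-set tests.

The enrichment layer answers two questions about GWAS risk SNPs and somatic
driver genes:

1. *Region enrichment* — is the proportion of driver genes among the coding
   genes resident in risk-SNP flanking regions higher than expected?  The
   null is built from sets of pool SNPs matched to the risk SNPs on allele
   frequency, LD-buddy count, distance to nearest gene and gene density
   (SNPsnap-style matching), and the permutation P is the fraction of matched
   sets whose driver proportion is >= the observed one.

2. *Gene- and pathway-level enrichment* — hypergeometric upper-tail tests of
   susceptibility genes against the driver list, and of both lists against
   each pathway, with Benjamini-Hochberg control across pathways.  Pathways
   in which both lists are enriched at FDR <= 0.1 are "key pathways".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import PathwayGeneSet, RiskSNP, SnpFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "SusceptibilityRegion",
    "EnrichmentResult",
    "build_regions",
    "genes_in_regions",
    "assign_csgs",
    "driver_proportion",
    "sample_matched_snps",
    "region_permutation_test",
    "hypergeom_enrichment",
    "pathway_co_enrichment",
    "bh_adjust",
    "snp_features_from_annotation",
    "per_snp_resident_genes",
]

#: Flank sizes (kb) scanned in the region-enrichment analysis.
DEFAULT_FLANKS_KB = (50, 100, 200, 500)


@dataclass
class SusceptibilityRegion:
    """A genomic window flanking one risk SNP (1-based closed, clipped at 1)."""

    snp_id: str
    chrom: str
    start: int
    end: int
    flank_kb: float


@dataclass
class EnrichmentResult:
    """Outcome of one enrichment test (permutation or hypergeometric)."""

    label: str
    statistic: float
    p: float
    null_count_ge: int | None = None
    n_perm: int | None = None
    fold: float | None = None
    fdr: float | None = None

    def p_display(self) -> str:
        """Permutation P of 0 is reported as a bound, not as exactly zero."""
        if self.n_perm and self.p == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p:g}"


# ---------------------------------------------------------------------------
# regions and susceptibility genes
# ---------------------------------------------------------------------------

def build_regions(
    snps: list[RiskSNP], flank_kb: float = 200
) -> list[SusceptibilityRegion]:
    """One susceptibility region per SNP: pos +/- flank, clipped at position 1."""
    if flank_kb <= 0:
        raise ValueError("flank_kb must be positive")
    flank = int(round(flank_kb * 1000))
    return [
        SusceptibilityRegion(
            snp_id=s.snp_id,
            chrom=s.chrom,
            start=max(1, s.pos - flank),
            end=s.pos + flank,
            flank_kb=flank_kb,
        )
        for s in snps
    ]


def genes_in_regions(
    regions: list[SusceptibilityRegion], genes: pd.DataFrame, coding_only: bool = True
) -> frozenset[str]:
    """Symbols of (coding) genes whose interval overlaps any region by >= 1 bp."""
    g = genes[genes["coding"]] if coding_only else genes
    hit: set[str] = set()
    by_chrom = {c: sub for c, sub in g.groupby("chrom")}
    for r in regions:
        sub = by_chrom.get(r.chrom)
        if sub is None:
            continue
        mask = (sub["start"].to_numpy() <= r.end) & (sub["end"].to_numpy() >= r.start)
        hit.update(sub["gene_symbol"].to_numpy()[mask])
    return frozenset(hit)


def assign_csgs(
    regions: list[SusceptibilityRegion],
    genes: pd.DataFrame,
    eqtl_genes: list[str] | None = None,
) -> frozenset[str]:
    """Cancer susceptibility genes: region-resident coding genes plus eQTL genes.

    eQTL-derived symbols absent from the annotation are kept (and logged) —
    the eQTL list is an external input and may use a different gene universe.
    """
    resident = set(genes_in_regions(regions, genes))
    eqtl_genes = list(eqtl_genes or [])
    known = set(genes["gene_symbol"])
    for g in eqtl_genes:
        if g not in known:
            logger.info("assign_csgs: eQTL gene %s absent from annotation; kept", g)
    return frozenset(resident | set(eqtl_genes))


def driver_proportion(
    regions: list[SusceptibilityRegion],
    genes: pd.DataFrame,
    drivers: frozenset[str] | set[str],
) -> float:
    """Fraction of distinct region-resident coding genes that are driver genes.

    Returns 0 (with a warning) when no coding gene falls in any region.
    """
    if genes.empty:
        raise ValueError("empty gene annotation")
    resident = genes_in_regions(regions, genes)
    if not resident:
        logger.warning("driver_proportion: no coding genes resident in regions")
        return 0.0
    return len(resident & set(drivers)) / len(resident)


def per_snp_resident_genes(
    snps: list[RiskSNP],
    genes: pd.DataFrame,
    flank_kb: float,
    coding_only: bool = True,
) -> dict[str, frozenset[str]]:
    """Resident coding genes of each SNP's flanking region, in one indexed pass.

    Equivalent to calling :func:`genes_in_regions` per single-SNP region, but
    fast enough to score thousands of pool SNPs for the permutation null.
    """
    flank = int(round(flank_kb * 1000))
    g = genes[genes["coding"]] if coding_only else genes
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in g.groupby("chrom"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        by_chrom[chrom] = (
            starts, ends, np.maximum.accumulate(ends), sub["gene_symbol"].to_numpy()
        )
    out: dict[str, frozenset[str]] = {}
    for s in snps:
        entry = by_chrom.get(s.chrom)
        if entry is None:
            out[s.snp_id] = frozenset()
            continue
        starts, ends, cummax_end, syms = entry
        lo_bound = max(1, s.pos - flank)
        hi = int(np.searchsorted(starts, s.pos + flank, side="right"))
        lo = int(np.searchsorted(cummax_end, lo_bound, side="left"))
        sel = ends[lo:hi] >= lo_bound
        out[s.snp_id] = frozenset(syms[lo:hi][sel])
    return out


def snp_features_from_annotation(
    snps: list[RiskSNP],
    genes: pd.DataFrame,
    ld_buddies: dict[str, int],
    density_flank: int = 500_000,
) -> list[SnpFeatures]:
    """Compute matching features (distance to nearest gene, gene density) from
    an annotation; MAF comes from the SNP record and LD-buddy counts are an
    external input (no LD computation from reference panels here)."""
    out = []
    by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    for s in snps:
        sub = by_chrom.get(s.chrom)
        if sub is None or sub.empty:
            dist, dens = float("inf"), 0
        else:
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            d = np.where(
                (starts <= s.pos) & (s.pos <= ends),
                0,
                np.minimum(np.abs(starts - s.pos), np.abs(ends - s.pos)),
            )
            dist = float(d.min())
            dens = int(((starts <= s.pos + density_flank) & (ends >= s.pos - density_flank)).sum())
        out.append(
            SnpFeatures(
                snp_id=s.snp_id,
                maf=s.maf,
                ld_buddies=ld_buddies.get(s.snp_id, 0),
                dist_nearest_gene=dist,
                gene_density=dens,
            )
        )
    return out


# ---------------------------------------------------------------------------
# matched-SNP sampling
# ---------------------------------------------------------------------------

#: Matching windows: MAF absolute, the rest relative (SNPsnap-style defaults).
DEFAULT_MAF_WINDOW = 0.05
DEFAULT_REL_WINDOW = 0.5
#: A target feature of zero matches pool values at or below these floors.
DEFAULT_ZERO_FLOORS = {"ld_buddies": 1.0, "dist_nearest_gene": 10_000.0, "gene_density": 1.0}


def _eligible(
    target: SnpFeatures,
    pool: list[SnpFeatures],
    maf_window: float,
    rel_window: float,
    zero_floors: dict[str, float],
) -> np.ndarray:
    ok = np.ones(len(pool), dtype=bool)
    maf = np.array([p.maf for p in pool])
    ok &= np.abs(maf - target.maf) <= maf_window
    for feat in ("ld_buddies", "dist_nearest_gene", "gene_density"):
        vals = np.array([getattr(p, feat) for p in pool], dtype=float)
        t = float(getattr(target, feat))
        if t <= zero_floors[feat] or not math.isfinite(t):
            # a zero/near-zero target would get a vanishing relative window;
            # it matches any pool value at or below the floor instead
            ok &= vals <= zero_floors[feat]
        else:
            ok &= np.abs(vals - t) <= rel_window * t
    return np.flatnonzero(ok)


def sample_matched_snps(
    targets: list[SnpFeatures],
    pool: list[SnpFeatures],
    n_sets: int = 10_000,
    seed: int | np.random.Generator = 0,
    maf_window: float = DEFAULT_MAF_WINDOW,
    rel_window: float = DEFAULT_REL_WINDOW,
    zero_floors: dict[str, float] | None = None,
) -> list[list[str]]:
    """Draw ``n_sets`` feature-matched SNP sets from a background pool.

    Each set contains one pool SNP per target, sampled uniformly (seeded RNG)
    from the target's eligibility window — |MAF difference| <= ``maf_window``,
    and LD-buddy count, distance to nearest gene and gene density each within
    +/- ``rel_window`` (relative) of the target's value (a target at or below
    a feature's small-value floor matches pool values at or below that floor).
    Within a set, SNPs are drawn without replacement.

    Raises if a target has no eligible match (naming the SNP), or fewer than
    ``n_sets / 10`` eligible matches (suggesting wider tolerances).
    """
    zero_floors = dict(DEFAULT_ZERO_FLOORS, **(zero_floors or {}))
    target_ids = {t.snp_id for t in targets}
    pool = [p for p in pool if p.snp_id not in target_ids]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pool_ids = np.array([p.snp_id for p in pool])
    elig: list[np.ndarray] = []
    min_needed = max(1, math.ceil(n_sets / 10))
    for t in targets:
        idx = _eligible(t, pool, maf_window, rel_window, zero_floors)
        if idx.size == 0:
            raise ValueError(f"no eligible pool match for target SNP {t.snp_id}")
        if idx.size < min_needed:
            raise ValueError(
                f"target SNP {t.snp_id} has only {idx.size} eligible matches "
                f"(< {min_needed} for {n_sets} sets); widen the matching tolerances"
            )
        elig.append(idx)

    # fill scarcest targets first so without-replacement conflicts stay rare
    order = np.argsort([e.size for e in elig])
    sets: list[list[str]] = []
    for _ in range(n_sets):
        chosen: dict[int, int] = {}
        used: set[int] = set()
        for ti in order:
            cands = elig[ti]
            for _attempt in range(100):
                pick = int(cands[rng.integers(cands.size)])
                if pick not in used:
                    break
            else:
                free = [c for c in cands if c not in used]
                if not free:
                    raise ValueError(
                        f"cannot draw a within-set-unique match for target "
                        f"{targets[ti].snp_id}; widen the matching tolerances"
                    )
                pick = int(free[rng.integers(len(free))])
            used.add(pick)
            chosen[ti] = pick
        sets.append([str(pool_ids[chosen[ti]]) for ti in range(len(targets))])
    return sets


def region_permutation_test(
    observed: float,
    null_props: list[float] | np.ndarray,
    label: str = "region_enrichment",
    add_one: bool = False,
) -> EnrichmentResult:
    """Permutation P for region enrichment: #{null >= observed} / n_perm.

    Ties count toward the numerator.  ``add_one`` switches to the
    (count + 1) / (n + 1) estimator; off by default to match the plain
    count / n_perm convention.
    """
    nulls = np.asarray(null_props, dtype=float)
    n_perm = nulls.size
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    count = int((nulls >= observed).sum())
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return EnrichmentResult(
        label=label, statistic=float(observed), p=float(p),
        null_count_ge=count, n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# hypergeometric and pathway tests
# ---------------------------------------------------------------------------

def hypergeom_enrichment(k: int, n_draw: int, K: int, N: int) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric P of an overlap.

    ``k`` genes of a drawn set of ``n_draw`` fall in a category of size ``K``
    within a universe of ``N`` genes.  Returns
    ``fold = (k / n_draw) / (K / N)`` and ``P(X >= k)`` for
    X ~ Hypergeometric(N, K, n_draw).
    """
    if not (0 <= k <= n_draw and k <= K and n_draw <= N and K <= N):
        raise ValueError(
            f"invalid hypergeometric configuration k={k}, n_draw={n_draw}, K={K}, N={N}"
        )
    fold = (k / n_draw) / (K / N) if n_draw and K else 0.0
    p = float(hypergeom.sf(k - 1, N, K, n_draw))
    return fold, min(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (input order preserved).

    adjusted[i] = min over ranks j >= rank(i) of p(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def pathway_co_enrichment(
    pathways: list[PathwayGeneSet],
    csgs: frozenset[str] | set[str],
    drivers: frozenset[str] | set[str],
    universe_size: int,
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """Per-pathway hypergeometric enrichment of susceptibility and driver genes.

    Pathways are prefiltered to those containing at least one driver or
    susceptibility gene.  For each pathway two upper-tail tests are run — the
    pathway's overlap with the CSG list and with the driver list, against a
    universe of ``universe_size`` genes — and BH adjustment is applied across
    pathways separately per gene list.  Key pathways have FDR <= ``fdr_max``
    on both sides.

    Returns a DataFrame indexed by pathway name with columns n_genes,
    csg_k/csg_fold/csg_p/csg_fdr, driver_k/driver_fold/driver_p/driver_fdr,
    and a boolean ``key`` column.
    """
    if not pathways:
        raise ValueError("empty pathway list")
    csgs, drivers = set(csgs), set(drivers)
    kept = [pw for pw in pathways if pw.genes & (csgs | drivers)]
    if not kept:
        raise ValueError("no pathway contains a driver or susceptibility gene")
    rows = []
    for pw in kept:
        n_draw = len(pw.genes)
        k_c = len(pw.genes & csgs)
        k_d = len(pw.genes & drivers)
        fold_c, p_c = hypergeom_enrichment(k_c, n_draw, len(csgs), universe_size)
        fold_d, p_d = hypergeom_enrichment(k_d, n_draw, len(drivers), universe_size)
        rows.append(
            {
                "pathway": pw.name,
                "n_genes": n_draw,
                "csg_k": k_c,
                "csg_fold": fold_c,
                "csg_p": p_c,
                "driver_k": k_d,
                "driver_fold": fold_d,
                "driver_p": p_d,
            }
        )
    res = pd.DataFrame(rows).set_index("pathway")
    res["csg_fdr"] = bh_adjust(res["csg_p"].to_numpy())
    res["driver_fdr"] = bh_adjust(res["driver_p"].to_numpy())
    res["key"] = (res["csg_fdr"] <= fdr_max) & (res["driver_fdr"] <= fdr_max)
    return res
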