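"""Synthetic cohort generator with known ground truth for every pipeline stage.

The generator emulates the inputs of a germline-somatic interaction study of
a gastric-cancer cohort: imputed genotype dosages at GWAS risk SNPs (Hardy-
Weinberg draws at stated MAFs, with imputation info scores), a background SNP
pool with matching features, a protein-coding gene annotation with driver
genes optionally planted near risk SNPs, pathway gene sets constructed so a
known number pass both co-enrichment tests, per-sample somatic mutation
catalogs drawn from stated signature mixtures, gene-level copy number and
GISTIC-style lesions, clinical covariates, and planted genotype-to-somatic-
phenotype effects of stated odds ratios or slopes.

Default cohort parameters mirror the study design the pipeline targets:
442 samples, 11 risk SNPs, 276 driver genes, 8 key pathways, 11 reference
signatures; the gene/SNP universe is scaled down (2,000 coding genes, 5,000
pool SNPs) so the full analysis runs in seconds.  Every generator is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .enrichment import build_regions, genes_in_regions, snp_features_from_annotation
from .io import (
    CONTEXTS_96,
    LesionTable,
    MutationRecord,
    PathwayGeneSet,
    RiskSNP,
    SnpFeatures,
)
from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "PlantedEffect",
    "GASTRIC_SIGNATURES",
    "make_synthetic_signatures",
    "simulate_risk_snps",
    "simulate_genotypes",
    "simulate_annotation_and_sets",
    "simulate_somatic",
    "simulate_covariates",
    "simulate_cohort",
    "write_cohort",
    "AnnotationSets",
    "SomaticData",
    "SyntheticCohort",
]

#: The 11 COSMIC signature names reported in gastric tumors.  The reference
#: matrix used in tests is synthetic (well-separated columns, see
#: :func:`make_synthetic_signatures`); the real COSMIC matrix is a drop-in
#: user input with the same shape.
GASTRIC_SIGNATURES = (
    "Signature.1", "Signature.2", "Signature.5", "Signature.13",
    "Signature.15", "Signature.17", "Signature.18", "Signature.20",
    "Signature.21", "Signature.26", "Signature.28",
)

_TRUNCATING = ("Nonsense", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site", "Nonstop")


@dataclass
class PlantedEffect:
    """A known genotype-to-somatic-phenotype effect.

    ``family`` is one of driver_mutation / pathway_truncation / copy_number /
    lesion / signature.  ``effect`` is a log-odds ratio for binary families, a
    per-allele slope for copy_number, and a per-allele weight shift for
    signature.  ``baseline`` is the phenotype prevalence at dosage 0 (binary
    families only).
    """

    snp_id: str
    phenotype: str
    family: str
    effect: float
    baseline: float = 0.15


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Counts default to the target study design (442 samples, 11 risk SNPs,
    276 drivers, 8 key pathways); the genome is scaled down for speed.
    """

    seed: int
    n_samples: int = 442
    n_risk_snps: int = 11
    n_pool_snps: int = 5000
    mafs: list[float] | None = None        # per risk SNP; default U(0.05, 0.5)
    dosage_noise_sd: float = 0.0           # optional imputation-style noise
    info_range: tuple[float, float] = (0.3, 1.0)

    n_chromosomes: int = 10
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    gene_gap_range: tuple[int, int] = (5_000, 60_000)

    n_drivers: int = 276
    driver_planting_rate: float = 0.0      # P(plant drivers near a risk SNP)
    planted_drivers_per_snp: int = 1
    planting_flank: int = 50_000

    n_eqtl_genes: int = 5
    key_pathway_count: int = 8
    n_background_pathways: int = 40
    pathway_size: int = 40
    # planted overlaps per key pathway; None = smallest counts whose
    # hypergeometric tail clears the BH threshold with a 20x safety margin
    key_pathway_drivers: int | None = None
    key_pathway_csgs: int | None = None

    n_signatures: int = 11
    n_active_signatures: int = 3
    dirichlet_alpha: float = 1.0
    true_signature_weights: np.ndarray | None = None  # n_samples x K, overrides

    mutations_per_sample_mean: float = 120.0
    mutations_per_sample_shape: float = 5.0  # negative-binomial shape
    truncation_fraction: float = 0.10
    silent_fraction: float = 0.30

    n_lesions: int = 10
    lesion_code_probs: tuple[float, float, float] = (0.8, 0.15, 0.05)
    cn_noise_sd: float = 0.3
    cn_planted_baseline: float = 1.0       # keeps planted CN genes away from 0

    missing_covariate_rate: float = 0.05
    planted_effects: list[PlantedEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for e in self.planted_effects:
            if e.family in ("driver_mutation", "pathway_truncation", "lesion"):
                if not 0 < e.baseline < 1:
                    raise ValueError(f"baseline for {e.phenotype} must be in (0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def make_synthetic_signatures(
    k: int = 11, seed: int = 20180620, names: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """A deterministic 96 x k column-stochastic matrix with well-separated columns.

    Each synthetic signature concentrates most of its mass on a distinct block
    of channels, giving a well-conditioned refitting problem.  This is a
    synthetic stand-in with the same shape and conventions as a COSMIC
    reference matrix, not the COSMIC matrix itself.
    """
    rng = np.random.default_rng(seed)
    if names is None:
        names = GASTRIC_SIGNATURES[:k] if k <= len(GASTRIC_SIGNATURES) else tuple(
            f"Signature.S{i}" for i in range(1, k + 1)
        )
    if len(names) != k:
        raise ValueError("need exactly k signature names")
    S = rng.uniform(0.1, 1.0, size=(96, k))
    block = 96 // k
    for j in range(k):
        lo = j * block
        hi = 96 if j == k - 1 else lo + block
        S[lo:hi, j] += 20.0 * rng.uniform(0.5, 1.5, size=hi - lo)
    S /= S.sum(axis=0, keepdims=True)
    return pd.DataFrame(S, index=list(CONTEXTS_96), columns=list(names))


# ---------------------------------------------------------------------------
# genome, SNPs, genotypes
# ---------------------------------------------------------------------------

def _chrom_names(n: int) -> list[str]:
    return [f"chr{i}" for i in range(1, n + 1)]


def simulate_risk_snps(cfg: SimConfig) -> list[RiskSNP]:
    """Risk SNPs placed uniformly on the synthetic genome with stated MAFs."""
    rng = cfg.rng(1)
    chrom_span = _genome_span(cfg)
    chroms = _chrom_names(cfg.n_chromosomes)
    mafs = cfg.mafs if cfg.mafs is not None else rng.uniform(
        0.05, 0.5, size=cfg.n_risk_snps
    ).tolist()
    if len(mafs) != cfg.n_risk_snps:
        raise ValueError("mafs must have one entry per risk SNP")
    snps = []
    margin = min(500_000, chrom_span // 4)  # keep density windows off chromosome ends
    for i in range(cfg.n_risk_snps):
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        pos = int(rng.integers(1 + margin, chrom_span - margin))
        snps.append(
            RiskSNP(
                snp_id=f"rs{100000 + i}", chrom=chrom, pos=pos,
                risk_allele="A", other_allele="G", maf=float(mafs[i]),
                gwas_p=float(10 ** -rng.uniform(6, 9)),
            )
        )
    return snps


def simulate_genotypes(
    cfg: SimConfig, snps: list[RiskSNP] | None = None
) -> GenotypeMatrix:
    """Hardy-Weinberg genotype dosages at the risk SNPs.

    Risk-allele dosage per sample is Binomial(2, MAF) (risk allele = minor
    allele); optional Gaussian dosage noise emulates imputation uncertainty,
    and per-variant imputation info scores are drawn uniformly from
    ``cfg.info_range`` so the downstream QC filter has variants to remove.
    """
    if snps is None:
        snps = simulate_risk_snps(cfg)
    rng = cfg.rng(2)
    samples = [f"TCGA-SY-{i:04d}" for i in range(cfg.n_samples)]  # patient-level barcodes
    d = np.column_stack(
        [rng.binomial(2, s.maf, size=cfg.n_samples).astype(float) for s in snps]
    )
    if cfg.dosage_noise_sd > 0:
        d = np.clip(d + rng.normal(0, cfg.dosage_noise_sd, size=d.shape), 0, 2)
    dosages = pd.DataFrame(d, index=samples, columns=[s.snp_id for s in snps])
    variants = pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "risk_allele": [s.risk_allele for s in snps],
            "other_allele": [s.other_allele for s in snps],
            "info": rng.uniform(*cfg.info_range, size=len(snps)),
        },
        index=dosages.columns,
    )
    return GenotypeMatrix(dosages=dosages, variants=variants).compute_qc_metrics()


def _min_enriched_overlap(p_target: float, n_draw: int, K: int, N: int) -> int:
    """Smallest overlap k whose hypergeometric upper-tail P is <= p_target."""
    from scipy.stats import hypergeom

    kmax = min(n_draw, K)
    for k in range(1, kmax + 1):
        if hypergeom.sf(k - 1, N, K, n_draw) <= p_target:
            return k
    logger.warning(
        "cannot reach p<=%g with n_draw=%d, K=%d, N=%d; planting the maximum %d",
        p_target, n_draw, K, N, kmax,
    )
    return kmax


def _genome_span(cfg: SimConfig) -> int:
    """Approximate per-chromosome span implied by the gene tiling."""
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    mean_pitch = (sum(cfg.gene_length_range) + sum(cfg.gene_gap_range)) / 2
    return int(genes_per_chrom * mean_pitch)


# ---------------------------------------------------------------------------
# annotation, drivers, pathways
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSets:
    """Gene annotation and gene lists with recorded ground truth."""

    genes: pd.DataFrame
    drivers: frozenset[str]
    eqtl_genes: list[str]
    pathways: list[PathwayGeneSet]
    risk_snps: list[RiskSNP]
    pool_snps: list[RiskSNP]
    target_features: list[SnpFeatures]
    pool_features: list[SnpFeatures]
    key_pathway_names: list[str]
    planted_driver_genes: frozenset[str]


def simulate_annotation_and_sets(
    cfg: SimConfig, risk_snps: list[RiskSNP] | None = None
) -> AnnotationSets:
    """Tile genes on synthetic chromosomes and build driver/CSG/pathway sets.

    A fraction ``driver_planting_rate`` of risk SNPs get
    ``planted_drivers_per_snp`` resident genes (within +/- ``planting_flank``)
    converted to drivers; the remaining drivers are drawn uniformly.  Key
    pathways are constructed with enough drivers and susceptibility genes to
    pass both enrichment tests at FDR <= 0.1; background pathways are uniform
    draws.  Pool SNPs are placed uniformly and their matching features
    computed from the annotation (LD-buddy counts are drawn independently,
    Poisson with the same mean for pool and targets).
    """
    rng = cfg.rng(3)
    chroms = _chrom_names(cfg.n_chromosomes)
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)

    rows = []
    gid = 0
    for chrom in chroms:
        pos = 1
        for _ in range(genes_per_chrom):
            if gid >= cfg.n_genes:
                break
            length = int(rng.integers(*cfg.gene_length_range))
            gap = int(rng.integers(*cfg.gene_gap_range))
            start = pos + gap
            rows.append((f"G{gid:05d}", chrom, start, start + length, True))
            pos = start + length
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_symbol", "chrom", "start", "end", "coding"])

    if risk_snps is None:
        risk_snps = simulate_risk_snps(cfg)

    # plant drivers near risk SNPs
    planted: set[str] = set()
    for s in risk_snps:
        if rng.random() >= cfg.driver_planting_rate:
            continue
        sub = genes[genes["chrom"] == s.chrom]
        near = sub[
            (sub["start"] <= s.pos + cfg.planting_flank)
            & (sub["end"] >= s.pos - cfg.planting_flank)
        ]
        if near.empty:  # fall back to the nearest gene on the chromosome
            d = np.minimum(
                np.abs(sub["start"].to_numpy() - s.pos),
                np.abs(sub["end"].to_numpy() - s.pos),
            )
            near = sub.iloc[np.argsort(d)[: cfg.planted_drivers_per_snp]]
        take = near["gene_symbol"].tolist()[: cfg.planted_drivers_per_snp]
        planted.update(take)
    others = [g for g in genes["gene_symbol"] if g not in planted]
    n_extra = max(0, cfg.n_drivers - len(planted))
    drivers = frozenset(planted | set(rng.choice(others, size=n_extra, replace=False)))

    eqtl_genes = list(rng.choice(genes["gene_symbol"], size=cfg.n_eqtl_genes, replace=False))

    # susceptibility genes at the default 200 kb flank, for pathway construction
    regions = build_regions(risk_snps, flank_kb=200)
    csgs = set(genes_in_regions(regions, genes)) | set(eqtl_genes)

    all_symbols = genes["gene_symbol"].tolist()
    pathways: list[PathwayGeneSet] = []
    key_names: list[str] = []
    csg_nondriver = sorted(csgs - drivers)
    driver_list = sorted(drivers)
    n_pathways = cfg.key_pathway_count + cfg.n_background_pathways
    # BH across n_pathways at FDR 0.1 with the key pathways occupying the top
    # ranks needs p <= 0.1 * key_count / n_pathways; plant with a 20x margin.
    p_target = 0.1 * max(1, cfg.key_pathway_count) / max(1, n_pathways) / 20.0
    k_driver = cfg.key_pathway_drivers
    if k_driver is None:
        k_driver = _min_enriched_overlap(
            p_target, cfg.pathway_size, len(drivers), cfg.n_genes
        )
    k_csg = cfg.key_pathway_csgs
    if k_csg is None:
        k_csg = _min_enriched_overlap(
            p_target, cfg.pathway_size, len(csg_nondriver), cfg.n_genes
        )
    for i in range(cfg.key_pathway_count):
        n_csg = min(k_csg, len(csg_nondriver))
        members = set(rng.choice(driver_list, size=min(k_driver, len(driver_list)),
                                 replace=False))
        members |= set(rng.choice(csg_nondriver, size=n_csg, replace=False))
        filler = [g for g in all_symbols if g not in members and g not in csgs and g not in drivers]
        need = max(0, cfg.pathway_size - len(members))
        members |= set(rng.choice(filler, size=need, replace=False))
        name = f"KEY_PW_{i + 1}"
        pathways.append(PathwayGeneSet(name=name, genes=frozenset(members)))
        key_names.append(name)
    for i in range(cfg.n_background_pathways):
        members = set(rng.choice(all_symbols, size=cfg.pathway_size, replace=False))
        pathways.append(PathwayGeneSet(name=f"PW_{i + 1}", genes=frozenset(members)))

    # pool SNPs with matching features
    span = _genome_span(cfg)
    margin = min(500_000, span // 4)
    pool: list[RiskSNP] = []
    for i in range(cfg.n_pool_snps):
        pool.append(
            RiskSNP(
                snp_id=f"pool{i}",
                chrom=chroms[int(rng.integers(cfg.n_chromosomes))],
                pos=int(rng.integers(1 + margin, span - margin)),
                risk_allele="A", other_allele="G",
                maf=float(rng.uniform(0.05, 0.5)),
            )
        )
    # the synthetic genome carries no LD structure, so every SNP has zero LD
    # buddies; the matching floor makes the feature non-binding, as it should be
    buddies = {s.snp_id: 0 for s in risk_snps + pool}
    target_features = snp_features_from_annotation(risk_snps, genes, buddies)
    pool_features = snp_features_from_annotation(pool, genes, buddies)

    return AnnotationSets(
        genes=genes,
        drivers=drivers,
        eqtl_genes=eqtl_genes,
        pathways=pathways,
        risk_snps=risk_snps,
        pool_snps=pool,
        target_features=target_features,
        pool_features=pool_features,
        key_pathway_names=key_names,
        planted_driver_genes=frozenset(planted),
    )


# ---------------------------------------------------------------------------
# somatic data
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _channel_to_record(channel: str, sample: str, gene: str, classification: str) -> MutationRecord:
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return MutationRecord(
        sample_id=sample, gene_symbol=gene, variant_classification=classification,
        ref_allele=ref, alt_allele=alt, context5=five, context3=three,
    )


@dataclass
class SomaticData:
    """Synthetic somatic inputs plus the ground truth used to generate them."""

    records: list[MutationRecord]
    cn: pd.DataFrame                      # genes x samples signed CN values
    lesions: LesionTable
    signatures: pd.DataFrame              # 96 x K reference used
    true_weights: pd.DataFrame            # samples x K
    true_flags: dict[str, pd.Series]      # planted binary phenotype per (snp, phenotype)


def simulate_somatic(
    cfg: SimConfig,
    gm: GenotypeMatrix,
    sets: AnnotationSets,
    signatures: pd.DataFrame | None = None,
) -> SomaticData:
    """Per-sample mutation catalogs, copy number and lesions with planted effects.

    Mutation counts are negative-binomial; each SNV's channel is drawn from
    the sample's true signature mixture (contexts emitted directly);
    classifications are truncating with probability ``truncation_fraction``.
    Binary planted effects follow logistic models in the risk-allele dosage:
    the phenotype flag is drawn first and the mutation records are made
    consistent with it (planted genes/pathways receive no background records).
    Copy-number values are Gaussian around 0 (planted genes: around
    ``cn_planted_baseline``) with planted per-allele slopes.
    """
    rng = cfg.rng(4)
    samples = list(gm.dosages.index)
    n = len(samples)
    if signatures is None:
        signatures = make_synthetic_signatures(cfg.n_signatures)
    S = signatures.to_numpy()
    K = S.shape[1]

    # per-sample true signature mixtures
    if cfg.true_signature_weights is not None:
        W = np.asarray(cfg.true_signature_weights, dtype=float)
        if W.ndim == 1:
            W = np.tile(W, (n, 1))
    else:
        W = np.zeros((n, K))
        for i in range(n):
            active = rng.choice(K, size=min(cfg.n_active_signatures, K), replace=False)
            W[i, active] = rng.dirichlet([cfg.dirichlet_alpha] * len(active))
    sig_effects = [e for e in cfg.planted_effects if e.family == "signature"]
    for e in sig_effects:
        j = list(signatures.columns).index(e.phenotype)
        dose = gm.dosages[e.snp_id].to_numpy()
        W[:, j] = np.clip(W[:, j] + e.effect * dose, 0, None)
    W /= W.sum(axis=1, keepdims=True)

    # reserved targets of binary planted effects get no background records
    gene_effects = [e for e in cfg.planted_effects if e.family == "driver_mutation"]
    pw_effects = [e for e in cfg.planted_effects if e.family == "pathway_truncation"]
    reserved_genes = {e.phenotype for e in gene_effects}
    pw_by_name = {p.name: p for p in sets.pathways}
    reserved_trunc_genes = set()
    for e in pw_effects:
        reserved_trunc_genes |= set(pw_by_name[e.phenotype].genes)
    bg_genes = np.array(
        [g for g in sets.genes["gene_symbol"] if g not in reserved_genes]
    )
    bg_trunc_genes = np.array(
        [g for g in bg_genes if g not in reserved_trunc_genes]
    )

    shape = cfg.mutations_per_sample_shape
    mean = cfg.mutations_per_sample_mean
    totals = rng.negative_binomial(shape, shape / (shape + mean), size=n)
    contexts = np.array(CONTEXTS_96)

    records: list[MutationRecord] = []
    true_flags: dict[str, pd.Series] = {}
    flag_draws: dict[tuple[str, str], np.ndarray] = {}
    for e in gene_effects + pw_effects:
        dose = gm.dosages[e.snp_id].to_numpy()
        logit0 = np.log(e.baseline / (1 - e.baseline))
        p = _sigmoid(logit0 + e.effect * dose)
        flags = rng.binomial(1, p)
        flag_draws[(e.snp_id, e.phenotype)] = flags
        true_flags[f"{e.snp_id}:{e.phenotype}"] = pd.Series(flags, index=samples)

    for i, sid in enumerate(samples):
        m = max(1, int(totals[i]))
        probs = S @ W[i]
        chans = contexts[rng.choice(96, size=m, p=probs / probs.sum())]
        is_trunc = rng.random(m) < cfg.truncation_fraction
        for ch, tr in zip(chans, is_trunc):
            if tr:
                cls = _TRUNCATING[int(rng.integers(len(_TRUNCATING)))]
                gene = str(bg_trunc_genes[rng.integers(bg_trunc_genes.size)])
            else:
                cls = "Silent" if rng.random() < cfg.silent_fraction else "Missense"
                gene = str(bg_genes[rng.integers(bg_genes.size)])
            records.append(_channel_to_record(ch, sid, gene, cls))
        # planted driver-gene mutations
        for e in gene_effects:
            if flag_draws[(e.snp_id, e.phenotype)][i]:
                ch = contexts[rng.choice(96, p=probs / probs.sum())]
                records.append(_channel_to_record(ch, sid, e.phenotype, "Missense"))
        # planted pathway truncation mutations
        for e in pw_effects:
            if flag_draws[(e.snp_id, e.phenotype)][i]:
                pw_genes = sorted(pw_by_name[e.phenotype].genes)
                gene = pw_genes[int(rng.integers(len(pw_genes)))]
                cls = _TRUNCATING[int(rng.integers(len(_TRUNCATING)))]
                ch = contexts[rng.choice(96, p=probs / probs.sum())]
                records.append(_channel_to_record(ch, sid, gene, cls))

    # copy number: drivers x samples
    driver_list = sorted(sets.drivers)
    cn = rng.normal(0.0, cfg.cn_noise_sd, size=(len(driver_list), n))
    cn_effects = [e for e in cfg.planted_effects if e.family == "copy_number"]
    cn_df = pd.DataFrame(cn, index=driver_list, columns=samples)
    for e in cn_effects:
        dose = gm.dosages[e.snp_id].to_numpy()
        cn_df.loc[e.phenotype] = (
            cfg.cn_planted_baseline
            + e.effect * dose
            + rng.normal(0, cfg.cn_noise_sd, size=n)
        )

    # lesions
    lesion_ids = [f"Amp {i}p{i}.1" for i in range(1, cfg.n_lesions // 2 + 1)] + [
        f"Del {i}q{i}.2" for i in range(1, cfg.n_lesions - cfg.n_lesions // 2 + 1)
    ]
    codes = rng.choice([0, 1, 2], size=(len(lesion_ids), n), p=cfg.lesion_code_probs)
    codes_df = pd.DataFrame(codes, index=lesion_ids, columns=samples)
    for e in cfg.planted_effects:
        if e.family != "lesion":
            continue
        dose = gm.dosages[e.snp_id].to_numpy()
        logit0 = np.log(e.baseline / (1 - e.baseline))
        flags = rng.binomial(1, _sigmoid(logit0 + e.effect * dose))
        codes_df.loc[e.phenotype] = flags * rng.choice([1, 2], size=n)
        true_flags[f"{e.snp_id}:{e.phenotype}"] = pd.Series(flags, index=samples)
    lesion_type = {
        lid: ("amplification" if lid.startswith("Amp") else "deletion")
        for lid in codes_df.index
    }
    lesions = LesionTable(codes=codes_df, lesion_type=lesion_type)

    return SomaticData(
        records=records,
        cn=cn_df,
        lesions=lesions,
        signatures=signatures,
        true_weights=pd.DataFrame(W, index=samples, columns=signatures.columns),
        true_flags=true_flags,
    )


def simulate_covariates(cfg: SimConfig, samples: list[str]) -> pd.DataFrame:
    """Clinical covariates (age, gender, ordinal stage) with missing values."""
    rng = cfg.rng(5)
    n = len(samples)
    age = np.round(rng.normal(65, 11, size=n)).clip(25, 95)
    gender = rng.choice(["F", "M"], size=n)
    stage = rng.integers(1, 5, size=n).astype(float)
    for arr in (age, stage):
        miss = rng.random(n) < cfg.missing_covariate_rate
        arr[miss] = np.nan
    return pd.DataFrame(
        {"age": age, "gender": gender, "stage": stage}, index=pd.Index(samples, name="sample_id")
    )


@dataclass
class SyntheticCohort:
    """Everything one end-to-end pipeline run consumes, plus ground truth."""

    config: SimConfig
    sets: AnnotationSets
    genotypes: GenotypeMatrix
    somatic: SomaticData
    covariates: pd.DataFrame


def simulate_cohort(cfg: SimConfig, signatures: pd.DataFrame | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort (deterministic under cfg.seed)."""
    risk_snps = simulate_risk_snps(cfg)
    sets = simulate_annotation_and_sets(cfg, risk_snps=risk_snps)
    gm = simulate_genotypes(cfg, snps=risk_snps)
    somatic = simulate_somatic(cfg, gm, sets, signatures=signatures)
    cov = simulate_covariates(cfg, list(gm.dosages.index))
    return SyntheticCohort(
        config=cfg, sets=sets, genotypes=gm, somatic=somatic, covariates=cov
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort input in its standard on-disk format; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "risk_snps": outdir / "risk_snps.tsv",
        "dosages": outdir / "dosages.tsv",
        "genes": outdir / "genes.bed",
        "drivers": outdir / "drivers.txt",
        "eqtl_genes": outdir / "eqtl_genes.txt",
        "pathways": outdir / "pathways.gmt",
        "mutations": outdir / "mutations.maf",
        "lesions": outdir / "all_lesions.conf_99.txt",
        "gene_cn": outdir / "all_data_by_genes.txt",
        "covariates": outdir / "covariates.tsv",
        "signatures": outdir / "signatures.tsv",
        "target_features": outdir / "target_features.tsv",
        "pool_features": outdir / "pool_features.tsv",
    }
    gio.write_risk_snps(cohort.sets.risk_snps, paths["risk_snps"])
    cohort.genotypes.to_tsv(paths["dosages"])
    gio.write_gene_bed(cohort.sets.genes, paths["genes"])
    gio.write_gene_list(sorted(cohort.sets.drivers), paths["drivers"])
    gio.write_gene_list(cohort.sets.eqtl_genes, paths["eqtl_genes"])
    gio.write_gmt(cohort.sets.pathways, paths["pathways"])
    gio.write_maf(cohort.somatic.records, paths["mutations"])
    gio.write_gistic_lesions(cohort.somatic.lesions, paths["lesions"])
    gio.write_gistic_gene_cn(cohort.somatic.cn, paths["gene_cn"])
    gio.write_covariates(cohort.covariates, paths["covariates"])
    gio.write_signatures(cohort.somatic.signatures, paths["signatures"])
    gio.write_snp_features(cohort.sets.target_features, paths["target_features"])
    gio.write_snp_features(cohort.sets.pool_features, paths["pool_features"])
    return paths
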