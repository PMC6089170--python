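"""Readers, writers and shared domain types for every external format the pipeline touches.

Formats handled here: MAF-style somatic mutation tables (TSV subset of columns),
GMT pathway gene sets, BED gene annotation, GISTIC2 ``all_lesions.conf_99.txt``
and ``all_data_by_genes.txt`` dialects, dosage matrices (variants x samples),
96-context signature reference matrices, covariate tables and plain-text gene
lists.

Conventions fixed once for the whole package:

* Genomic coordinates are 1-based closed intervals internally.  BED input
  (0-based half-open) is converted on read.
* Sample identity is the patient-level barcode: TCGA-style barcodes are
  truncated to a configurable prefix length (default 12 characters) so that
  genotype, mutation, copy-number and covariate tables join per patient.
* Trinucleotide context comes from explicit context columns in the mutation
  table; there is no reference-genome fetch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RiskSNP",
    "SnpFeatures",
    "MutationRecord",
    "PathwayGeneSet",
    "LesionTable",
    "FormatError",
    "CONTEXTS_96",
    "SUBSTITUTIONS",
    "read_maf",
    "write_maf",
    "read_gmt",
    "write_gmt",
    "read_gene_bed",
    "write_gene_bed",
    "read_gene_list",
    "write_gene_list",
    "read_gistic_lesions",
    "write_gistic_lesions",
    "read_gistic_gene_cn",
    "write_gistic_gene_cn",
    "read_signatures",
    "write_signatures",
    "read_covariates",
    "write_covariates",
    "read_risk_snps",
    "write_risk_snps",
    "read_snp_features",
    "write_snp_features",
    "truncate_barcode",
    "validate_signature_matrix",
]


class FormatError(ValueError):
    """An input file does not follow the expected dialect."""


# ---------------------------------------------------------------------------
# canonical 96 trinucleotide-context channels
# ---------------------------------------------------------------------------

#: The six pyrimidine-reference substitution types, in canonical order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_BASES = "ACGT"

#: Canonical channel order: substitution-major, then 5' base, then 3' base
#: ("A[C>A]A", "A[C>A]C", ... "T[T>G]T").
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RiskSNP:
    """A germline susceptibility variant.

    ``maf`` is folded to the minor-allele convention (<= 0.5) on construction.
    """

    snp_id: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    maf: float
    gwas_p: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: risk and other allele are identical")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 1]")
        self.maf = min(self.maf, 1.0 - self.maf)


@dataclass
class SnpFeatures:
    """Genomic matching features of one SNP for matched-set sampling.

    ``ld_buddies`` counts pool SNPs in LD (r^2 >= 0.5); ``dist_nearest_gene``
    is in bp; ``gene_density`` counts genes within +/-500 kb.
    """

    snp_id: str
    maf: float
    ld_buddies: int
    dist_nearest_gene: float
    gene_density: int

    def __post_init__(self) -> None:
        for name in ("maf", "ld_buddies", "dist_nearest_gene", "gene_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.snp_id}: {name} must be non-negative")


#: Variant classifications kept verbatim; everything else maps to "other".
KNOWN_CLASSIFICATIONS = (
    "Missense",
    "Nonsense",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Nonstop",
    "Silent",
)

# Accept both the bare names above and standard MAF spellings.
_CLASSIFICATION_ALIASES = {
    "Missense_Mutation": "Missense",
    "Nonsense_Mutation": "Nonsense",
    "Nonstop_Mutation": "Nonstop",
    **{c: c for c in KNOWN_CLASSIFICATIONS},
}

# Canonical MAF spelling used when writing records back out.
_CLASSIFICATION_MAF_NAMES = {
    "Missense": "Missense_Mutation",
    "Nonsense": "Nonsense_Mutation",
    "Nonstop": "Nonstop_Mutation",
    "Frame_Shift_Del": "Frame_Shift_Del",
    "Frame_Shift_Ins": "Frame_Shift_Ins",
    "Splice_Site": "Splice_Site",
    "Silent": "Silent",
    "other": "other",
}


@dataclass
class MutationRecord:
    """One somatic mutation call.

    ``context5``/``context3`` are the reference bases flanking the variant
    (single-nucleotide variants only; empty strings otherwise).
    """

    sample_id: str
    gene_symbol: str
    variant_classification: str
    ref_allele: str
    alt_allele: str
    context5: str = ""
    context3: str = ""

    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _BASES
            and self.alt_allele in _BASES
            and self.ref_allele != self.alt_allele
        )


@dataclass
class PathwayGeneSet:
    """A named gene set (e.g. one Reactome pathway)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has an empty gene set")


@dataclass
class LesionTable:
    """Recurrent copy-number lesions with per-sample threshold codes.

    ``codes`` is a lesions x samples integer DataFrame (0 = unaltered,
    >= 1 = amplified/deleted past the GISTIC threshold); ``lesion_type``
    maps lesion id -> "amplification" or "deletion".
    """

    codes: pd.DataFrame
    lesion_type: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.codes.to_numpy() < 0).any():
            raise ValueError("lesion codes must be non-negative")

    @property
    def lesion_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.columns)


def truncate_barcode(barcode: str, length: int = 12) -> str:
    """Truncate a TCGA-style sample barcode to its patient-level prefix."""
    return barcode[:length]


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_MAF_REQUIRED = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)


def read_maf(path: str | Path, barcode_length: int = 12) -> list[MutationRecord]:
    """Read a somatic mutation table (MAF-format subset of columns).

    Requires the tab-separated columns Hugo_Symbol, Tumor_Sample_Barcode,
    Variant_Classification, Reference_Allele and Tumor_Seq_Allele2; an
    optional ``CONTEXT`` column (odd-length reference sequence centred on the
    variant) supplies flanking bases for the trinucleotide spectrum.

    Sample barcodes are truncated to ``barcode_length`` characters
    (patient-level identity).  Unknown variant classifications map to
    ``"other"``.  Rows with missing required fields are rejected and logged;
    rows in = records out + rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"{path}: empty mutation file", stacklevel=2)
        return []
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required MAF column {col!r}")
    if df.empty:
        warnings.warn(f"{path}: mutation file has a header but no data rows", stacklevel=2)
        return []

    records: list[MutationRecord] = []
    n_rejected = 0
    has_context = "CONTEXT" in df.columns
    for idx, row in df.iterrows():
        fields = [row[c] for c in _MAF_REQUIRED]
        if any(pd.isna(v) or v == "" for v in fields):
            n_rejected += 1
            logger.warning("read_maf: row %s rejected (missing required field)", idx)
            continue
        gene, barcode, vc, ref, alt = fields
        context5 = context3 = ""
        if has_context and not pd.isna(row["CONTEXT"]):
            ctx = str(row["CONTEXT"]).upper()
            if len(ctx) >= 3 and len(ctx) % 2 == 1:
                mid = len(ctx) // 2
                context5, context3 = ctx[mid - 1], ctx[mid + 1]
        records.append(
            MutationRecord(
                sample_id=truncate_barcode(barcode, barcode_length),
                gene_symbol=gene,
                variant_classification=_CLASSIFICATION_ALIASES.get(vc, "other"),
                ref_allele=ref.upper(),
                alt_allele=alt.upper(),
                context5=context5,
                context3=context3,
            )
        )
    if n_rejected:
        logger.warning("read_maf: %d/%d rows rejected", n_rejected, len(df))
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write mutation records as a minimal MAF-format TSV (with CONTEXT column)."""
    rows = []
    for r in records:
        ctx = f"{r.context5}{r.ref_allele}{r.context3}" if r.context5 and r.context3 else ""
        rows.append(
            {
                "Hugo_Symbol": r.gene_symbol,
                "Tumor_Sample_Barcode": r.sample_id,
                "Variant_Classification": _CLASSIFICATION_MAF_NAMES.get(
                    r.variant_classification, r.variant_classification
                ),
                "Reference_Allele": r.ref_allele,
                "Tumor_Seq_Allele2": r.alt_allele,
                "CONTEXT": ctx,
            }
        )
    pd.DataFrame(rows, columns=list(_MAF_REQUIRED) + ["CONTEXT"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[PathwayGeneSet]:
    """Read gene sets in GMT format (name, description, then gene symbols).

    The description field is discarded; duplicate genes within a set are
    deduplicated.  A line with fewer than three fields is a format error.
    """
    sets: list[PathwayGeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs name, description and "
                    f">=1 gene, got {len(parts)} fields"
                )
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            sets.append(PathwayGeneSet(name=name, genes=frozenset(genes)))
    return sets


def write_gmt(pathways: Iterable[PathwayGeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.name, "na"] + sorted(pw.genes)) + "\n")


# ---------------------------------------------------------------------------
# gene annotation (BED)
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4(+1) gene annotation into a 1-based closed-interval table.

    Columns in: chrom, start (0-based), end (half-open), gene symbol, and an
    optional fifth column with a 0/1 protein-coding flag (default 1).
    Returns a DataFrame with columns gene_symbol, chrom, start, end, coding.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] < 4:
        raise FormatError(f"{path}: gene BED needs >= 4 columns")
    out = pd.DataFrame(
        {
            "gene_symbol": df[3].astype(str),
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,  # BED 0-based -> 1-based closed
            "end": df[2].astype(int),
            "coding": df[4].astype(int).astype(bool) if df.shape[1] >= 5 else True,
        }
    )
    if (out["start"] > out["end"]).any():
        bad = out.loc[out["start"] > out["end"], "gene_symbol"].iloc[0]
        raise FormatError(f"{path}: gene {bad} has start > end")
    if out["gene_symbol"].duplicated().any():
        dup = out.loc[out["gene_symbol"].duplicated(), "gene_symbol"].iloc[0]
        raise FormatError(f"{path}: duplicated gene symbol {dup}")
    return out


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene annotation table back to BED4+1 (inverse of read_gene_bed)."""
    bed = pd.DataFrame(
        {
            0: genes["chrom"],
            1: genes["start"] - 1,
            2: genes["end"],
            3: genes["gene_symbol"],
            4: genes["coding"].astype(int),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line; order kept, deduped."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                seen.setdefault(sym, None)
    return list(seen)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# GISTIC2 outputs
# ---------------------------------------------------------------------------

_LESION_META_COLS = (
    "Unique Name",
    "Descriptor",
    "Wide Peak Limits",
    "Peak Limits",
    "Region Limits",
    "q values",
    "Residual q values after removing segments shared with higher peaks",
    "Broad or Focal",
    "Amplitude Threshold",
)


def read_gistic_lesions(path: str | Path, barcode_length: int = 12) -> LesionTable:
    """Read a GISTIC2 ``all_lesions.conf_99.txt`` file into threshold codes.

    Each lesion appears twice in the file, once threshold-coded and once as
    raw "CN values"; the CN-values duplicates are skipped.  The lesion type is
    parsed from the Unique Name field ("Amplification Peak N" / "Deletion
    Peak N") and the lesion id is "<Amp|Del> <descriptor>".
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "Unique Name" not in df.columns or "Descriptor" not in df.columns:
        raise FormatError(f"{path}: not a GISTIC all_lesions file (missing Unique Name)")
    meta = [c for c in _LESION_META_COLS if c in df.columns]
    sample_cols = [
        c for c in df.columns
        if c not in meta and not c.startswith("Unnamed")
    ]
    rows: dict[str, np.ndarray] = {}
    types: dict[str, str] = {}
    for idx, row in df.iterrows():
        name = str(row["Unique Name"]).strip()
        if "CN values" in name:
            continue  # raw copy-number duplicate of a threshold-coded row
        low = name.lower()
        if low.startswith("amplification"):
            typ, prefix = "amplification", "Amp"
        elif low.startswith("deletion"):
            typ, prefix = "deletion", "Del"
        else:
            raise FormatError(f"{path}: row {idx}: unparseable lesion name {name!r}")
        lesion_id = f"{prefix} {str(row['Descriptor']).strip()}"
        rows[lesion_id] = row[sample_cols].astype(float).astype(int).to_numpy()
        types[lesion_id] = typ
    if not rows:
        warnings.warn(f"{path}: no lesion rows found", stacklevel=2)
        return LesionTable(codes=pd.DataFrame(columns=[]), lesion_type={})
    codes = pd.DataFrame.from_dict(rows, orient="index", columns=sample_cols)
    codes.columns = [truncate_barcode(c, barcode_length) for c in codes.columns]
    return LesionTable(codes=codes, lesion_type=types)


def write_gistic_lesions(table: LesionTable, path: str | Path) -> None:
    """Write a LesionTable in the GISTIC2 all_lesions dialect (threshold rows only)."""
    recs = []
    for i, lesion_id in enumerate(table.lesion_ids, start=1):
        typ = table.lesion_type.get(lesion_id, "amplification")
        prefix = "Amplification" if typ == "amplification" else "Deletion"
        descriptor = lesion_id.split(" ", 1)[1] if " " in lesion_id else lesion_id
        rec = {
            "Unique Name": f"{prefix} Peak {i}",
            "Descriptor": descriptor,
            "Wide Peak Limits": "na",
            "Peak Limits": "na",
            "Region Limits": "na",
            "q values": "0.01",
            "Residual q values after removing segments shared with higher peaks": "0.01",
            "Broad or Focal": "Focal",
            "Amplitude Threshold": "0: t<0.1; 1: 0.1<t<0.9; 2: t>0.9",
        }
        rec.update(table.codes.loc[lesion_id].to_dict())
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def read_gistic_gene_cn(
    path: str | Path, barcode_length: int = 12
) -> pd.DataFrame:
    """Read GISTIC2 ``all_data_by_genes.txt``: gene-level copy-number values.

    Returns a genes x samples DataFrame of real copy-number values (signed,
    as in the file), indexed by gene symbol.  Duplicated gene symbols are a
    format error.
    """
    df = pd.read_csv(path, sep="\t")
    sym_col = df.columns[0]
    if sym_col not in ("Gene Symbol", "Gene_Symbol"):
        raise FormatError(f"{path}: first column must be Gene Symbol, got {sym_col!r}")
    meta = [c for c in ("Gene ID", "Locus ID", "Cytoband") if c in df.columns]
    cn = df.drop(columns=meta).set_index(sym_col)
    cn.index.name = "gene_symbol"
    if cn.index.duplicated().any():
        dup = cn.index[cn.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated gene symbol {dup}")
    cn.columns = [truncate_barcode(c, barcode_length) for c in cn.columns]
    return cn.astype(float)


def write_gistic_gene_cn(cn: pd.DataFrame, path: str | Path) -> None:
    out = cn.copy()
    out.insert(0, "Locus ID", range(1, len(out) + 1))
    out.insert(1, "Cytoband", "na")
    out.index.name = "Gene Symbol"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# signature reference
# ---------------------------------------------------------------------------

def validate_signature_matrix(sigs: pd.DataFrame) -> pd.DataFrame:
    """Check a 96 x K reference signature matrix and return it in canonical row order.

    Each column must be a probability distribution over the 96 canonical
    trinucleotide channels (non-negative, summing to 1 within 1e-6).
    """
    if set(sigs.index) != set(CONTEXTS_96):
        missing = sorted(set(CONTEXTS_96) - set(sigs.index))[:3]
        raise FormatError(f"signature matrix rows are not the 96 canonical contexts "
                          f"(e.g. missing {missing})")
    sigs = sigs.loc[list(CONTEXTS_96)].astype(float)
    if (sigs.to_numpy() < 0).any():
        raise FormatError("signature matrix has negative entries")
    sums = sigs.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = sums.index[np.argmax(np.abs(sums - 1.0))]
        raise FormatError(f"signature column {bad!r} sums to {sums[bad]:.6g}, not 1")
    return sigs


def read_signatures(path: str | Path) -> pd.DataFrame:
    """Read a signature reference TSV (96 context rows x K signature columns)."""
    sigs = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signature_matrix(sigs)


def write_signatures(sigs: pd.DataFrame, path: str | Path) -> None:
    validate_signature_matrix(sigs).rename_axis("context").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# risk SNPs and matching features
# ---------------------------------------------------------------------------

def read_risk_snps(path: str | Path) -> list[RiskSNP]:
    """Read a risk-SNP TSV (snp_id, chrom, pos, risk_allele, other_allele, maf,
    optional gwas_p)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ("snp_id", "chrom", "pos", "risk_allele", "other_allele", "maf")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing risk-SNP column {col!r}")
    snps = []
    for _, row in df.iterrows():
        gwas_p = row.get("gwas_p")
        snps.append(
            RiskSNP(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                risk_allele=str(row["risk_allele"]),
                other_allele=str(row["other_allele"]),
                maf=float(row["maf"]),
                gwas_p=None if gwas_p is None or pd.isna(gwas_p) else float(gwas_p),
            )
        )
    return snps


def write_risk_snps(snps: Iterable[RiskSNP], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
                "risk_allele": s.risk_allele, "other_allele": s.other_allele,
                "maf": s.maf,
                "gwas_p": s.gwas_p if s.gwas_p is not None else np.nan,
            }
            for s in snps
        ]
    ).to_csv(path, sep="\t", index=False)


def read_snp_features(path: str | Path) -> list[SnpFeatures]:
    """Read per-SNP matching features (snp_id, maf, ld_buddies,
    dist_nearest_gene, gene_density)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SnpFeatures(
            snp_id=str(r["snp_id"]),
            maf=float(r["maf"]),
            ld_buddies=int(r["ld_buddies"]),
            dist_nearest_gene=float(r["dist_nearest_gene"]),
            gene_density=int(r["gene_density"]),
        )
        for _, r in df.iterrows()
    ]


def write_snp_features(features: Iterable[SnpFeatures], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "snp_id": f.snp_id, "maf": f.maf, "ld_buddies": f.ld_buddies,
                "dist_nearest_gene": f.dist_nearest_gene,
                "gene_density": f.gene_density,
            }
            for f in features
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a covariate TSV (sample_id, age, gender, stage, optional PC columns)."""
    cov = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in cov.columns:
        raise FormatError(f"{path}: covariate table needs a sample_id column")
    cov = cov.set_index("sample_id")
    if cov.index.duplicated().any():
        raise FormatError(f"{path}: duplicated sample ids in covariate table")
    pc_cols = [c for c in cov.columns if c.startswith("PC")]
    if pc_cols and not np.isfinite(cov[pc_cols].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite principal component values")
    return cov


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.rename_axis("sample_id").to_csv(path, sep="\t")
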