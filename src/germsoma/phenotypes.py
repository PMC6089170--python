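"""Per-sample somatic phenotypes: mutation flags, copy number, signature weights.

Four phenotype families are derived from somatic inputs:

* driver-gene mutation flags — a gene is "mutated" in a patient if at least
  one somatic call maps to it (any classification by default; a
  nonsilent-only switch is provided);
* key-pathway truncation flags — at least one protein-shortening call
  (nonsense, frameshift, splice-site, nonstop) in any pathway gene;
* copy-number values — absolute gene-level values restricted to the driver
  list, plus binary GISTIC lesion flags;
* mutational-signature weights — per-sample non-negative least-squares refit
  of the 96-channel substitution spectrum onto a fixed reference signature
  matrix, with small weights (< 0.06 by default) discarded and the remaining
  support refit, following the deconstructSigs weighting convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .io import (
    CONTEXTS_96,
    LesionTable,
    MutationRecord,
    PathwayGeneSet,
    validate_signature_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TRUNCATING_CLASSIFICATIONS",
    "MutationSpectrum",
    "SignatureWeights",
    "is_truncating",
    "gene_mutation_matrix",
    "pathway_truncation_flags",
    "gene_cn_values",
    "lesion_flags",
    "mutation_spectrum",
    "cohort_spectra",
    "SignatureRefitter",
    "refit_signatures",
]

#: Protein-shortening classifications (configurable in the pathway flags).
TRUNCATING_CLASSIFICATIONS = frozenset(
    {"Nonsense", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site", "Nonstop"}
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CHANNEL_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


@dataclass
class MutationSpectrum:
    """One sample's counts over the 96 canonical substitution channels."""

    sample_id: str
    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if int(round(self.counts.sum())) != self.total:
            raise ValueError("spectrum counts do not sum to total")


@dataclass
class SignatureWeights:
    """Refit signature weights for one sample; ``unknown`` is the unassigned mass."""

    sample_id: str
    weights: dict[str, float]
    unknown: float


def is_truncating(classification: str) -> bool:
    """True for protein-shortening variant classifications."""
    return classification in TRUNCATING_CLASSIFICATIONS


def gene_mutation_matrix(
    records: list[MutationRecord],
    genes: frozenset[str] | set[str] | list[str],
    samples: list[str] | None = None,
    nonsilent_only: bool = False,
) -> pd.DataFrame:
    """Sample x gene binary mutation flags restricted to ``genes``.

    An entry is 1 iff at least one record of any classification (silent
    included — set ``nonsilent_only`` to exclude Silent) maps the sample to
    the gene.  ``samples`` fixes the row universe (samples with no records
    get all-zero rows); by default rows are the samples seen in ``records``.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("empty gene set")
    if samples is None:
        samples = sorted({r.sample_id for r in records})
    mat = pd.DataFrame(0, index=list(samples), columns=genes, dtype=int)
    gene_set = set(genes)
    for r in records:
        if r.gene_symbol not in gene_set or r.sample_id not in mat.index:
            continue
        if nonsilent_only and r.variant_classification == "Silent":
            continue
        mat.at[r.sample_id, r.gene_symbol] = 1
    return mat


def pathway_truncation_flags(
    records: list[MutationRecord],
    key_pathways: list[PathwayGeneSet],
    samples: list[str] | None = None,
    truncating: frozenset[str] = TRUNCATING_CLASSIFICATIONS,
) -> pd.DataFrame:
    """Sample x pathway flags: 1 iff >= 1 truncating call in >= 1 pathway gene."""
    if samples is None:
        samples = sorted({r.sample_id for r in records})
    mat = pd.DataFrame(
        0, index=list(samples), columns=[pw.name for pw in key_pathways], dtype=int
    )
    gene_to_pws: dict[str, list[str]] = {}
    for pw in key_pathways:
        for g in pw.genes:
            gene_to_pws.setdefault(g, []).append(pw.name)
    for r in records:
        if r.variant_classification not in truncating:
            continue
        if r.sample_id not in mat.index:
            continue
        for pw_name in gene_to_pws.get(r.gene_symbol, ()):
            mat.at[r.sample_id, pw_name] = 1
    return mat


def gene_cn_values(
    cn: pd.DataFrame, drivers: frozenset[str] | set[str] | list[str]
) -> pd.DataFrame:
    """Sample x gene matrix of |copy-number value|, restricted to driver genes.

    Driver genes missing from the table are logged and skipped.
    """
    drivers = sorted(set(drivers))
    present = [g for g in drivers if g in cn.index]
    missing = set(drivers) - set(present)
    if missing:
        logger.info("gene_cn_values: %d driver genes absent from CN table", len(missing))
    return cn.loc[present].abs().T.copy()


def lesion_flags(lesions: LesionTable) -> pd.DataFrame:
    """Sample x lesion binary flags: altered iff the threshold code is >= 1."""
    return (lesions.codes >= 1).astype(int).T.copy()


# ---------------------------------------------------------------------------
# mutation spectra
# ---------------------------------------------------------------------------

def _channel_of(record: MutationRecord) -> str | None:
    """Canonical 96-channel label of an SNV record, or None if not usable.

    Purine-reference SNVs are reverse-complemented into the pyrimidine
    convention: ref, alt and both flanks are complemented and the flanks swap.
    """
    if not record.is_snv():
        return None
    ref, alt = record.ref_allele, record.alt_allele
    c5, c3 = record.context5, record.context3
    if c5 not in _COMPLEMENT or c3 not in _COMPLEMENT:
        return None
    if ref in ("A", "G"):  # purine reference: flip strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        c5, c3 = _COMPLEMENT[c3], _COMPLEMENT[c5]
    return f"{c5}[{ref}>{alt}]{c3}"


def mutation_spectrum(
    records: list[MutationRecord], sample_id: str | None = None
) -> MutationSpectrum:
    """Accumulate one sample's SNV records into a 96-channel spectrum.

    Non-SNV records and records with ambiguous context bases are skipped with
    a logged count; the spectrum total equals the number of usable SNVs.
    """
    counts = np.zeros(96)
    n_skipped = 0
    for r in records:
        ch = _channel_of(r)
        if ch is None:
            n_skipped += 1
            continue
        counts[_CHANNEL_INDEX[ch]] += 1
    if n_skipped:
        logger.info("mutation_spectrum: skipped %d non-SNV/ambiguous records", n_skipped)
    if sample_id is None:
        sample_id = records[0].sample_id if records else ""
    return MutationSpectrum(sample_id=sample_id, counts=counts, total=int(counts.sum()))


def cohort_spectra(records: list[MutationRecord]) -> pd.DataFrame:
    """Samples x 96 spectrum count matrix for a whole cohort."""
    by_sample: dict[str, list[MutationRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    rows = {
        sid: mutation_spectrum(recs, sample_id=sid).counts
        for sid, recs in sorted(by_sample.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CONTEXTS_96))


# ---------------------------------------------------------------------------
# signature refitting
# ---------------------------------------------------------------------------

def _nnls_refit(m: np.ndarray, S: np.ndarray, discard: float) -> np.ndarray:
    """NNLS fit of frequencies m onto signature columns S, with the
    deconstructSigs-style discard-and-refit: weights below ``discard`` are
    zeroed and the surviving support is refit."""
    w, _ = nnls(S, m)
    support = w >= discard
    w[~support] = 0.0
    if support.any() and not support.all():
        w_sub, _ = nnls(S[:, support], m)
        w = np.zeros_like(w)
        w[support] = w_sub
        w[w < discard] = 0.0
    return w


class SignatureRefitter(BaseEstimator, TransformerMixin):
    """Refit per-sample mutation spectra onto fixed reference signatures.

    The estimator holds a 96 x K reference matrix (columns are signature
    probability profiles over the canonical trinucleotide channels).  For
    each sample the spectrum is normalized to frequencies ``m`` and the
    weights solve ``min ||m - S w||_2`` subject to ``w >= 0``; weights below
    ``discard`` (default 0.06) are zeroed and the surviving support is refit.
    The unassigned mass ``unknown = max(0, 1 - sum(w))`` is reported as an
    extra column.  The procedure is deterministic.

    ``tri_counts``, if given, is a 96-vector (indexed like the canonical
    channels, or aligned to them) of relative trinucleotide abundances; each
    spectrum is divided by it channel-wise before normalization, the usual
    correction when spectra and reference signatures come from differently
    sized sequence contexts.  Default is no correction.

    Attributes (after fit): ``signatures_`` (validated 96 x K DataFrame),
    ``signature_names_``.
    """

    def __init__(
        self,
        signatures: pd.DataFrame | None = None,
        discard: float = 0.06,
        tri_counts: pd.Series | None = None,
    ):
        self.signatures = signatures
        self.discard = discard
        self.tri_counts = tri_counts

    def fit(self, X=None, y=None) -> "SignatureRefitter":
        if self.signatures is None:
            raise ValueError("a reference signature matrix is required")
        self.signatures_ = validate_signature_matrix(self.signatures)
        self.signature_names_ = list(self.signatures_.columns)
        if self.tri_counts is not None:
            tc = pd.Series(self.tri_counts)
            if set(tc.index) >= set(CONTEXTS_96):
                tc = tc.loc[list(CONTEXTS_96)]
            elif len(tc) != 96:
                raise ValueError("tri_counts must cover the 96 canonical channels")
            if (tc <= 0).any():
                raise ValueError("tri_counts must be strictly positive")
            self.tri_counts_ = tc.to_numpy(dtype=float)
        else:
            self.tri_counts_ = None
        return self

    def transform(self, spectra: pd.DataFrame) -> pd.DataFrame:
        """Weights for each row of a samples x 96 spectrum count matrix.

        Returns a DataFrame with one column per signature plus ``unknown``.
        Rows must have a positive total count.
        """
        S = self.signatures_.to_numpy()
        cols = [c for c in CONTEXTS_96]
        X = spectra[cols].to_numpy(dtype=float)
        out = np.zeros((X.shape[0], S.shape[1] + 1))
        for i in range(X.shape[0]):
            total = X[i].sum()
            if total <= 0:
                raise ValueError(
                    f"empty spectrum for sample {spectra.index[i]!r}"
                )
            x = X[i] / total
            if self.tri_counts_ is not None:
                x = x / self.tri_counts_
                x = x / x.sum()
            w = _nnls_refit(x, S, self.discard)
            out[i, :-1] = w
            out[i, -1] = max(0.0, 1.0 - w.sum())
        return pd.DataFrame(
            out, index=spectra.index, columns=self.signature_names_ + ["unknown"]
        )


def refit_signatures(
    spectrum: MutationSpectrum, signatures: pd.DataFrame, discard: float = 0.06
) -> SignatureWeights:
    """Signature weights of a single spectrum; see :class:`SignatureRefitter`."""
    if spectrum.total < 1:
        raise ValueError("empty spectrum")
    df = pd.DataFrame([spectrum.counts], index=[spectrum.sample_id], columns=list(CONTEXTS_96))
    w = SignatureRefitter(signatures, discard=discard).fit().transform(df).iloc[0]
    return SignatureWeights(
        sample_id=spectrum.sample_id,
        weights={k: float(v) for k, v in w.drop("unknown").items()},
        unknown=float(w["unknown"]),
    )
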