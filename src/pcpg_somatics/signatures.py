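"""Mutation-context catalogs and non-negative signature refitting.

Catalogs are context-class count vectors (SBS-96 pyrimidine-centric,
DBS-78 canonical-strand doublets, ID-83 accepted precomputed).  Exposures are
estimated by non-negative least squares against a signature matrix whose
columns are per-class probability distributions; per-cohort reporting applies
a proportion threshold (15% of a sample's fitted total) together with a
scheme-specific minimum mutation count (SBS 500, ID 50, DBS 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SBS96_CLASSES",
    "DBS78_CLASSES",
    "SCHEME_SIZES",
    "SCHEME_MIN_MUTATIONS",
    "PROPORTION_THRESHOLD",
    "revcomp",
    "sbs96_context",
    "dbs78_context",
    "build_sbs96_catalog",
    "ExposureFit",
    "fit_exposures",
    "report_signatures",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
_PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _sbs96_classes() -> list[str]:
    classes = []
    for sub in _PYRIMIDINE_SUBS:
        for five in _BASES:
            for three in _BASES:
                classes.append(f"{five}[{sub}]{three}")
    return classes


def _dbs78_classes() -> list[str]:
    # canonical reference doublets (reverse-complement-deduplicated set)
    refs = ["AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT"]
    canonical_refs = set(refs)
    classes = []
    for ref in refs:
        seen = set()
        for a1 in _BASES:
            for a2 in _BASES:
                alt = a1 + a2
                if a1 == ref[0] or a2 == ref[1]:
                    continue
                # palindromic refs: deduplicate alt by reverse complement
                if revcomp(ref) == ref:
                    alt_rc = revcomp(alt)
                    if min(alt, alt_rc) in seen:
                        continue
                    seen.add(min(alt, alt_rc))
                classes.append(f"{ref}>{alt}")
    assert len(classes) == 78
    assert all(c.split(">")[0] in canonical_refs for c in classes)
    return classes


SBS96_CLASSES: tuple[str, ...] = tuple(_sbs96_classes())
DBS78_CLASSES: tuple[str, ...] = tuple(_dbs78_classes())

SCHEME_SIZES = {"SBS96": 96, "DBS78": 78, "ID83": 83}
#: minimum per-sample mutation count for a signature to be reportable
SCHEME_MIN_MUTATIONS = {"SBS96": 500, "ID83": 50, "DBS78": 10}
#: minimum per-sample proportional contribution for reporting
PROPORTION_THRESHOLD = 0.15


def sbs96_context(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str],
) -> str:
    """SBS-96 class for a single-base substitution at 1-based ``pos``.

    Purine-reference mutations are mapped to the reverse-complement strand so
    the mutated base is pyrimidine (C or T).  ``reference`` maps chromosome
    name to its full sequence (or any object supporting string slicing, e.g.
    a pyfaidx record).
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    seq = reference[chrom]
    if pos < 2 or pos > len(seq) - 1:
        raise ValueError(f"position {pos} lacks flanking context on {chrom}")
    tri = str(seq[pos - 2 : pos + 1]).upper()
    if tri[1] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref}, found {tri[1]}"
        )
    if ref in "AG":  # purine-centered: flip strand
        tri = revcomp(tri)
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def dbs78_context(ref: str, alt: str) -> str:
    """DBS-78 class for a doublet substitution, canonicalized by strand."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 2 or len(alt) != 2:
        raise ValueError("doublet substitution requires two-base alleles")
    label = f"{ref}>{alt}"
    if label in DBS78_CLASSES:
        return label
    rc = f"{revcomp(ref)}>{revcomp(alt)}"
    if rc in DBS78_CLASSES:
        return rc
    raise ValueError(f"unclassifiable doublet {label}")


def build_sbs96_catalog(
    variants: Iterable[tuple[str, int, str, str]],
    reference: Mapping[str, str],
) -> pd.Series:
    """Count SBS-96 classes over an iterable of (chrom, pos, ref, alt)."""
    counts = pd.Series(0, index=list(SBS96_CLASSES), dtype=int)
    for chrom, pos, ref, alt in variants:
        counts[sbs96_context(chrom, pos, ref, alt, reference)] += 1
    return counts


@dataclass(frozen=True)
class ExposureFit:
    """Per-signature mutation counts and the L2 reconstruction residual."""

    exposures: pd.Series
    residual: float

    @property
    def total(self) -> float:
        return float(self.exposures.sum())


def _validate_signature_matrix(signatures: pd.DataFrame) -> None:
    arr = signatures.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("signature matrix has negative entries")
    sums = arr.sum(axis=0)
    if (sums == 0).any():
        bad = signatures.columns[sums == 0].tolist()
        raise ValueError(f"all-zero signature column(s): {bad}")
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1 (tol 1e-6)")


def fit_exposures(catalog: pd.Series, signatures: pd.DataFrame) -> ExposureFit:
    """Non-negative least squares refit of ``catalog`` onto ``signatures``.

    ``catalog`` is a class-indexed count vector; ``signatures`` is a
    classes x signatures probability matrix with the same index.  Returns
    exposures e >= 0 minimizing ||S e - m||_2.
    """
    if not catalog.index.equals(signatures.index):
        if set(catalog.index) != set(signatures.index):
            raise ValueError("catalog and signature class schemes do not match")
        signatures = signatures.loc[catalog.index]
    if (catalog < 0).any():
        raise ValueError("catalog counts must be non-negative")
    _validate_signature_matrix(signatures)
    m = catalog.to_numpy(dtype=float)
    s = signatures.to_numpy(dtype=float)
    e, rnorm = nnls(s, m)
    return ExposureFit(
        exposures=pd.Series(e, index=signatures.columns, name=catalog.name),
        residual=float(rnorm),
    )


def report_signatures(
    exposures: pd.DataFrame,
    scheme: str,
    proportion_threshold: float = PROPORTION_THRESHOLD,
    min_mutations: float | None = None,
) -> list[str]:
    """Signatures reportable at cohort level, ranked by mean proportional
    contribution (ties broken by signature id).

    ``exposures`` is signatures x samples (fitted mutation counts).  A
    signature is reported iff in at least one sample its exposure is both
    >= ``proportion_threshold`` of that sample's fitted total and >= the
    scheme minimum count.
    """
    if min_mutations is None:
        try:
            min_mutations = SCHEME_MIN_MUTATIONS[scheme]
        except KeyError:
            raise ValueError(f"unknown scheme {scheme!r}") from None
    totals = exposures.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = exposures.div(totals.replace(0, np.nan), axis=1)
    qualifies = (proportions >= proportion_threshold) & (exposures >= min_mutations)
    reported = [sig for sig in exposures.index if qualifies.loc[sig].any()]
    mean_prop = proportions.fillna(0.0).mean(axis=1)
    reported.sort(key=lambda sig: (-mean_prop[sig], sig))
    return reported


def fit_cohort(
    catalogs: pd.DataFrame, signatures: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Fit every sample column of ``catalogs``; returns (exposure matrix
    signatures x samples, per-sample residual norms)."""
    fits = {s: fit_exposures(catalogs[s], signatures) for s in catalogs.columns}
    exposures = pd.DataFrame({s: f.exposures for s, f in fits.items()})
    residuals = pd.Series({s: f.residual for s, f in fits.items()})
    return exposures, residuals
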