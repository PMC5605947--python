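"""SNP/sample quality control and cross-cohort harmonization.

Filters mirror the conventions of array-based cohort studies: per-SNP
call rate, minor allele frequency, and a Hardy-Weinberg equilibrium test;
harmonization intersects two SNP panels on position with allele-aware
matching (ref/alt swaps are retained with a dosage-flip flag, true allele
mismatches are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: genotype code for missing calls in dosage matrices
MISSING = -9

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class QCThresholds:
    """SNP/sample QC cutoffs (fractions in (0, 1])."""

    snp_call_rate: float = 0.98
    sample_call_rate: float = 0.98
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6

    def __post_init__(self):
        for name in ("snp_call_rate", "sample_call_rate", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def hwe_chisq_p(n0: int, n1: int, n2: int, min_n: int = 50) -> float:
    """1-df chi-square Hardy-Weinberg P from genotype counts.

    ``n0/n1/n2`` are counts of 0/1/2 copies of the tested allele.  The
    expected counts are ``n q^2, 2npq, n p^2`` with ``p`` the sample allele
    frequency.  Small samples (``n < min_n``) and monomorphic sites return
    P = 1 (no evidence of deviation; the chi-square approximation is not
    trusted at small counts).
    """
    n = n0 + n1 + n2
    if n < min_n:
        return 1.0
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    if p <= 0 or q <= 0:
        return 1.0
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    dosages: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-SNP QC on an ``(n, m)`` dosage matrix (missing = :data:`MISSING`).

    Returns the kept SNP indices and an exclusion report with one row per
    removed SNP.  A SNP failing several filters is reported under the
    first failing one, in the order call-rate, MAF, HWE.
    """
    thresholds = thresholds or QCThresholds()
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    observed = dosages != MISSING
    call_rate = observed.mean(axis=0)

    d = np.where(observed, dosages, 0)
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = d.sum(axis=0) / (2 * np.maximum(n_obs, 1))
    maf = np.minimum(freq, 1 - freq)

    reasons = np.full(m, "", dtype=object)
    fail_cr = call_rate < thresholds.snp_call_rate
    fail_maf = maf < thresholds.maf_min
    hwe_p = np.ones(m)
    for j in range(m):
        if fail_cr[j] or fail_maf[j]:
            continue
        col = dosages[observed[:, j], j]
        hwe_p[j] = hwe_chisq_p(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
    fail_hwe = hwe_p < thresholds.hwe_p_min
    reasons[fail_hwe] = "hwe"
    reasons[fail_maf] = "maf"
    reasons[fail_cr] = "call_rate"

    removed = reasons != ""
    kept = np.flatnonzero(~removed)
    report = pd.DataFrame(
        {
            "snp_index": np.flatnonzero(removed),
            "reason": reasons[removed],
            "call_rate": call_rate[removed],
            "maf": maf[removed],
            "hwe_p": hwe_p[removed],
        }
    )
    return kept, report


def sample_qc(dosages: np.ndarray, thresholds: QCThresholds | None = None) -> np.ndarray:
    """Indices of individuals with call rate >= threshold."""
    thresholds = thresholds or QCThresholds()
    rate = (np.asarray(dosages) != MISSING).mean(axis=1)
    return np.flatnonzero(rate >= thresholds.sample_call_rate)


def _is_ambiguous(ref: str, alt: str) -> bool:
    return (ref, alt) in _AMBIGUOUS


def harmonize_cohorts(
    snps_a: pd.DataFrame, snps_b: pd.DataFrame
) -> pd.DataFrame:
    """Intersect two SNP tables on chromosome + bp with allele matching.

    Returns a table with ``chrom, pos, idx_a, idx_b, flip, ambiguous``:
    ``flip`` marks sites whose ref/alt are swapped between cohorts (their
    dosages must be reflected as ``2 - x`` in cohort B), ``ambiguous``
    flags strand-ambiguous (A/T, C/G) sites, which are kept.  Sites whose
    alleles match neither directly nor swapped are dropped.  Duplicate
    positions within a cohort raise.
    """
    for name, t in (("A", snps_a), ("B", snps_b)):
        if t.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError(f"duplicate chrom+pos in cohort {name}")
    a = snps_a.reset_index(drop=True).reset_index(names="idx_a")
    b = snps_b.reset_index(drop=True).reset_index(names="idx_b")
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if merged.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "idx_a", "idx_b", "flip", "ambiguous"]
        )
    direct = (merged["ref_a"] == merged["ref_b"]) & (merged["alt_a"] == merged["alt_b"])
    swapped = (merged["ref_a"] == merged["alt_b"]) & (merged["alt_a"] == merged["ref_b"])
    keep = merged[direct | swapped].copy()
    keep["flip"] = swapped[direct | swapped].to_numpy()
    keep["ambiguous"] = [
        _is_ambiguous(r, a_) for r, a_ in zip(keep["ref_a"], keep["alt_a"])
    ]
    return keep[["chrom", "pos", "idx_a", "idx_b", "flip", "ambiguous"]].reset_index(
        drop=True
    )
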