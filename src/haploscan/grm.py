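"""Genomic relationship matrices (GRMs) and relatedness pruning.

The GRM entry between individuals j and k over m SNPs is

    G_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with x the 0/1/2 allele dosage and p_i the sample allele frequency.  The
diagonal uses the same form, so diagonal entries are ~1 in expectation
under Hardy-Weinberg.  Leave-one-chromosome-out (LOCO) variants exclude
the tested chromosome to avoid proximal contamination; the thresholded
matrix G_t zeroes off-diagonals below 0.05, retaining only close-relative
structure.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cohort import PhasedCohort


class GRM:
    """A symmetric genomic relationship matrix with provenance."""

    def __init__(self, matrix: np.ndarray, n_snps: int, excluded_chrom=None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(matrix, matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("GRM contains non-finite entries")
        self.matrix = matrix
        self.n_snps = int(n_snps)
        self.excluded_chrom = excluded_chrom

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)


def _standardize(dosages: np.ndarray, freqs: np.ndarray | None):
    dosages = np.asarray(dosages, dtype=float)
    if freqs is None:
        freqs = dosages.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNPs from GRM",
            stacklevel=3,
        )
    d = dosages[:, poly]
    p = freqs[poly]
    return (d - 2 * p) / np.sqrt(2 * p * (1 - p)), int(poly.sum())


def compute_grm(
    dosages: np.ndarray, freqs: np.ndarray | None = None, excluded_chrom=None
) -> GRM:
    """GRM from an ``(n, m)`` dosage matrix; frequencies default to sample."""
    w, m = _standardize(dosages, freqs)
    if m == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    return GRM(w @ w.T / m, n_snps=m, excluded_chrom=excluded_chrom)


class GRMSet:
    """Full and leave-one-chromosome-out GRMs for a cohort.

    Per-chromosome cross-products are accumulated once, so each LOCO
    matrix is a cheap difference rather than a fresh O(n^2 m) pass.
    """

    def __init__(self, cohort: PhasedCohort):
        self._parts: dict = {}
        self._counts: dict = {}
        n = cohort.n_samples
        for chrom in cohort.chromosomes:
            idx = np.flatnonzero(cohort.chrom_mask(chrom))
            w, m = _standardize(cohort.dosages(idx), None)
            self._parts[chrom] = w @ w.T
            self._counts[chrom] = m
        self._total = sum(self._parts.values(), start=np.zeros((n, n)))
        self._m_total = sum(self._counts.values())

    @property
    def chromosomes(self) -> list:
        return list(self._parts)

    def full(self) -> GRM:
        return GRM(self._total / self._m_total, n_snps=self._m_total)

    def loco(self, chrom) -> GRM:
        """GRM over all SNPs not on ``chrom``."""
        if len(self._parts) < 2:
            raise ValueError("LOCO requires at least two chromosomes")
        if chrom not in self._parts:
            return self.full()
        m = self._m_total - self._counts[chrom]
        return GRM(
            (self._total - self._parts[chrom]) / m, n_snps=m, excluded_chrom=chrom
        )


def loco_grm(cohort: PhasedCohort, chrom) -> GRM:
    """One-off LOCO GRM (use :class:`GRMSet` when scanning many chromosomes)."""
    if len(set(cohort.snps["chrom"])) < 2:
        raise ValueError("LOCO requires at least two chromosomes")
    mask = ~cohort.chrom_mask(chrom)
    return compute_grm(cohort.dosages(np.flatnonzero(mask)), excluded_chrom=chrom)


def threshold_grm(grm: GRM, cutoff: float = 0.05) -> GRM:
    """Zero off-diagonal entries < ``cutoff`` (signed comparison, so
    negative relationships are zeroed); diagonals untouched."""
    m = grm.matrix.copy()
    off = ~np.eye(m.shape[0], dtype=bool)
    m[off & (m < cutoff)] = 0.0
    return GRM(m, n_snps=grm.n_snps, excluded_chrom=grm.excluded_chrom)


def unrelated_subset(grm: GRM, cutoff: float = 0.025) -> np.ndarray:
    """Greedy pruning to a subset with all pairwise relationships <= cutoff.

    Repeatedly drops the individual participating in the most pairs above
    ``cutoff`` (ties broken by lowest sample index) until none remain.
    Returns the kept indices in ascending order.
    """
    a = grm.matrix > cutoff
    np.fill_diagonal(a, False)
    a = a.copy()
    removed = np.zeros(a.shape[0], dtype=bool)
    degree = a.sum(axis=1)
    while degree.max(initial=0) > 0:
        worst = int(np.argmax(degree))  # argmax takes the lowest index on ties
        removed[worst] = True
        degree -= a[worst].astype(degree.dtype)
        a[worst, :] = False
        a[:, worst] = False
        degree[worst] = 0
    return np.flatnonzero(~removed)
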