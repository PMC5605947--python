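"""Phase-resolved cohort container.

A :class:`PhasedCohort` holds the haplotype-resolved genotypes of a cohort:
two binary allele sequences per individual over a panel of biallelic SNPs
with both physical (bp) and genetic (cM) coordinates.  It is the in-memory
interchange object between the simulator, the VCF reader, the QC layer and
the haplotype-window machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ["chrom", "pos", "cm", "ref", "alt"]


@dataclass
class PhasedCohort:
    """Haplotype-resolved genotypes for a set of individuals.

    Parameters
    ----------
    sample_ids
        Individual identifiers, length ``n``.
    snps
        SNP table with columns ``chrom, pos, cm, ref, alt``; ``pos`` must be
        strictly increasing within each chromosome and ``cm`` non-decreasing
        with ``pos``.
    haplotypes
        ``(2n, m)`` uint8 array of 0/1 alleles.  Rows ``2i`` and ``2i+1``
        are the two phased haplotypes of individual ``i``.
    """

    sample_ids: np.ndarray
    snps: pd.DataFrame
    haplotypes: np.ndarray
    pedigree: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (2n, m) array")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"haplotype rows ({self.haplotypes.shape[0]}) != 2 x samples "
                f"({len(self.sample_ids)})"
            )
        if self.haplotypes.shape[1] != len(self.snps):
            raise ValueError("haplotype columns != number of SNPs")
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snp table missing columns: {missing}")
        self.snps = self.snps.reset_index(drop=True)
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            cm = sub["cm"].to_numpy(dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decrease with bp on {chrom}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in table order."""
        return list(dict.fromkeys(self.snps["chrom"]))

    def chrom_mask(self, chrom) -> np.ndarray:
        return (self.snps["chrom"] == chrom).to_numpy()

    def dosages(self, snp_indices=None) -> np.ndarray:
        """Per-individual alt-allele dosages (0/1/2), shape ``(n, m')``."""
        h = self.haplotypes if snp_indices is None else self.haplotypes[:, snp_indices]
        return (h[0::2].astype(np.int16) + h[1::2]).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per SNP over the 2n chromosomes."""
        return self.haplotypes.mean(axis=0)

    def take_snps(self, indices) -> "PhasedCohort":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return PhasedCohort(
            self.sample_ids,
            self.snps.iloc[indices].reset_index(drop=True),
            self.haplotypes[:, indices],
            pedigree=self.pedigree,
        )

    def take_samples(self, indices) -> "PhasedCohort":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        hap_rows = np.empty(2 * len(indices), dtype=np.int64)
        hap_rows[0::2] = 2 * indices
        hap_rows[1::2] = 2 * indices + 1
        ped = self.pedigree
        if ped is not None:
            keep = set(np.asarray(self.sample_ids)[indices])
            ped = ped[ped["iid"].isin(keep)].reset_index(drop=True)
        return PhasedCohort(
            self.sample_ids[indices],
            self.snps,
            self.haplotypes[hap_rows],
            pedigree=ped,
        )

    def sample_index(self, ids) -> np.ndarray:
        """Positions of ``ids`` within ``sample_ids`` (KeyError if absent)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"sample {exc.args[0]!r} not in cohort") from None
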