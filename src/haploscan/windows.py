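"""Genetic-map interpolation, cM sliding windows and haplotype enumeration.

Association testing operates on *haplotype alleles*: the distinct multi-SNP
allele strings observed within a sliding window of fixed genetic length.
Windows are delimited in centimorgans (recombination distance), not base
pairs, so SNP membership is driven by an interpolated genetic map.  The
window slides along the chromosome in steps of a quarter of its own size,
so each SNP is typically covered by four windows of a given size.

Enumerated alleles are quality-controlled: a window must contribute at
least ``min_snps`` SNPs, and an allele must reach frequency ``min_freq``
and pass a Hardy-Weinberg test on its 0/1/2 carrier dosage, otherwise it
is not assessed — but it stays in the pooled "alternative" class, i.e. it
still counts in the frequency denominator and in the dosage complement of
the assessed alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PhasedCohort
from .qc import hwe_chisq_p

DEFAULT_WINDOW_SIZES_CM = (1.0, 0.5, 0.25)


class GeneticMapIndex:
    """Per-chromosome (bp, cM) anchors with linear interpolation.

    Positions between anchors are linearly interpolated; positions beyond
    the terminal anchors are extrapolated at the terminal interval's
    recombination rate (rates are never negative because cM is
    non-decreasing in bp).
    """

    def __init__(self, map_table: pd.DataFrame):
        required = {"chrom", "pos", "cm"}
        if not required.issubset(map_table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        self._anchors: dict = {}
        for chrom, sub in map_table.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            bp = sub["pos"].to_numpy(dtype=np.int64)
            cm = sub["cm"].to_numpy(dtype=float)
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"duplicate/unordered bp anchors on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM anchors decrease on {chrom}")
            self._anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list:
        return list(self._anchors)

    def chrom_length_cm(self, chrom) -> float:
        bp, cm = self._require(chrom)
        return float(cm[-1])

    def _require(self, chrom):
        try:
            return self._anchors[chrom]
        except KeyError:
            raise KeyError(f"no genetic map for chromosome {chrom!r}") from None

    def interpolate(self, chrom, positions) -> np.ndarray:
        """Map bp ``positions`` on ``chrom`` to cM."""
        bp, cm = self._require(chrom)
        positions = np.asarray(positions, dtype=float)
        out = np.interp(positions, bp, cm)
        if len(bp) >= 2:
            # np.interp clamps outside the anchor range; extend at the
            # terminal intervals' rates instead.
            lo_rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
            hi_rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
            below = positions < bp[0]
            above = positions > bp[-1]
            out = np.where(below, cm[0] + (positions - bp[0]) * lo_rate, out)
            out = np.where(above, cm[-1] + (positions - bp[-1]) * hi_rate, out)
        return out


def interpolate_cm(positions, genetic_map: GeneticMapIndex, chrom) -> np.ndarray:
    """Functional wrapper around :meth:`GeneticMapIndex.interpolate`."""
    return genetic_map.interpolate(chrom, positions)


@dataclass(frozen=True)
class Window:
    """A cM-delimited SNP interval on one chromosome.

    ``snp_indices`` index into the cohort's global SNP table.  The bp span
    reported (``bp_start``/``bp_end``) corresponds to the outermost member
    SNPs, which is also the span used for gene-region overlap queries.
    """

    window_id: str
    chrom: object
    cm_start: float
    cm_end: float
    snp_indices: np.ndarray
    bp_start: int
    bp_end: int
    size_cm: float

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def build_windows(
    cohort_snps: pd.DataFrame,
    window_cm: float,
    step_fraction: float = 0.25,
) -> list[Window]:
    """Sliding windows of ``window_cm`` centimorgans, stepping a quarter window.

    Starts lie on the step grid from 0 cM; the last gridded window is the
    final full-size window fitting on the chromosome.  If SNPs beyond its
    end would otherwise be uncovered, one terminal window ending at the
    chromosome end is appended.  Membership is half-open ``[start, end)``
    except for the last window on each chromosome, which is closed so the
    terminal SNP is covered.  Windows containing no SNP are discarded.
    """
    if window_cm <= 0:
        raise ValueError("window size must be positive")
    step = window_cm * step_fraction
    windows: list[Window] = []
    for chrom, sub in cohort_snps.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        length = float(cm[-1])
        starts = []
        if length <= window_cm:
            starts = [0.0]
            ends = [length]
        else:
            k_max = int(np.floor((length - window_cm) / step + 1e-9))
            starts = [k * step for k in range(k_max + 1)]
            ends = [s + window_cm for s in starts]
            if ends[-1] < length:  # residual SNPs uncovered by the grid
                starts.append(length - window_cm)
                ends.append(length)
        n_chrom_windows = len(starts)
        for j, (s, e) in enumerate(zip(starts, ends)):
            closed = j == n_chrom_windows - 1
            if closed:
                member = (cm >= s - 1e-12) & (cm <= e + 1e-12)
            else:
                member = (cm >= s - 1e-12) & (cm < e - 1e-12)
            if not member.any():
                continue
            snp_idx = idx[member]
            windows.append(
                Window(
                    window_id=f"{chrom}:{s:g}-{e:g}cm",
                    chrom=chrom,
                    cm_start=float(s),
                    cm_end=float(e),
                    snp_indices=snp_idx,
                    bp_start=int(pos[member][0]),
                    bp_end=int(pos[member][-1]),
                    size_cm=float(window_cm),
                )
            )
    return windows


@dataclass
class HaplotypeAllele:
    """One distinct SNP-allele string within a window.

    ``frequency`` is the fraction of the cohort's 2n chromosomes carrying
    the string; ``dosage`` counts the string among each individual's two
    haplotypes (0/1/2).  ``assessed`` is set by :func:`haplotype_qc`.
    """

    hap_id: str
    window: Window
    allele_string: str
    frequency: float
    dosage: np.ndarray = field(repr=False)
    assessed: bool = True
    qc_reason: str | None = None

    @property
    def chrom(self):
        return self.window.chrom


def enumerate_haplotypes(cohort: PhasedCohort, window: Window) -> list[HaplotypeAllele]:
    """Distinct haplotype alleles of ``window`` across all 2n chromosomes."""
    sub = cohort.haplotypes[:, window.snp_indices]
    # np.unique on rows via void view: exact string-identity semantics.
    strings, inverse, counts = np.unique(
        sub, axis=0, return_inverse=True, return_counts=True
    )
    two_n = sub.shape[0]
    inverse = inverse.reshape(-1, 2)  # per-individual pair of allele indices
    alleles = []
    for a in range(strings.shape[0]):
        dosage = (inverse == a).sum(axis=1).astype(np.int8)
        s = "".join(map(str, strings[a]))
        alleles.append(
            HaplotypeAllele(
                hap_id=f"{window.window_id}|{s}",
                window=window,
                allele_string=s,
                frequency=counts[a] / two_n,
                dosage=dosage,
            )
        )
    return alleles


def haplotype_qc(
    alleles: list[HaplotypeAllele],
    min_snps: int = 5,
    min_freq: float = 0.005,
    hwe_p_min: float = 1e-6,
) -> list[HaplotypeAllele]:
    """Mark alleles as assessed or alternative-pool only.

    A window with fewer than ``min_snps`` member SNPs contributes no
    assessed alleles at all.  Otherwise an allele is dropped from
    assessment when its frequency is below ``min_freq`` or its
    biallelic-collapse (this allele vs all others) Hardy-Weinberg P-value
    falls below ``hwe_p_min``.  Excluded alleles keep their dosages and
    frequencies — they remain part of the alternative class, so windowwise
    frequency and dosage conservation is untouched.
    """
    for allele in alleles:
        if allele.window.n_snps < min_snps:
            allele.assessed = False
            allele.qc_reason = "window_snps"
            continue
        if allele.frequency < min_freq:
            allele.assessed = False
            allele.qc_reason = "freq"
            continue
        d = allele.dosage
        n0 = int(np.sum(d == 0))
        n1 = int(np.sum(d == 1))
        n2 = int(np.sum(d == 2))
        p_hwe = hwe_chisq_p(n0, n1, n2)
        if p_hwe < hwe_p_min:
            allele.assessed = False
            allele.qc_reason = "hwe"
            continue
        allele.assessed = True
        allele.qc_reason = None
    return alleles


def enumerate_assessed(
    cohort: PhasedCohort,
    windows: list[Window],
    min_snps: int = 5,
    min_freq: float = 0.005,
    hwe_p_min: float = 1e-6,
) -> list[HaplotypeAllele]:
    """Enumerate + QC over many windows, returning assessed alleles only."""
    out = []
    for w in windows:
        alleles = haplotype_qc(
            enumerate_haplotypes(cohort, w),
            min_snps=min_snps,
            min_freq=min_freq,
            hwe_p_min=hwe_p_min,
        )
        out.extend(a for a in alleles if a.assessed)
    return out


def region_overlap(
    haplotypes: list[HaplotypeAllele],
    regions: pd.DataFrame,
) -> list[HaplotypeAllele]:
    """Haplotypes whose outermost-SNP bp span intersects any region.

    ``regions`` has columns ``chrom, start, end`` (1-based, inclusive on
    both ends); intersection is closed-interval.
    """
    required = {"chrom", "start", "end"}
    if not required.issubset(regions.columns):
        raise ValueError(f"regions need columns {sorted(required)}")
    if (regions["end"] < regions["start"]).any():
        raise ValueError("malformed region: end < start")
    hits = []
    for hap in haplotypes:
        w = hap.window
        sub = regions[regions["chrom"] == w.chrom]
        if ((w.bp_start <= sub["end"]) & (w.bp_end >= sub["start"])).any():
            hits.append(hap)
    return hits


def window_registry(windows: list[Window]) -> pd.DataFrame:
    """Tabular view: ``chr cm_start cm_end bp_start bp_end n_snps``."""
    return pd.DataFrame(
        {
            "window_id": [w.window_id for w in windows],
            "chr": [w.chrom for w in windows],
            "cm_start": [w.cm_start for w in windows],
            "cm_end": [w.cm_end for w in windows],
            "bp_start": [w.bp_start for w in windows],
            "bp_end": [w.bp_end for w in windows],
            "n_snps": [w.n_snps for w in windows],
        }
    )


def haplotype_registry(alleles: list[HaplotypeAllele]) -> pd.DataFrame:
    """Tabular view: ``window_id hap_id allele_string freq assessed``."""
    return pd.DataFrame(
        {
            "window_id": [a.window.window_id for a in alleles],
            "hap_id": [a.hap_id for a in alleles],
            "allele_string": [a.allele_string for a in alleles],
            "freq": [a.frequency for a in alleles],
            "assessed": [a.assessed for a in alleles],
            "qc_reason": [a.qc_reason for a in alleles],
        }
    )
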