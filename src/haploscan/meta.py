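"""Multiple-testing correction and cross-cohort meta-analysis.

Independent-test counting follows the clumping approach: haplotypes are
visited by ascending association P-value; each unassigned haplotype
becomes an index, and every unassigned haplotype on the same chromosome
with dosage LD r^2 at or above the threshold (default 0.4) is assigned to
it.  The Bonferroni threshold is ``alpha / n_independent``.  Cohort
estimates are pooled by fixed-effects inverse-variance weighting with a
per-cohort direction string ("+", "-", or "?" when a haplotype was not
observed in that cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from scipy import stats


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two 0/1/2 dosage vectors.

    Returns NaN when either vector has zero variance (undefined LD).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("dosage vectors differ in length")
    if a.var() == 0 or b.var() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class ClumpReport:
    """Index haplotypes and the assignment of every haplotype to its index."""

    index_haplotypes: list
    assignment: dict  # hap_id -> index hap_id (indices map to themselves)

    @property
    def n_independent(self) -> int:
        return len(self.index_haplotypes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hap_id": list(self.assignment),
                "index_hap": [self.assignment[h] for h in self.assignment],
            }
        )


def clump_independent(
    assoc: pd.DataFrame,
    dosages: dict,
    r2_threshold: float = 0.4,
) -> ClumpReport:
    """Greedy LD clumping of association results.

    ``assoc`` needs columns ``hap_id, chr, p`` (``bp_start`` and
    ``allele_string`` are used for deterministic tie-breaking);
    ``dosages`` maps hap_id to its 0/1/2 dosage vector.  r^2 is computed
    within-chromosome only.
    """
    t = assoc.copy()
    for col in ("bp_start", "allele_string"):
        if col not in t.columns:
            t[col] = ""
    t = t.sort_values(
        ["p", "chr", "bp_start", "allele_string"], kind="mergesort"
    )
    assignment: dict = {}
    indices: list = []
    pending: dict = {}  # chrom -> list of hap_ids not yet assigned, in P order
    for row in t.itertuples():
        pending.setdefault(row.chr, []).append(row.hap_id)
    order = t["hap_id"].tolist()
    chrom_of = dict(zip(t["hap_id"], t["chr"]))
    for hap_id in order:
        if hap_id in assignment:
            continue
        indices.append(hap_id)
        assignment[hap_id] = hap_id
        chrom = chrom_of[hap_id]
        d_index = np.asarray(dosages[hap_id], dtype=float)
        still = [h for h in pending[chrom] if h not in assignment]
        if still:
            mat = np.stack([np.asarray(dosages[h], float) for h in still])
            with np.errstate(invalid="ignore", divide="ignore"):
                dc = mat - mat.mean(axis=1, keepdims=True)
                ic = d_index - d_index.mean()
                denom = np.sqrt((dc**2).sum(axis=1) * (ic**2).sum())
                r = np.where(denom > 0, dc @ ic / np.where(denom > 0, denom, 1), np.nan)
            for h, r2 in zip(still, r * r):
                if np.isfinite(r2) and r2 >= r2_threshold:
                    assignment[h] = hap_id
        pending[chrom] = [h for h in pending[chrom] if h not in assignment]
    return ClumpReport(index_haplotypes=indices, assignment=assignment)


def bonferroni_threshold(n_independent: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold ``alpha / n_independent``."""
    if n_independent < 1:
        raise ValueError("independent count must be >= 1")
    return alpha / n_independent


def round_threshold(threshold: float, sig_figs: int = 1) -> float:
    """One-significant-figure rounding used when reporting the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(threshold))
    factor = 10.0 ** (exponent - sig_figs + 1)
    return round(threshold / factor) * factor


@dataclass
class MetaResult:
    """Fixed-effects IVW pooled estimate with per-cohort directions."""

    hap_id: str
    beta: float
    se: float
    z: float
    p: float
    direction: str
    n_cohorts: int
    cohort_betas: list = field(default_factory=list)


def ivw_meta(cohort_estimates, hap_id: str = "") -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling.

    ``cohort_estimates`` is a sequence of (beta, se) pairs in cohort
    order; a missing cohort is ``None`` (or has a non-finite beta) and
    contributes "?" to the direction string.  Weights are ``1/se^2``;
    pooled se is ``(sum w)^(-1/2)``.
    """
    weights, betas, direction = [], [], []
    for est in cohort_estimates:
        beta = se = None
        if est is not None:
            beta, se = est
        if beta is None or se is None or not np.isfinite(beta) or not np.isfinite(se):
            direction.append("?")
            continue
        if se <= 0:
            raise ValueError("standard errors must be positive")
        direction.append("+" if beta >= 0 else "-")
        weights.append(1.0 / se**2)
        betas.append(beta)
    if not weights:
        raise ValueError("no cohort contributed a finite estimate")
    w = np.asarray(weights)
    b = np.asarray(betas)
    pooled_beta = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled_beta / pooled_se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return MetaResult(
        hap_id=hap_id,
        beta=pooled_beta,
        se=pooled_se,
        z=float(z),
        p=p,
        direction="".join(direction),
        n_cohorts=len(betas),
        cohort_betas=list(betas),
    )


def meta_analyse(tables: list[pd.DataFrame], key: str = "hap_id") -> pd.DataFrame:
    """Pool per-cohort association tables (columns ``hap_id beta se``) rowwise.

    Haplotypes absent from a cohort (or untestable there) get "?" in that
    cohort's direction slot; the union of keys over all cohorts is pooled.
    """
    keys: list = []
    seen = set()
    for t in tables:
        for k in t[key]:
            if k not in seen:
                seen.add(k)
                keys.append(k)
    lookups = [t.set_index(key) for t in tables]
    rows = []
    for k in keys:
        ests = []
        for lk in lookups:
            if k in lk.index and np.isfinite(lk.loc[k, "beta"]):
                ests.append((float(lk.loc[k, "beta"]), float(lk.loc[k, "se"])))
            else:
                ests.append(None)
        m = ivw_meta(ests, hap_id=k)
        rows.append(
            {
                "hap_id": k, "beta": m.beta, "se": m.se, "z": m.z, "p": m.p,
                "direction": m.direction, "n_cohorts": m.n_cohorts,
            }
        )
    return pd.DataFrame(rows)


def replication_power(n: int, variance_explained: float, alpha: float = 0.05) -> float:
    """Power of a 1-df test for an effect explaining ``variance_explained``.

    The Wald chi-square is non-central with ncp = n r^2 / (1 - r^2); power
    is the probability of exceeding the central chi-square critical value
    at ``alpha``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0 <= variance_explained < 1):
        raise ValueError("variance_explained must be in [0, 1)")
    crit = stats.chi2.isf(alpha, df=1)
    if variance_explained == 0:
        return float(alpha)
    ncp = n * variance_explained / (1.0 - variance_explained)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))
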