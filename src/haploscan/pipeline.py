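"""End-to-end orchestration: discovery scan, replication lookups, meta-analysis.

The discovery run executes phenotype derivation -> SNP QC -> window
construction -> haplotype enumeration/QC -> GRMs -> two-GRM mixed-model
scan -> LD clumping, logging the counts at every filter so a run's
bookkeeping (windows built, haplotypes enumerated/assessed, independent
count, significance threshold) is reproducible from the log alone.

Replication re-enumerates haplotypes in each replication cohort inside
the same cM windows and matches discovery haplotypes by identical allele
string over the shared SNP panel; haplotypes absent from a cohort are
reported as missing ("?" in the meta-analysis direction string) and the
pooled estimate uses the remaining cohorts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort import PhasedCohort
from .grm import GRMSet, compute_grm, unrelated_subset
from .meta import bonferroni_threshold, clump_independent, meta_analyse, round_threshold
from .mixed_model import greml_h2, lambda_gc, scan_haplotypes
from .phenotype import derive_g
from .qc import QCThresholds, snp_qc
from .windows import (
    DEFAULT_WINDOW_SIZES_CM,
    build_windows,
    enumerate_haplotypes,
    haplotype_qc,
    region_overlap,
)

logger = logging.getLogger("haploscan")


@dataclass
class DiscoveryResult:
    """All artifacts of a discovery run."""

    assoc: pd.DataFrame
    haplotypes: dict  # hap_id -> HaplotypeAllele (assessed only)
    windows: list
    clump: object
    n_independent: int
    significance_threshold: float
    reported_threshold: float
    lambda_gc: float | None
    counts: dict = field(default_factory=dict)


def g_from_phenotypes(pheno: pd.DataFrame, test_columns=None):
    """Derive g and the sex/age covariate design from a phenotype table."""
    if test_columns is None:
        test_columns = [c for c in pheno.columns if c.startswith("test")]
    score = derive_g(pheno[["iid", *test_columns]])
    covariates = np.column_stack(
        [np.ones(len(pheno)), pheno["sex"].to_numpy(float), pheno["age"].to_numpy(float)]
    )
    return score, covariates


def assessed_haplotypes(
    cohort: PhasedCohort,
    window_sizes=DEFAULT_WINDOW_SIZES_CM,
    min_snps: int = 5,
    min_freq: float = 0.005,
    hwe_p_min: float = 1e-6,
):
    """Windows + enumerated/assessed haplotypes with filter bookkeeping."""
    windows, assessed, counts = [], [], {"enumerated": 0, "assessed": 0}
    excl = {"window_snps": 0, "freq": 0, "hwe": 0}
    for size in window_sizes:
        ws = build_windows(cohort.snps, size)
        windows.extend(ws)
        for w in ws:
            alleles = haplotype_qc(
                enumerate_haplotypes(cohort, w),
                min_snps=min_snps, min_freq=min_freq, hwe_p_min=hwe_p_min,
            )
            counts["enumerated"] += len(alleles)
            for a in alleles:
                if a.assessed:
                    assessed.append(a)
                else:
                    excl[a.qc_reason] += 1
    counts["assessed"] = len(assessed)
    counts.update({f"excluded_{k}": v for k, v in excl.items()})
    counts["n_windows"] = len(windows)
    assert counts["assessed"] + sum(excl.values()) == counts["enumerated"]
    return windows, assessed, counts


def run_discovery(
    cohort: PhasedCohort,
    pheno: pd.DataFrame,
    window_sizes=DEFAULT_WINDOW_SIZES_CM,
    qc_thresholds: QCThresholds | None = None,
    clump_r2: float = 0.4,
    alpha: float = 0.05,
    two_grm: bool = True,
    grm_cutoff: float = 0.05,
    cohort_label: str = "discovery",
) -> DiscoveryResult:
    """Full discovery pipeline on an in-memory cohort."""
    pheno = pheno.set_index("iid").loc[list(map(str, cohort.sample_ids))].reset_index() \
        if not np.array_equal(pheno["iid"].to_numpy(object), cohort.sample_ids) else pheno
    kept, qc_report = snp_qc(cohort.dosages(), qc_thresholds or QCThresholds())
    logger.info("SNP QC: kept %d of %d SNPs", len(kept), cohort.n_snps)
    cohort = cohort.take_snps(kept)

    score, covariates = g_from_phenotypes(pheno)
    logger.info("g derived: PC1 explains %.3f of battery variance",
                score.proportion_variance_explained)

    windows, assessed, counts = assessed_haplotypes(cohort, window_sizes)
    logger.info("windows built: %d; haplotypes enumerated: %d, assessed: %d",
                counts["n_windows"], counts["enumerated"], counts["assessed"])

    grm_set = GRMSet(cohort)
    assoc = scan_haplotypes(
        score.g, covariates, assessed, grm_set,
        two_grm=two_grm, grm_cutoff=grm_cutoff, cohort_label=cohort_label,
    )
    testable = assoc[~assoc["untestable"]]
    lam = lambda_gc(testable["p"]) if len(testable) >= 100 else None
    if lam is not None:
        logger.info("genomic-control lambda: %.3f", lam)

    dosages = {a.hap_id: a.dosage for a in assessed}
    clump = clump_independent(testable, dosages, r2_threshold=clump_r2)
    threshold = bonferroni_threshold(clump.n_independent, alpha=alpha)
    logger.info("independent haplotypes: %d -> threshold %.3g (reported %.0e)",
                clump.n_independent, threshold, round_threshold(threshold))
    counts["n_snps_kept"] = len(kept)
    counts["n_independent"] = clump.n_independent
    return DiscoveryResult(
        assoc=assoc,
        haplotypes={a.hap_id: a for a in assessed},
        windows=windows,
        clump=clump,
        n_independent=clump.n_independent,
        significance_threshold=threshold,
        reported_threshold=round_threshold(threshold),
        lambda_gc=lam,
        counts=counts,
    )


def select_for_replication(
    discovery: DiscoveryResult,
    p_cutoff: float = 1e-6,
    regions: pd.DataFrame | None = None,
) -> list:
    """Haplotypes with discovery P < cutoff plus gene-region overlaps."""
    t = discovery.assoc
    sel = set(t.loc[(~t["untestable"]) & (t["p"] < p_cutoff), "hap_id"])
    if regions is not None and len(regions):
        for hap in region_overlap(list(discovery.haplotypes.values()), regions):
            sel.add(hap.hap_id)
    return [discovery.haplotypes[h] for h in t["hap_id"] if h in sel]


def _match_haplotype(rep_cohort: PhasedCohort, hap) -> object | None:
    """Find ``hap``'s allele (same window, same allele string) in a cohort."""
    w = hap.window
    snps = rep_cohort.snps
    on_chrom = snps["chrom"] == w.chrom
    chrom_max_cm = snps.loc[on_chrom, "cm"].max()
    is_final = w.cm_end >= chrom_max_cm - 1e-9  # closed terminal window
    upper = (snps["cm"] <= w.cm_end + 1e-12) if is_final else (snps["cm"] < w.cm_end - 1e-12)
    member = on_chrom & (snps["cm"] >= w.cm_start - 1e-12) & upper
    idx = snps.index[member].to_numpy()
    if len(idx) != len(hap.allele_string):
        return None  # shared-panel mismatch: cannot key by allele string
    from .windows import Window

    rep_window = Window(
        window_id=w.window_id, chrom=w.chrom, cm_start=w.cm_start, cm_end=w.cm_end,
        snp_indices=idx,
        bp_start=int(snps.loc[member, "pos"].iloc[0]),
        bp_end=int(snps.loc[member, "pos"].iloc[-1]),
        size_cm=w.size_cm,
    )
    for allele in enumerate_haplotypes(rep_cohort, rep_window):
        if allele.allele_string == hap.allele_string:
            allele.hap_id = hap.hap_id  # key replication rows by discovery id
            return allele
    return None


def run_replication_meta(
    discovery: DiscoveryResult,
    replication_cohorts: list,
    p_cutoff: float = 1e-6,
    regions: pd.DataFrame | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Replication scans (one-GRM) and IVW meta-analysis.

    ``replication_cohorts`` is a list of ``(label, PhasedCohort, pheno)``
    tuples.  Returns the per-cohort association tables (discovery first)
    and the pooled table with direction strings.
    """
    selected = select_for_replication(discovery, p_cutoff=p_cutoff, regions=regions)
    disc_table = discovery.assoc[
        discovery.assoc["hap_id"].isin([h.hap_id for h in selected])
    ]
    if not selected:
        logger.warning("no haplotypes selected for replication")
        return [disc_table], disc_table.assign(direction="", n_cohorts=1)

    tables = [disc_table]
    for label, rep_cohort, rep_pheno in replication_cohorts:
        matched = []
        for hap in selected:
            m = _match_haplotype(rep_cohort, hap)
            if m is not None:
                matched.append(m)
        logger.info("%s: matched %d of %d haplotypes", label, len(matched), len(selected))
        if matched:
            score, covariates = g_from_phenotypes(rep_pheno)
            grm_set = GRMSet(rep_cohort)
            t = scan_haplotypes(
                score.g, covariates, matched, grm_set,
                two_grm=False, cohort_label=label,
            )
        else:
            t = disc_table.iloc[0:0]
        tables.append(t)
    meta = meta_analyse(tables)
    return tables, meta


def greml_pipeline(
    cohort: PhasedCohort,
    pheno: pd.DataFrame,
    relatedness_cutoff: float = 0.025,
) -> dict:
    """GREML heritability of g on the relatedness-pruned subsample."""
    score, covariates = g_from_phenotypes(pheno)
    grm = compute_grm(cohort.dosages())
    keep = unrelated_subset(grm, cutoff=relatedness_cutoff)
    logger.info("unrelated subset: kept %d of %d", len(keep), cohort.n_samples)
    sub = compute_grm(cohort.take_samples(keep).dosages())
    h2, se, res = greml_h2(score.g[keep], covariates[keep], sub)
    return {"h2": h2, "se": se, "n": len(keep), "converged": res.converged}


def write_manifest(path: str, inputs: dict, params: dict, counts: dict) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(
            {"haploscan_version": __version__, "inputs": inputs,
             "parameters": params, "counts": counts},
            fh, indent=2, default=str,
        )
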