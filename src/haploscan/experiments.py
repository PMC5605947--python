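"""Reproducible calibration and validation experiments.

These routines regenerate the package's headline numbers from scratch:
worked inverse-variance poolings of the published per-cohort estimates,
the genome-wide Bonferroni threshold, analytic replication power, GREML
parameter recovery on simulated unrelated cohorts, and the null-scan
calibration (type-I error and genomic-control lambda) that contrasts the
two-GRM discovery model with a single-GRM model on family-structured
data.
"""

from __future__ import annotations

import numpy as np

from . import datasets
from .grm import GRMSet, compute_grm, threshold_grm
from .meta import bonferroni_threshold, ivw_meta, replication_power, round_threshold
from .mixed_model import fit_reml, lambda_gc, scan_haplotypes
from .simulate import SimConfig, simulate_cohort, simulate_unrelated


def ivw_worked_examples() -> dict:
    """Pool the published per-cohort gene-region estimates by IVW.

    Returns ``{gene: pooled beta}`` for the top BDNF/DAOA/APOE haplotypes;
    the inputs are the printed two-decimal cohort estimates, so pooled
    values carry ~0.01 input-rounding uncertainty.
    """
    return {
        gene: ivw_meta(ests).beta
        for gene, ests in datasets.top_gene_region_estimates().items()
    }


def genomewide_threshold() -> dict:
    """Bonferroni threshold implied by the published independent count."""
    thr = bonferroni_threshold(datasets.INDEPENDENT_HAPLOTYPE_COUNT)
    return {"exact": thr, "reported": round_threshold(thr)}


def smallest_replication_power(alpha: float = 0.05) -> float:
    """Power of the smallest replication cohort for the smallest
    published per-haplotype effect."""
    n = datasets.COHORT_N["ELSA"]
    r2 = datasets.VARIANCE_EXPLAINED_RANGE[0]
    return replication_power(n, r2, alpha=alpha)


def _recovery_config(h2: float, seed: int) -> SimConfig:
    return SimConfig(
        n_chromosomes=5,
        snps_per_chromosome=1000,
        chromosome_length_cm=100.0,
        h2_polygenic=h2,
        c2_family=0.0,
        seed=seed,
    )


def greml_recovery(
    h2_values=(0.0, 0.2, 0.5), n: int = 2000, seed: int = 0
) -> list[dict]:
    """Simulate unrelated cohorts and re-estimate h2 by single-GRM REML.

    One genotype panel per h2 value (m = 5 x 1000 SNPs); the phenotype is
    the latent g, so the GRM-based estimate should recover the simulated
    value within its standard error.
    """
    out = []
    for k, h2 in enumerate(h2_values):
        cfg = _recovery_config(h2, seed=seed + 101 * k)
        cohort, _, truth = simulate_unrelated(cfg, n)
        grm = compute_grm(cohort.dosages())
        res = fit_reml(truth.g, np.ones((n, 1)), [grm])
        est, se = res.heritability()
        out.append({"h2_true": h2, "h2_hat": est, "se": se, "n": n,
                    "m": grm.n_snps, "converged": res.converged})
    return out


def null_scan_calibration(
    seed: int = 0,
    n_founders: int = 1060,
    n_chromosomes: int = 4,
    snps_per_chromosome: int = 750,
    alpha: float = 0.05,
    n_replicates: int = 2,
    variance_components: tuple = (0.30, 0.20, 0.50),
) -> dict:
    """Null genome scan on a family cohort: type-I error and lambda_GC.

    Gene-drops a family-structured cohort (~2 x n_founders individuals),
    then draws traits from the discovery model's own null per chromosome:

        y ~ MVN(0,  s2_u G_loco + s2_v G_t + s2_e I)

    with G_loco the realized leave-one-chromosome-out GRM, G_t its
    close-relative thresholded counterpart and (s2_u, s2_v, s2_e) =
    ``variance_components`` — i.e. polygenic plus close-relative familial
    covariance, no haplotype effect.  Every assessed 1 cM haplotype on
    that chromosome is then tested under the two-GRM model (correctly
    specified, so the rejection rate at ``alpha`` measures type-I error)
    and under the single-GRM model, which cannot represent the extra
    close-relative covariance with one genome-wide coefficient and
    therefore shows stratification-style lambda inflation.  Windows are
    tiled without overlap here (step = window size) and ``n_replicates``
    independent trait draws are pooled per chromosome so the test count
    behaves like the nominal count in the binomial calibration check.
    """
    cfg = SimConfig(
        n_founders=n_founders,
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        chromosome_length_cm=100.0,
        h2_polygenic=0.0,
        c2_family=0.0,
        seed=seed,
    )
    cohort, pheno, truth = simulate_cohort(cfg)
    n = cohort.n_samples
    from .windows import build_windows, enumerate_haplotypes, haplotype_qc

    assessed = []
    for w in build_windows(cohort.snps, 1.0, step_fraction=1.0):
        alleles = haplotype_qc(enumerate_haplotypes(cohort, w))
        assessed.extend(a for a in alleles if a.assessed)
    covars = np.column_stack(
        [np.ones(n), pheno["sex"].to_numpy(float), pheno["age"].to_numpy(float)]
    )
    grm_set = GRMSet(cohort)
    s2_u, s2_v, s2_e = variance_components
    rng = np.random.default_rng([seed, 99])
    pvals = {"two_grm": [], "one_grm": []}
    for chrom in [str(c + 1) for c in range(n_chromosomes)]:
        haps = [a for a in assessed if a.chrom == chrom]
        g = grm_set.loco(chrom)
        gt = threshold_grm(g, 0.05)
        V = s2_u * g.matrix + s2_v * gt.matrix + s2_e * np.eye(n)
        chol = np.linalg.cholesky(V + 1e-8 * np.eye(n))
        for _ in range(n_replicates):
            y = chol @ rng.normal(size=n)
            for label, two_grm in (("two_grm", True), ("one_grm", False)):
                assoc = scan_haplotypes(
                    y, covars, haps, grm_set, two_grm=two_grm, cohort_label=label
                )
                pvals[label].append(assoc.loc[~assoc["untestable"], "p"].to_numpy())
    out = {"n": n}
    for label, chunks in pvals.items():
        p = np.concatenate(chunks)
        out["n_tests"] = len(p)
        out[f"alpha_hat_{label}"] = float(np.mean(p < alpha))
        out[f"lambda_{label}"] = lambda_gc(p)
    return out


def checksum_false_positive_experiment(
    n_a: int = 1000, n_b: int = 1000, n_snps: int = 500, seed: int = 0
) -> dict:
    """Duplicate detection at scale: planted duplicates vs independent pairs.

    Two cohorts of independent genotypes (``n_a x n_b`` >= 1e6 cross
    pairs) share ``n_snps`` panel SNPs; two planted duplicates must be
    the only pairs matching on all 10 batches.
    """
    import pandas as pd

    from .overlap import batch_checksums, detect_overlap, select_panel

    rng = np.random.default_rng(seed)
    snps = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, n_snps + 1) * 997, "ref": "A", "alt": "G"}
    )
    panel = select_panel(snps, n_snps=n_snps, seed=seed)
    freqs = rng.uniform(0.05, 0.95, size=n_snps)
    da = rng.binomial(2, freqs, size=(n_a, n_snps))
    db = rng.binomial(2, freqs, size=(n_b, n_snps))
    planted = [(0, 0), (n_a - 1, n_b - 1)]
    for ia, ib in planted:
        db[ib] = da[ia]
    pa = batch_checksums(da, [f"a{i}" for i in range(n_a)], panel)
    pb = batch_checksums(db, [f"b{i}" for i in range(n_b)], panel)
    report = detect_overlap(pa, pb)
    hits = report[report["overlap"]]
    planted_ids = {(f"a{ia}", f"b{ib}") for ia, ib in planted}
    found = set(zip(hits["iid_a"], hits["iid_b"]))
    return {
        "n_pairs": n_a * n_b,
        "planted_found": len(planted_ids & found),
        "n_planted": len(planted_ids),
        "false_full_matches": len(found - planted_ids),
    }
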