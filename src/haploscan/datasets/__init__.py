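"""Bundled published summary data for worked examples.

``cohort_summary_stats.tsv`` holds the published per-cohort haplotype
association estimates (beta, s.e., P) from a three-cohort haplotype
study of general cognitive ability — discovery in Generation Scotland:
Scottish Family Health Study (GS:SFHS), replication in the English
Longitudinal Study of Ageing (ELSA) and UK Biobank — for the
genome-wide suggestive haplotypes and the top independently segregating
haplotypes overlapping the BDNF, DAOA and APOE gene coding regions.
"na" cells (a haplotype unobserved in a cohort) are stored as ".".

These printed estimates are *inputs* for the meta-analysis worked
examples; re-pooling them by inverse-variance weighting reproduces the
published pooled effects.
"""

from __future__ import annotations

import importlib.resources as resources

import numpy as np
import pandas as pd

#: published number of independently segregating haplotypes in the
#: discovery cohort at LD r^2 threshold 0.4
INDEPENDENT_HAPLOTYPE_COUNT = 1_070_216

#: per-cohort sample sizes with a derivable g score
COHORT_N = {"GS:SFHS": 19_326, "ELSA": 5_876, "UK Biobank": 22_800}

#: published range of per-haplotype variance in g explained (discovery)
VARIANCE_EXPLAINED_RANGE = (3.93e-3, 4.63e-3)

#: published SNP heritabilities of g per cohort (estimate, s.e.)
SNP_HERITABILITY = {
    "GS:SFHS": (0.41, 0.05),
    "ELSA": (0.17, 0.06),
    "UK Biobank": (0.21, 0.02),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str}, na_values=["."])


def load_cohort_summary_stats() -> pd.DataFrame:
    """Published per-cohort haplotype estimates (see module docstring)."""
    return _read("cohort_summary_stats.tsv")


def load_gene_regions() -> pd.DataFrame:
    """Default BDNF/DAOA/APOE lookup intervals (GRCh37 bp, 1-based closed).

    The intervals are the published containing spans of the reported
    gene-overlapping haplotypes, not transcript annotations.
    """
    return _read("gene_regions.tsv")


def top_gene_region_estimates() -> dict:
    """Per-gene top-row cohort (beta, se) triples for IVW worked examples.

    Returns ``{gene: [(beta, se) or None per cohort in GS:SFHS, ELSA,
    UK Biobank order]}`` for the most significant haplotype of each gene
    region.
    """
    t = load_cohort_summary_stats()
    t = t[t["analysis"] == "gene_region"]
    out: dict = {}
    for gene, sub in t.groupby("gene", sort=False):
        row = sub.sort_values("p_meta").iloc[0]
        ests = []
        for c in ("gs", "elsa", "ukb"):
            b, s = row[f"beta_{c}"], row[f"se_{c}"]
            ests.append(None if (pd.isna(b) or pd.isna(s)) else (float(b), float(s)))
        out[gene] = ests
    return out
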