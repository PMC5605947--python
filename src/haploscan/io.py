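"""File formats: phased VCF, genetic-map / phenotype / GRM / pedigree TSVs.

The pipeline consumes already-phased data, so the VCF reader insists on
phased GT fields ("0|1", not "0/1") and raises naming the first offending
sample and site.  Writing is plain VCF 4.2 text; reading goes through
cyvcf2.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .cohort import PhasedCohort


def write_phased_vcf(cohort: PhasedCohort, path: str) -> None:
    """Write the cohort as an uncompressed phased VCF 4.2 file."""
    snps = cohort.snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haploscan\n")
        for chrom in cohort.chromosomes:
            max_pos = int(snps.loc[snps["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, cohort.sample_ids))
            + "\n"
        )
        h = cohort.haplotypes
        ids = snps["id"] if "id" in snps.columns else [f"snp{i}" for i in range(len(snps))]
        for j, (chrom, pos, ref, alt, sid) in enumerate(
            zip(snps["chrom"], snps["pos"], snps["ref"], snps["alt"], ids)
        ):
            gts = "\t".join(
                f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(cohort.n_samples)
            )
            fh.write(f"{chrom}\t{pos}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path: str) -> PhasedCohort:
    """Read a phased VCF into a :class:`PhasedCohort`.

    Raises ``ValueError`` naming the sample and site on the first
    unphased or missing genotype (phased input is a precondition of
    haplotype enumeration).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.array(vcf.samples, dtype=object)
    n = len(samples)
    rows = []
    hap_cols = []
    for var in vcf:
        gts = np.asarray(var.genotypes, dtype=np.int32)
        if np.any(gts[:, 2] == 0):
            bad = samples[np.flatnonzero(gts[:, 2] == 0)[0]]
            raise ValueError(
                f"unphased genotype for sample {bad} at {var.CHROM}:{var.POS}"
            )
        if np.any(gts[:, :2] < 0):
            bad = samples[np.flatnonzero((gts[:, :2] < 0).any(axis=1))[0]]
            raise ValueError(
                f"missing genotype for sample {bad} at {var.CHROM}:{var.POS}"
            )
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "cm": np.nan,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "id": var.ID or f"{var.CHROM}:{var.POS}",
            }
        )
        col = np.empty(2 * n, dtype=np.uint8)
        col[0::2] = gts[:, 0]
        col[1::2] = gts[:, 1]
        hap_cols.append(col)
    vcf.close()
    snps = pd.DataFrame(rows)
    haplos = np.stack(hap_cols, axis=1) if hap_cols else np.zeros((2 * n, 0), np.uint8)
    return PhasedCohort(samples, snps, haplos)


def write_genetic_map(map_table: pd.DataFrame, path: str) -> None:
    map_table[["chrom", "pos", "cm"]].rename(columns={"chrom": "chr"}).to_csv(
        path, sep="\t", index=False
    )


def read_genetic_map(path: str) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return t.rename(columns={"chr": "chrom"})[["chrom", "pos", "cm"]]


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"iid": str})


def write_pedigree(pedigree: pd.DataFrame, path: str) -> None:
    pedigree[["iid", "fid", "mid", "famid"]].to_csv(path, sep="\t", index=False)


def read_pedigree(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_grm(grm: np.ndarray, ids, path: str) -> None:
    """Lower-triangle triplet TSV (``i j value``) plus an ``.ids`` sidecar."""
    n = grm.shape[0]
    i, j = np.tril_indices(n)
    pd.DataFrame({"i": i, "j": j, "value": grm[i, j]}).to_csv(path, sep="\t", index=False)
    with open(path + ".ids", "w") as fh:
        fh.writelines(f"{s}\n" for s in ids)


def read_grm(path: str) -> tuple[np.ndarray, np.ndarray]:
    t = pd.read_csv(path, sep="\t")
    n = int(t["i"].max()) + 1
    grm = np.zeros((n, n))
    grm[t["i"], t["j"]] = t["value"]
    grm[t["j"], t["i"]] = t["value"]
    with open(path + ".ids") as fh:
        ids = np.array([line.strip() for line in fh if line.strip()], dtype=object)
    return grm, ids


def export_cohort(
    cohort: PhasedCohort,
    phenotypes: pd.DataFrame,
    outdir: str,
    prefix: str = "cohort",
) -> dict:
    """Write VCF + map + phenotype (+ pedigree) files; returns the paths."""
    if set(map(str, cohort.sample_ids)) != set(map(str, phenotypes["iid"])):
        raise ValueError("sample IDs of cohort and phenotype table differ")
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, f"{prefix}.vcf"),
        "map": os.path.join(outdir, f"{prefix}.map.tsv"),
        "pheno": os.path.join(outdir, f"{prefix}.pheno.tsv"),
    }
    try:
        write_phased_vcf(cohort, paths["vcf"])
        write_genetic_map(cohort.snps, paths["map"])
        write_phenotypes(phenotypes, paths["pheno"])
        if cohort.pedigree is not None:
            paths["pedigree"] = os.path.join(outdir, f"{prefix}.ped.tsv")
            write_pedigree(cohort.pedigree, paths["pedigree"])
    except OSError as exc:
        raise OSError(f"failed writing cohort files under {outdir}: {exc}") from exc
    return paths


def load_cohort(vcf_path: str, map_path: str) -> PhasedCohort:
    """Read a phased VCF and attach interpolated cM coordinates."""
    from .windows import GeneticMapIndex

    cohort = read_phased_vcf(vcf_path)
    gmap = GeneticMapIndex(read_genetic_map(map_path))
    cm = np.empty(len(cohort.snps))
    for chrom in cohort.chromosomes:
        mask = cohort.chrom_mask(chrom)
        cm[mask] = gmap.interpolate(chrom, cohort.snps.loc[mask, "pos"].to_numpy())
    cohort.snps["cm"] = cm
    return cohort
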