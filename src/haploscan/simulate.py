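"""Family-structured cohort simulator with a haplotype-aware trait model.

The simulator produces the inputs the association pipeline consumes:
truth-phased genotypes over a synthetic genetic map, a pedigree with
realistic nuclear-family structure, and a cognitive test battery driven
by a single latent factor g.

Genetic architecture of the latent trait::

    g = polygenic + causal-haplotype terms + family environment + noise

* the polygenic term sums normally distributed effects of every SNP's
  standardized genotype, rescaled to explain exactly ``h2_polygenic`` of
  the phenotypic variance;
* each causal window contributes one designated haplotype allele whose
  standardized 0/1/2 dosage explains its configured variance fraction —
  the causal unit is the haplotype allele, matching the unit the scan
  tests, not a single SNP;
* a family-environment component shared by members of the same nuclear
  family (variance ``c2_family``) creates close-relative covariance that
  the SNP-based relationship matrix does not capture, which is what makes
  the thresholded second relationship matrix of the discovery model do
  real work.

Founder haplotypes are drawn from small per-block template pools
(``template_pool_size`` ancestral haplotypes per ``block_length_cm``
segment, copied with a small per-SNP error rate), which yields a handful
of haplotype alleles per window with non-trivial frequencies.  Meiosis is
modelled Poisson/Haldane: crossover counts per chromosome are Poisson
with mean equal to the map length in Morgans and positions are uniform in
cM; crossover interference is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PhasedCohort
from .windows import HaplotypeAllele, Window, enumerate_haplotypes


@dataclass(frozen=True)
class CausalWindow:
    """A cM interval on one chromosome harbouring one causal haplotype allele."""

    chrom: str
    cm_start: float
    cm_end: float
    variance_explained: float


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate a family-based discovery cohort at desk scale:
    nuclear families with 0-4 offspring, SNP heritability inside the
    0.17-0.41 range reported for general cognitive ability, a shared
    family environment, and a four-test battery whose first principal
    component explains just under half of the battery variance.
    """

    n_founders: int = 600
    n_generations: int = 2
    #: distribution over offspring counts per couple
    family_sizes: dict = field(
        default_factory=lambda: {0: 0.10, 1: 0.35, 2: 0.30, 3: 0.15, 4: 0.10}
    )
    n_chromosomes: int = 5
    snps_per_chromosome: int = 1000
    chromosome_length_cm: float = 100.0
    block_length_cm: float = 0.5
    template_pool_size: int = 6
    copy_error_rate: float = 0.01
    maf_range: tuple = (0.05, 0.5)
    uniform_spacing: bool = False
    bp_per_cm: float = 1_000_000.0
    h2_polygenic: float = 0.30
    #: restrict polygenic effects to these chromosomes (None = genome-wide)
    polygenic_chromosomes: tuple | None = None
    c2_family: float = 0.20
    causal_windows: list = field(default_factory=list)
    n_tests: int = 4
    loading_range: tuple = (0.45, 0.65)
    age_range: tuple = (18.0, 90.0)
    beta_age: float = -0.10  # effect per SD of age on each subtest
    beta_sex: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "n_generations", "n_chromosomes",
                     "snps_per_chromosome", "n_tests", "template_pool_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.chromosome_length_cm <= 0:
            raise ValueError("chromosome_length_cm must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        budget = self.h2_polygenic + self.c2_family + sum(
            cw.variance_explained for cw in self.causal_windows
        )
        if budget > 1 + 1e-12:
            raise ValueError(f"variance budget {budget:.3f} exceeds 1")
        if not (0 <= self.h2_polygenic <= 1):
            raise ValueError("h2_polygenic must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per simulation stage."""
        return np.random.default_rng([self.seed, stream])


# deterministic sub-stream labels
_STREAM_MAP, _STREAM_FOUNDERS, _STREAM_PED, _STREAM_TRANSMIT, _STREAM_PHENO = range(5)


def _chrom_labels(config: SimConfig) -> list[str]:
    return [str(c + 1) for c in range(config.n_chromosomes)]


def simulate_genetic_map(config: SimConfig) -> pd.DataFrame:
    """Synthetic genetic map: per chromosome, SNP bp and cM positions.

    cM positions span ``[0, chromosome_length_cm]`` exactly; bp increments
    follow the cM increments at ``bp_per_cm`` with log-normal local rate
    jitter (or uniformly with ``uniform_spacing``).
    """
    rng = config.rng(_STREAM_MAP)
    m = config.snps_per_chromosome
    length = config.chromosome_length_cm
    rows = []
    for chrom in _chrom_labels(config):
        if config.uniform_spacing or m == 1:
            cm = np.linspace(0.0, length, m)
            pos = np.round(1 + cm * config.bp_per_cm).astype(np.int64)
        else:
            gaps = rng.exponential(size=m - 1)
            cm = np.concatenate([[0.0], np.cumsum(gaps)])
            cm *= length / cm[-1]
            bp_gaps = np.maximum(
                1,
                np.round(np.diff(cm) * config.bp_per_cm * rng.lognormal(0, 0.3, m - 1)),
            ).astype(np.int64)
            pos = np.concatenate([[1], 1 + np.cumsum(bp_gaps)])
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "cm": cm}))
    return pd.concat(rows, ignore_index=True)


def simulate_founders(config: SimConfig, genetic_map: pd.DataFrame,
                      n_founders: int | None = None) -> PhasedCohort:
    """Founder haplotypes from per-block ancestral template pools.

    Within each ``block_length_cm`` segment, ``template_pool_size``
    ancestral haplotypes are constructed so that each SNP's template-pool
    frequency approximates a target drawn from ``maf_range`` (at least one
    carrier and one non-carrier template, so no SNP is monomorphic in the
    pool).  Every founder chromosome copies one template per block,
    flipping each allele independently with ``copy_error_rate``.
    """
    rng = config.rng(_STREAM_FOUNDERS)
    n = n_founders if n_founders is not None else config.n_founders
    snps = genetic_map.reset_index(drop=True)  # already in map order
    m = len(snps)
    T = config.template_pool_size
    haplos = np.zeros((2 * n, m), dtype=np.uint8)
    col = 0
    for chrom in dict.fromkeys(snps["chrom"]):
        sub = snps[snps["chrom"] == chrom]
        cm = sub["cm"].to_numpy()
        mc = len(sub)
        block_of = np.floor(cm / config.block_length_cm).astype(int)
        for b in np.unique(block_of):
            j = np.flatnonzero(block_of == b) + col
            mb = len(j)
            target = rng.uniform(*config.maf_range, size=mb)
            carriers = np.clip(np.round(target * T), 1, max(T - 1, 1)).astype(int)
            templates = np.zeros((T, mb), dtype=np.uint8)
            for k in range(mb):
                templates[rng.permutation(T)[: carriers[k]], k] = 1
            choice = rng.integers(0, T, size=2 * n)
            block_haps = templates[choice]
            if config.copy_error_rate > 0:
                flips = rng.random((2 * n, mb)) < config.copy_error_rate
                block_haps = block_haps ^ flips
            haplos[:, j] = block_haps
        col += mc
    snp_table = snps.assign(
        ref="A", alt="G", id=[f"snp{i}" for i in range(m)]
    )[["chrom", "pos", "cm", "ref", "alt", "id"]]
    ids = np.array([f"F{i:05d}" for i in range(n)], dtype=object)
    ped = pd.DataFrame(
        {"iid": ids, "fid": "0", "mid": "0",
         "famid": [f"fam_{i}" for i in range(n)], "generation": 0}
    )
    return PhasedCohort(ids, snp_table, haplos, pedigree=ped)


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Nuclear-family pedigree: ``iid fid mid famid generation``.

    Founders are paired into couples whose offspring counts follow
    ``family_sizes``.  With more than two generations, offspring of the
    previous generation are paired across families (no inbreeding) and
    reproduce again.  Unpaired individuals remain singletons.
    """
    rng = config.rng(_STREAM_PED)
    sizes = np.array(sorted(config.family_sizes))
    probs = np.array([config.family_sizes[s] for s in sizes], dtype=float)
    probs /= probs.sum()

    founders = [f"F{i:05d}" for i in range(config.n_founders)]
    rows = [
        {"iid": iid, "fid": "0", "mid": "0", "famid": f"fam_{i}", "generation": 0}
        for i, iid in enumerate(founders)
    ]
    fam_of = {iid: f"fam_{i}" for i, iid in enumerate(founders)}
    current = list(founders)
    next_id = 0
    fam_counter = config.n_founders
    for gen in range(1, config.n_generations):
        order = rng.permutation(len(current))
        children: list[str] = []
        for c in range(len(current) // 2):
            pa, ma = current[order[2 * c]], current[order[2 * c + 1]]
            if fam_of[pa] == fam_of[ma]:  # avoid sib-sib matings
                continue
            k = int(rng.choice(sizes, p=probs))
            famid = f"fam_{fam_counter}"
            fam_counter += 1
            # the couple joins the household: family environment is shared
            # by parents and offspring alike
            fam_of[pa] = fam_of[ma] = famid
            for r in rows:
                if r["iid"] in (pa, ma):
                    r["famid"] = famid
            for _ in range(k):
                iid = f"I{next_id:06d}"
                next_id += 1
                rows.append({"iid": iid, "fid": pa, "mid": ma,
                             "famid": famid, "generation": gen})
                fam_of[iid] = famid
                children.append(iid)
        current = children
        if not current:
            break
    return pd.DataFrame(rows)


def _meiosis(rng, parent_haps: np.ndarray, cm_by_chrom: list[np.ndarray]) -> np.ndarray:
    """One recombinant gamete from a parent's two haplotypes."""
    gamete = np.empty(parent_haps.shape[1], dtype=np.uint8)
    offset = 0
    for cm in cm_by_chrom:
        mc = len(cm)
        length_morgan = cm[-1] / 100.0
        n_cross = rng.poisson(length_morgan)
        phase0 = rng.integers(0, 2)
        if n_cross == 0:
            phase = np.full(mc, phase0)
        else:
            xpos = np.sort(rng.uniform(0.0, cm[-1], size=n_cross))
            phase = (phase0 + np.searchsorted(xpos, cm, side="right")) % 2
        seg = parent_haps[:, offset:offset + mc]
        gamete[offset:offset + mc] = np.where(phase == 0, seg[0], seg[1])
        offset += mc
    return gamete


def transmit_pedigree(
    founders: PhasedCohort, pedigree: pd.DataFrame, config: SimConfig
) -> PhasedCohort:
    """Gene-drop: recombinant transmission of founder haplotypes.

    Each non-founder receives one recombinant haplotype per parent.
    Truth phase is retained (first haplotype paternal, second maternal).
    """
    rng = config.rng(_STREAM_TRANSMIT)
    snps = founders.snps
    cm_by_chrom = [
        snps.loc[snps["chrom"] == c, "cm"].to_numpy() for c in founders.chromosomes
    ]
    hap_of: dict = {}
    for i, iid in enumerate(founders.sample_ids):
        hap_of[iid] = founders.haplotypes[2 * i:2 * i + 2]
    ped = pedigree.sort_values("generation", kind="stable").reset_index(drop=True)
    for row in ped.itertuples():
        if row.fid == "0":
            if row.iid not in hap_of:
                raise ValueError(f"founder {row.iid} has no simulated genotypes")
            continue
        try:
            pa, ma = hap_of[row.fid], hap_of[row.mid]
        except KeyError as exc:
            raise ValueError(f"missing parent genotypes: {exc.args[0]}") from None
        hap_of[row.iid] = np.stack(
            [_meiosis(rng, pa, cm_by_chrom), _meiosis(rng, ma, cm_by_chrom)]
        )
    ids = ped["iid"].to_numpy(dtype=object)
    haplos = np.concatenate([hap_of[iid] for iid in ids], axis=0)
    return PhasedCohort(ids, snps, haplos, pedigree=ped)


@dataclass
class SimTruth:
    """Ground-truth latent quantities retained for validation."""

    g: np.ndarray
    polygenic: np.ndarray
    family_effect: np.ndarray
    loadings: np.ndarray
    causal_haplotypes: list[HaplotypeAllele]


def _causal_window_obj(cohort: PhasedCohort, cw: CausalWindow) -> Window:
    snps = cohort.snps
    member = (
        (snps["chrom"] == cw.chrom)
        & (snps["cm"] >= cw.cm_start)
        & (snps["cm"] < cw.cm_end)
    )
    idx = snps.index[member].to_numpy()
    if len(idx) == 0:
        raise ValueError(f"causal window {cw} contains no SNPs")
    pos = snps.loc[member, "pos"]
    return Window(
        window_id=f"{cw.chrom}:{cw.cm_start:g}-{cw.cm_end:g}cm",
        chrom=cw.chrom,
        cm_start=cw.cm_start,
        cm_end=cw.cm_end,
        snp_indices=idx,
        bp_start=int(pos.iloc[0]),
        bp_end=int(pos.iloc[-1]),
        size_cm=cw.cm_end - cw.cm_start,
    )


def _scaled(x: np.ndarray, variance: float) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot scale a zero-variance component")
    return (x - x.mean()) / sd * np.sqrt(variance)


def designate_causal_alleles(cohort: PhasedCohort, config: SimConfig) -> list[str]:
    """Pick the causal allele string per causal window: frequency closest
    to 0.2 in ``cohort`` (common enough for a stable standardized dosage),
    ties broken lexicographically."""
    out = []
    for cw in config.causal_windows:
        alleles = enumerate_haplotypes(cohort, _causal_window_obj(cohort, cw))
        chosen = min(alleles, key=lambda a: (abs(a.frequency - 0.2), a.allele_string))
        out.append(chosen.allele_string)
    return out


def simulate_phenotypes(
    cohort: PhasedCohort,
    config: SimConfig,
    stream: int = 0,
    causal_alleles: list[str] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Latent g and the derived cognitive battery with age/sex covariates.

    The designated causal allele of each causal window defaults to the
    cohort's own allele with frequency closest to 0.2; pass
    ``causal_alleles`` (one string per causal window, e.g. designated on
    a shared founder pool) to keep the causal unit identical across
    cohorts.  Components are rescaled to their exact sample variances, so
    configured fractions are realized fractions up to the correlation
    between components.  ``stream`` decorrelates the noise of multiple
    cohorts simulated under one config.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PHENO, stream])
    n = cohort.n_samples
    total_causal = sum(cw.variance_explained for cw in config.causal_windows)
    resid_var = 1.0 - config.h2_polygenic - config.c2_family - total_causal

    g = np.zeros(n)
    polygenic = np.zeros(n)
    if config.h2_polygenic > 0:
        freqs = cohort.allele_frequencies()
        poly_ok = (freqs > 0) & (freqs < 1)
        if config.polygenic_chromosomes is not None:
            on_causal = cohort.snps["chrom"].isin(config.polygenic_chromosomes)
            poly_ok &= on_causal.to_numpy()
        dos = cohort.dosages(np.flatnonzero(poly_ok)).astype(float)
        p = freqs[poly_ok]
        dos = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
        effects = rng.normal(size=dos.shape[1])
        polygenic = _scaled(dos @ effects, config.h2_polygenic)
        g += polygenic

    causal_haps: list[HaplotypeAllele] = []
    for k, cw in enumerate(config.causal_windows):
        window = _causal_window_obj(cohort, cw)
        alleles = enumerate_haplotypes(cohort, window)
        if causal_alleles is None:
            designated = min(
                alleles, key=lambda a: (abs(a.frequency - 0.2), a.allele_string)
            )
        else:
            matches = [a for a in alleles if a.allele_string == causal_alleles[k]]
            if not matches or matches[0].dosage.std() == 0:
                continue  # designated allele absent here: no contribution
            designated = matches[0]
        causal_haps.append(designated)
        g += _scaled(designated.dosage.astype(float), cw.variance_explained)

    family_effect = np.zeros(n)
    if config.c2_family > 0:
        if cohort.pedigree is None:
            famid = pd.Series(np.arange(n))
        else:
            ped = cohort.pedigree.set_index("iid")
            famid = pd.Series([ped.loc[i, "famid"] for i in cohort.sample_ids])
        codes = famid.astype("category").cat.codes.to_numpy()
        per_family = rng.normal(size=codes.max() + 1)
        family_effect = _scaled(per_family[codes], config.c2_family)
        g += family_effect

    if resid_var > 0:
        g += _scaled(rng.normal(size=n), resid_var)
    g = (g - g.mean()) / g.std()

    age = rng.uniform(*config.age_range, size=n)
    age_z = (age - age.mean()) / age.std()
    sex = rng.integers(0, 2, size=n)
    loadings = rng.uniform(*config.loading_range, size=config.n_tests)
    pheno = pd.DataFrame({"iid": cohort.sample_ids, "sex": sex, "age": np.round(age, 1)})
    for j, lam in enumerate(loadings):
        noise = rng.normal(size=n) * np.sqrt(max(1 - lam**2, 0))
        pheno[f"test{j + 1}"] = (
            lam * g + config.beta_sex * (sex - 0.5) + config.beta_age * age_z + noise
        )
    truth = SimTruth(
        g=g, polygenic=polygenic, family_effect=family_effect,
        loadings=loadings, causal_haplotypes=causal_haps,
    )
    return pheno, truth


def simulate_cohort(config: SimConfig) -> tuple[PhasedCohort, pd.DataFrame, SimTruth]:
    """Full pipeline: map -> founders -> pedigree -> gene drop -> phenotypes."""
    gmap = simulate_genetic_map(config)
    pedigree = simulate_pedigree(config)
    n_founders = int((pedigree["fid"] == "0").sum())
    founders = simulate_founders(config, gmap, n_founders=n_founders)
    cohort = transmit_pedigree(founders, pedigree, config)
    pheno, truth = simulate_phenotypes(cohort, config)
    return cohort, pheno, truth


def simulate_unrelated(config: SimConfig, n: int) -> tuple[PhasedCohort, pd.DataFrame, SimTruth]:
    """Convenience: ``n`` unrelated individuals (founders only) + phenotypes."""
    gmap = simulate_genetic_map(config)
    cohort = simulate_founders(config, gmap, n_founders=n)
    pheno, truth = simulate_phenotypes(cohort, config)
    return cohort, pheno, truth


def simulate_study(
    config: SimConfig, n_replication: tuple = ()
) -> list[tuple[PhasedCohort, pd.DataFrame, SimTruth]]:
    """A discovery cohort plus unrelated replication cohorts on one map.

    All cohorts are drawn from one founder pool (so haplotype alleles are
    shared across cohorts and keyed by identical allele strings) and the
    causal alleles are designated once on that pool.  The first returned
    cohort is the family-structured discovery cohort; the others are
    unrelated cohorts of the sizes in ``n_replication``.
    """
    gmap = simulate_genetic_map(config)
    pedigree = simulate_pedigree(config)
    n_disc_founders = int((pedigree["fid"] == "0").sum())
    total = n_disc_founders + sum(n_replication)
    pool = simulate_founders(config, gmap, n_founders=total)
    causal_alleles = designate_causal_alleles(pool, config)

    out = []
    disc_founders = pool.take_samples(np.arange(n_disc_founders))
    discovery = transmit_pedigree(disc_founders, pedigree, config)
    out.append(
        (discovery,) + simulate_phenotypes(
            discovery, config, stream=0, causal_alleles=causal_alleles
        )
    )
    offset = n_disc_founders
    for k, n in enumerate(n_replication, start=1):
        rep = pool.take_samples(np.arange(offset, offset + n))
        # replication individuals are founders: rename for clarity
        rep.sample_ids = np.array([f"R{k}_{i:05d}" for i in range(n)], object)
        rep.pedigree = pd.DataFrame(
            {"iid": rep.sample_ids, "fid": "0", "mid": "0",
             "famid": [f"rep{k}_fam{i}" for i in range(n)], "generation": 0}
        )
        out.append(
            (rep,) + simulate_phenotypes(
                rep, config, stream=k, causal_alleles=causal_alleles
            )
        )
        offset += n
    return out
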