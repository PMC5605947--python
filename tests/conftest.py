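import numpy as np
import pandas as pd
import pytest

from haploscan import PhasedCohort, SimConfig, simulate_cohort


def make_cohort(haplotypes, cm=None, chrom="1", pos=None):
    """Hand-built cohort from a (2n, m) 0/1 array."""
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    m = haplotypes.shape[1]
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if cm is None:
        cm = np.linspace(0.0, 1.0, m)
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "cm": cm, "ref": "A", "alt": "G",
         "id": [f"s{i}" for i in range(m)]}
    )
    n = haplotypes.shape[0] // 2
    return PhasedCohort(np.array([f"i{k}" for k in range(n)], object), snps, haplotypes)


@pytest.fixture(scope="session")
def family_sim():
    """A small family-structured cohort with one causal haplotype window."""
    from haploscan import CausalWindow

    cfg = SimConfig(
        n_founders=240,
        n_chromosomes=2,
        snps_per_chromosome=300,
        chromosome_length_cm=30.0,
        h2_polygenic=0.3,
        c2_family=0.2,
        causal_windows=[CausalWindow("1", 10.0, 11.0, 0.02)],
        seed=11,
    )
    cohort, pheno, truth = simulate_cohort(cfg)
    return cfg, cohort, pheno, truth
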