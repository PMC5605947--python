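"""Simulator: genetic map, founder LD blocks, gene drop, trait architecture."""

import numpy as np
import pandas as pd
import pytest

from haploscan import (
    CausalWindow,
    SimConfig,
    build_windows,
    compute_grm,
    enumerate_haplotypes,
    simulate_cohort,
    simulate_founders,
    simulate_genetic_map,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_unrelated,
    transmit_pedigree,
)


class TestGeneticMap:
    def test_uniform_spacing_forced(self):
        cfg = SimConfig(n_chromosomes=1, snps_per_chromosome=5,
                        chromosome_length_cm=1.0, uniform_spacing=True, seed=0)
        gmap = simulate_genetic_map(cfg)
        np.testing.assert_allclose(gmap["cm"], [0, 0.25, 0.5, 0.75, 1.0])

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_chromosomes=2, snps_per_chromosome=50, seed=42)
        pd.testing.assert_frame_equal(simulate_genetic_map(cfg),
                                      simulate_genetic_map(cfg))

    def test_map_invariants(self):
        cfg = SimConfig(n_chromosomes=3, snps_per_chromosome=200,
                        chromosome_length_cm=50, seed=1)
        gmap = simulate_genetic_map(cfg)
        for chrom, sub in gmap.groupby("chrom"):
            assert (np.diff(sub["pos"]) > 0).all()
            assert (np.diff(sub["cm"]) >= 0).all()
            assert sub["cm"].iloc[0] == 0.0
            assert sub["cm"].iloc[-1] == pytest.approx(50.0)

    def test_mean_window_occupancy_tracks_density(self):
        # 10,000 SNPs over 100 cM: about 100 SNPs per 1 cM window
        cfg = SimConfig(n_chromosomes=1, snps_per_chromosome=10_000,
                        chromosome_length_cm=100, seed=2)
        gmap = simulate_genetic_map(cfg)
        cm = gmap["cm"].to_numpy()
        counts = [
            ((cm >= s) & (cm < s + 1.0)).sum() for s in range(0, 99)
        ]
        assert np.mean(counts) == pytest.approx(100, rel=0.05)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(snps_per_chromosome=0)
        with pytest.raises(ValueError):
            SimConfig(chromosome_length_cm=-1)


class TestFounders:
    def test_degenerate_pool_single_template(self):
        cfg = SimConfig(n_founders=30, n_chromosomes=1, snps_per_chromosome=40,
                        chromosome_length_cm=2.0, block_length_cm=2.0,
                        template_pool_size=1, copy_error_rate=0.0, seed=3)
        gmap = simulate_genetic_map(cfg)
        founders = simulate_founders(cfg, gmap)
        (window,) = build_windows(founders.snps, 2.0)
        alleles = enumerate_haplotypes(founders, window)
        assert len(alleles) == 1
        assert alleles[0].frequency == 1.0

    def test_pool_bounds_distinct_alleles(self):
        cfg = SimConfig(n_founders=100, n_chromosomes=1, snps_per_chromosome=30,
                        chromosome_length_cm=1.0, block_length_cm=2.0,
                        template_pool_size=4, copy_error_rate=0.0, seed=4)
        founders = simulate_founders(cfg, simulate_genetic_map(cfg))
        (window,) = build_windows(founders.snps, 1.0)
        assert len(enumerate_haplotypes(founders, window)) <= 4

    def test_realized_maf_within_configured_range(self):
        cfg = SimConfig(n_founders=400, n_chromosomes=1, snps_per_chromosome=200,
                        chromosome_length_cm=20, maf_range=(0.1, 0.5),
                        copy_error_rate=0.0, seed=5)
        founders = simulate_founders(cfg, simulate_genetic_map(cfg))
        freq = founders.allele_frequencies()
        maf = np.minimum(freq, 1 - freq)
        # binomial sampling tolerance at 2n = 800 chromosomes around the
        # template-pool frequency grid (coarsest point 1/6 > 0.1)
        tol = 4 * np.sqrt(0.5 * 0.5 / 800)
        assert maf.min() >= min(0.1, 1 / cfg.template_pool_size) - tol
        assert maf.max() <= 0.5

    def test_deterministic(self):
        cfg = SimConfig(n_founders=20, n_chromosomes=1, snps_per_chromosome=50, seed=6)
        gmap = simulate_genetic_map(cfg)
        f1 = simulate_founders(cfg, gmap)
        f2 = simulate_founders(cfg, gmap)
        np.testing.assert_array_equal(f1.haplotypes, f2.haplotypes)


class TestTransmission:
    def test_zero_morgan_chromosome_copies_parent_exactly(self):
        cfg = SimConfig(n_founders=4, n_chromosomes=1, snps_per_chromosome=30,
                        chromosome_length_cm=1e-9, seed=7,
                        family_sizes={2: 1.0})
        gmap = simulate_genetic_map(cfg)
        ped = simulate_pedigree(cfg)
        founders = simulate_founders(cfg, gmap)
        cohort = transmit_pedigree(founders, ped, cfg)
        idx = {s: i for i, s in enumerate(cohort.sample_ids)}
        for row in ped.itertuples():
            if row.fid == "0":
                continue
            child = cohort.haplotypes[2 * idx[row.iid]]
            father = cohort.haplotypes[2 * idx[row.fid]:2 * idx[row.fid] + 2]
            assert any(np.array_equal(child, h) for h in father)

    def test_missing_parent_errors(self):
        cfg = SimConfig(n_founders=4, n_chromosomes=1, snps_per_chromosome=10, seed=8)
        gmap = simulate_genetic_map(cfg)
        founders = simulate_founders(cfg, gmap)
        ped = pd.DataFrame(
            [{"iid": "kid", "fid": "ghost", "mid": "F00000", "famid": "x",
              "generation": 1}]
        )
        ped = pd.concat([founders.pedigree, ped], ignore_index=True)
        with pytest.raises(ValueError, match="missing parent"):
            transmit_pedigree(founders, ped, cfg)

    def test_full_sibs_share_expected_relatedness(self, family_sim):
        cfg, cohort, pheno, truth = family_sim
        ped = cohort.pedigree
        sib_groups = ped[ped["fid"] != "0"].groupby(["fid", "mid"])["iid"].apply(list)
        g = compute_grm(cohort.dosages()).matrix
        idx = {s: i for i, s in enumerate(cohort.sample_ids)}
        vals = []
        for sibs in sib_groups:
            for a in range(len(sibs)):
                for b in range(a + 1, len(sibs)):
                    vals.append(g[idx[sibs[a]], idx[sibs[b]]])
        assert len(vals) > 30
        assert np.mean(vals) == pytest.approx(0.5, abs=0.06)

    def test_sib_ibd_proportions_near_1_2_1(self):
        """Full sibs share 0/1/2 parental haplotypes per locus ~ 1:2:1."""
        cfg = SimConfig(n_founders=40, n_chromosomes=4, snps_per_chromosome=250,
                        chromosome_length_cm=100, family_sizes={2: 1.0}, seed=9)
        gmap = simulate_genetic_map(cfg)
        ped = simulate_pedigree(cfg)
        founders = simulate_founders(cfg, gmap)
        # label founder haplotypes uniquely so IBD can be read off directly
        n_snps = founders.n_snps
        founders.haplotypes = np.tile(
            np.arange(2 * founders.n_samples, dtype=np.uint8)[:, None], (1, n_snps)
        )
        cohort = transmit_pedigree(founders, ped, cfg)
        idx = {s: i for i, s in enumerate(cohort.sample_ids)}
        tallies = np.zeros(3)
        for (_, _), sibs in ped[ped["fid"] != "0"].groupby(["fid", "mid"])["iid"]:
            sibs = list(sibs)
            for a in range(len(sibs)):
                for b in range(a + 1, len(sibs)):
                    h1 = cohort.haplotypes[2 * idx[sibs[a]]:2 * idx[sibs[a]] + 2]
                    h2 = cohort.haplotypes[2 * idx[sibs[b]]:2 * idx[sibs[b]] + 2]
                    shared = (h1[0] == h2[0]).astype(int) + (h1[1] == h2[1]).astype(int)
                    tallies += np.bincount(shared, minlength=3)
        props = tallies / tallies.sum()
        assert props[1] == pytest.approx(0.5, abs=0.06)
        assert props[0] == pytest.approx(0.25, abs=0.05)
        assert props[2] == pytest.approx(0.25, abs=0.05)


class TestPhenotypes:
    def test_variance_budget_validated(self):
        with pytest.raises(ValueError, match="budget"):
            SimConfig(h2_polygenic=0.7, c2_family=0.2,
                      causal_windows=[CausalWindow("1", 0, 1, 0.2)])

    def test_variance_accounting(self):
        cfg = SimConfig(n_chromosomes=2, snps_per_chromosome=200,
                        chromosome_length_cm=20, h2_polygenic=0.4,
                        c2_family=0.0, seed=10)
        cohort, pheno, truth = simulate_unrelated(cfg, 3000)
        assert np.var(truth.g) == pytest.approx(1.0)
        assert np.var(truth.polygenic) == pytest.approx(0.4, abs=0.02)

    def test_causal_window_contributes_variance(self):
        cfg = SimConfig(n_chromosomes=2, snps_per_chromosome=200,
                        chromosome_length_cm=20, h2_polygenic=0.0, c2_family=0.0,
                        causal_windows=[CausalWindow("1", 5.0, 6.0, 0.05)],
                        seed=11)
        cohort, pheno, truth = simulate_unrelated(cfg, 1000)
        (hap,) = truth.causal_haplotypes
        d = hap.dosage.astype(float)
        r2 = np.corrcoef(d, truth.g)[0, 1] ** 2
        assert r2 == pytest.approx(0.05, abs=0.02)

    def test_battery_loads_on_g(self):
        cfg = SimConfig(n_chromosomes=1, snps_per_chromosome=100, seed=12)
        cohort, pheno, truth = simulate_unrelated(cfg, 800)
        for j, lam in enumerate(truth.loadings):
            r = np.corrcoef(pheno[f"test{j+1}"], truth.g)[0, 1]
            assert r == pytest.approx(lam, abs=0.08)

    def test_end_to_end_determinism(self):
        cfg = SimConfig(n_founders=40, n_chromosomes=2, snps_per_chromosome=60,
                        chromosome_length_cm=10, seed=13)
        c1, p1, t1 = simulate_cohort(cfg)
        c2, p2, t2 = simulate_cohort(cfg)
        np.testing.assert_array_equal(c1.haplotypes, c2.haplotypes)
        pd.testing.assert_frame_equal(p1, p2)
        np.testing.assert_array_equal(t1.g, t2.g)
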