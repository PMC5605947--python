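"""Genetic-map interpolation, window construction and haplotype enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploscan import (
    GeneticMapIndex,
    build_windows,
    enumerate_haplotypes,
    haplotype_qc,
    region_overlap,
)
from haploscan.windows import window_registry

from conftest import make_cohort


class TestInterpolation:
    def setup_method(self):
        self.gmap = GeneticMapIndex(
            pd.DataFrame({"chrom": "1", "pos": [1000, 2000, 4000], "cm": [0.0, 1.0, 1.5]})
        )

    def test_anchor_identity(self):
        assert self.gmap.interpolate("1", [1000, 2000, 4000]) == pytest.approx(
            [0.0, 1.0, 1.5]
        )

    def test_midpoint(self):
        assert self.gmap.interpolate("1", [1500])[0] == pytest.approx(0.5)

    def test_extrapolation_at_terminal_rate(self):
        # below: rate 1 cM / 1000 bp; above: rate 0.5 cM / 2000 bp
        assert self.gmap.interpolate("1", [500])[0] == pytest.approx(-0.5)
        assert self.gmap.interpolate("1", [6000])[0] == pytest.approx(2.0)

    def test_matches_piecewise_rate_integration_oracle(self):
        # oracle: integrate the per-interval recombination rate from the
        # first anchor to the query position
        bp = np.array([1000, 2000, 4000])
        cm = np.array([0.0, 1.0, 1.5])
        rng = np.random.default_rng(0)
        queries = rng.integers(1000, 4000, size=50)

        def oracle(q):
            total, prev_bp, prev_cm = 0.0, bp[0], cm[0]
            for b, c in zip(bp[1:], cm[1:]):
                rate = (c - prev_cm) / (b - prev_bp)
                total += rate * (min(q, b) - prev_bp)
                if q <= b:
                    break
                prev_bp, prev_cm = b, c
            return total

        expected = [oracle(q) for q in queries]
        np.testing.assert_allclose(
            self.gmap.interpolate("1", queries), expected, atol=1e-12
        )

    def test_missing_chromosome_errors(self):
        with pytest.raises(KeyError):
            self.gmap.interpolate("2", [1500])


def _snp_table(cm, chrom="1"):
    cm = np.asarray(cm, dtype=float)
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, len(cm) + 1) * 1000, "cm": cm,
         "ref": "A", "alt": "G"}
    )


class TestBuildWindows:
    def test_ten_cm_chromosome_has_37_one_cm_windows(self):
        # starts 0, 0.25, ..., 9.0 -> floor((10-1)/0.25)+1 = 37
        snps = _snp_table(np.linspace(0, 10, 101))
        ws = build_windows(snps, 1.0)
        assert len(ws) == 37
        assert ws[0].cm_start == 0.0
        assert ws[-1].cm_start == pytest.approx(9.0)

    def test_chromosome_shorter_than_window(self):
        snps = _snp_table([0.0, 0.2, 0.4])
        ws = build_windows(snps, 1.0)
        assert len(ws) == 1
        assert ws[0].n_snps == 3

    def test_half_open_membership_except_final(self):
        # SNP at exactly 1.0 cM is excluded from [0, 1) but included in
        # windows starting at 0.25..1.0
        snps = _snp_table([0.0, 0.5, 1.0, 1.5, 2.0])
        ws = build_windows(snps, 1.0)
        first = ws[0]
        assert first.cm_start == 0.0
        assert 2 not in first.snp_indices  # cm == 1.0 excluded
        covering = [w for w in ws if w.cm_start <= 1.0 <= w.cm_end and 2 in w.snp_indices]
        assert covering, "boundary SNP must be covered by a later window"
        final = ws[-1]
        assert 4 in final.snp_indices  # closed terminal window keeps cm == 2.0

    def test_terminal_residual_window_appended(self):
        # length 2.3 cM: grid start max = 1.25, ends at 2.25 < 2.3, so a
        # terminal window [1.3, 2.3] must cover the last SNP
        snps = _snp_table([0.0, 1.0, 2.29, 2.3])
        ws = build_windows(snps, 1.0)
        assert ws[-1].cm_end == pytest.approx(2.3)
        assert 3 in ws[-1].snp_indices

    def test_empty_windows_discarded(self):
        snps = _snp_table([0.0, 0.1, 9.9, 10.0])
        ws = build_windows(snps, 1.0)
        assert all(w.n_snps >= 1 for w in ws)

    def test_registry_reports_outermost_snp_span(self):
        snps = _snp_table([0.0, 0.5, 0.9])
        reg = window_registry(build_windows(snps, 1.0))
        assert reg.loc[0, "bp_start"] == 1000
        assert reg.loc[0, "bp_end"] == 3000


class TestEnumeration:
    def test_hand_example(self):
        # chromosome strings 01, 01, 11, 01 -> {01: 0.75, 11: 0.25}
        cohort = make_cohort([[0, 1], [0, 1], [1, 1], [0, 1]])
        (window,) = build_windows(cohort.snps, 2.0)
        alleles = {a.allele_string: a for a in enumerate_haplotypes(cohort, window)}
        assert set(alleles) == {"01", "11"}
        assert alleles["01"].frequency == pytest.approx(0.75)
        assert alleles["11"].frequency == pytest.approx(0.25)
        np.testing.assert_array_equal(alleles["01"].dosage, [2, 1])
        np.testing.assert_array_equal(alleles["11"].dosage, [0, 1])

    def test_monomorphic_window(self):
        cohort = make_cohort([[1, 0], [1, 0], [1, 0], [1, 0]])
        (window,) = build_windows(cohort.snps, 2.0)
        (allele,) = enumerate_haplotypes(cohort, window)
        assert allele.frequency == 1.0
        assert np.all(allele.dosage == 2)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 12), st.integers(1, 6))
    def test_matches_brute_force_string_tally(self, seed, n, m):
        """Enumeration equals a dict-of-strings tally on random cohorts."""
        rng = np.random.default_rng(seed)
        h = rng.integers(0, 2, size=(2 * n, m))
        cohort = make_cohort(h, cm=np.linspace(0, 0.5, m))
        (window,) = build_windows(cohort.snps, 1.0)
        alleles = enumerate_haplotypes(cohort, window)
        # oracle: plain python string tally
        strings = ["".join(map(str, row)) for row in h]
        from collections import Counter

        counts = Counter(strings)
        assert {a.allele_string: a.frequency for a in alleles} == {
            s: c / (2 * n) for s, c in counts.items()
        }
        for a in alleles:
            expected = [
                (strings[2 * i] == a.allele_string) + (strings[2 * i + 1] == a.allele_string)
                for i in range(n)
            ]
            np.testing.assert_array_equal(a.dosage, expected)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_conservation(self, seed):
        """Frequencies sum to 1 and per-individual dosages sum to 2."""
        rng = np.random.default_rng(seed)
        h = rng.integers(0, 2, size=(20, 8))
        cohort = make_cohort(h)
        (window,) = build_windows(cohort.snps, 2.0)
        alleles = enumerate_haplotypes(cohort, window)
        assert sum(a.frequency for a in alleles) == pytest.approx(1.0)
        total = np.sum([a.dosage for a in alleles], axis=0)
        assert np.all(total == 2)


class TestHaplotypeQC:
    def test_small_window_contributes_nothing(self):
        rng = np.random.default_rng(1)
        cohort = make_cohort(rng.integers(0, 2, size=(40, 4)))
        (window,) = build_windows(cohort.snps, 2.0)
        alleles = haplotype_qc(enumerate_haplotypes(cohort, window), min_snps=5)
        assert all(not a.assessed for a in alleles)
        assert all(a.qc_reason == "window_snps" for a in alleles)

    def test_rare_allele_excluded_but_kept_in_denominator(self):
        # 300 chromosomes: 299 copies of one string, 1 of another
        h = np.zeros((300, 5), dtype=np.uint8)
        h[0] = 1
        cohort = make_cohort(h)
        (window,) = build_windows(cohort.snps, 2.0)
        alleles = haplotype_qc(enumerate_haplotypes(cohort, window), min_freq=0.005)
        by_string = {a.allele_string: a for a in alleles}
        rare = by_string["11111"]
        assert not rare.assessed and rare.qc_reason == "freq"
        common = by_string["00000"]
        assert common.assessed
        assert common.frequency == pytest.approx(299 / 300)

    def test_hwe_exact_proportions_kept(self):
        # diplotype counts (49, 42, 9) at allele frequency 0.3: expected
        # counts are exactly (49, 42, 9), chi-square 0, so the allele stays
        dosage_counts = [(0, 49), (1, 42), (2, 9)]
        haps = []
        for d, k in dosage_counts:
            for _ in range(k):
                if d == 0:
                    haps.extend([[0] * 5, [0] * 5])
                elif d == 1:
                    haps.extend([[1] * 5, [0] * 5])
                else:
                    haps.extend([[1] * 5, [1] * 5])
        cohort = make_cohort(np.array(haps))
        (window,) = build_windows(cohort.snps, 2.0)
        alleles = haplotype_qc(enumerate_haplotypes(cohort, window))
        target = {a.allele_string: a for a in alleles}["11111"]
        assert target.frequency == pytest.approx(0.3)
        assert target.assessed


class TestRegionOverlap:
    def _haps(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.integers(0, 2, size=(10, 6)),
                             pos=[100, 120, 150, 180, 199, 200])
        (window,) = build_windows(cohort.snps, 2.0)
        return enumerate_haplotypes(cohort, window)

    def test_closed_interval_intersection(self):
        haps = self._haps()  # span [100, 200]
        regions = pd.DataFrame({"chrom": ["1"], "start": [150], "end": [300]})
        assert region_overlap(haps, regions) == haps

    def test_adjacent_region_does_not_overlap(self):
        haps = self._haps()
        regions = pd.DataFrame({"chrom": ["1"], "start": [201], "end": [300]})
        assert region_overlap(haps, regions) == []

    def test_malformed_region_errors(self):
        with pytest.raises(ValueError):
            region_overlap(self._haps(), pd.DataFrame(
                {"chrom": ["1"], "start": [300], "end": [200]}
            ))

    def test_hand_enumerated_fixture(self):
        haps = self._haps()
        other = make_cohort(np.zeros((4, 2), np.uint8), chrom="2", pos=[500, 900])
        (w2,) = build_windows(other.snps, 2.0)
        haps2 = enumerate_haplotypes(other, w2)
        regions = pd.DataFrame(
            {"chrom": ["1", "2"], "start": [90, 1000], "end": [99, 2000]}
        )
        assert region_overlap(haps + haps2, regions) == []
        regions2 = pd.DataFrame(
            {"chrom": ["1", "2"], "start": [200, 850], "end": [210, 950]}
        )
        assert region_overlap(haps + haps2, regions2) == haps + haps2
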