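"""Tests for the synthetic-data generators."""

import numpy as np
import pytest

from cdhtest.core import InputError, PhenotypeVector
from cdhtest.simulate import (
    FeasibilityError,
    HaplotypeModel,
    RegionModel,
    SimConfig,
    chip_maf_sampler,
    haplotypes_for_target_r2,
    max_r2,
    power_table,
    product_haplotypes,
    recessive_set_exposure,
    simulate_hwe_pair,
    simulate_linked_quartet,
    simulate_phenotype_ch,
    simulate_region,
    simulate_two_locus,
    uniform_maf_sampler,
)


def _sample_r2(g1, g2):
    a = g1.values.astype(float)
    b = g2.values.astype(float)
    return float(np.corrcoef(a, b)[0, 1] ** 2)


class TestHwePair:
    def test_maf_within_three_se(self):
        rng = np.random.default_rng(5)
        n = 100_000
        g1, g2 = simulate_hwe_pair(0.05, 0.05, n, rng)
        se = np.sqrt(0.05 * 0.95 / (2 * n))
        assert abs(g1.maf - 0.05) < 3 * se
        assert abs(g2.maf - 0.05) < 3 * se

    def test_independence(self):
        rng = np.random.default_rng(6)
        g1, g2 = simulate_hwe_pair(0.2, 0.2, 100_000, rng)
        assert _sample_r2(g1, g2) < 0.001

    def test_seed_replay_bitwise(self):
        a = simulate_hwe_pair(0.03, 0.04, 500, np.random.default_rng(9))
        b = simulate_hwe_pair(0.03, 0.04, 500, np.random.default_rng(9))
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_invalid_maf(self):
        with pytest.raises(InputError):
            simulate_hwe_pair(0.0, 0.05, 10, np.random.default_rng(0))


class TestTargetR2:
    def test_zero_target_gives_product_freqs(self):
        hm = haplotypes_for_target_r2(0.03, 0.2, 0.0)
        assert np.allclose(hm.freqs, product_haplotypes(0.03, 0.2).freqs)
        assert hm.r2 == pytest.approx(0.0, abs=1e-15)

    def test_round_trip_r2(self):
        hm = haplotypes_for_target_r2(0.03, 0.2, 0.1)
        assert hm.r2 == pytest.approx(0.1, abs=1e-9)
        assert hm.d > 0

    def test_perfect_coupling_equal_mafs(self):
        hm = haplotypes_for_target_r2(0.1, 0.1, 1.0)
        rng = np.random.default_rng(3)
        g1, g2 = simulate_two_locus(hm, 2000, rng)
        assert np.array_equal(g1.values, g2.values)
        assert hm.dprime == pytest.approx(1.0)

    def test_infeasible_r2_reports_bound(self):
        with pytest.raises(FeasibilityError) as exc:
            haplotypes_for_target_r2(0.01, 0.4, 0.5)
        assert exc.value.r2_max == pytest.approx(max_r2(0.01, 0.4))
        assert exc.value.r2_max < 0.5


class TestLinkedQuartet:
    def test_empirical_r2_matches_model(self):
        rng = np.random.default_rng(11)
        hm1 = haplotypes_for_target_r2(0.03, 0.2, 0.1)
        hm2 = haplotypes_for_target_r2(0.05, 0.1, 0.3)
        n = 100_000
        s1, s3, s2, s4 = simulate_linked_quartet(hm1, hm2, n, rng)
        # binomial-ish SE for the sample r^2 at this n is ~0.004
        assert _sample_r2(s1, s3) == pytest.approx(hm1.r2, abs=0.015)
        assert _sample_r2(s2, s4) == pytest.approx(hm2.r2, abs=0.015)
        assert _sample_r2(s1, s2) < 0.001  # cross-pair independence

    def test_maximal_coupling_restricts_cooccurrence(self):
        # at the feasibility bound the causal allele only rides tag haplotypes
        hm = haplotypes_for_target_r2(0.05, 0.2, max_r2(0.05, 0.2))
        assert hm.freqs[2] == pytest.approx(0.0, abs=1e-12)


class TestPhenotype:
    def test_null_case_fraction(self):
        rng = np.random.default_rng(21)
        g1, g2 = simulate_hwe_pair(0.03, 0.03, 50_000, rng)
        y = simulate_phenotype_ch(g1, g2, 0.05, 1.0, rng=rng)
        assert np.mean(y.values == 1) == pytest.approx(0.05, abs=0.005)

    def test_ch_cell_penetrance(self):
        rng = np.random.default_rng(22)
        n = 400_000
        g1, g2 = simulate_hwe_pair(0.03, 0.03, n, rng)
        y = simulate_phenotype_ch(g1, g2, 0.05, 5.0, rng=rng)
        ch = (g1.values == 1) & (g2.values == 1)
        assert ch.sum() > 500
        assert np.mean(y.values[ch] == 1) == pytest.approx(0.25, abs=0.05)

    def test_seed_replay(self):
        rng = np.random.default_rng(23)
        g1, g2 = simulate_hwe_pair(0.03, 0.03, 1000, rng)
        y1 = simulate_phenotype_ch(g1, g2, 0.05, 2.0, rng=np.random.default_rng(4))
        y2 = simulate_phenotype_ch(g1, g2, 0.05, 2.0, rng=np.random.default_rng(4))
        assert np.array_equal(y1.values, y2.values)

    def test_bound_violation(self):
        rng = np.random.default_rng(24)
        g1, g2 = simulate_hwe_pair(0.03, 0.03, 100, rng)
        with pytest.raises(InputError):
            simulate_phenotype_ch(g1, g2, 0.3, 5.0, rng=rng)


def test_power_table_threshold_nesting():
    cfg = SimConfig(n_individuals=3000, n_reps=30, rng_seed=17)
    df = power_table(cfg, [4.0])
    sub = df[df.test == "cdh"].sort_values("threshold")
    vals = sub.percent.to_numpy()
    assert (np.diff(vals) >= 0).all()  # power weakly increasing with looser threshold
    assert set(df.test) == {"snp1_trend", "snp2_trend", "cdh"}


def test_power_table_reproducible():
    cfg = SimConfig(n_individuals=1000, n_reps=10, rng_seed=3)
    a = power_table(cfg, [2.0])
    b = power_table(cfg, [2.0])
    assert a.equals(b)


class TestRegion:
    def test_exposure_closed_form_two_causal(self):
        """Exposed fraction ~= 6 q^2 (1-q)^2 for two independent causal SNPs."""
        rng = np.random.default_rng(31)
        q, n = 0.03, 400_000
        g1, g2 = simulate_hwe_pair(q, q, n, rng)
        gc = np.column_stack([g1.values, g2.values])
        frac = recessive_set_exposure(gc).mean()
        expect = 6 * q**2 * (1 - q) ** 2
        assert frac == pytest.approx(expect, rel=0.1)

    def test_phase_aware_exposure_subset_of_genotype_level(self):
        rng = np.random.default_rng(37)
        rm = RegionModel(m=20, portion_causal=0.3, phase_aware=True)
        region = simulate_region(rm, 3000, rng)
        gc = region.genotypes[:, region.causal_mask]
        hap_a, hap_b = region.haplotypes
        ha = hap_a[:, region.causal_mask]
        hb = hap_b[:, region.causal_mask]
        phased = recessive_set_exposure(gc, (ha, hb))
        unphased = recessive_set_exposure(gc)
        assert (phased <= unphased).all()

    def test_null_region_phenotype_independent(self):
        rng = np.random.default_rng(32)
        rm = RegionModel(m=20, portion_causal=0.0, grr=1.0)
        region = simulate_region(rm, 2000, rng)
        assert not region.causal_mask.any()
        assert np.mean(region.phenotype.values == 1) == pytest.approx(0.05, abs=0.02)

    def test_causal_flags_only_on_rare_snps(self):
        rng = np.random.default_rng(33)
        region = simulate_region(RegionModel(portion_causal=0.09), 500, rng)
        assert region.causal_mask.any()
        assert (region.pool_maf[region.causal_mask] < 0.05).all()

    def test_genotypes_match_haplotype_sums(self):
        rng = np.random.default_rng(34)
        region = simulate_region(RegionModel(m=10, phase_aware=True), 300, rng)
        hap_a, hap_b = region.haplotypes
        assert np.array_equal(region.genotypes, hap_a + hap_b)

    def test_no_rare_snp_raises(self):
        rng = np.random.default_rng(35)
        rm = RegionModel(
            m=5,
            portion_causal=0.5,
            maf_sampler=lambda r: 0.4,  # only common SNPs
            n_founders=4,
        )
        with pytest.raises(InputError):
            simulate_region(rm, 100, rng)

    def test_intra_region_ld_exists(self):
        """Founder-pool assembly should induce nontrivial LD between SNPs."""
        rng = np.random.default_rng(36)
        region = simulate_region(RegionModel(portion_causal=0.0), 4000, rng)
        G = region.genotypes.astype(float)
        poly = G.std(axis=0) > 0
        r2 = np.corrcoef(G[:, poly].T) ** 2
        iu = np.triu_indices_from(r2, k=1)
        assert np.quantile(r2[iu], 0.9) > 0.1


def test_maf_samplers_ranges():
    rng = np.random.default_rng(41)
    u = uniform_maf_sampler()
    c = chip_maf_sampler()
    us = [u(rng) for _ in range(200)]
    cs = [c(rng) for _ in range(500)]
    assert all(0.01 <= q <= 0.05 for q in us)
    assert all(0.01 <= q <= 0.5 for q in cs)
    assert 0.2 < np.mean([q < 0.05 for q in cs]) < 0.7
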