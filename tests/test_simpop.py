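"""Simulator contracts: drift LD, divergence, trait architecture, families, DRP."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from jointgp import ld, simpop
from jointgp.simpop import SimConfig


def small_config(**kw) -> SimConfig:
    base = dict(
        n_chromosomes=1, n_markers_per_chrom=120, effective_size_ne=40,
        n_burnin_generations=30, n_divergence_generations=5, split_sizes=(20, 20),
        n_qtl=30, seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(effective_size_ne=1),
            dict(n_markers_per_chrom=0),
            dict(h2=0.0),
            dict(h2=1.5),
            dict(cross_pop_genetic_correlation=1.2),
            dict(n_qtl=500),  # exceeds 120 markers
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestBasePopulation:
    def test_no_burnin_matches_initial_draws(self):
        """With zero generations the haplotypes are the initialization draws."""
        cfg = small_config(n_burnin_generations=0, seed=5)
        pop = simpop.simulate_base_population(cfg)
        rng = np.random.default_rng(cfg.seed)
        p0 = rng.uniform(0.05, 0.95, size=cfg.n_markers)
        expected = (rng.random((cfg.effective_size_ne, 2, cfg.n_markers)) < p0).astype(np.uint8)
        np.testing.assert_array_equal(pop.haplotypes, expected)

    def test_same_seed_bit_identical(self):
        cfg = small_config()
        a = simpop.simulate_base_population(cfg)
        b = simpop.simulate_base_population(cfg)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_equilibrium_ld_near_drift_recombination_expectation(self):
        """Mean adjacent r2 within a factor of 2 of 1/(1 + 4 Ne c) at the
        adjacent-pair recombination fraction, over 5 seeds."""
        ratios = []
        for seed in range(5):
            cfg = SimConfig(
                n_chromosomes=1, chrom_length_morgans=1.0, n_markers_per_chrom=500,
                effective_size_ne=100, n_burnin_generations=200, n_qtl=10, seed=seed,
            )
            pop = simpop.simulate_base_population(cfg)
            rec = ld.adjacent_ld(pop)
            c = 0.5 * (1 - np.exp(-2.0 / 499))
            ratios.append(np.nanmean(rec["r2"]) / (1.0 / (1 + 4 * 100 * c)))
        mean_ratio = np.mean(ratios)
        assert 0.5 < mean_ratio < 2.0

    def test_heterozygosity_decays_at_one_over_two_ne(self):
        """Expected heterozygosity declines ~(1 - 1/(2Ne)) per generation."""
        cfg = SimConfig(
            n_chromosomes=2, n_markers_per_chrom=400, effective_size_ne=50,
            n_burnin_generations=60, n_qtl=10, seed=3,
        )
        rng = np.random.default_rng(cfg.seed)
        pop0 = simpop.simulate_base_population(dataclasses.replace(cfg, n_burnin_generations=0))
        pop1 = simpop.simulate_base_population(cfg)
        h0 = np.mean(2 * pop0.allele_frequencies() * (1 - pop0.allele_frequencies()))
        h1 = np.mean(2 * pop1.allele_frequencies() * (1 - pop1.allele_frequencies()))
        expected = h0 * (1 - 1 / (2 * cfg.effective_size_ne)) ** cfg.n_burnin_generations
        assert abs(h1 / expected - 1) < 0.25

    def test_hardy_weinberg_after_one_generation(self):
        cfg = SimConfig(
            n_chromosomes=1, n_markers_per_chrom=300, effective_size_ne=200,
            n_burnin_generations=1, n_qtl=10, seed=9,
        )
        pop = simpop.simulate_base_population(cfg)
        dos = pop.dosages()
        p = pop.allele_frequencies()
        informative = (p > 0.2) & (p < 0.8)
        obs_het = (dos == 1).mean(axis=0)[informative]
        exp_het = (2 * p * (1 - p))[informative]
        # binomial sampling error at n=200 animals, averaged over loci
        assert abs(obs_het.mean() - exp_het.mean()) < 0.02


class TestSplitAndDiverge:
    def test_zero_divergence_identical_founders_share_ld(self):
        cfg = small_config(n_divergence_generations=0, effective_size_ne=60, split_sizes=(40, 40))
        base = simpop.simulate_base_population(cfg)
        founders = np.arange(40)
        a, b = simpop.split_and_diverge(base, cfg, founders_a=founders, founders_b=founders)
        ra = ld.adjacent_ld(a)["r"]
        rb = ld.adjacent_ld(b)["r"]
        ok = ~(ra.isna() | rb.isna())
        assert np.corrcoef(ra[ok], rb[ok])[0, 1] > 0.99

    def test_degenerate_split_rejected(self):
        cfg = small_config(split_sizes=(0, 10))
        base = simpop.simulate_base_population(cfg)
        with pytest.raises(ValueError):
            simpop.split_and_diverge(base, cfg)

    def test_oversized_split_rejected(self):
        cfg = small_config(split_sizes=(30, 30), effective_size_ne=40)
        base = simpop.simulate_base_population(cfg)
        with pytest.raises(ValueError, match="exceed"):
            simpop.split_and_diverge(base, cfg)


@pytest.fixture(scope="module")
def pops():
    cfg = small_config(n_markers_per_chrom=200, n_qtl=60)
    base = simpop.simulate_base_population(cfg)
    return (*simpop.split_and_diverge(base, cfg), cfg)


@pytest.fixture(scope="module")
def pool():
    cfg = small_config(n_markers_per_chrom=200, n_qtl=60, split_sizes=(30, 30), effective_size_ne=60)
    base = simpop.simulate_base_population(cfg)
    a, b = simpop.split_and_diverge(base, cfg)
    tv = simpop.assign_trait_architecture(a, b, cfg)
    return a, tv, cfg


class TestTraitArchitecture:
    def test_perfect_correlation_gives_proportional_effects(self, pops):
        a, b, cfg = pops
        cfg1 = dataclasses.replace(cfg, cross_pop_genetic_correlation=1.0)
        tv = simpop.assign_trait_architecture(a, b, cfg1)
        e = tv.effects
        ratio = e[:, 1] / e[:, 0]
        assert np.allclose(ratio, ratio[0])
        tbv0 = tv.tbv_for(a, 0)
        tbv1 = tv.tbv_for(a, 1)
        assert np.corrcoef(tbv0, tbv1)[0, 1] > 0.999999

    def test_target_genetic_correlation_recovered(self, pops):
        """Realized cross-population TBV correlation within 0.1 of the
        target over 10 effect draws."""
        a, b, cfg = pops
        cors = []
        for seed in range(10):
            tv = simpop.assign_trait_architecture(
                a, b, cfg, np.random.default_rng(seed)
            )
            pooled = a.concat(b)
            cors.append(np.corrcoef(tv.tbv_for(pooled, 0), tv.tbv_for(pooled, 1))[0, 1])
        assert abs(np.mean(cors) - cfg.cross_pop_genetic_correlation) < 0.1

    def test_tbv_variance_scaled_to_h2(self, pops):
        a, b, cfg = pops
        tv = simpop.assign_trait_architecture(a, b, cfg)
        assert np.var(tv.tbv["A"].to_numpy()) == pytest.approx(cfg.h2, rel=0.02)
        assert np.var(tv.tbv["B"].to_numpy()) == pytest.approx(cfg.h2, rel=0.02)

    def test_stored_tbv_matches_recomputation(self, pops):
        a, b, cfg = pops
        tv = simpop.assign_trait_architecture(a, b, cfg)
        dos = a.haplotypes[:, :, tv.qtl_indices].sum(axis=1)
        np.testing.assert_allclose(tv.tbv["A"].to_numpy(), dos @ tv.effects[:, 0])


class TestFamilyStructure:
    def test_every_cow_gets_one_sire_and_sizes_in_range(self, pool):
        a, tv, cfg = pool
        ped, animals = simpop.build_family_structure(
            a, tv, cfg, np.random.default_rng(1), n_bulls=20, n_sires=6, n_cows=80,
            family_size_range=(8, 25),
        )
        cows = ped[ped["sex"] == "F"]
        bulls = set(ped.loc[ped["sex"] == "M", "animal_id"])
        assert len(cows) == 80
        assert cows["sire_id"].isin(bulls).all()
        sizes = cows.groupby("sire_id").size()
        assert len(sizes) == 6
        assert sizes.between(8, 25).all()
        assert animals.n_animals == 100

    def test_single_family(self, pool):
        a, tv, cfg = pool
        ped, _ = simpop.build_family_structure(
            a, tv, cfg, np.random.default_rng(2), n_bulls=2, n_sires=1, n_cows=10,
            family_size_range=(10, 10),
        )
        assert ped[ped["sex"] == "F"].groupby("sire_id").size().tolist() == [10]

    def test_infeasible_family_sizes_rejected(self, pool):
        a, tv, cfg = pool
        with pytest.raises(ValueError, match="cannot split"):
            simpop.build_family_structure(
                a, tv, cfg, np.random.default_rng(3), n_bulls=10, n_sires=2, n_cows=100,
                family_size_range=(5, 10),
            )

    def test_zero_trend_gives_flat_tbv_over_years(self, pool):
        """With no selection, the regression of bull TBV on birth year is
        not significantly different from zero (|t| < 3 over 10 seeds)."""
        a, tv, cfg = pool
        cfg0 = dataclasses.replace(cfg, trend_per_year=0.0)
        tstats = []
        for seed in range(10):
            ped, bulls, _ = simpop.breed_bull_cohorts(
                a, tv, 0, cfg0, np.random.default_rng(seed), n_bulls=60,
                birth_years=(1993, 2002), cohort_size=60,
            )
            years = ped["birth_year"].to_numpy(float)
            tbv = tv.tbv_for(bulls, 0)
            x = np.column_stack([np.ones_like(years), years])
            beta, res, *_ = np.linalg.lstsq(x, tbv, rcond=None)
            dof = len(tbv) - 2
            s2 = res[0] / dof
            se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
            tstats.append(beta[1] / se)
        assert np.mean(np.abs(tstats) < 3) >= 0.9

    def test_positive_trend_emerges_under_selection(self, pool):
        a, tv, cfg = pool
        slopes = []
        for seed in range(5):
            ped, bulls, _ = simpop.breed_bull_cohorts(
                a, tv, 0, cfg, np.random.default_rng(seed), n_bulls=80,
                birth_years=(1993, 2002), cohort_size=100,
            )
            slopes.append(np.polyfit(ped["birth_year"], tv.tbv_for(bulls, 0), 1)[0])
        expected = cfg.trend_per_year * np.sqrt(cfg.h2)
        assert 0.3 * expected < np.mean(slopes) < 3 * expected


class TestGenerateDrp:
    def test_full_reliability_is_exact(self, rng):
        tbv = rng.standard_normal(50)
        drp = simpop.generate_drp(tbv, 1.0, 1.0, rng)
        np.testing.assert_allclose(drp["drp"], tbv)

    def test_reliability_calibration(self, rng):
        """Cor^2(DRP, TBV) matches the prescribed reliability 0.5 at n=5000."""
        tbv = rng.standard_normal(5000)
        drp = simpop.generate_drp(tbv, 0.5, 1.0, rng)
        cor2 = np.corrcoef(drp["drp"], tbv)[0, 1] ** 2
        assert 0.45 < cor2 < 0.55

    def test_error_variance_monotone_in_reliability(self, rng):
        tbv = np.zeros(4000)
        bull = simpop.generate_drp(tbv, 0.9, 1.0, rng)["drp"]
        cow = simpop.generate_drp(tbv, 0.3, 1.0, rng)["drp"]
        assert bull.var() == pytest.approx(1 / 9, rel=0.15)
        assert cow.var() == pytest.approx(7 / 3, rel=0.15)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.2])
    def test_invalid_reliability_rejected(self, bad, rng):
        with pytest.raises(ValueError):
            simpop.generate_drp(np.zeros(3), bad, 1.0, rng)
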