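"""Synthetic-population generator: structure, moments, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from workability.pedigree import Pedigree
from workability.simulate import (
    ConfigError,
    FixedEffectSpec,
    HALF_SIB_SIZE_REFERENCE,
    SCORE_TARGETS,
    SimulationConfig,
    SizeDistribution,
    fit_thresholds,
    gene_drop,
    generate_genotypes,
    generate_pedigree,
    generate_phenotypes,
    simulate_population,
)


def latent_config(**kw) -> SimulationConfig:
    spec = FixedEffectSpec(
        hys_sd=(0.0, 0.0),
        stage_effects=tuple((0.0, 0.0) for _ in range(8)),
        age_coeff=(0.0, 0.0),
        hf_coeff=(0.0, 0.0),
    )
    base = dict(
        fixed_effect_spec=spec,
        n_snps=0,
        genotyped_fraction_of_sires=0.0,
        ordinal_mode=False,
        seed=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestPedigreeGeneration:
    def test_smallest_family(self):
        cfg = SimulationConfig(
            n_sires=1, daughters_per_sire=SizeDistribution("constant", 3), seed=1
        )
        ped = generate_pedigree(cfg)
        assert len(ped) == 7  # 1 sire + 3 dams + 3 cows
        sires = {s for s in ped.sires if s is not None}
        assert len(sires) == 1  # all cows are paternal half-sibs

    def test_constant_family_count_arithmetic(self):
        cfg = SimulationConfig(
            n_sires=300, daughters_per_sire=SizeDistribution("constant", 15), seed=1
        )
        ped = generate_pedigree(cfg)
        assert int((~ped.is_founder()).sum()) == 4500

    def test_reference_distribution_majority_in_large_families(self):
        """Family sizes sampled from the recorded size-class table put well
        over 35% of cows in half-sib groups of at least 10."""
        cfg = SimulationConfig(
            n_sires=1000,
            daughters_per_sire=SizeDistribution.half_sib_reference(),
            seed=3,
        )
        ped = generate_pedigree(cfg)
        sire_ids = [s for s in ped.sires if s is not None]
        sizes = {}
        for s in sire_ids:
            sizes[s] = sizes.get(s, 0) + 1
        counts = np.array(list(sizes.values()))
        frac = counts[counts >= 10].sum() / counts.sum()
        assert frac >= 0.35

    def test_invalid_distribution_spec_raises(self):
        with pytest.raises(ConfigError):
            SizeDistribution("constant", 0).sample(3, np.random.default_rng(0))
        with pytest.raises(ConfigError):
            SizeDistribution("bogus").sample(3, np.random.default_rng(0))


class TestGenotypes:
    def test_symmetric_frequency_mean_dosage_near_one(self):
        cfg = SimulationConfig(
            n_sires=400,
            daughters_per_sire=SizeDistribution("constant", 1),
            n_snps=1,
            maf_range=(0.5, 0.5),
            genotyped_fraction_of_sires=1.0,
            seed=2,
        )
        ped = generate_pedigree(cfg)
        g = generate_genotypes(ped, cfg)
        mean = g.dosages.mean()
        se = g.dosages.std() / np.sqrt(g.n_animals)
        assert abs(mean - 1.0) < 3 * se

    def test_zero_fraction_gives_empty_matrix(self):
        cfg = SimulationConfig(
            n_sires=5,
            daughters_per_sire=SizeDistribution("constant", 2),
            n_snps=10,
            genotyped_fraction_of_sires=0.0,
            seed=2,
        )
        ped = generate_pedigree(cfg)
        assert generate_genotypes(ped, cfg).is_empty()

    def test_homozygous_parents_transmit_deterministically(self):
        cfg = SimulationConfig(
            n_sires=30,
            daughters_per_sire=SizeDistribution("constant", 5),
            n_snps=40,
            maf_range=(0.2, 0.4),
            seed=4,
        )
        ped = generate_pedigree(cfg)
        dos, _ = gene_drop(ped, cfg)
        s_idx, d_idx = ped.parent_indices()
        for i in np.flatnonzero(s_idx >= 0):
            both_zero = (dos[s_idx[i]] == 0) & (dos[d_idx[i]] == 0)
            assert (dos[i][both_zero] == 0).all()
            both_two = (dos[s_idx[i]] == 2) & (dos[d_idx[i]] == 2)
            assert (dos[i][both_two] == 2).all()

    def test_sire_daughter_dosage_correlation_matches_enumeration(self):
        """Gene dropping vs brute-force enumeration of Mendelian
        transmissions: with HWE founders, corr(sire, daughter) = 0.5."""
        p = 0.3
        # enumerate sire dosage x dam dosage x transmitted alleles
        probs = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
        transmit = {0: {0: 1.0}, 1: {0: 0.5, 1: 0.5}, 2: {1: 1.0}}
        e_sd, e_s, e_d, e_s2, e_d2 = 0.0, 0.0, 0.0, 0.0, 0.0
        for gs, ps in probs.items():
            for gd, pd in probs.items():
                for als, pas in transmit[gs].items():
                    for ald, pad in transmit[gd].items():
                        w = ps * pd * pas * pad
                        daughter = als + ald
                        e_sd += w * gs * daughter
                        e_s += w * gs
                        e_d += w * daughter
                        e_s2 += w * gs**2
                        e_d2 += w * daughter**2
        rho = (e_sd - e_s * e_d) / np.sqrt(
            (e_s2 - e_s**2) * (e_d2 - e_d**2)
        )
        assert rho == pytest.approx(0.5)

        cfg = SimulationConfig(
            n_sires=2500,
            daughters_per_sire=SizeDistribution("constant", 1),
            n_snps=5,
            maf_range=(p, p),
            seed=6,
        )
        ped = generate_pedigree(cfg)
        dos, _ = gene_drop(ped, cfg)
        s_idx, d_idx = ped.parent_indices()
        kids = np.flatnonzero(s_idx >= 0)
        sire_d = dos[s_idx[kids]].ravel().astype(float)
        kid_d = dos[kids].ravel().astype(float)
        emp = np.corrcoef(sire_d, kid_d)[0, 1]
        assert emp == pytest.approx(rho, abs=3.0 / np.sqrt(len(kid_d)))

    def test_zero_snps_rejected(self):
        cfg = SimulationConfig(n_sires=2, seed=1, n_snps=0)
        ped = generate_pedigree(cfg)
        with pytest.raises(ConfigError):
            gene_drop(ped, cfg)


class TestPhenotypes:
    def test_zero_genetic_variance_gives_zero_breeding_values(self):
        cfg = latent_config(
            n_sires=50,
            daughters_per_sire=SizeDistribution("constant", 4),
            true_G0=((0.0, 0.0), (0.0, 0.0)),
        )
        pop = generate_phenotypes(generate_pedigree(cfg), cfg)
        assert np.abs(pop.breeding_values).max() == 0.0

    def test_latent_variance_matches_truth_at_large_n(self):
        """Latent MS variance ~ 0.2157 (the pedigree-run phenotypic truth)."""
        cfg = latent_config(
            n_sires=3000, daughters_per_sire=SizeDistribution("constant", 2)
        )
        pop = generate_phenotypes(generate_pedigree(cfg), cfg)
        n = len(pop.records)
        p0 = cfg.g0 + cfg.r0
        var = pop.latent[:, 0].var(ddof=1)
        se = p0[0, 0] * np.sqrt(2.0 / n)
        # small inflation of the MC error from half-sib clustering
        assert var == pytest.approx(p0[0, 0], abs=3 * se + 0.003)

    def test_phenotypic_covariance_recovers_g0_plus_r0(self):
        cfg = latent_config(
            n_sires=5000, daughters_per_sire=SizeDistribution("constant", 2)
        )
        pop = generate_phenotypes(generate_pedigree(cfg), cfg)
        n = len(pop.records)
        p0 = cfg.g0 + cfg.r0
        emp = np.cov(pop.latent, rowvar=False)
        for i in range(2):
            for j in range(2):
                se = np.sqrt((p0[i, i] * p0[j, j] + p0[i, j] ** 2) / n)
                assert emp[i, j] == pytest.approx(p0[i, j], abs=3 * se + 1e-3)

    def test_unrelated_cows_have_uncorrelated_breeding_values(self):
        cfg = latent_config(
            n_sires=10000, daughters_per_sire=SizeDistribution("constant", 1)
        )
        ped = generate_pedigree(cfg)
        pop = generate_phenotypes(ped, cfg)
        cows = ~ped.is_founder()
        bv = pop.breeding_values[cows, 0]
        r = np.corrcoef(bv[::2][: len(bv) // 2], bv[1::2][: len(bv) // 2])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(bv) // 2)

    def test_half_sibs_share_quarter_of_genetic_variance(self):
        cfg = latent_config(
            n_sires=4000, daughters_per_sire=SizeDistribution("constant", 2)
        )
        ped = generate_pedigree(cfg)
        pop = generate_phenotypes(ped, cfg)
        cows = np.flatnonzero(~ped.is_founder())
        bv = pop.breeding_values[cows, 0]
        # consecutive cows within a constant-size family are half-sibs
        pairs = bv.reshape(-1, 2)
        emp = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert emp == pytest.approx(0.25, abs=3.0 / np.sqrt(len(pairs)))

    def test_ordinal_scores_match_recorded_moments(self, small_population):
        rec = small_population.records
        for col, trait in (("ms_score", "MS"), ("mt_score", "MT")):
            mean, sd = SCORE_TARGETS[trait]
            assert rec[col].mean() == pytest.approx(mean, abs=0.06)
            assert rec[col].std(ddof=1) == pytest.approx(sd, abs=0.06)
        assert rec["ms_score"].between(1, 5).all()
        assert rec["mt_score"].between(1, 3).all()

    def test_non_pd_residual_covariance_rejected(self):
        with pytest.raises(ConfigError):
            latent_config(true_R0=((1.0, 2.0), (2.0, 1.0)))


class TestThresholds:
    def test_three_category_closed_form(self):
        # for mean 1.97 / sd 0.37 on scores {1,2,3}: p1 = 0.0839, p3 = 0.0539
        cuts = fit_thresholds(3, 1.97, 0.37)
        p1 = stats.norm.cdf(cuts[0])
        p3 = 1.0 - stats.norm.cdf(cuts[1])
        assert p1 == pytest.approx(0.0839, abs=1e-4)
        assert p3 == pytest.approx(0.0539, abs=1e-4)

    def test_five_category_moments_reproduced(self):
        cuts = fit_thresholds(5, 3.05, 0.73)
        grid = np.diff(
            np.concatenate([[0.0], stats.norm.cdf(cuts), [1.0]])
        )
        scores = np.arange(1, 6)
        mean = grid @ scores
        sd = np.sqrt(grid @ (scores - mean) ** 2)
        assert mean == pytest.approx(3.05, abs=1e-6)
        assert sd == pytest.approx(0.73, abs=1e-6)


class TestReproducibility:
    def test_identical_seed_identical_population(self):
        cfg = SimulationConfig(
            n_sires=20,
            daughters_per_sire=SizeDistribution("poisson", 6),
            n_snps=50,
            seed=42,
        )
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        assert a.pedigree.animals == b.pedigree.animals
        assert a.records.equals(b.records)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_array_equal(a.latent, b.latent)

    def test_table_reference_totals(self):
        assert sum(c for _, _, c in HALF_SIB_SIZE_REFERENCE) == 16720
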