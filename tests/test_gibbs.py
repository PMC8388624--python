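"""Design assembly and the Gibbs variance-component sampler."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import make_record
from workability.gibbs import (
    AnimalModelGibbs,
    GibbsConfig,
    ModelError,
    ObservationModel,
    build_design,
    gibbs_sample,
    run_analysis,
)
from workability.posterior import derive_params, mce
from workability.relationship import GenotypeMatrix, RelationshipKernel, a_inverse
from workability._ldl import LDLFactorization


def identity_kernel(ids):
    n = len(ids)
    eye = sp.identity(n, format="csr")
    return RelationshipKernel("A_inverse", ids, eye, factor=eye.tocsr())


class TestBuildDesign:
    def test_single_levels_collapse_to_intercept_plus_covariates(self):
        rows = [
            make_record(cow_id=f"c{i}", dim_eval=41 + i, age_days=age, hf=hf)
            for i, (age, hf) in enumerate([(760, 91.0), (775, 98.5), (790, 88.0)])
        ]  # one HYS, one stage, non-collinear covariates
        kernel = identity_kernel([f"c{i}" for i in range(3)])
        model = build_design(pd.DataFrame(rows), kernel)
        # one HYS level and one stage level carry no contrast columns
        assert model.fixed_labels == ["intercept", "age", "hf"]
        assert model.X.shape == (3, 3)

    def test_two_hys_levels_one_contrast(self):
        rows = [
            make_record(cow_id="a", herd_id="H1"),
            make_record(cow_id="b", herd_id="H2"),
            make_record(cow_id="c", herd_id="H2"),
        ]
        kernel = identity_kernel(["a", "b", "c"])
        model = build_design(pd.DataFrame(rows), kernel, factors=("hys",), covariates=())
        hys_cols = [l for l in model.fixed_labels if l.startswith("hys[")]
        assert len(hys_cols) == 1

    def test_unphenotyped_kernel_animals_absent_from_z(self):
        rows = [make_record(cow_id="a"), make_record(cow_id="b", ms=4)]
        kernel = identity_kernel(["s1", "a", "b"])  # s1 has no record
        model = build_design(pd.DataFrame(rows), kernel, factors=(), covariates=())
        z = model.Z.toarray()
        assert z.shape == (2, 3)
        assert z[:, 0].sum() == 0  # s1 column empty
        assert z.sum() == 2

    def test_confounded_design_rejected(self):
        rows = [
            make_record(cow_id="a", herd_id="H1", dim_eval=25),
            make_record(cow_id="b", herd_id="H2", dim_eval=35),
        ]
        kernel = identity_kernel(["a", "b"])
        with pytest.raises(ModelError):
            build_design(pd.DataFrame(rows), kernel, factors=("hys", "stage"), covariates=())

    def test_out_of_window_records_rejected_for_stage_factor(self):
        rows = [make_record(cow_id="a", dim_eval=150)]
        kernel = identity_kernel(["a"])
        with pytest.raises(ModelError):
            build_design(pd.DataFrame(rows), kernel)


class TestChainBookkeeping:
    def test_study_protocol_yields_16000_samples(self):
        assert GibbsConfig(n_iter=100_000, burn_in=20_000, thin=5).n_recorded == 16_000

    def test_recording_rule_on_short_run(self, latent_population):
        pop = latent_population
        config = GibbsConfig(n_iter=60, burn_in=20, thin=5, seed=3)
        result = run_analysis(
            pop.records, pop.pedigree, config=config,
            factors=("hys",), covariates=(), apply_prep_filters=False,
        )
        assert len(result.chain) == config.n_recorded == 8
        assert list(result.chain["iteration"]) == [25, 30, 35, 40, 45, 50, 55, 60]

    def test_every_recorded_matrix_positive_definite(self, latent_population):
        pop = latent_population
        samples = gibbs_sample(
            build_design(
                pop.records,
                _pedigree_kernel(pop),
                factors=("hys",),
                covariates=(),
            ),
            GibbsConfig(n_iter=120, burn_in=20, thin=2, seed=9),
        )
        for s in samples:
            assert np.linalg.eigvalsh(s.G0).min() > 0
            assert np.linalg.eigvalsh(s.R0).min() > 0

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ModelError):
            GibbsConfig(n_iter=100, burn_in=100)
        with pytest.raises(ModelError):
            GibbsConfig(thin=0)
        with pytest.raises(ModelError):
            GibbsConfig(location_update="single-site")


def _pedigree_kernel(pop):
    ped = pop.pedigree.prune_singleton_parents(pop.records["cow_id"])
    ainv = a_inverse(ped)
    return ainv


class TestDeterminismAndDegeneracy:
    def test_same_seed_identical_chains(self, latent_population):
        pop = latent_population
        config = GibbsConfig(n_iter=80, burn_in=20, thin=3, seed=17)
        runs = [
            run_analysis(
                pop.records, pop.pedigree, config=config,
                factors=("hys",), covariates=(), apply_prep_filters=False,
            ).chain
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_no_genotypes_equals_empty_genotypes(self, latent_population):
        pop = latent_population
        config = GibbsConfig(n_iter=60, burn_in=20, thin=5, seed=5)
        empty = GenotypeMatrix([], ["snp1"], np.zeros((0, 1), dtype=np.int8))
        chains = [
            run_analysis(
                pop.records, pop.pedigree, genotypes=g, config=config,
                factors=("hys",), covariates=(), apply_prep_filters=False,
            ).chain
            for g in (None, empty)
        ]
        pd.testing.assert_frame_equal(chains[0], chains[1])

    def test_record_order_does_not_move_posterior_means(self, latent_population):
        pop = latent_population
        config = GibbsConfig(n_iter=1500, burn_in=300, thin=2, seed=21)
        base = run_analysis(
            pop.records, pop.pedigree, config=config,
            factors=("hys",), covariates=(), apply_prep_filters=False,
        ).chain
        rng = np.random.default_rng(0)
        shuffled = pop.records.sample(frac=1.0, random_state=7).reset_index(drop=True)
        perm = run_analysis(
            shuffled, pop.pedigree, config=config,
            factors=("hys",), covariates=(), apply_prep_filters=False,
        ).chain
        for col in ("sigma2_a_MS", "sigma2_e_MS", "sigma2_a_MT", "sigma2_e_MT"):
            tol = 2.0 * np.hypot(mce(base[col].to_numpy()), mce(perm[col].to_numpy()))
            assert abs(base[col].mean() - perm[col].mean()) <= tol + 1e-12


class TestAgainstConjugateReference:
    """One trait, kernel = identity: compare with an independent scalar
    Gibbs sampler for the random-intercept model y_ij = mu + a_i + e_ij."""

    @staticmethod
    def reference_chain(y, groups, n_groups, n_iter, burn_in, seed):
        rng = np.random.default_rng(seed)
        n = len(y)
        mu, sa2, se2 = y.mean(), y.var() / 2, y.var() / 2
        a = np.zeros(n_groups)
        counts = np.bincount(groups, minlength=n_groups)
        out = []
        for it in range(n_iter):
            resid_sum = np.bincount(groups, weights=y - mu, minlength=n_groups)
            prec = counts / se2 + 1.0 / sa2
            mean = (resid_sum / se2) / prec
            a = mean + rng.standard_normal(n_groups) / np.sqrt(prec)
            r = y - a[groups]
            mu = r.mean() + rng.standard_normal() * np.sqrt(se2 / n)
            e = y - mu - a[groups]
            # inverse-Wishart (1x1) == inverse-gamma; same prior as the sampler
            sa2 = 1.0 / rng.gamma((2 + n_groups) / 2.0, 2.0 / (0.01 + a @ a))
            se2 = 1.0 / rng.gamma((2 + n) / 2.0, 2.0 / (0.01 + e @ e))
            if it >= burn_in:
                out.append((sa2, se2))
        return np.array(out)

    def test_posterior_means_agree(self):
        rng = np.random.default_rng(100)
        n_groups, per = 60, 6
        groups = np.repeat(np.arange(n_groups), per)
        y = 2.0 + rng.standard_normal(n_groups)[groups] * 0.6 + rng.standard_normal(len(groups)) * 0.9

        ids = [f"g{i}" for i in range(n_groups)]
        kernel = identity_kernel(ids)
        Z = sp.csr_matrix(
            (np.ones(len(y)), (np.arange(len(y)), groups)), shape=(len(y), n_groups)
        )
        X = sp.csr_matrix(np.ones((len(y), 1)))
        model = ObservationModel(
            y.reshape(-1, 1), X, Z, kernel, ["intercept"], trait_names=("T",)
        )
        est = AnimalModelGibbs(n_iter=6000, burn_in=1000, thin=1, seed=13).fit(model)
        ref = self.reference_chain(y, groups, n_groups, 6000, 1000, seed=14)

        mine = est.g0_samples_[:, 0, 0], est.r0_samples_[:, 0, 0]
        for k, (chain, other) in enumerate(zip(mine, (ref[:, 0], ref[:, 1]))):
            tol = 2.0 * np.hypot(mce(chain), mce(other))
            assert abs(chain.mean() - other.mean()) <= tol


class TestAgainstAnovaOracle:
    def test_balanced_half_sib_sire_variance(self):
        """Posterior mean sire variance vs the expected-mean-squares
        (ANOVA) estimator on a balanced 200 x 20 half-sib design."""
        rng = np.random.default_rng(55)
        s, k = 200, 20
        sa2_true, se2_true = 0.05, 0.95
        sires = np.repeat(np.arange(s), k)
        a = rng.standard_normal(s) * np.sqrt(sa2_true)
        y = 3.0 + a[sires] + rng.standard_normal(s * k) * np.sqrt(se2_true)

        group_means = y.reshape(s, k).mean(axis=1)
        msb = k * group_means.var(ddof=1)
        msw = (y.reshape(s, k) - group_means[:, None]).var(ddof=0) * (s * k) / (s * (k - 1))
        anova = (msb - msw) / k

        ids = [f"s{i}" for i in range(s)]
        kernel = identity_kernel(ids)
        Z = sp.csr_matrix((np.ones(s * k), (np.arange(s * k), sires)), shape=(s * k, s))
        X = sp.csr_matrix(np.ones((s * k, 1)))
        model = ObservationModel(
            y.reshape(-1, 1), X, Z, kernel, ["intercept"], trait_names=("T",)
        )
        est = AnimalModelGibbs(n_iter=4000, burn_in=1000, thin=1, seed=23).fit(model)
        chain = est.g0_samples_[:, 0, 0]
        assert abs(chain.mean() - anova) <= 3.0 * mce(chain)


class TestNullHeritability:
    def test_no_genetic_variance_recovered_as_tiny_h2(self):
        from workability.simulate import (
            SimulationConfig,
            SizeDistribution,
            FixedEffectSpec,
            generate_pedigree,
            generate_phenotypes,
        )

        spec = FixedEffectSpec(
            hys_sd=(0.1, 0.05),
            stage_effects=tuple((0.0, 0.0) for _ in range(8)),
            age_coeff=(0.0, 0.0),
            hf_coeff=(0.0, 0.0),
        )
        # 60 x 50 half-sib families: SE of realized h2-hat ~ 0.015 at n=3000,
        # so the positive-part posterior mean sits well below 0.03
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                n_sires=60,
                daughters_per_sire=SizeDistribution("constant", 50),
                n_herds=20,
                hys_size_target=SizeDistribution("constant", 50),
                true_G0=((0.0, 0.0), (0.0, 0.0)),
                fixed_effect_spec=spec,
                n_snps=0,
                genotyped_fraction_of_sires=0.0,
                ordinal_mode=False,
                seed=seed,
            )
            ped = generate_pedigree(cfg)
            pop = generate_phenotypes(ped, cfg)
            result = run_analysis(
                pop.records, ped,
                config=GibbsConfig(n_iter=4000, burn_in=2000, thin=2, seed=seed),
                factors=("hys",), covariates=(), apply_prep_filters=False,
            )
            derived = derive_params(result.estimator.samples_)
            assert derived["h2_MS"].mean() < 0.03
            assert derived["h2_MT"].mean() < 0.03


def test_ldl_factorization_matches_dense_solve():
    rng = np.random.default_rng(2)
    n = 50
    base = sp.random(n, n, density=0.1, random_state=3).toarray()
    m = base @ base.T + np.eye(n) * n
    msp = sp.triu(sp.csc_matrix(m), format="csc")
    msp.sort_indices()
    ldl = LDLFactorization(msp.indptr, msp.indices)
    ldl.factorize(msp.data)
    b = rng.standard_normal(n)
    np.testing.assert_allclose(ldl.solve(b), np.linalg.solve(m, b), atol=1e-8)
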