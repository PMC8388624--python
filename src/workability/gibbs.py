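"""Two-trait animal model and Gibbs sampling of its covariance components.

The observation model is the multivariate mixed ("animal") model

    y_t = X b_t + Z a_t + e_t,   t = MS, MT

with fixed effects b (HYS, lactation stage, regressions on age at calving
and percent HF), additive genetic effects a ~ N(0, G0 (x) K) for a
relationship kernel K (pedigree A or single-step H; only K^{-1} is ever
used), and residuals e ~ N(0, R0 (x) I) with both traits recorded on
every cow. G0 and R0 are the 2x2 genetic and residual covariance matrices.

Sampling scheme (one Gibbs cycle):

1. Location parameters theta = (b, a) for both traits jointly from their
   Gaussian full conditional N(C^{-1} r, C^{-1}), where C is the
   mixed-model coefficient matrix. The draw uses sampling-by-perturbation:
   solve C theta = r + c with c ~ N(0, C) assembled from the analytic
   factors of R0^{-1} (x) I and G0^{-1} (x) K^{-1}; one sparse LU
   factorization per cycle.
2. G0 from an inverse-Wishart with scale S0 + a' K^{-1} a and degrees of
   freedom nu0 + q.
3. R0 from an inverse-Wishart with scale S0 + e'e and degrees nu0 + n.

Priors default to minimally informative inverse-Wisharts
(scale 0.01 * I, df = n_traits + 1). Chains are deterministic given the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.linalg import splu
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from ._ldl import LDLFactorization

from .pedigree import Pedigree
from .prep import add_assignments, apply_filters
from .relationship import (
    GenotypeMatrix,
    RelationshipKernel,
    a_inverse,
    g_matrix,
    h_inverse,
    maf_filter,
    spd_factor,
)

__all__ = [
    "ObservationModel",
    "GibbsConfig",
    "CovarianceSample",
    "build_design",
    "AnimalModelGibbs",
    "gibbs_sample",
    "run_analysis",
]


class ModelError(ValueError):
    pass


@dataclass
class ObservationModel:
    """Assembled y = Xb + Za + e structures for one analysis.

    ``y`` is n x n_traits; ``X`` and ``Z`` are shared across traits; the
    kernel must be an inverse (A_inverse or H_inverse) over all animals the
    model knows about, phenotyped or not.
    """

    y: np.ndarray
    X: sp.csr_matrix
    Z: sp.csr_matrix
    kernel: RelationshipKernel
    fixed_labels: list[str]
    trait_names: tuple[str, ...] = ("MS", "MT")

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.shape[0] == 1 and self.y.shape[1] > len(self.trait_names):
            self.y = self.y.T
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ModelError("X and Z must have one row per observation")
        if not self.kernel.kind.endswith("_inverse"):
            raise ModelError("kernel must be an inverse (A_inverse or H_inverse)")
        if self.Z.shape[1] != self.kernel.n:
            raise ModelError("Z columns must align with the kernel index")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]


def build_design(
    records: pd.DataFrame,
    kernel: RelationshipKernel,
    factors: Sequence[str] = ("hys", "stage"),
    covariates: Sequence[str] = ("age", "hf"),
    trait_columns: Sequence[str] = ("ms_score", "mt_score"),
    trait_names: Sequence[str] = ("MS", "MT"),
) -> ObservationModel:
    """Sparse design matrices with reference-coded factors and centred
    covariates.

    Every factor keeps one reference level (the first in sorted order) so
    the intercept-bearing X has full column rank; a rank check on X'X
    guards against residual confounding. Animals appearing in the kernel
    without phenotypes simply contribute no Z rows.
    """
    df = add_assignments(records)
    n = len(df)
    if n == 0:
        raise ModelError("no records to model")

    cols = [sp.csr_matrix(np.ones((n, 1)))]
    labels = ["intercept"]
    for factor in factors:
        if factor == "hys":
            values = df["hys"].astype(str)
        elif factor == "stage":
            if df["stage"].isna().any():
                raise ModelError("records outside the lactation-stage window; filter first")
            values = df["stage"].astype(int).astype(str)
        else:
            raise ModelError(f"unknown factor {factor!r}")
        levels = sorted(values.unique())
        counts = values.value_counts()
        if (counts == 0).any():
            raise ModelError(f"factor {factor} has empty levels")
        for level in levels[1:]:  # first level is the reference
            cols.append(sp.csr_matrix((values == level).to_numpy(float).reshape(-1, 1)))
            labels.append(f"{factor}[{level}]")
    for cov in covariates:
        if cov == "age":
            x = (
                pd.to_datetime(df["calving_date"]) - pd.to_datetime(df["birth_date"])
            ).dt.days.to_numpy(float)
        elif cov == "hf":
            x = df["hf_percent"].to_numpy(float)
        else:
            raise ModelError(f"unknown covariate {cov!r}")
        cols.append(sp.csr_matrix((x - x.mean()).reshape(-1, 1)))
        labels.append(cov)
    X = sp.hstack(cols, format="csr")

    xtx = (X.T @ X).toarray()
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        raise ModelError("fixed-effect design is rank deficient beyond reference coding")

    animal_pos = {a: j for j, a in enumerate(kernel.ids)}
    try:
        zcols = np.array([animal_pos[str(c)] for c in df["cow_id"]])
    except KeyError as exc:
        raise ModelError(f"phenotyped animal missing from kernel: {exc}") from exc
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), zcols)), shape=(n, kernel.n)
    )
    y = df[list(trait_columns)].to_numpy(float)
    return ObservationModel(y, X, Z, kernel, labels, tuple(trait_names))


@dataclass(frozen=True)
class GibbsConfig:
    """Chain protocol; defaults follow the study (100k / 20k burn-in / thin 5)."""

    n_iter: int = 100_000
    burn_in: int = 20_000
    thin: int = 5
    prior_scale: float = 0.01
    prior_df: int | None = None  # None -> n_traits + 1
    seed: int = 0
    location_update: str = "blocked"

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ModelError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")
        if self.location_update != "blocked":
            raise ModelError("only the blocked location update is implemented")

    @property
    def n_recorded(self) -> int:
        """Samples kept: every ``thin``-th post burn-in iteration."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class CovarianceSample:
    """One recorded draw of the genetic and residual covariance matrices."""

    iteration: int
    G0: np.ndarray
    R0: np.ndarray


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.T)


def _symmetric_ordering(matrix: sp.csc_matrix) -> np.ndarray:
    """Fill-reducing permutation for an SPD pattern (SuperLU minimum degree)."""
    lu = splu(
        matrix,
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options=dict(SymmetricMode=True),
    )
    perm_c = np.asarray(lu.perm_c)
    # invert: row/col i of the permuted matrix must be original perm^{-1}[i]
    inv = np.empty_like(perm_c)
    inv[perm_c] = np.arange(len(perm_c))
    return inv


def _aligned_upper(
    a: sp.spmatrix, b: sp.spmatrix, perm: np.ndarray
) -> tuple[sp.csc_matrix, sp.csc_matrix]:
    """Upper triangles of the permuted a and b on their shared union pattern.

    Returned matrices have identical indptr/indices, so a linear
    combination is just a linear combination of the data vectors.
    """
    ap = sp.triu(sp.csc_matrix(a)[perm][:, perm], format="csc")
    bp = sp.triu(sp.csc_matrix(b)[perm][:, perm], format="csc")
    for mat in (ap, bp):
        mat.sum_duplicates()
        mat.sort_indices()
    union = sp.triu((ap != 0) + (bp != 0), format="csc").astype(float)
    union.sum_duplicates()
    union.sort_indices()

    def expand(mat: sp.csc_matrix) -> np.ndarray:
        data = np.zeros(union.nnz)
        for col in range(union.shape[1]):
            u0, u1 = union.indptr[col], union.indptr[col + 1]
            m0, m1 = mat.indptr[col], mat.indptr[col + 1]
            pos = np.searchsorted(union.indices[u0:u1], mat.indices[m0:m1])
            data[u0 + pos] = mat.data[m0:m1]
        return data

    a_u = sp.csc_matrix((expand(ap), union.indices, union.indptr), shape=ap.shape)
    b_u = sp.csc_matrix((expand(bp), union.indices, union.indptr), shape=bp.shape)
    return a_u, b_u


class AnimalModelGibbs(BaseEstimator):
    """Gibbs sampler for (co)variance components of the multitrait animal
    model, presented as a scikit-learn style estimator.

    Parameters mirror :class:`GibbsConfig`; :meth:`fit` consumes an
    :class:`ObservationModel` and exposes the recorded chain through
    ``g0_samples_`` / ``r0_samples_`` (arrays of shape
    ``(n_recorded, t, t)``), ``iterations_`` and ``chain_frame_``.
    """

    def __init__(
        self,
        n_iter: int = 100_000,
        burn_in: int = 20_000,
        thin: int = 5,
        prior_scale: float = 0.01,
        prior_df: int | None = None,
        seed: int = 0,
        location_update: str = "blocked",
    ) -> None:
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_scale = prior_scale
        self.prior_df = prior_df
        self.seed = seed
        self.location_update = location_update

    @classmethod
    def from_config(cls, config: GibbsConfig) -> "AnimalModelGibbs":
        return cls(
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            thin=config.thin,
            prior_scale=config.prior_scale,
            prior_df=config.prior_df,
            seed=config.seed,
            location_update=config.location_update,
        )

    def _config(self) -> GibbsConfig:
        return GibbsConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            prior_scale=self.prior_scale,
            prior_df=self.prior_df,
            seed=self.seed,
            location_update=self.location_update,
        )

    # -- sampling ------------------------------------------------------

    def fit(self, model: ObservationModel, y=None) -> "AnimalModelGibbs":
        """Run the chain on an assembled :class:`ObservationModel`.

        The joint location update exploits the canonical decomposition of
        the multitrait system: with Q the generalized eigenvectors of
        (G0^{-1}, R0^{-1}) (Q' R0^{-1} Q = I, Q' G0^{-1} Q = diag(lam)),
        the 2m x 2m mixed-model system splits into one m x m SPD system
        W'W + lam_t * Kpad per transformed trait, all sharing a single
        sparsity pattern, so one symbolic LDL analysis serves every
        iteration.
        """
        config = self._config()  # validates the protocol
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x6B1B5]))
        t = model.n_traits
        n, q = model.n_obs, model.kernel.n
        nu0 = self.prior_df if self.prior_df is not None else t + 1
        s0 = self.prior_scale * np.eye(t)

        kinv = sp.csr_matrix(model.kernel.matrix)
        kfac = model.kernel.factor
        if kfac is None:
            kfac = spd_factor(kinv)
        kfac = sp.csr_matrix(kfac)
        n_fixed = model.X.shape[1]
        W = sp.hstack([model.X, model.Z], format="csr")
        Wt = W.T.tocsr()
        m = W.shape[1]
        WtW = (Wt @ W).tocsr()
        Wty = np.column_stack([Wt @ model.y[:, j] for j in range(t)])
        kpad = sp.bmat(
            [[sp.csr_matrix((n_fixed, n_fixed)), None], [None, kinv]],
            format="csr",
        )

        # one-off ordering (SuperLU minimum degree) + aligned upper patterns
        perm = _symmetric_ordering((WtW + kpad).tocsc())
        inv_perm = np.empty_like(perm)
        inv_perm[perm] = np.arange(m)
        wtw_u, kpad_u = _aligned_upper(WtW, kpad, perm)
        ldl = LDLFactorization(wtw_u.indptr, wtw_u.indices)

        # moment start: half the phenotypic covariance to each component
        p_hat = np.atleast_2d(np.cov(model.y, rowvar=False, ddof=1))
        g0 = 0.5 * p_hat + 1e-8 * np.eye(t)
        r0 = 0.5 * p_hat + 1e-8 * np.eye(t)

        g_samples, r_samples, its = [], [], []
        for it in range(1, self.n_iter + 1):
            r0_inv = np.linalg.inv(r0)
            g0_inv = np.linalg.inv(g0)
            lam, qmat = eigh(g0_inv, r0_inv)  # qmat' r0_inv qmat = I

            # transformed rhs and N(0, M_t) perturbations, per trait
            b_tilde = Wty @ (r0_inv @ qmat)
            c1 = Wt @ rng.standard_normal((n, t))
            u = kfac @ rng.standard_normal((kfac.shape[1], t))
            theta_tilde = np.empty((m, t))
            for j in range(t):
                rhs = b_tilde[:, j] + c1[:, j]
                rhs[n_fixed:] += math.sqrt(lam[j]) * u[:, j]
                ldl.factorize(wtw_u.data + lam[j] * kpad_u.data)
                theta_tilde[perm, j] = ldl.solve(rhs[perm])
            theta = theta_tilde @ qmat.T  # back to observed traits

            beta = theta[:n_fixed, :]
            a = theta[n_fixed:, :]  # (q, t)
            resid = model.y - (model.X @ beta) - (model.Z @ a)

            sa = _symmetrize(a.T @ (kinv @ a))
            se = _symmetrize(resid.T @ resid)
            g0 = self._draw_invwishart(rng, nu0 + q, s0 + sa, t)
            r0 = self._draw_invwishart(rng, nu0 + n, s0 + se, t)

            if it > self.burn_in and (it - self.burn_in) % self.thin == 0:
                g_samples.append(g0.copy())
                r_samples.append(r0.copy())
                its.append(it)

        self.n_traits_ = t
        self.trait_names_ = model.trait_names[:t]
        self.g0_samples_ = np.array(g_samples)
        self.r0_samples_ = np.array(r_samples)
        self.iterations_ = np.array(its)
        return self

    @staticmethod
    def _draw_invwishart(rng, df: float, scale: np.ndarray, t: int) -> np.ndarray:
        scale = _symmetrize(scale)
        for attempt in range(2):
            try:
                draw = invwishart.rvs(df=df, scale=scale, random_state=rng)
                draw = np.atleast_2d(draw)
                np.linalg.cholesky(_symmetrize(draw))  # PD guard
                return _symmetrize(draw)
            except np.linalg.LinAlgError:
                # numerical non-PD: jitter the scale once and retry
                scale = scale + 1e-10 * np.trace(scale) * np.eye(t)
        raise ModelError("inverse-Wishart draw failed to be positive definite")

    # -- fitted accessors ---------------------------------------------

    @property
    def samples_(self) -> list[CovarianceSample]:
        return [
            CovarianceSample(int(i), g, r)
            for i, g, r in zip(self.iterations_, self.g0_samples_, self.r0_samples_)
        ]

    @property
    def chain_frame_(self) -> pd.DataFrame:
        """Chain as a flat table: one column per covariance entry."""
        names = self.trait_names_
        data = {"iteration": self.iterations_}
        for prefix, arr in (("a", self.g0_samples_), ("e", self.r0_samples_)):
            for i in range(self.n_traits_):
                for j in range(i, self.n_traits_):
                    if i == j:
                        col = f"sigma2_{prefix}_{names[i]}"
                    else:
                        col = f"cov_{prefix}_{names[i]}_{names[j]}"
                    data[col] = arr[:, i, j]
        return pd.DataFrame(data)


def gibbs_sample(model: ObservationModel, config: GibbsConfig) -> list[CovarianceSample]:
    """Functional wrapper: run the sampler, return recorded samples."""
    est = AnimalModelGibbs.from_config(config).fit(model)
    return est.samples_


# ----------------------------------------------------------------------
# orchestration


@dataclass
class AnalysisResult:
    mode: str  # "pedigree" or "pedigree+genomic"
    estimator: AnimalModelGibbs
    chain: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def run_analysis(
    records: pd.DataFrame,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix | None = None,
    config: GibbsConfig = GibbsConfig(),
    maf_threshold: float = 0.001,
    blend: float = 0.95,
    factors: Sequence[str] = ("hys", "stage"),
    covariates: Sequence[str] = ("age", "hf"),
    apply_prep_filters: bool = True,
    prune_parents: bool = True,
) -> AnalysisResult:
    """Filter records, build the kernel inverse and design, run the chain.

    With genotypes the run is tagged "pedigree+genomic" and uses the
    single-step H^{-1}; otherwise (or with an empty genotype set) it
    degrades exactly to the pedigree A^{-1} run.
    """
    if apply_prep_filters:
        records = apply_filters(records).kept
    if prune_parents:
        pedigree = pedigree.prune_singleton_parents(records["cow_id"].astype(str))

    genomic = genotypes is not None and not genotypes.is_empty()
    ainv = a_inverse(pedigree)
    if genomic:
        g = g_matrix(maf_filter(genotypes, maf_threshold))
        kernel = h_inverse(ainv, g, pedigree, blend=blend)
        mode = "pedigree+genomic"
    else:
        kernel = RelationshipKernel(
            "H_inverse", list(ainv.ids), ainv.matrix, factor=ainv.factor
        )
        mode = "pedigree"

    model = build_design(records, kernel, factors=factors, covariates=covariates)
    est = AnimalModelGibbs.from_config(config).fit(model)
    provenance = {
        "mode": mode,
        "n_records": int(model.n_obs),
        "n_animals": int(kernel.n),
        "n_genotyped": int(genotypes.n_animals) if genomic else 0,
        "config": {
            "n_iter": config.n_iter,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "prior_scale": config.prior_scale,
            "prior_df": config.prior_df,
            "seed": config.seed,
        },
    }
    return AnalysisResult(mode, est, est.chain_frame_, provenance)
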