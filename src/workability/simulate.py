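"""Synthetic populations with the structure of national workability recording.

The real data behind the analysis — milking speed (MS, scored 1-5) and
milking temperament (MT, scored 1-3) on first-lactation Holstein-Friesian
cows, recorded once per cow by a classifier — sit in a national database
with no public deposit. This module generates populations with the same
statistical skeleton so the whole pipeline is testable:

* a sire-dominated two-generation pedigree: founder sires with half-sib
  daughter groups, dams as unrelated non-genotyped founders;
* herd-year-season (HYS) contemporary groups with a configurable size
  distribution;
* SNP genotypes for a subset of sires by gene dropping from founder
  alleles in Hardy-Weinberg proportions;
* two-trait phenotypes from the generative animal model
  y = Xb + Za + e, with breeding values a ~ N(0, G0 (x) A) simulated
  exactly down the pedigree via Mendelian-sampling terms, residuals
  e ~ N(0, R0 (x) I), and optional threshold discretization calibrated so
  score means/SDs match the recorded population (MS 3.05/0.73,
  MT 1.97/0.37).

The default true covariance components are the pedigree-analysis posterior
means of the study this package reproduces: genetic (co)variances
0.02588 / 0.00055 / 0.00462 and residual = phenotypic - genetic.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree
from .relationship import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SizeDistribution",
    "FixedEffectSpec",
    "SyntheticPopulation",
    "generate_pedigree",
    "generate_genotypes",
    "generate_phenotypes",
    "simulate_population",
    "fit_thresholds",
    "HALF_SIB_SIZE_REFERENCE",
    "HYS_SIZE_REFERENCE",
]


class ConfigError(ValueError):
    pass


#: Published size-class distribution of half-sib (paternal) daughter groups
#: in the recorded population: (low, high, number of groups).
HALF_SIB_SIZE_REFERENCE: list[tuple[int, int, int]] = [
    (1, 1, 4690),
    (2, 5, 3600),
    (6, 9, 1575),
    (10, 19, 1518),
    (20, 49, 1543),
    (50, 99, 1498),
    (100, 199, 1371),
    (200, 499, 558),
    (500, 999, 213),
    (1000, 1999, 106),
    (2000, 4999, 39),
    (5000, 9999, 8),
    (10453, 10453, 1),
]

#: Published size-class distribution of herd-year-season subclasses.
HYS_SIZE_REFERENCE: list[tuple[int, int, int]] = [
    (1, 1, 21756),
    (2, 5, 38429),
    (6, 9, 11642),
    (10, 19, 8528),
    (20, 49, 3271),
    (50, 99, 1223),
    (100, 199, 301),
    (200, 499, 22),
]

#: Recorded-population score moments (mean, SD) used to calibrate thresholds.
SCORE_TARGETS = {"MS": (3.05, 0.73), "MT": (1.97, 0.37)}

_DEFAULT_G0 = np.array([[0.02588, 0.00055], [0.00055, 0.00462]])
_DEFAULT_P0 = np.array([[0.21570, 0.01560], [0.01560, 0.05770]])


@dataclass(frozen=True)
class SizeDistribution:
    """Spec for sampling group sizes: constant, poisson, or empirical bins."""

    kind: str = "constant"  # {"constant", "poisson", "empirical"}
    value: float = 10.0  # constant size or poisson mean
    bins: tuple = ()  # (low, high, weight) triples for "empirical"

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            size = int(self.value)
            if size < 1:
                raise ConfigError("constant group size must be >= 1")
            return np.full(n, size)
        if self.kind == "poisson":
            if self.value <= 0:
                raise ConfigError("poisson mean must be positive")
            return np.maximum(rng.poisson(self.value, size=n), 1)
        if self.kind == "empirical":
            bins = list(self.bins)
            if not bins:
                raise ConfigError("empirical spec requires bins")
            weights = np.array([b[2] for b in bins], dtype=float)
            weights /= weights.sum()
            which = rng.choice(len(bins), size=n, p=weights)
            lows = np.array([b[0] for b in bins])[which]
            highs = np.array([b[1] for b in bins])[which]
            return rng.integers(lows, highs + 1)
        raise ConfigError(f"unknown size-distribution kind {self.kind!r}")

    @classmethod
    def half_sib_reference(cls) -> "SizeDistribution":
        return cls(kind="empirical", bins=tuple(HALF_SIB_SIZE_REFERENCE))

    @classmethod
    def hys_reference(cls) -> "SizeDistribution":
        return cls(kind="empirical", bins=tuple(HYS_SIZE_REFERENCE))


@dataclass(frozen=True)
class FixedEffectSpec:
    """Magnitudes of the simulated fixed effects, per trait (MS, MT).

    ``hys_sd`` is the SD of i.i.d. normal HYS effects, ``stage_effects`` an
    8 x 2 array over the eight 10-day lactation stages, and the two
    regression coefficients act on centred age at calving (days) and
    centred percent of HF genes.
    """

    trait_means: tuple[float, float] = (3.05, 1.97)
    hys_sd: tuple[float, float] = (0.20, 0.10)
    stage_effects: tuple = tuple(
        (round(x, 4), round(x / 2, 4)) for x in np.linspace(0.06, -0.06, 8)
    )
    age_coeff: tuple[float, float] = (0.0003, 0.0001)
    hf_coeff: tuple[float, float] = (0.002, 0.001)

    def stage_array(self) -> np.ndarray:
        arr = np.asarray(self.stage_effects, dtype=float)
        if arr.shape != (8, 2):
            raise ConfigError("stage_effects must be 8 x 2")
        return arr


def _check_spd(m: np.ndarray, name: str, allow_psd: bool = False) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2) or not np.allclose(m, m.T):
        raise ConfigError(f"{name} must be a symmetric 2x2 matrix")
    eig = np.linalg.eigvalsh(m)
    lo = -1e-10 if allow_psd else 1e-12
    if eig.min() < lo:
        raise ConfigError(f"{name} must be positive {'semi' if allow_psd else ''}definite")
    return m


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic population; defaults mirror the study.

    ``true_G0``/``true_R0`` are the 2x2 genetic and residual covariance
    matrices in trait order (MS, MT); the defaults are the pedigree-analysis
    posterior means (residual = phenotypic - genetic). ``ordinal_mode``
    discretizes latent phenotypes through thresholds calibrated to the
    recorded score moments; switching it off yields the latent-continuous
    model world used for parameter-recovery experiments.
    """

    n_sires: int = 300
    daughters_per_sire: SizeDistribution = SizeDistribution("constant", 15)
    n_herds: int = 45
    years: tuple[int, int] = (2010, 2012)
    hys_size_target: SizeDistribution = SizeDistribution("constant", 50)
    true_G0: tuple = tuple(map(tuple, _DEFAULT_G0))
    true_R0: tuple = tuple(map(tuple, _DEFAULT_P0 - _DEFAULT_G0))
    fixed_effect_spec: FixedEffectSpec = FixedEffectSpec()
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.01, 0.5)
    genotyped_fraction_of_sires: float = 0.2
    ordinal_mode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires < 1:
            raise ConfigError("n_sires must be >= 1")
        _check_spd(np.asarray(self.true_G0), "true_G0", allow_psd=True)
        _check_spd(np.asarray(self.true_R0), "true_R0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must sit within (0, 0.5]")
        if not 0.0 <= self.genotyped_fraction_of_sires <= 1.0:
            raise ConfigError("genotyped_fraction_of_sires must be in [0, 1]")

    @property
    def g0(self) -> np.ndarray:
        return np.asarray(self.true_G0, dtype=float)

    @property
    def r0(self) -> np.ndarray:
        return np.asarray(self.true_R0, dtype=float)

    def rng_for(self, stage: str) -> np.random.Generator:
        """Per-stage stream derived from the master seed (reproducible)."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage_key]))


@dataclass
class SyntheticPopulation:
    """A generated pedigree + records + genotypes bundle and its truth.

    ``latent`` holds the continuous phenotypes (n_cows x 2) before any
    discretization and ``breeding_values`` the simulated additive effects
    for every pedigree animal — truth side-channels for tests.
    """

    pedigree: Pedigree
    records: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: SimulationConfig
    latent: np.ndarray = None
    breeding_values: np.ndarray = None


# ----------------------------------------------------------------------
# pedigree


def generate_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Founder sires and dams plus half-sib daughter groups.

    Each sire receives a family of daughters whose size follows
    ``config.daughters_per_sire``; every daughter has her own unrelated
    founder dam. Parents precede offspring in the returned ordering.
    """
    rng = rng if rng is not None else config.rng_for("pedigree")
    sizes = config.daughters_per_sire.sample(config.n_sires, rng)
    n_cows = int(sizes.sum())
    sires = [f"S{i + 1:05d}" for i in range(config.n_sires)]
    dams = [f"D{i + 1:06d}" for i in range(n_cows)]
    cows = [f"C{i + 1:06d}" for i in range(n_cows)]
    cow_sire = np.repeat(np.arange(config.n_sires), sizes)
    animals = sires + dams + cows
    sire_col = [None] * (config.n_sires + n_cows) + [sires[j] for j in cow_sire]
    dam_col = [None] * (config.n_sires + n_cows) + dams
    return Pedigree(animals, sire_col, dam_col)


# ----------------------------------------------------------------------
# genotypes


def gene_drop(
    pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dosages for every pedigree animal by Mendelian gene dropping.

    Founder haplotypes are drawn per SNP with an ALT frequency uniform on
    ``maf_range``; each descendant inherits one uniformly chosen allele
    from each parent, independently per SNP (no linkage). Returns
    ``(dosages, founder_freqs)``.
    """
    if config.n_snps == 0:
        raise ConfigError("n_snps must be positive to simulate genotypes")
    rng = rng if rng is not None else config.rng_for("genotypes")
    n, m = len(pedigree), config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    hap = np.zeros((2, n, m), dtype=np.int8)
    s_idx, d_idx = pedigree.parent_indices()
    for i in range(n):
        si, di = s_idx[i], d_idx[i]
        for h, par in ((0, si), (1, di)):
            if par < 0:
                hap[h, i] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[h, i] = hap[pick, par, np.arange(m)]
    return hap.sum(axis=0), p


def generate_genotypes(
    pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Gene-dropped dosages restricted to the genotyped fraction of sires."""
    rng = rng if rng is not None else config.rng_for("genotypes")
    sires = sorted({s for s in pedigree.sires if s is not None})
    n_geno = int(round(config.genotyped_fraction_of_sires * len(sires)))
    snp_ids = [f"snp{j + 1}" for j in range(config.n_snps)]
    if n_geno == 0:
        return GenotypeMatrix([], snp_ids, np.zeros((0, config.n_snps), dtype=np.int8))
    chosen = sorted(rng.choice(sires, size=n_geno, replace=False))
    dosages, _ = gene_drop(pedigree, config, rng)
    rows = [pedigree.index_of(s) for s in chosen]
    return GenotypeMatrix(chosen, snp_ids, dosages[rows])


# ----------------------------------------------------------------------
# thresholds for ordinal scores


def _score_moments(cuts: np.ndarray, n_cats: int) -> tuple[float, float]:
    """Mean and SD of a score obtained by cutting a standard normal."""
    cdf = np.concatenate([[0.0], stats.norm.cdf(cuts), [1.0]])
    probs = np.diff(cdf)
    scores = np.arange(1, n_cats + 1)
    mean = float(probs @ scores)
    var = float(probs @ (scores - mean) ** 2)
    return mean, math.sqrt(var)


def fit_thresholds(n_cats: int, target_mean: float, target_sd: float) -> np.ndarray:
    """Equally spaced cutpoints on a standard-normal latent scale matching
    a target score mean and SD.

    Two free parameters (location and spacing) are solved against the two
    moment constraints; for three categories this parameterization spans
    all cutpoint pairs, for five it imposes equal spacing.
    """
    if n_cats < 2:
        raise ConfigError("need at least two score categories")
    offsets = np.arange(1, n_cats) - n_cats / 2.0

    def residual(params):
        loc, log_s = params
        cuts = loc + math.exp(log_s) * offsets
        mean, sd = _score_moments(cuts, n_cats)
        return [mean - target_mean, sd - target_sd]

    sol = optimize.root(residual, x0=[0.0, 0.0], method="hybr")
    if not sol.success or max(abs(np.array(residual(sol.x)))) > 1e-8:
        raise ConfigError(
            f"threshold calibration failed for {n_cats} categories "
            f"(mean {target_mean}, sd {target_sd})"
        )
    loc, log_s = sol.x
    return loc + math.exp(log_s) * offsets


# ----------------------------------------------------------------------
# phenotypes


def _sample_breeding_values(
    pedigree: Pedigree, g0: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exact draw of a ~ N(0, G0 (x) A) via the pedigree decomposition.

    Founders get a ~ N(0, G0); descendants get the parent average plus a
    Mendelian-sampling term with covariance D_i * G0.
    """
    n = len(pedigree)
    eigval, eigvec = np.linalg.eigh(g0)
    g_half = eigvec @ np.diag(np.sqrt(np.maximum(eigval, 0.0))) @ eigvec.T
    dvar = pedigree.mendelian_variances()
    s_idx, d_idx = pedigree.parent_indices()
    z = rng.standard_normal((n, 2)) @ g_half.T
    a = np.zeros((n, 2))
    for i in range(n):
        pa = np.zeros(2)
        if s_idx[i] >= 0:
            pa += 0.5 * a[s_idx[i]]
        if d_idx[i] >= 0:
            pa += 0.5 * a[d_idx[i]]
        a[i] = pa + math.sqrt(dvar[i]) * z[i]
    return a


_SUMMER_MONTHS = (4, 5, 6, 7, 8, 9)
_WINTER_MONTHS_SAME_YEAR = (10, 11, 12)


def _random_date(year: int, months: Sequence[int], rng: np.random.Generator) -> dt.date:
    month = int(rng.choice(months))
    day = int(rng.integers(1, 29))
    return dt.date(year, month, day)


def generate_phenotypes(
    pedigree: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> SyntheticPopulation:
    """Two-trait phenotype records for every cow in the pedigree.

    Cows (non-founder animals) are assigned to herd-year-season cells whose
    sizes follow ``hys_size_target``; calving dates fall inside the cell's
    season so the cell coincides with the analysis HYS subclass. Latent
    phenotypes follow y = Xb + Za + e under the configured truth; in
    ordinal mode they are standardized and cut at calibrated thresholds.
    """
    rng = rng if rng is not None else config.rng_for("phenotypes")
    g0 = _check_spd(config.g0, "true_G0", allow_psd=True)
    r0 = _check_spd(config.r0, "true_R0")
    spec = config.fixed_effect_spec

    bv = _sample_breeding_values(pedigree, g0, rng)
    founder = pedigree.is_founder()
    cow_idx = np.flatnonzero(~founder)
    n_cows = len(cow_idx)
    if n_cows == 0:
        raise ConfigError("pedigree contains no non-founder cows to phenotype")

    # --- herd-year-season cells ------------------------------------
    cells: list[tuple[str, int, str]] = []
    total = 0
    cell_sizes: list[int] = []
    while total < n_cows:
        size = int(config.hys_size_target.sample(1, rng)[0])
        herd = f"H{(len(cells) % config.n_herds) + 1:03d}"
        year = int(rng.integers(config.years[0], config.years[1] + 1))
        season = "summer" if rng.random() < 0.5 else "winter"
        cells.append((herd, year, season))
        cell_sizes.append(size)
        total += size
    assignment = np.repeat(np.arange(len(cells)), cell_sizes)[:n_cows]
    perm = rng.permutation(n_cows)
    cell_of_cow = assignment[perm]

    hys_eff = rng.standard_normal((len(cells), 2)) * np.array(spec.hys_sd)
    stage_eff = spec.stage_array()

    calving = np.empty(n_cows, dtype=object)
    herd_ids = np.empty(n_cows, dtype=object)
    for k, c in enumerate(cell_of_cow):
        herd, year, season = cells[c]
        months = _SUMMER_MONTHS if season == "summer" else _WINTER_MONTHS_SAME_YEAR
        calving[k] = _random_date(year, months, rng)
        herd_ids[k] = herd

    age_days = np.clip(rng.normal(790, 55, size=n_cows), 640, 1100).round().astype(int)
    dim_eval = rng.integers(15, 111, size=n_cows)
    dim_first_test = rng.integers(5, 36, size=n_cows)
    hf = np.clip(rng.normal(93.0, 6.0, size=n_cows), 50.0, 100.0).round(1)

    stage = np.where(
        (dim_eval >= 21) & (dim_eval <= 100), (dim_eval - 21) // 10, -1
    )
    fixed = np.array(spec.trait_means) + hys_eff[cell_of_cow]
    in_range = stage >= 0
    fixed[in_range] += stage_eff[stage[in_range]]
    age_c = age_days - age_days.mean()
    hf_c = hf - hf.mean()
    fixed += np.outer(age_c, np.array(spec.age_coeff))
    fixed += np.outer(hf_c, np.array(spec.hf_coeff))

    eigval, eigvec = np.linalg.eigh(r0)
    r_half = eigvec @ np.diag(np.sqrt(np.maximum(eigval, 0.0))) @ eigvec.T
    resid = rng.standard_normal((n_cows, 2)) @ r_half.T
    latent = fixed + bv[cow_idx] + resid

    if config.ordinal_mode:
        scores = np.empty((n_cows, 2))
        for t, (trait, n_cats) in enumerate((("MS", 5), ("MT", 3))):
            target_mean, target_sd = SCORE_TARGETS[trait]
            cuts = fit_thresholds(n_cats, target_mean, target_sd)
            z = (latent[:, t] - latent[:, t].mean()) / latent[:, t].std()
            scores[:, t] = np.digitize(z, cuts) + 1
        ms, mt = scores[:, 0], scores[:, 1]
    else:
        ms, mt = latent[:, 0], latent[:, 1]

    cow_ids = [pedigree.animals[i] for i in cow_idx]
    records = pd.DataFrame(
        {
            "cow_id": cow_ids,
            "sire_id": [pedigree.sires[i] or "0" for i in cow_idx],
            "dam_id": [pedigree.dams[i] or "0" for i in cow_idx],
            "birth_date": [c - dt.timedelta(days=int(a)) for c, a in zip(calving, age_days)],
            "calving_date": list(calving),
            "eval_date": [c + dt.timedelta(days=int(d)) for c, d in zip(calving, dim_eval)],
            "first_test_date": [
                c + dt.timedelta(days=int(d)) for c, d in zip(calving, dim_first_test)
            ],
            "herd_id": herd_ids,
            "hf_percent": hf,
            "ms_score": ms,
            "mt_score": mt,
        }
    )

    if genotypes is None:
        if config.n_snps > 0 and config.genotyped_fraction_of_sires > 0:
            genotypes = generate_genotypes(pedigree, config)
        else:
            genotypes = GenotypeMatrix(
                [], [f"snp{j + 1}" for j in range(max(config.n_snps, 0))],
                np.zeros((0, max(config.n_snps, 0)), dtype=np.int8),
            )
    return SyntheticPopulation(
        pedigree=pedigree,
        records=records,
        genotypes=genotypes,
        truth=config,
        latent=latent,
        breeding_values=bv,
    )


def simulate_population(config: SimulationConfig) -> SyntheticPopulation:
    """Pedigree, genotypes and phenotypes in one reproducible call."""
    pedigree = generate_pedigree(config)
    if config.n_snps > 0 and config.genotyped_fraction_of_sires > 0:
        genotypes = generate_genotypes(pedigree, config)
    else:
        genotypes = GenotypeMatrix(
            [], [f"snp{j + 1}" for j in range(max(config.n_snps, 0))],
            np.zeros((0, max(config.n_snps, 0)), dtype=np.int8),
        )
    return generate_phenotypes(pedigree, config, genotypes=genotypes)
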