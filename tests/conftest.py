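import datetime as dt

import numpy as np
import pandas as pd
import pytest

from workability.pedigree import Pedigree
from workability.simulate import (
    FixedEffectSpec,
    SimulationConfig,
    SizeDistribution,
    generate_pedigree,
    generate_phenotypes,
)


def make_record(
    cow_id="C1",
    sire_id="S1",
    dam_id="D1",
    herd_id="H1",
    calving=dt.date(2012, 5, 1),
    dim_eval=40,
    dim_first_test=10,
    age_days=780,
    hf=95.0,
    ms=3,
    mt=2,
) -> dict:
    calving = pd.Timestamp(calving)
    return {
        "cow_id": cow_id,
        "sire_id": sire_id,
        "dam_id": dam_id,
        "birth_date": calving - pd.Timedelta(days=age_days),
        "calving_date": calving,
        "eval_date": calving + pd.Timedelta(days=dim_eval),
        "first_test_date": calving + pd.Timedelta(days=dim_first_test),
        "herd_id": herd_id,
        "hf_percent": hf,
        "ms_score": ms,
        "mt_score": mt,
    }


def random_pedigree(rng: np.random.Generator, n: int = 40) -> Pedigree:
    """Arbitrary valid pedigree: parents drawn among earlier animals."""
    animals = [f"A{i}" for i in range(n)]
    sires, dams = [], []
    for i in range(n):
        if i < 4 or rng.random() < 0.25:
            sires.append(None)
            dams.append(None)
            continue
        s = f"A{rng.integers(0, i)}" if rng.random() < 0.9 else None
        d = f"A{rng.integers(0, i)}" if rng.random() < 0.9 else None
        if s is not None and s == d:
            d = None
        sires.append(s)
        dams.append(d)
    return Pedigree(animals, sires, dams)


@pytest.fixture(scope="session")
def small_population():
    """60 sires x 8 daughters, ordinal scores, genotyped sires."""
    config = SimulationConfig(
        n_sires=60,
        daughters_per_sire=SizeDistribution("constant", 8),
        n_herds=12,
        years=(2011, 2012),
        hys_size_target=SizeDistribution("constant", 25),
        n_snps=300,
        genotyped_fraction_of_sires=0.5,
        seed=7,
    )
    pedigree = generate_pedigree(config)
    return generate_phenotypes(pedigree, config)


@pytest.fixture(scope="session")
def latent_population():
    """Latent-continuous phenotypes with no fixed-effect noise beyond HYS."""
    spec = FixedEffectSpec(
        hys_sd=(0.15, 0.08),
        stage_effects=tuple((0.0, 0.0) for _ in range(8)),
        age_coeff=(0.0, 0.0),
        hf_coeff=(0.0, 0.0),
    )
    config = SimulationConfig(
        n_sires=80,
        daughters_per_sire=SizeDistribution("constant", 10),
        n_herds=10,
        years=(2011, 2011),
        hys_size_target=SizeDistribution("constant", 40),
        fixed_effect_spec=spec,
        n_snps=0,
        genotyped_fraction_of_sires=0.0,
        ordinal_mode=False,
        seed=11,
    )
    pedigree = generate_pedigree(config)
    return generate_phenotypes(pedigree, config)
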