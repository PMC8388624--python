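"""Data structuring for workability records.

Reproduces the preparation applied to the national recording extract:
herd-year-season (HYS) contemporary groups, eight 10-day lactation stages
over days 21-100, the filter cascade producing the working dataset
(day-in-milk window, 26-day gap to the first test milking, removal of
herds without score variation), the sire-sampled / HYS-pruned estimation
subset, and the descriptive tables (group-size distributions, per-birth-
year score statistics).

Records are handled as pandas DataFrames with the documented phenotype
schema; see ``workability.io`` for the CSV reader that validates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "HYSKey",
    "assign_hys",
    "assign_lactation_stage",
    "days_in_milk",
    "apply_filters",
    "build_dataset_b",
    "group_distributions",
    "descriptive_stats",
    "SIZE_CLASS_BINS",
    "distribution_total",
]

#: Size-class bins used for both the half-sib and the HYS distribution
#: tables: 1, 2-5, 6-9, 10-19, 20-49, ... (upper bin open).
SIZE_CLASS_BINS: list[tuple[int, float]] = [
    (1, 1),
    (2, 5),
    (6, 9),
    (10, 19),
    (20, 49),
    (50, 99),
    (100, 199),
    (200, 499),
    (500, 999),
    (1000, 1999),
    (2000, 4999),
    (5000, 9999),
    (10000, math.inf),
]


class HYSKey(NamedTuple):
    """Herd-year-season of calving; summer = April-September calvings."""

    herd_id: str
    year: int
    season: str


class PrepError(ValueError):
    pass


def _as_date(x) -> pd.Timestamp:
    ts = pd.Timestamp(x)
    if pd.isna(ts):
        raise PrepError("missing date")
    return ts


def assign_hys(calving_date, herd_id: str) -> HYSKey:
    """HYS subclass of a record: calving calendar year + summer/winter season."""
    ts = _as_date(calving_date)
    season = "summer" if 4 <= ts.month <= 9 else "winter"
    return HYSKey(str(herd_id), int(ts.year), season)


def days_in_milk(eval_date, calving_date) -> int:
    """Day of lactation at evaluation, counting the calving day as day 0."""
    d = (_as_date(eval_date) - _as_date(calving_date)).days
    if d < 0:
        raise PrepError("evaluation date precedes calving date")
    return int(d)


def assign_lactation_stage(eval_date, calving_date) -> int | None:
    """Stage 1-8 for days in milk 21-100 (10-day bins), else None."""
    d = days_in_milk(eval_date, calving_date)
    if 21 <= d <= 100:
        return (d - 21) // 10 + 1
    return None


def add_assignments(records: pd.DataFrame) -> pd.DataFrame:
    """Attach hys (string key), dim and stage columns to a record frame."""
    out = records.copy()
    calving = pd.to_datetime(out["calving_date"])
    evald = pd.to_datetime(out["eval_date"])
    out["dim"] = (evald - calving).dt.days
    month = calving.dt.month
    season = np.where((month >= 4) & (month <= 9), "summer", "winter")
    out["hys"] = (
        out["herd_id"].astype(str)
        + "/"
        + calving.dt.year.astype(str)
        + "/"
        + season
    )
    stage = (out["dim"] - 21) // 10 + 1
    out["stage"] = stage.where((out["dim"] >= 21) & (out["dim"] <= 100)).astype("Int64")
    return out


@dataclass
class FilterResult:
    kept: pd.DataFrame
    removed: dict[str, int]


def apply_filters(records: pd.DataFrame) -> FilterResult:
    """The working-dataset filter cascade, applied in order.

    1. ``day_window`` — evaluation must fall on days 21-100 of lactation
       (stage-assignable; later than day 100 or before the stage window is
       dropped).
    2. ``first_test_gap`` — evaluation at least 26 days after the first
       test milking.
    3. ``herd_variance`` — herds where either score shows zero sample
       variance are removed entirely.

    Returns the kept records plus per-rule removal counts.
    """
    removed: dict[str, int] = {}
    if len(records) == 0:
        return FilterResult(records.copy(), {"day_window": 0, "first_test_gap": 0, "herd_variance": 0})
    df = add_assignments(records)

    ok = df["stage"].notna()
    removed["day_window"] = int((~ok).sum())
    df = df[ok]

    gap = (pd.to_datetime(df["eval_date"]) - pd.to_datetime(df["first_test_date"])).dt.days
    ok = gap >= 26
    removed["first_test_gap"] = int((~ok).sum())
    df = df[ok]

    herd_var = df.groupby("herd_id")[["ms_score", "mt_score"]].var(ddof=1)
    bad_herds = herd_var.index[
        (herd_var["ms_score"].fillna(0) == 0) | (herd_var["mt_score"].fillna(0) == 0)
    ]
    ok = ~df["herd_id"].isin(bad_herds)
    removed["herd_variance"] = int((~ok).sum())
    df = df[ok]

    return FilterResult(df.reset_index(drop=True), removed)


def build_dataset_b(
    records: pd.DataFrame,
    sire_fraction: float = 0.10,
    min_hys: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimation subset: daughters of a random sire sample, large HYS only.

    ``ceil(sire_fraction * n_distinct_sires)`` sires are drawn without
    replacement; records of other sires are dropped, then HYS subclasses
    with fewer than ``min_hys`` remaining cows are removed (sample first,
    prune second).
    """
    sires = sorted(s for s in records["sire_id"].astype(str).unique() if s not in ("0", "nan"))
    if not sires:
        raise PrepError("no known sires in the record set")
    n_pick = math.ceil(sire_fraction * len(sires))
    if n_pick < 1:
        raise PrepError("sire_fraction selects no sires")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(sires, size=n_pick, replace=False))
    df = records[records["sire_id"].astype(str).isin(chosen)]
    df = add_assignments(df)
    sizes = df.groupby("hys")["cow_id"].transform("size")
    df = df[sizes >= min_hys]
    return df.drop(columns=["dim", "hys", "stage"]).reset_index(drop=True)


def _bin_label(lo: int, hi: float) -> str:
    if lo == hi:
        return str(lo)
    if math.isinf(hi):
        return f"{lo}+"
    return f"{lo}-{hi:.0f}"


def _size_table(sizes: pd.Series) -> pd.DataFrame:
    rows = []
    for lo, hi in SIZE_CLASS_BINS:
        count = int(((sizes >= lo) & (sizes <= hi)).sum())
        rows.append({"size_class": _bin_label(lo, hi), "count": count})
    rows.append({"size_class": "Total", "count": int(len(sizes))})
    return pd.DataFrame(rows)


def distribution_total(table: pd.DataFrame) -> int:
    """Sum of the size-class counts (excluding the Total row)."""
    body = table[table["size_class"] != "Total"]
    return int(body["count"].sum())


def group_distributions(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Size-class tables of half-sib groups and HYS subclasses.

    Cows with an unknown sire count as singleton half-sib groups.
    """
    sire = records["sire_id"].astype(str)
    known = sire[~sire.isin(["0", "nan", ""])]
    group_sizes = known.value_counts()
    n_singletons = len(records) - len(known)
    half_sib = pd.concat([group_sizes, pd.Series(np.ones(n_singletons, dtype=int))])
    df = add_assignments(records)
    hys_sizes = df.groupby("hys")["cow_id"].size()
    return _size_table(half_sib), _size_table(hys_sizes)


def descriptive_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Score statistics (N, mean, SD, CV%) per birth year and overall.

    SD uses the n-1 denominator; CV = 100 * SD / mean. Values are reported
    unrounded; the reporting layer rounds means/SDs to two decimals.
    """
    df = records.copy()
    df["birth_year"] = pd.to_datetime(df["birth_date"]).dt.year
    rows = []

    def stats_for(sub: pd.DataFrame, label) -> dict:
        row = {"group": label, "n": len(sub)}
        for trait, col in (("MS", "ms_score"), ("MT", "mt_score")):
            mean = sub[col].mean()
            sd = sub[col].std(ddof=1) if len(sub) > 1 else 0.0
            row[f"{trait.lower()}_mean"] = mean
            row[f"{trait.lower()}_sd"] = sd
            row[f"{trait.lower()}_cv"] = 100.0 * sd / mean if mean > 0 else np.nan
        return row

    for year, sub in df.groupby("birth_year"):
        rows.append(stats_for(sub, int(year)))
    rows.append(stats_for(df, "Total"))
    return pd.DataFrame(rows)
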