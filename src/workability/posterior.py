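"""Posterior summaries and derived genetic parameters.

From a chain of (G0, R0) draws this module derives, per sample,

    P0   = G0 + R0                       (phenotypic covariance)
    h2_t = G0[t,t] / P0[t,t]             (heritability)
    r_g  = G0[0,1] / sqrt(G0[0,0] G0[1,1])
    r_p  = P0[0,1] / sqrt(P0[0,0] P0[1,1])

and summarizes every scalar chain by its posterior mean, Monte Carlo
standard error (batch means with floor(sqrt(n)) batches), 95% highest
posterior density interval (shortest interval containing the requested
mass) and Geweke convergence z-score (first 10% vs last 50% of the chain,
variances from spectral densities at frequency zero estimated through an
AIC-selected autoregressive fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gibbs import CovarianceSample

__all__ = [
    "PosteriorSummary",
    "derive_params",
    "hpd",
    "mce",
    "geweke",
    "summarize",
    "format_report",
]


class PosteriorError(ValueError):
    pass


@dataclass
class PosteriorSummary:
    parameter: str
    mean: float
    mce: float
    hpd_low: float
    hpd_high: float
    geweke_z: float


def _coerce_samples(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        g, r = samples
        return np.asarray(g, dtype=float), np.asarray(r, dtype=float)
    sample_list = list(samples)
    if not sample_list:
        raise PosteriorError("empty chain")
    if isinstance(sample_list[0], CovarianceSample):
        g = np.array([s.G0 for s in sample_list], dtype=float)
        r = np.array([s.R0 for s in sample_list], dtype=float)
        return g, r
    raise PosteriorError("expected CovarianceSample list or (G0, R0) arrays")


def derive_params(
    samples: "Iterable[CovarianceSample] | tuple[np.ndarray, np.ndarray]",
    trait_names: Sequence[str] = ("MS", "MT"),
) -> pd.DataFrame:
    """Per-sample heritabilities and genetic/phenotypic correlations.

    Samples with a zero variance in any denominator are excluded; the
    number excluded is reported in ``frame.attrs['n_excluded']``.
    """
    g, r = _coerce_samples(samples)
    if g.ndim == 2:
        g, r = g[None, ...], r[None, ...]
    p = g + r
    ok = (
        (np.diagonal(g, axis1=1, axis2=2) > 0).all(axis=1)
        & (np.diagonal(p, axis1=1, axis2=2) > 0).all(axis=1)
    )
    n_excluded = int((~ok).sum())
    g, p = g[ok], p[ok]
    if len(g) == 0:
        raise PosteriorError("all samples excluded (zero variances)")
    out = {}
    t = g.shape[1]
    for i in range(t):
        out[f"h2_{trait_names[i]}"] = g[:, i, i] / p[:, i, i]
    if t >= 2:
        out["r_g"] = g[:, 0, 1] / np.sqrt(g[:, 0, 0] * g[:, 1, 1])
        out["r_p"] = p[:, 0, 1] / np.sqrt(p[:, 0, 0] * p[:, 1, 1])
    frame = pd.DataFrame(out)
    frame.attrs["n_excluded"] = n_excluded
    return frame


def hpd(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise PosteriorError("need at least 20 samples for an HPD interval")
    if not 0.0 < mass <= 1.0:
        raise PosteriorError("mass must be in (0, 1]")
    m = math.ceil(mass * n)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def mce(samples: np.ndarray) -> float:
    """Batch-means Monte Carlo standard error with floor(sqrt(n)) batches."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 100:
        raise PosteriorError("need at least 100 samples for a batch-means MCE")
    n_batches = int(math.isqrt(n))
    length = n // n_batches
    trimmed = x[n - n_batches * length :]
    means = trimmed.reshape(n_batches, length).mean(axis=1)
    if np.allclose(means, means[0]):
        return 0.0
    return float(means.std(ddof=1) / math.sqrt(n_batches))


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    if np.allclose(x, x[0]):
        return 0.0
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    max_lag = max(1, min(20, len(x) // 10))
    try:
        sel = ar_select_order(x, maxlag=max_lag, ic="aic", old_names=False)
        lags = sel.ar_lags or []
    except (ValueError, np.linalg.LinAlgError):
        lags = []
    if not lags:
        return float(np.var(x, ddof=1))
    res = AutoReg(x, lags=lags, old_names=False).fit()
    phi_sum = float(np.sum(res.params[1:]))
    sigma2 = float(res.sigma2)
    denom = (1.0 - phi_sum) ** 2
    if denom <= 1e-12:
        return float(np.var(x, ddof=1))
    return sigma2 / denom


def geweke(samples: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score between early and late chain segments."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 200:
        raise PosteriorError("need at least 200 samples for the Geweke diagnostic")
    n1 = int(first * n)
    n2 = int(last * n)
    seg1, seg2 = x[:n1], x[n - n2 :]
    var1 = _spectrum0(seg1) / n1
    var2 = _spectrum0(seg2) / n2
    diff = seg1.mean() - seg2.mean()
    denom = math.sqrt(var1 + var2)
    if denom == 0.0:
        return 0.0
    return float(diff / denom)


def summarize(
    chain: pd.DataFrame,
    hpd_mass: float = 0.95,
    derived: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Posterior summary table for every scalar column of a chain frame.

    ``derived`` (e.g. from :func:`derive_params`) is appended so reported
    heritabilities/correlations carry their own MCE and HPD bounds,
    computed on the per-sample derived chain.
    """
    frames = [chain.drop(columns=["iteration"], errors="ignore")]
    if derived is not None:
        frames.append(derived.reset_index(drop=True))
    table = pd.concat(frames, axis=1)
    rows = []
    for col in table.columns:
        x = table[col].to_numpy(float)
        lo, hi = hpd(x, hpd_mass)
        rows.append(
            PosteriorSummary(
                parameter=col,
                mean=float(x.mean()),
                mce=mce(x),
                hpd_low=lo,
                hpd_high=hi,
                geweke_z=geweke(x),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


_COMPONENT_FMT = "{:.5f}"
_PARAM_FMT = "{:.2f}"


def format_report(summary: pd.DataFrame, title: str = "Posterior summary") -> str:
    """Human-readable report: covariance components to 5 d.p. (genetic and
    phenotypic blocks), derived parameters to 2 d.p. with MCE in
    parentheses."""
    lines = [title, "=" * len(title), ""]
    comp = summary[summary["parameter"].str.startswith(("sigma2_", "cov_"))]
    derived = summary[~summary["parameter"].isin(comp["parameter"])]
    if len(comp):
        lines.append(f"{'parameter':<22}{'mean':>10}{'MCE':>10}{'HPD low':>11}{'HPD high':>11}{'Geweke z':>10}")
        for _, row in comp.iterrows():
            lines.append(
                f"{row['parameter']:<22}"
                f"{_COMPONENT_FMT.format(row['mean']):>10}"
                f"{row['mce']:>10.4f}"
                f"{_COMPONENT_FMT.format(row['hpd_low']):>11}"
                f"{_COMPONENT_FMT.format(row['hpd_high']):>11}"
                f"{row['geweke_z']:>10.2f}"
            )
        lines.append("")
    for _, row in derived.iterrows():
        lines.append(
            f"{row['parameter']:<8} = "
            f"{_PARAM_FMT.format(row['mean'])} (+/-{row['mce']:.4f})  "
            f"HPD95 [{row['hpd_low']:.3f}, {row['hpd_high']:.3f}]  "
            f"Geweke z = {row['geweke_z']:.2f}"
        )
    return "\n".join(lines) + "\n"
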