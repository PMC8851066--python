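"""Pooling of aggregated regional estimates, homogeneity tests, heterogeneity
(I-squared) and the standardised mortality ratio with exact Poisson CI.

Regional estimates are pooled on the aggregate scale (summed numerators over
summed denominators). Homogeneity across regions is tested with the k-sample
chi-square test on the 2 x k count table for proportions, and with one-way
ANOVA (reconstructed from per-region n/mean/sd summaries) for means.
Between-region heterogeneity is quantified as Higgins' I-squared,
``I2 = max(0, (Q - df) / Q) * 100``, where Q is the chi-square statistic for
proportions and, for means, the inverse-variance-weighted sum of squared
deviations from the weighted mean (meta-analytic Q); an ANOVA-based variant
``max(0, (F - 1) / F) * 100`` is available as an option.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .model import age_band

__all__ = ["PooledResult", "SMRResult", "pool_and_test", "smr", "expected_deaths",
           "poisson_exact_ci"]


@dataclasses.dataclass(frozen=True)
class PooledResult:
    indicator_id: str
    cohort: str
    statistic: str
    pooled_estimate: float
    regional_estimates: dict
    Q: float
    df: int
    p_homogeneity: float
    I2: float
    anova_F: float = float("nan")


@dataclasses.dataclass(frozen=True)
class SMRResult:
    observed: int
    expected: float
    smr: float
    ci95: tuple[float, float]


def _i2(Q: float, df: int) -> float:
    if not np.isfinite(Q) or Q <= 0 or df < 1:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def pool_and_test(estimates: pd.DataFrame, i2_from: str = "Q") -> PooledResult:
    """Pool one indicator's regional estimates and test homogeneity.

    ``estimates`` holds one row per region with columns ``region, indicator_id,
    cohort, statistic, numerator, denominator, estimate, se`` (as produced by
    :func:`quadim.indicators.compute_indicators`). Rows with undefined
    estimates are dropped; with fewer than two defined regions the pooled
    estimate is returned with heterogeneity fields undefined (NaN).

    ``i2_from``: for mean-type indicators, "Q" (default) derives I2 from the
    meta-analytic Q; "anova" uses max(0, (F-1)/F) * 100.
    """
    e = estimates.dropna(subset=["estimate"]).copy()
    if e.empty:
        raise ValueError("no defined regional estimates to pool")
    ind = str(e["indicator_id"].iloc[0])
    cohort = str(e["cohort"].iloc[0])
    statistic = str(e["statistic"].iloc[0])
    regional = dict(zip(e["region"], e["estimate"]))

    num = e["numerator"].to_numpy(dtype=float)
    den = e["denominator"].to_numpy(dtype=float)
    pooled = float(num.sum() / den.sum()) if den.sum() > 0 else float("nan")

    k = len(e)
    if k < 2:
        return PooledResult(ind, cohort, statistic, pooled, regional,
                            float("nan"), 0, float("nan"), float("nan"))

    if statistic in ("proportion", "admission_proportion"):
        table = np.vstack([num, den - num])
        # drop all-zero columns (empty regions) for the test
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            Q, p, df = float("nan"), float("nan"), 0
        else:
            chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
            Q = float(chi2)
        return PooledResult(ind, cohort, statistic, pooled, regional, Q, int(df),
                            float(p), _i2(Q, df))

    # mean-type indicators: one-way ANOVA from per-region summaries
    n = den
    mean = e["estimate"].to_numpy(dtype=float)
    se = e["se"].to_numpy(dtype=float)
    sd = se * np.sqrt(n)
    grand = float((n * mean).sum() / n.sum())
    ss_between = float((n * (mean - grand) ** 2).sum())
    df_b = k - 1
    ss_within = float(((n - 1) * sd**2).sum())
    df_w = float(n.sum() - k)
    if df_w <= 0 or ss_within <= 0:
        F, p = float("nan"), float("nan")
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    valid = np.isfinite(se) & (se > 0)
    if valid.sum() >= 2:
        w = 1.0 / se[valid] ** 2
        xw = float((w * mean[valid]).sum() / w.sum())
        Q = float((w * (mean[valid] - xw) ** 2).sum())
        df_q = int(valid.sum()) - 1
    else:
        Q, df_q = float("nan"), 0
    if i2_from == "anova":
        i2 = max(0.0, (F - 1.0) / F) * 100.0 if np.isfinite(F) and F > 0 else 0.0
    else:
        i2 = _i2(Q, df_q)
    return PooledResult(ind, cohort, statistic, pooled, regional, Q, df_q,
                        p, i2, anova_F=float(F))


# ---------------------------------------------------------------------------
# SMR


def poisson_exact_ci(observed: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) CI for a Poisson count via chi-square quantiles."""
    alpha = 1.0 - level
    o = int(observed)
    low = 0.0 if o == 0 else float(stats.chi2.ppf(alpha / 2, 2 * o) / 2.0)
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * o + 2) / 2.0)
    return low, high


def expected_deaths(members: pd.DataFrame, population_rates: pd.DataFrame) -> float:
    """Expected deaths: patients per (sex, 5-year band) x general-population rate."""
    bands = age_band(members["age_at_index"].to_numpy())
    counts = pd.DataFrame({"sex": members["sex"].values, "age_band": bands}) \
        .value_counts().rename("n").reset_index()
    merged = counts.merge(population_rates, on=["sex", "age_band"], how="left")
    if merged["rate"].isna().any():
        missing = merged.loc[merged["rate"].isna(), ["sex", "age_band"]]
        raise ValueError(f"population_rates missing strata: {missing.to_records(index=False).tolist()}")
    return float((merged["n"] * merged["rate"]).sum())


def smr(observed: int, expected: float, level: float = 0.95) -> SMRResult:
    """Standardised mortality ratio with exact Poisson CI on observed deaths."""
    if expected <= 0:
        raise ValueError("expected deaths must be positive")
    lo, hi = poisson_exact_ci(observed, level)
    return SMRResult(int(observed), float(expected), observed / expected,
                     (lo / expected, hi / expected))
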