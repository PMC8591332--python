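"""Diversity landscape summaries: group means, X/A ratios, regressions.

Pooled diversity per population / chromosome / region / feature is the
informative-site-weighted mean of per-unit values, with dispersion from
bootstrapping units (100 iterations by default).  X/autosome ratios carry a
propagated standard deviation sd = sqrt(sd_A^2/A^2 + sd_X^2/X^2) * (X/A).
Chromosome-level and NB-vs-B regressions are ordinary least squares,
reporting the slope ("predictor"), R^2 and the two-sided p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from driftscape._rand import as_seedseq
from driftscape.diversity import bootstrap_sd, skew_S, weighted_mean

__all__ = [
    "RatioWithSD",
    "RegressionResult",
    "xa_ratio",
    "group_summary",
    "regress",
    "regress_nb_vs_b",
]


@dataclass
class RatioWithSD:
    ratio: float
    sd: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def xa_ratio(x_stat: float, x_sd: float, a_stat: float, a_sd: float) -> RatioWithSD:
    """X/A diversity ratio with uncertainty propagation.

    sd = sqrt(sd_A^2 / A^2 + sd_X^2 / X^2) * (X / A).  At neutral
    mutation-drift equilibrium the expectation is 0.75 (hemizygous X at 3/4
    the autosomal effective size).
    """
    if a_stat == 0:
        raise ZeroDivisionError("autosomal statistic is zero")
    ratio = x_stat / a_stat
    sd = np.sqrt((a_sd / a_stat) ** 2 + (x_sd / x_stat) ** 2) * ratio \
        if x_stat != 0 else np.nan
    return RatioWithSD(ratio=float(ratio), sd=float(sd))


def group_summary(
    unit_div: pd.DataFrame,
    by: str,
    n_boot: int = 100,
    seed=None,
) -> pd.DataFrame:
    """Pooled pi, theta_W and S per group with bootstrap SDs.

    ``unit_div`` is a unit-diversity table (pi, theta_w, weight plus the
    grouping column); groups are chromosome, region_class or feature_class.
    Empty or single-unit-free groups are omitted with a warning.  S is
    computed from the pooled pi and theta_W, and its bootstrap SD from
    jointly resampled units.
    """
    rows = []
    ss = as_seedseq(seed)
    for (label, grp), child in zip(unit_div.groupby(by), ss.spawn(
            unit_div[by].nunique())):
        if len(grp) < 2:
            warnings.warn(f"group {label!r} has <2 units; omitted")
            continue
        w = grp["weight"].to_numpy(dtype=float)
        pi = weighted_mean(grp["pi"], w)
        th = weighted_mean(grp["theta_w"], w)
        rng = np.random.default_rng(child)
        idx = rng.integers(0, len(grp), size=(n_boot, len(grp)))
        pv = grp["pi"].to_numpy()[idx]
        tv = grp["theta_w"].to_numpy()[idx]
        wv = w[idx]
        pi_b = np.sum(pv * wv, axis=1) / np.sum(wv, axis=1)
        th_b = np.sum(tv * wv, axis=1) / np.sum(wv, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s_b = np.where(th_b > 0, 1.0 - pi_b / th_b, np.nan)
        s_b = s_b[~np.isnan(s_b)]
        s_sd = float(np.std(s_b)) if s_b.size >= 2 else float("nan")
        rows.append(
            {
                by: label,
                "pi": pi,
                "pi_sd": float(np.std(pi_b)),
                "theta_w": th,
                "theta_sd": float(np.std(th_b)),
                "S": skew_S(pi, th),
                "S_sd": s_sd,
                "weight": int(w.sum()),
                "n_units": len(grp),
            }
        )
    return pd.DataFrame(rows)


def pooled_summary(unit_div: pd.DataFrame, n_boot: int = 100, seed=None) -> dict:
    """Global pooled pi/theta/S with bootstrap SDs over all units."""
    w = unit_div["weight"].to_numpy(dtype=float)
    pi = weighted_mean(unit_div["pi"], w)
    th = weighted_mean(unit_div["theta_w"], w)
    ss = as_seedseq(seed).spawn(2)
    return {
        "pi": pi,
        "pi_sd": bootstrap_sd(unit_div["pi"], w, n_iter=n_boot, seed=ss[0]),
        "theta_w": th,
        "theta_sd": bootstrap_sd(unit_div["theta_w"], w, n_iter=n_boot,
                                 seed=ss[1]),
        "S": skew_S(pi, th),
        "weight": float(w.sum()),
        "n_units": int(len(unit_div)),
    }


def regress(x, y) -> RegressionResult:
    """OLS of y on x: slope, intercept, R^2, two-sided p, n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least three paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    if np.ptp(y) == 0:
        # flat response: slope 0, nothing explained
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def regress_nb_vs_b(
    nb_div: pd.DataFrame,
    b_div: pd.DataFrame,
    statistic: str = "pi",
    by: str = "region_class",
    min_units: int = 3,
) -> pd.DataFrame:
    """Per-region OLS of B diversity on NB diversity over shared units.

    The flatter and weaker (lower slope/R^2) the relationship, the more the
    bottleneck has reshuffled the diversity landscape.  Regions with fewer
    than ``min_units`` shared units are omitted.
    """
    merged = nb_div.merge(
        b_div[["unit_id", statistic]], on="unit_id", suffixes=("_nb", "_b")
    )
    rows = []
    for label, grp in merged.groupby(by):
        if len(grp) < min_units:
            continue
        try:
            fit = regress(grp[f"{statistic}_nb"], grp[f"{statistic}_b"])
        except ValueError:
            continue
        rows.append(
            {
                by: label,
                "statistic": statistic,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
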