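"""Per-site and per-unit diversity estimators.

Estimators are count-based on called genotypes: per-site nucleotide
diversity pi is the unbiased pairwise-difference estimator
``2 * ref * alt / (n * (n - 1))`` and per-site Watterson theta is
``1 / a_{n-1}`` at segregating sites, with ``a_k`` the harmonic number
``sum_{i=1..k} 1/i``.  The haploid sample size ``n`` is taken per site, so
missingness (and male hemizygosity on the X) is handled exactly.  Invariant
sites contribute 0; per-unit values are means over informative sites only,
and pooled summaries weight units by their informative-site counts.

The skew statistic ``S = 1 - pi/theta_W`` is positive when rare variants are
in excess over the neutral mutation-drift equilibrium expectation (e.g.
under purifying selection or population growth) and negative when
intermediate-frequency variants dominate (e.g. after a bottleneck).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from driftscape.panel import FEMALE, MALE, GenotypePanel, SiteCountsArrays

__all__ = [
    "harmonic_number",
    "site_pi",
    "site_theta_w",
    "skew_S",
    "weighted_mean",
    "bootstrap_sd",
    "x_effective_hap_n",
    "nearly_neutral_threshold",
    "unit_diversity_table",
    "exclude_par",
    "UnitDiversity",
]


@dataclass
class UnitDiversity:
    """Per-unit diversity: per-site pi, theta_W, skew S (NaN when theta_W=0)
    and the informative-site count used as pooling weight."""

    unit_id: str
    pi: float
    theta_w: float
    S: float
    weight: int


def harmonic_number(n) -> np.ndarray | float:
    """H_n = sum_{i=1}^{n} 1/i (H_0 = 0), elementwise."""
    n = np.asarray(n)
    nmax = int(n.max()) if n.size else 0
    table = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, nmax + 1))])
    out = table[n]
    return float(out) if out.ndim == 0 else out


def site_pi(ref, alt):
    """Unbiased per-site pairwise diversity 2*ref*alt/(n*(n-1)).

    ``n = ref + alt`` non-missing haploid calls; requires n >= 2.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    n = ref + alt
    if np.any(n < 2):
        raise ValueError("site_pi requires at least two haploid calls")
    out = 2.0 * ref * alt / (n * (n - 1.0))
    return float(out) if out.ndim == 0 else out


def site_theta_w(ref, alt):
    """Per-site Watterson theta: 1/a_{n-1} if segregating else 0."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    n = ref + alt
    if np.any(n < 2):
        raise ValueError("site_theta_w requires at least two haploid calls")
    a = harmonic_number(np.asarray(n) - 1)
    seg = (ref > 0) & (alt > 0)
    out = np.where(seg, 1.0 / np.asarray(a), 0.0)
    return float(out) if out.ndim == 0 else out


def skew_S(pi, theta_w):
    """SFS skew S = 1 - pi/theta_W; NaN where theta_W = 0 (undefined)."""
    pi = np.asarray(pi, dtype=float)
    theta_w = np.asarray(theta_w, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(theta_w > 0, 1.0 - pi / theta_w, np.nan)
    return float(out) if out.ndim == 0 else out


def weighted_mean(values, weights) -> float:
    """sum(v*w)/sum(w), ignoring NaN values (their weight is dropped too)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_mean of empty input")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    keep = ~np.isnan(values)
    if not keep.any():
        raise ValueError("weighted_mean: all values are NaN")
    return float(np.sum(values[keep] * weights[keep]) / np.sum(weights[keep]))


def bootstrap_sd(values, weights, n_iter: int = 100, seed=None) -> float:
    """SD of the weighted mean under bootstrap resampling of units.

    Units are resampled with replacement (same count) ``n_iter`` times; the
    returned value is the standard deviation of the resampled weighted means.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap_sd needs at least two units")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(int(n_iter), values.size))
    v = values[idx]
    w = weights[idx]
    w = np.where(np.isnan(v), 0.0, w)
    means = np.nansum(v * w, axis=1) / np.sum(w, axis=1)
    return float(np.std(means))


def x_effective_hap_n(sex) -> int:
    """Haploid sample size on the X: 2 per female + 1 per hemizygous male."""
    sex = np.asarray(sex, dtype="<U1")
    bad = set(sex) - {MALE, FEMALE}
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    return int(2 * np.sum(sex == FEMALE) + np.sum(sex == MALE))


def nearly_neutral_threshold(ne: float) -> float:
    """Selection coefficient 1/(2*Ne) below which drift dominates selection.

    Variants with s below this threshold behave as effectively neutral; a
    bottleneck (smaller Ne) widens the effectively neutral range.
    """
    if ne <= 0:
        raise ValueError("Ne must be positive")
    return 1.0 / (2.0 * ne)


def _per_site_stats(counts: SiteCountsArrays):
    """pi/theta per site, zeroed at non-informative sites."""
    pi = np.zeros(counts.positions.size)
    th = np.zeros(counts.positions.size)
    inf = counts.informative
    if inf.any():
        pi[inf] = site_pi(counts.ref[inf], counts.alt[inf])
        th[inf] = site_theta_w(counts.ref[inf], counts.alt[inf])
    return pi, th


def count_informative(
    panel: GenotypePanel, units: pd.DataFrame, individuals=None
) -> pd.DataFrame:
    """Return ``units`` with ``n_total`` and ``n_informative`` columns
    computed against ``panel``."""
    units = units.copy()
    units["n_total"] = units["end"] - units["start"]
    n_inf = np.zeros(len(units), dtype=np.int64)
    for contig, grp in units.groupby("contig"):
        if contig not in panel.calls:
            continue
        counts = panel.site_counts(contig, individuals)
        cum = np.concatenate([[0], np.cumsum(counts.informative)])
        lo = np.searchsorted(counts.positions, grp["start"].to_numpy())
        hi = np.searchsorted(counts.positions, grp["end"].to_numpy())
        n_inf[grp.index.to_numpy()] = cum[hi] - cum[lo]
    units["n_informative"] = n_inf
    return units


def unit_diversity_table(
    panel: GenotypePanel, units: pd.DataFrame, individuals=None
) -> pd.DataFrame:
    """Per-unit pi, theta_W, S and informative-site weight.

    ``units`` needs columns unit_id/contig/start/end and should already have
    passed the informative-site filter; units with zero informative sites
    raise, as they cannot carry a diversity estimate.
    """
    units = units.reset_index(drop=True)
    pi_out = np.full(len(units), np.nan)
    th_out = np.full(len(units), np.nan)
    w_out = np.zeros(len(units), dtype=np.int64)
    for contig, grp in units.groupby("contig"):
        if contig not in panel.calls:
            raise KeyError(f"panel has no calls for contig {contig!r}")
        counts = panel.site_counts(contig, individuals)
        pi_site, th_site = _per_site_stats(counts)
        cum_pi = np.concatenate([[0.0], np.cumsum(pi_site)])
        cum_th = np.concatenate([[0.0], np.cumsum(th_site)])
        cum_inf = np.concatenate([[0], np.cumsum(counts.informative)])
        lo = np.searchsorted(counts.positions, grp["start"].to_numpy())
        hi = np.searchsorted(counts.positions, grp["end"].to_numpy())
        n_inf = cum_inf[hi] - cum_inf[lo]
        if np.any(n_inf == 0):
            bad = grp.loc[grp.index[np.asarray(n_inf) == 0], "unit_id"].iloc[0]
            raise ValueError(
                f"unit {bad!r} has zero informative sites; filter units first"
            )
        rows = grp.index.to_numpy()
        pi_out[rows] = (cum_pi[hi] - cum_pi[lo]) / n_inf
        th_out[rows] = (cum_th[hi] - cum_th[lo]) / n_inf
        w_out[rows] = n_inf
    out = units.copy()
    out["pi"] = pi_out
    out["theta_w"] = th_out
    out["S"] = skew_S(pi_out, th_out)
    out["weight"] = w_out
    return out


def exclude_par(
    x_units: pd.DataFrame,
    chrom_map: pd.DataFrame,
    par_length: int = 10_000_000,
    x_label: str = "chrX",
) -> pd.DataFrame:
    """Drop X units overlapping the pseudo-autosomal region.

    The PAR is taken as the terminal ``par_length`` bp at the start extreme
    of the X chromosome (default 10 Mb); it recombines with the Y and behaves
    autosomally, so it is excluded from hemizygous-X summaries.  ``chrom_map``
    (contig, start, end, chromosome, chrom_start) places contigs on
    chromosome coordinates.
    """
    if par_length <= 0 or x_units.empty:
        return x_units.copy()
    xmap = chrom_map[chrom_map["chromosome"] == x_label]
    offsets = dict(zip(xmap["contig"], xmap["chrom_start"] - xmap["start"]))
    keep = np.ones(len(x_units), dtype=bool)
    for i, row in enumerate(x_units.itertuples(index=False)):
        off = offsets.get(row.contig)
        if off is None:
            continue
        chrom_start = row.start + off
        if chrom_start < par_length:  # overlaps [0, par_length)
            keep[i] = False
    return x_units.loc[keep].reset_index(drop=True)
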