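"""Windowed NB-vs-B relative diversity: the delta statistic and its tests.

For each feature class, the units of the two populations are concatenated
in genomic order, both populations are subsampled to the same number of
individuals, and only sites informative in *both* populations are kept.
Diversity is then computed in non-overlapping windows of 1000 matched sites
and compared through

    delta = (B - NB) / (B + NB),

which is bounded in [-1, 1], roughly symmetric, and positive when the
bottlenecked population is the more diverse.  Windows where both
populations fall below an empirically fitted "no diversity" threshold get
delta set to 0 (their ratios are dominated by noise).  Feature delta
distributions are compared with Wilcoxon tests under a strict Bonferroni
correction; window classes (theta_W gain windows, delta_thetaW > 0.1, and
the ND/D classes of windows with no NB diversity) are contrasted on
genomic covariates with Mann-Whitney tests and effect sizes r = |Z|/sqrt(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from driftscape._rand import as_seedseq
from driftscape.diversity import site_pi, site_theta_w
from driftscape.panel import GenotypePanel

__all__ = [
    "MatchedSeries",
    "delta",
    "match_and_concatenate",
    "make_windows",
    "fit_zero_threshold",
    "zero_transform",
    "compare_feature_deltas",
    "classify_windows",
    "classify_and_contrast",
    "bootstrap_delta_dispersion",
    "mann_whitney_z",
    "effect_size_r",
    "bonferroni",
]


@dataclass
class MatchedSeries:
    """Sites informative in both (subsampled) populations, in genomic order
    along the concatenated units of one feature class."""

    feature_class: str
    unit_id: np.ndarray  # per matched site
    pi_nb: np.ndarray
    theta_nb: np.ndarray
    pi_b: np.ndarray
    theta_b: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.unit_id.size)


def delta(b_value, nb_value):
    """(B - NB) / (B + NB); 0 when both are 0 (no information either way)."""
    b = np.asarray(b_value, dtype=float)
    nb = np.asarray(nb_value, dtype=float)
    if np.any(b < 0) or np.any(nb < 0):
        raise ValueError("diversities must be non-negative")
    tot = b + nb
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tot > 0, (b - nb) / np.where(tot > 0, tot, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def _subsample(panel: GenotypePanel, n: int, rng) -> np.ndarray:
    if n > panel.n_samples:
        raise ValueError(
            f"subsample_n={n} exceeds {panel.population} size {panel.n_samples}"
        )
    return np.sort(rng.choice(panel.n_samples, size=n, replace=False))


def match_and_concatenate(
    panel_nb: GenotypePanel,
    panel_b: GenotypePanel,
    units: pd.DataFrame,
    subsample_n: int | None = None,
    seed=None,
) -> MatchedSeries:
    """Build the matched per-site series of one feature class.

    Both panels are subsampled (without replacement, seeded) to
    ``subsample_n`` individuals; a site enters the series only if it is
    informative in both subsampled populations.
    """
    feature = units["feature_class"].iloc[0] if len(units) else "?"
    ss = as_seedseq(seed).spawn(2)
    idx_nb = (
        _subsample(panel_nb, subsample_n, np.random.default_rng(ss[0]))
        if subsample_n is not None else None
    )
    idx_b = (
        _subsample(panel_b, subsample_n, np.random.default_rng(ss[1]))
        if subsample_n is not None else None
    )
    chunks = {k: [] for k in ("unit", "pi_nb", "th_nb", "pi_b", "th_b")}
    for contig, grp in units.sort_values(["contig", "start"]).groupby(
            "contig", sort=True):
        if contig not in panel_nb.calls or contig not in panel_b.calls:
            continue
        c_nb = panel_nb.site_counts(contig, idx_nb)
        c_b = panel_b.site_counts(contig, idx_b)
        if not np.array_equal(c_nb.positions, c_b.positions):
            raise ValueError(f"panels disagree on positions of {contig!r}")
        both = c_nb.informative & c_b.informative
        for u in grp.itertuples(index=False):
            lo = np.searchsorted(c_nb.positions, u.start)
            hi = np.searchsorted(c_nb.positions, u.end)
            sel = np.flatnonzero(both[lo:hi]) + lo
            if sel.size == 0:
                continue
            chunks["unit"].append(np.full(sel.size, u.unit_id, dtype=object))
            chunks["pi_nb"].append(site_pi(c_nb.ref[sel], c_nb.alt[sel]))
            chunks["th_nb"].append(site_theta_w(c_nb.ref[sel], c_nb.alt[sel]))
            chunks["pi_b"].append(site_pi(c_b.ref[sel], c_b.alt[sel]))
            chunks["th_b"].append(site_theta_w(c_b.ref[sel], c_b.alt[sel]))
    cat = (lambda key: np.concatenate(chunks[key]) if chunks[key]
           else np.array([]))
    return MatchedSeries(
        feature_class=feature,
        unit_id=cat("unit"),
        pi_nb=cat("pi_nb"),
        theta_nb=cat("th_nb"),
        pi_b=cat("pi_b"),
        theta_b=cat("th_b"),
    )


def make_windows(series: MatchedSeries, window: int = 1000) -> pd.DataFrame:
    """Cut the matched series into consecutive windows of exactly ``window``
    matched sites (trailing partial window dropped) and average per-site
    diversities within each; deltas are attached, unzeroed."""
    n_win = series.n_sites // window
    if n_win == 0:
        warnings.warn(
            f"{series.feature_class}: {series.n_sites} matched sites "
            f"< one {window}-site window"
        )
    rows = []
    for k in range(n_win):
        sl = slice(k * window, (k + 1) * window)
        ids, counts = np.unique(series.unit_id[sl], return_counts=True)
        rows.append(
            {
                "feature_class": series.feature_class,
                "window_index": k,
                "pi_nb": series.pi_nb[sl].mean(),
                "theta_nb": series.theta_nb[sl].mean(),
                "pi_b": series.pi_b[sl].mean(),
                "theta_b": series.theta_b[sl].mean(),
                "unit_sites": dict(zip(ids, counts)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["feature_class", "window_index", "pi_nb", "theta_nb",
                 "pi_b", "theta_b", "unit_sites"],
    )
    if len(df):
        df["delta_pi"] = delta(df["pi_b"].to_numpy(), df["pi_nb"].to_numpy())
        df["delta_theta"] = delta(df["theta_b"].to_numpy(),
                                  df["theta_nb"].to_numpy())
        df["zeroed"] = False
    return df


def fit_zero_threshold(values, fallback: float = 1e-6,
                       bins: int = 60, smooth: float = 1.5,
                       max_threshold: float = 1e-4) -> float:
    """Empirical threshold separating the "no diversity" mode from the rest.

    Fits the minimum of a smoothed log10 histogram between its two largest
    modes; when the distribution is effectively unimodal (or too sparse to
    tell) the fixed ``fallback`` is returned.  A fitted threshold above
    ``max_threshold`` is rejected as well: a no-diversity mode is numerical
    noise sitting *below* the one-variant-per-window diversity floor, and a
    valley above that floor separates genuinely different diversity levels
    (e.g. feature classes), which must not be zeroed.  With count-based
    estimators truly empty windows sit at exactly 0, below any positive
    fallback.
    """
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size < 20 or np.ptp(np.log10(v)) < 1e-9:
        return fallback
    logv = np.log10(v)
    hist, edges = np.histogram(logv, bins=bins)
    sm = gaussian_filter1d(hist.astype(float), smooth)
    peaks = [
        i for i in range(1, bins - 1)
        if sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1] and sm[i] > 0
    ]
    if len(peaks) < 2:
        return fallback
    top = sorted(sorted(peaks, key=lambda i: sm[i])[-2:])
    valley = top[0] + int(np.argmin(sm[top[0]: top[1] + 1]))
    # a genuine second mode must be non-negligible and clearly separated
    # from the valley, otherwise the distribution is effectively unimodal
    minor = min(sm[top[0]], sm[top[1]])
    if minor < 0.05 * max(sm[top[0]], sm[top[1]]) or sm[valley] > 0.5 * minor:
        return fallback
    thr = float(10 ** ((edges[valley] + edges[valley + 1]) / 2))
    return thr if thr <= max_threshold else fallback


def zero_transform(windows: pd.DataFrame, threshold="auto") -> pd.DataFrame:
    """Zero both deltas of windows whose theta_W is below the no-diversity
    threshold in *both* populations; sets the ``zeroed`` flag.

    ``threshold='auto'`` fits :func:`fit_zero_threshold` on the pooled NB/B
    window theta_W values; ``threshold=0`` is the identity transform.
    """
    if windows.empty:
        raise ValueError("no windows to transform")
    out = windows.copy()
    if threshold == "auto":
        pooled = np.concatenate(
            [out["theta_nb"].to_numpy(), out["theta_b"].to_numpy()]
        )
        threshold = fit_zero_threshold(pooled)
    thr = float(threshold)
    low = (out["theta_nb"] < thr) & (out["theta_b"] < thr)
    out.loc[low, ["delta_pi", "delta_theta"]] = 0.0
    out["zeroed"] = low.to_numpy()
    out.attrs["zero_threshold"] = thr
    return out


# ---------------------------------------------------------------------------
# test machinery


def bonferroni(p: float, m: int) -> float:
    """Strict Bonferroni: min(1, m * p)."""
    return float(min(1.0, m * p))


def mann_whitney_z(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with tie- and continuity-corrected normal Z and p.

    Returns (U of x, Z, p).  When both groups have <= 10 observations and no
    ties, the p-value comes from the exact null distribution instead of the
    normal approximation; Z is always reported for effect sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    nt = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (nt * (nt - 1))
    var = n1 * n2 / 12 * ((nt + 1) - tie_term)
    if var <= 0:
        return float(u1), 0.0, 1.0
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(var)
    no_ties = tie_counts.size == nt
    if n1 <= 10 and n2 <= 10 and no_ties:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue)
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return float(u1), float(z), min(p, 1.0)


def signed_rank_test(x, y) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank (statistic, Z, p); zero differences are
    dropped (wilcox method).  All-zero differences give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 0.0, 1.0
    res = stats.wilcoxon(nz, zero_method="wilcox")  # method='auto': exact
    # when n <= 50 and no ties, else the normal approximation
    n = nz.size
    mu = n * (n + 1) / 4
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    return float(res.statistic), float(z), float(res.pvalue)


def effect_size_r(z: float, n: int) -> float:
    """Rank-test effect size r = |Z| / sqrt(N), N = total observations."""
    if n <= 0:
        raise ValueError("N must be positive")
    return float(abs(z) / np.sqrt(n))


def compare_feature_deltas(
    deltas_by_feature: dict,
    reference: str = "intergenic",
    paired: bool = True,
    min_windows: int = 5,
) -> pd.DataFrame:
    """Test each feature's delta distribution against the reference feature.

    Paired mode truncates both series to the common window count in order
    and applies the Wilcoxon signed-rank test; unpaired mode applies the
    Mann-Whitney rank-sum test.  p-values carry a strict Bonferroni
    correction over the comparisons actually performed.
    """
    if reference not in deltas_by_feature:
        raise KeyError(f"reference feature {reference!r} missing")
    ref = np.asarray(deltas_by_feature[reference], dtype=float)
    rows = []
    for feature, values in deltas_by_feature.items():
        if feature == reference:
            continue
        values = np.asarray(values, dtype=float)
        if values.size < min_windows or ref.size < min_windows:
            warnings.warn(f"{feature}: too few windows; comparison omitted")
            continue
        if paired:
            m = min(values.size, ref.size)
            statistic, z, p = signed_rank_test(values[:m], ref[:m])
            n_obs = 2 * m
        else:
            statistic, z, p = mann_whitney_z(values, ref)
            n_obs = values.size + ref.size
        rows.append(
            {
                "test": f"{feature} vs {reference}",
                "feature_class": feature,
                "statistic": statistic,
                "z": z,
                "p_raw": p,
                "effect_r": effect_size_r(z, n_obs),
                "n": n_obs,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bonferroni"] = [bonferroni(p, len(df)) for p in df["p_raw"]]
    return df


def classify_windows(windows: pd.DataFrame, gain_threshold: float = 0.1,
                     nd_threshold: float | None = None) -> pd.DataFrame:
    """Attach window class labels.

    ``class_gain``: windows with delta_thetaW above ``gain_threshold``
    (higher theta_W in the bottlenecked population).  ``class_nd``: among
    windows with no NB theta_W diversity (below the zero threshold),
    'ND_NB-ND_B' when B has none either, 'ND_NB-D_B' when B does; 'other'
    elsewhere.
    """
    out = windows.copy()
    if nd_threshold is None:
        nd_threshold = out.attrs.get("zero_threshold", 1e-6)
    out["class_gain"] = out["delta_theta"] > gain_threshold
    nd_nb = out["theta_nb"] < nd_threshold
    nd_b = out["theta_b"] < nd_threshold
    out["class_nd"] = np.where(
        nd_nb & nd_b, "ND_NB-ND_B", np.where(nd_nb & ~nd_b, "ND_NB-D_B",
                                             "other")
    )
    return out


def classify_and_contrast(
    windows: pd.DataFrame,
    covariates: list,
    features: tuple = ("cds", "intron", "intergenic"),
    min_windows: int = 2,
) -> pd.DataFrame:
    """Contrast window classes on genomic covariates.

    Two families of unpaired Mann-Whitney tests, each Bonferroni-corrected
    over the comparisons performed within the family: (1) theta_W-gain
    windows vs the rest, per feature restricted to ``features``; (2)
    ND_NB-ND_B vs ND_NB-D_B windows across features.  Effect size
    r = |Z|/sqrt(N) with N the windows in the contrast.
    """
    rows = []
    # family 1: gain vs rest per feature
    fam1 = []
    for feature in features:
        sub = windows[windows["feature_class"] == feature]
        gain = sub[sub["class_gain"]]
        rest = sub[~sub["class_gain"]]
        if len(gain) < min_windows or len(rest) < min_windows:
            continue
        for cov in covariates:
            a = gain[cov].dropna().to_numpy()
            b = rest[cov].dropna().to_numpy()
            if a.size < min_windows or b.size < min_windows:
                continue
            u, z, p = mann_whitney_z(a, b)
            fam1.append(
                {
                    "contrast": "gain_vs_rest",
                    "feature_class": feature,
                    "covariate": cov,
                    "statistic": u,
                    "z": z,
                    "p_raw": p,
                    "effect_r": effect_size_r(z, a.size + b.size),
                    "n": a.size + b.size,
                }
            )
    # family 2: ND_NB-ND_B vs ND_NB-D_B
    fam2 = []
    nd = windows[windows["class_nd"] != "other"]
    g1 = nd[nd["class_nd"] == "ND_NB-ND_B"]
    g2 = nd[nd["class_nd"] == "ND_NB-D_B"]
    if len(g1) >= min_windows and len(g2) >= min_windows:
        for cov in covariates:
            a = g1[cov].dropna().to_numpy()
            b = g2[cov].dropna().to_numpy()
            if a.size < min_windows or b.size < min_windows:
                continue
            u, z, p = mann_whitney_z(a, b)
            fam2.append(
                {
                    "contrast": "NDND_vs_NDD",
                    "feature_class": "all",
                    "covariate": cov,
                    "statistic": u,
                    "z": z,
                    "p_raw": p,
                    "effect_r": effect_size_r(z, a.size + b.size),
                    "n": a.size + b.size,
                }
            )
    for fam in (fam1, fam2):
        for row in fam:
            row["p_bonferroni"] = bonferroni(row["p_raw"], len(fam))
        rows.extend(fam)
    return pd.DataFrame(rows)


def bootstrap_delta_dispersion(
    deltas, n_iter: int = 1000, seed=None
) -> dict:
    """Bootstrap SD and percentile 95% CI of the mean delta over windows."""
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two windows")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(int(n_iter), d.size))
    means = d[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return {
        "mean": float(d.mean()),
        "sd": float(np.std(means)),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }
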