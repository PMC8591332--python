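"""Estimator correctness: per-site pi/theta, unit aggregation, skew,
bootstrap dispersion, X haploid counting and PAR exclusion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftscape.diversity import (
    bootstrap_sd,
    exclude_par,
    harmonic_number,
    nearly_neutral_threshold,
    site_pi,
    site_theta_w,
    skew_S,
    unit_diversity_table,
    weighted_mean,
    x_effective_hap_n,
)
from tests.conftest import make_panel, random_panel


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_pi(alleles_row):
    """Mean pairwise difference over all non-missing haploid call pairs."""
    calls = [a for a in alleles_row if a in (0, 1)]
    pairs = list(itertools.combinations(range(len(calls)), 2))
    if not pairs:
        return None
    diff = sum(1 for i, j in pairs if calls[i] != calls[j])
    return diff / len(pairs)


def brute_theta(alleles_row):
    calls = [a for a in alleles_row if a in (0, 1)]
    if len(calls) < 2:
        return None
    a = sum(1.0 / i for i in range(1, len(calls)))
    return (1.0 / a) if 0 < sum(calls) < len(calls) else 0.0


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ref,alt,expected",
    [(1, 1, 1.0), (4, 0, 0.0), (2, 2, 2.0 / 3.0)],
)
def test_site_pi_examples(ref, alt, expected):
    assert site_pi(ref, alt) == pytest.approx(expected)


@pytest.mark.parametrize(
    "ref,alt,expected",
    [(2, 2, 6.0 / 11.0), (4, 0, 0.0), (1, 1, 1.0)],
)
def test_site_theta_examples(ref, alt, expected):
    assert site_theta_w(ref, alt) == pytest.approx(expected)


def test_site_estimators_reject_single_call():
    with pytest.raises(ValueError):
        site_pi(1, 0)
    with pytest.raises(ValueError):
        site_theta_w(0, 1)


def test_harmonic_number_vectorised():
    assert harmonic_number(3) == pytest.approx(11.0 / 6.0)
    np.testing.assert_allclose(harmonic_number([0, 1, 2]), [0.0, 1.0, 1.5])


def test_estimators_match_brute_force_on_random_panels():
    """Count estimators equal exhaustive pairwise/segregating-site oracles
    on small random panels, including missing genotypes."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        n = int(rng.integers(2, 7))
        L = int(rng.integers(5, 60))
        panel = random_panel(rng, n, L, missing_rate=float(rng.uniform(0, 0.3)))
        counts = panel.site_counts("ctg01")
        for i in range(L):
            if not counts.informative[i]:
                continue
            row = panel.calls["ctg01"].alleles[i]
            assert site_pi(counts.ref[i], counts.alt[i]) == pytest.approx(
                brute_pi(row), abs=1e-12
            )
            assert site_theta_w(counts.ref[i], counts.alt[i]) == pytest.approx(
                brute_theta(row), abs=1e-12
            )


def test_unit_diversity_averages_over_informative_sites():
    # 4 sites, 2 diploids; one singleton site among 4 informative sites
    geno = [
        [[0, 0], [0, 0]],
        [[0, 1], [0, 0]],  # alt count 1 of 4 -> pi = 2*3*1/(4*3) = 0.5
        [[0, 0], [0, 0]],
        [[0, 0], [0, 0]],
    ]
    panel = make_panel(geno)
    units = pd.DataFrame(
        [{"unit_id": "u0", "feature_class": "intergenic", "contig": "ctg01",
          "start": 0, "end": 4}]
    )
    out = unit_diversity_table(panel, units)
    assert out.loc[0, "weight"] == 4
    assert out.loc[0, "pi"] == pytest.approx(0.5 / 4)
    a3 = 1 + 0.5 + 1.0 / 3.0
    assert out.loc[0, "theta_w"] == pytest.approx((1.0 / a3) / 4)


def test_unit_diversity_monomorphic_panel_is_zero():
    geno = [[[0, 0], [0, 0]]] * 5
    panel = make_panel(geno)
    units = pd.DataFrame(
        [{"unit_id": "u0", "feature_class": "x", "contig": "ctg01",
          "start": 0, "end": 5}]
    )
    out = unit_diversity_table(panel, units)
    assert out.loc[0, "pi"] == 0.0
    assert out.loc[0, "theta_w"] == 0.0
    assert np.isnan(out.loc[0, "S"])


def test_adding_monomorphic_site_never_increases_diversity():
    rng = np.random.default_rng(5)
    panel = random_panel(rng, 4, 30)
    units = pd.DataFrame(
        [{"unit_id": "u0", "feature_class": "x", "contig": "ctg01",
          "start": 0, "end": 30}]
    )
    base = unit_diversity_table(panel, units)
    # extend with a monomorphic site
    cc = panel.calls["ctg01"]
    import driftscape.panel as dp

    cc2 = dp.ContigCalls(
        positions=np.arange(31),
        alleles=np.vstack([cc.alleles, np.zeros((1, 8), dtype=np.int8)]),
    )
    panel.calls["ctg01"] = cc2
    units2 = units.assign(end=31)
    ext = unit_diversity_table(panel, units2)
    assert ext.loc[0, "pi"] <= base.loc[0, "pi"]
    assert ext.loc[0, "theta_w"] <= base.loc[0, "theta_w"]


@pytest.mark.parametrize(
    "values,weights,expected",
    [((0.1, 0.3), (1, 1), 0.2), ((0.1, 0.3), (3, 1), 0.15), ((0.7,), (5,), 0.7)],
)
def test_weighted_mean(values, weights, expected):
    assert weighted_mean(values, weights) == pytest.approx(expected)


def test_skew_examples():
    assert skew_S(1.0, 1.0) == 0.0
    assert skew_S(3.3e-4, 2.8e-4) == pytest.approx(1 - 3.3 / 2.8)
    assert skew_S(0.5, 1.0) == 0.5
    assert np.isnan(skew_S(0.1, 0.0))


def test_skew_sign_reflects_sfs_shape():
    """All-singleton panels have S > 0; intermediate-frequency-only panels
    have S < 0."""
    # 6 haploids: singleton sites
    singleton = [[[0, 1], [0, 0], [0, 0]] for _ in range(10)]
    inter = [[[1, 1], [1, 0], [0, 0]] for _ in range(10)]  # freq 1/2
    for geno, sign in ((singleton, 1), (inter, -1)):
        panel = make_panel(geno)
        units = pd.DataFrame(
            [{"unit_id": "u0", "feature_class": "x", "contig": "ctg01",
              "start": 0, "end": 10}]
        )
        out = unit_diversity_table(panel, units)
        s = skew_S(out.loc[0, "pi"], out.loc[0, "theta_w"])
        assert np.sign(s) == sign


def test_bootstrap_sd_degenerate_and_enumerated():
    vals = np.array([0.3, 0.3, 0.3])
    assert bootstrap_sd(vals, np.ones(3), n_iter=50, seed=1) == pytest.approx(
        0.0, abs=1e-12
    )
    # two units (0, 1), equal weights: exhaustive resample distribution has
    # SD sqrt(1/8) ~= 0.3536
    sd = bootstrap_sd(np.array([0.0, 1.0]), np.ones(2), n_iter=20_000, seed=2)
    assert sd == pytest.approx(np.sqrt(1.0 / 8.0), abs=0.01)
    with pytest.raises(ValueError):
        bootstrap_sd(np.array([1.0]), np.array([1.0]))


@pytest.mark.parametrize(
    "sexes,expected",
    [(["F"] * 6 + ["M"] * 6, 18), (["F"] * 4, 8), (["M"] * 5, 5)],
)
def test_x_effective_hap_n(sexes, expected):
    assert x_effective_hap_n(sexes) == expected


def test_x_effective_hap_n_rejects_unknown_sex():
    with pytest.raises(ValueError):
        x_effective_hap_n(["F", "?"])


def test_hemizygous_x_counts():
    """Male X calls contribute one haplotype; theta's harmonic size is 2F+M."""
    # 2 females + 2 hemizygous males at one segregating site
    geno = [[[0, 1], [0, 0], [1, "H"], [0, "H"]]]
    panel = make_panel(geno, sex=["F", "F", "M", "M"], x_contig=True)
    counts = panel.site_counts("ctg01")
    assert counts.n_hap[0] == 6  # 2*2 + 2
    assert panel.max_haplotypes("ctg01") == 6
    assert site_theta_w(counts.ref[0], counts.alt[0]) == pytest.approx(
        1.0 / harmonic_number(5)
    )


def test_exclude_par_drops_terminal_units():
    chrom_map = pd.DataFrame(
        [("ctgX", 0, 60_000_000, "chrX", 0)],
        columns=["contig", "start", "end", "chromosome", "chrom_start"],
    )
    units = pd.DataFrame(
        [
            {"unit_id": "a", "contig": "ctgX", "start": 5_000_000,
             "end": 5_001_000},
            {"unit_id": "b", "contig": "ctgX", "start": 50_000_000,
             "end": 50_001_000},
        ]
    )
    kept = exclude_par(units, chrom_map, par_length=10_000_000)
    assert list(kept["unit_id"]) == ["b"]
    ident = exclude_par(units, chrom_map, par_length=0)
    assert len(ident) == 2


@pytest.mark.parametrize("ne,expected", [(20, 0.025), (10, 0.05)])
def test_nearly_neutral_threshold(ne, expected):
    assert nearly_neutral_threshold(ne) == expected


@settings(max_examples=50, deadline=None)
@given(
    ref=st.integers(min_value=0, max_value=40),
    alt=st.integers(min_value=0, max_value=40),
)
def test_site_estimator_bounds(ref, alt):
    """0 <= pi <= 1 and theta >= 0 with S <= 1 whenever defined."""
    if ref + alt < 2:
        return
    pi = site_pi(ref, alt)
    th = site_theta_w(ref, alt)
    assert 0.0 <= pi <= 1.0
    assert th >= 0.0
    if th > 0:
        assert skew_S(pi, th) <= 1.0
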