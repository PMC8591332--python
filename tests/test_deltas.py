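"""Windowed delta statistics: matching, windowing, zero-thresholding,
rank-test machinery (against exact permutation enumeration) and window
classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftscape.deltas import (
    bonferroni,
    bootstrap_delta_dispersion,
    classify_windows,
    compare_feature_deltas,
    delta,
    effect_size_r,
    fit_zero_threshold,
    make_windows,
    mann_whitney_z,
    match_and_concatenate,
    signed_rank_test,
    zero_transform,
    MatchedSeries,
)
from tests.conftest import make_panel, random_panel


class TestDelta:
    @pytest.mark.parametrize(
        "b,nb,expected",
        [(0.5, 0.5, 0.0), (1e-4, 0.0, 1.0), (1e-4, 3e-4, -0.5),
         (0.0, 0.0, 0.0)],
    )
    def test_examples(self, b, nb, expected):
        assert delta(b, nb) == pytest.approx(expected)

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.floats(min_value=1e-9, max_value=1.0),
        b=st.floats(min_value=1e-9, max_value=1.0),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        assert delta(a, b) == pytest.approx(-delta(b, a))
        assert -1.0 <= delta(a, b) <= 1.0


class TestMatching:
    def panels(self, rng, missing_rate=0.2):
        nb = random_panel(rng, 6, 400, missing_rate=missing_rate)
        b = random_panel(rng, 6, 400, missing_rate=missing_rate)
        return nb, b

    def units(self):
        return pd.DataFrame(
            [{"unit_id": "u0", "feature_class": "intergenic",
              "contig": "ctg01", "start": 0, "end": 400}]
        )

    def test_identical_panels_keep_all_informative(self):
        rng = np.random.default_rng(0)
        nb = random_panel(rng, 6, 400, missing_rate=0.0)
        series = match_and_concatenate(nb, nb, self.units())
        assert series.n_sites == 400

    def test_site_informative_in_one_population_dropped(self):
        rng = np.random.default_rng(1)
        nb, b = self.panels(rng)
        series = match_and_concatenate(nb, b, self.units())
        both = (
            nb.site_counts("ctg01").informative
            & b.site_counts("ctg01").informative
        )
        assert series.n_sites == int(both.sum()) < 400

    def test_subsample_seeded_and_bounded(self):
        rng = np.random.default_rng(2)
        nb, b = self.panels(rng)
        s1 = match_and_concatenate(nb, b, self.units(), subsample_n=4, seed=9)
        s2 = match_and_concatenate(nb, b, self.units(), subsample_n=4, seed=9)
        np.testing.assert_array_equal(s1.pi_nb, s2.pi_nb)
        with pytest.raises(ValueError):
            match_and_concatenate(nb, b, self.units(), subsample_n=7, seed=0)


class TestWindows:
    def series(self, n, feature="intergenic"):
        return MatchedSeries(
            feature_class=feature,
            unit_id=np.array(["u0"] * n, dtype=object),
            pi_nb=np.zeros(n),
            theta_nb=np.zeros(n),
            pi_b=np.zeros(n),
            theta_b=np.zeros(n),
        )

    def test_floor_division_of_sites(self):
        assert len(make_windows(self.series(2500), 1000)) == 2

    def test_short_series_warns_and_empty(self):
        with pytest.warns(UserWarning):
            out = make_windows(self.series(999), 1000)
        assert len(out) == 0

    def test_monomorphic_window_zero_diversity(self):
        out = make_windows(self.series(1000), 1000)
        row = out.iloc[0]
        assert row[["pi_nb", "theta_nb", "pi_b", "theta_b"]].eq(0).all()
        assert row["delta_theta"] == 0.0


class TestZeroTransform:
    def frame(self, theta_nb, theta_b):
        n = len(theta_nb)
        return pd.DataFrame(
            {
                "feature_class": "intergenic",
                "window_index": range(n),
                "pi_nb": theta_nb,
                "theta_nb": theta_nb,
                "pi_b": theta_b,
                "theta_b": theta_b,
                "delta_pi": delta(np.asarray(theta_b), np.asarray(theta_nb)),
                "delta_theta": delta(np.asarray(theta_b),
                                     np.asarray(theta_nb)),
                "zeroed": False,
            }
        )

    def test_both_below_threshold_zeroed(self):
        win = self.frame([1e-7, 1e-3], [2e-7, 2e-3])
        out = zero_transform(win, threshold=1e-6)
        assert out.loc[0, "delta_theta"] == 0.0 and out.loc[0, "zeroed"]
        assert out.loc[1, "delta_theta"] != 0.0 and not out.loc[1, "zeroed"]

    def test_threshold_zero_is_identity(self):
        win = self.frame([1e-7, 1e-3], [2e-7, 2e-3])
        out = zero_transform(win, threshold=0.0)
        assert (out["delta_theta"] == win["delta_theta"]).all()
        assert not out["zeroed"].any()

    def test_auto_threshold_separates_bimodal_modes(self):
        rng = np.random.default_rng(3)
        low = 10 ** rng.normal(-6.5, 0.25, 400)
        high = 10 ** rng.normal(-3.0, 0.4, 400)
        thr = fit_zero_threshold(np.concatenate([low, high]))
        assert 1e-6 < thr < 1e-4

    def test_unimodal_falls_back(self):
        rng = np.random.default_rng(4)
        vals = 10 ** rng.normal(-3.0, 0.3, 500)
        assert fit_zero_threshold(vals) == 1e-6


# ---------------------------------------------------------------------------
# rank-test machinery vs exact enumeration


def exact_mann_whitney_p(x, y):
    """Two-sided p by complete enumeration of group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    u_star = max(u_obs, n1 * (len(y)) - u_obs)
    return min(1.0, 2.0 * np.mean(us >= u_star))


def exact_signed_rank_p(diffs):
    """Two-sided p by enumerating all 2^n sign assignments of |d| ranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append((ranks * np.asarray(signs)).sum())
    ws = np.asarray(ws)
    total = ranks.sum()
    w_star = min(w_obs, total - w_obs)
    return min(1.0, 2.0 * np.mean(ws <= w_star))


class TestRankMachinery:
    def test_mann_whitney_matches_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            x = rng.normal(0, 1, int(rng.integers(4, 9)))
            y = rng.normal(0.8, 1, int(rng.integers(4, 9)))
            _, _, p = mann_whitney_z(x, y)
            assert p == pytest.approx(exact_mann_whitney_p(x, y), abs=1e-9)

    def test_mann_whitney_extreme_separation(self):
        x = np.arange(10) + 100.0
        y = np.arange(10).astype(float)
        _, _, p = mann_whitney_z(x, y)
        from math import comb

        assert p == pytest.approx(2.0 / comb(20, 10), rel=1e-9)

    def test_signed_rank_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            x = rng.normal(0.5, 1, n)
            y = rng.normal(0.0, 1, n)
            _, _, p = signed_rank_test(x, y)
            assert p == pytest.approx(exact_signed_rank_p(x - y), abs=1e-9)

    def test_signed_rank_all_zero_differences(self):
        stat, z, p = signed_rank_test(np.ones(6), np.ones(6))
        assert (stat, z, p) == (0.0, 0.0, 1.0)

    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 10, 0.1), (0.2, 10, 1.0), (0.03, 1, 0.03)]
    )
    def test_bonferroni(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_effect_size_hand_case(self):
        assert effect_size_r(2.0, 100) == pytest.approx(0.2)
        assert effect_size_r(-3.0, 36) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_effect_size_bounded_by_one(self, data):
        x = data.draw(st.lists(st.floats(-5, 5), min_size=3, max_size=12))
        y = data.draw(st.lists(st.floats(-5, 5), min_size=3, max_size=12))
        _, z, _ = mann_whitney_z(np.array(x), np.array(y))
        assert effect_size_r(z, len(x) + len(y)) <= 1.0 + 1e-9


class TestFeatureComparison:
    def test_identical_to_reference_is_null(self):
        d = {"intergenic": np.linspace(-1, 1, 20),
             "cds": np.linspace(-1, 1, 20)}
        out = compare_feature_deltas(d, paired=True)
        assert out.iloc[0]["p_raw"] == 1.0

    def test_unpaired_mode_and_bonferroni_multiplier(self):
        rng = np.random.default_rng(12)
        d = {
            "intergenic": rng.normal(-0.5, 0.1, 15),
            "cds": rng.normal(0.5, 0.1, 15),
            "ucne": rng.normal(0.5, 0.1, 15),
        }
        out = compare_feature_deltas(d, paired=False)
        assert len(out) == 2
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, 2 * out["p_raw"])
        )

    def test_missing_reference_errors(self):
        with pytest.raises(KeyError):
            compare_feature_deltas({"cds": np.ones(6)}, reference="intergenic")


class TestClassification:
    def windows(self):
        df = pd.DataFrame(
            {
                "feature_class": ["cds"] * 4,
                "window_index": range(4),
                "pi_nb": [0.0, 0.0, 1e-3, 1e-3],
                "theta_nb": [0.0, 0.0, 1e-3, 1e-3],
                "pi_b": [0.0, 1e-3, 1e-3, 2e-3],
                "theta_b": [0.0, 1e-3, 1e-3, 2e-3],
            }
        )
        df["delta_pi"] = delta(df["pi_b"].to_numpy(), df["pi_nb"].to_numpy())
        df["delta_theta"] = delta(df["theta_b"].to_numpy(),
                                  df["theta_nb"].to_numpy())
        df["zeroed"] = False
        return df

    def test_gain_and_nd_classes(self):
        out = classify_windows(self.windows(), nd_threshold=1e-6)
        assert out["class_gain"].tolist() == [False, True, False, True]
        assert out["class_nd"].tolist() == [
            "ND_NB-ND_B", "ND_NB-D_B", "other", "other"
        ]


def test_constrained_class_loses_less_theta_than_intergenic():
    """After a bottleneck, the singleton-rich strongly constrained class
    keeps its windowed theta_W delta well above neutral intergenic (gains
    from new nearly-neutral mutations on a near-zero baseline while
    intergenic loses standing variation)."""
    from driftscape.experiments import constrained_gain_signature

    out = constrained_gain_signature(n_seeds=4, base_seed=900)
    d = out["detail"]
    assert len(d) == 4
    assert (d["dtheta_ucne"] > d["dtheta_intergenic"]).all()


class TestBootstrapDispersion:
    def test_constant_deltas(self):
        out = bootstrap_delta_dispersion(np.full(10, 0.3), n_iter=100, seed=0)
        assert out["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_two_window_enumeration(self):
        out = bootstrap_delta_dispersion(np.array([-1.0, 1.0]),
                                         n_iter=40_000, seed=1)
        assert out["sd"] == pytest.approx(np.sqrt(0.5), abs=0.01)

    def test_ci_contains_sample_mean(self):
        rng = np.random.default_rng(13)
        d = rng.normal(-0.2, 0.3, 50)
        out = bootstrap_delta_dispersion(d, n_iter=500, seed=2)
        assert out["ci_low"] <= out["mean"] <= out["ci_high"]

    def test_single_window_errors(self):
        with pytest.raises(ValueError):
            bootstrap_delta_dispersion(np.array([0.1]))
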