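"""Self-contained simulation experiments that check the method's behaviour
against population-genetic theory.

These are the package's "does the machinery reproduce what theory says"
probes: the neutral X/A equilibrium ratio (in :mod:`driftscape.simulate`),
the null calibration of the windowed delta statistic, and the
bottleneck-gain signature of strongly constrained, singleton-rich sequence
classes (theta_W falling less - or rising - relative to neutral sequence
after a bottleneck, driven by relaxed selection plus new neutral-behaving
mutation input at small Ne).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from driftscape import annotate, deltas, diversity
from driftscape.simulate import SimConfig, SimResult, simulate

__all__ = [
    "delta_windows_for_sim",
    "null_delta_calibration",
    "constrained_gain_signature",
]


def delta_windows_for_sim(
    result: SimResult,
    window_sites: int = 1000,
    subsample_n: int | None = None,
    seed=None,
    zero_threshold="auto",
    min_informative: int = 50,
    min_fraction: float = 0.20,
) -> pd.DataFrame:
    """Windows of the NB-vs-B delta comparison straight from an in-memory
    simulation (no file round trip): build units, filter per population,
    match sites per feature on autosomes, window, zero-transform."""
    genome = result.genome
    units = annotate.build_units(
        genome.features, genome.genes, genome.regions, genome.chrom_map,
        genome.contig_lengths,
    )
    units = units[~units["contig"].isin(genome.x_contigs)]
    kept = {}
    for pop, panel in result.panels.items():
        counted = diversity.count_informative(panel, units)
        kept[pop] = annotate.filter_units(counted, min_informative,
                                          min_fraction)
    shared = kept["NB"].merge(kept["B"][["unit_id"]], on="unit_id")
    frames = []
    for feature in sorted(set(shared["feature_class"])):
        f_units = shared[shared["feature_class"] == feature]
        series = deltas.match_and_concatenate(
            result.panels["NB"], result.panels["B"], f_units,
            subsample_n=subsample_n, seed=seed,
        )
        if series.n_sites >= window_sites:
            frames.append(deltas.make_windows(series, window_sites))
    if not frames:
        return pd.DataFrame()
    windows = pd.concat(frames, ignore_index=True)
    return deltas.zero_transform(windows, zero_threshold)


def null_delta_calibration(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: SimConfig | None = None,
    window_sites: int = 1000,
    min_windows: int = 15,
    n_boot: int = 1000,
) -> dict:
    """Coverage of zero by the bootstrap 95% CI of mean delta when B is
    sampled from the same generation as NB (pure sampling noise).

    Returns the fraction of (seed, feature) combinations whose CI covers 0;
    a well-calibrated delta machinery keeps this near the nominal 95%.
    """
    results = []
    for k in range(n_seeds):
        # default design: enough windows per feature for the percentile
        # bootstrap to be in its validity regime; samples large enough that
        # panel-level sampling noise (shared across all windows of a panel,
        # hence invisible to a bootstrap over windows) stays subdominant to
        # window-level noise; and neutral classes, so every feature's
        # window delta is quasi-continuous rather than a sparse -1/0/+1
        # mixture (the regime likelihood-based window diversities occupy)
        cfg = config
        if cfg is None:
            cfg = SimConfig(
                n_contigs=12,
                contig_length=30_000,
                sample_NB=20,
                sample_B=20,
                feature_layout=[("gene", 2600, 2), ("ucne", 300, 4)],
                x_fraction=0.0,
            )
            cfg.s_per_class = {k: 0.0 for k in cfg.s_per_class}
        cfg = SimConfig(**{**cfg.__dict__, "seed": base_seed + k})
        res = simulate(cfg, null_pair=True)
        windows = delta_windows_for_sim(
            res, window_sites=window_sites, seed=base_seed + k
        )
        for feature, grp in windows.groupby("feature_class"):
            if len(grp) < min_windows:
                continue
            for stat in ("delta_theta", "delta_pi"):
                boot = deltas.bootstrap_delta_dispersion(
                    grp[stat], n_iter=n_boot, seed=base_seed + k
                )
                results.append(
                    {
                        "seed": base_seed + k,
                        "feature_class": feature,
                        "statistic": stat,
                        "mean": boot["mean"],
                        "covers_zero": boot["ci_low"] <= 0 <= boot["ci_high"],
                    }
                )
    df = pd.DataFrame(results)
    return {
        "coverage": float(df["covers_zero"].mean()) if len(df) else np.nan,
        "n_intervals": int(len(df)),
        "detail": df,
    }


def _signature_config(seed: int) -> SimConfig:
    """Bottleneck scenario contrasting a strongly constrained,
    singleton-rich class (ucne, s at the top of the nearly-neutral window
    of the ancestral population) against neutral intergenic sequence."""
    return SimConfig(
        seed=seed,
        n_contigs=8,
        contig_length=30_000,
        feature_layout=[("ucne", 500, 8)],
        x_fraction=0.0,
        Ne_anc=2000,
        Ne_B=10,
        g_B=40,
    )


def constrained_gain_signature(
    n_seeds: int = 10,
    base_seed: int = 0,
    window_sites: int = 1000,
) -> dict:
    """Per-seed check of the post-bottleneck signature of constraint.

    For each seed: mean delta_thetaW(ucne) > mean delta_thetaW(intergenic)
    (constrained sequence loses proportionally less variant density), and
    mean delta_thetaW(ucne) > mean delta_pi(ucne) (the gain shows in variant
    density before allele frequencies).  Returns the fraction of seeds where
    both hold.
    """
    rows = []
    for k in range(n_seeds):
        res = simulate(_signature_config(base_seed + k))
        win = delta_windows_for_sim(res, window_sites=window_sites,
                                    seed=base_seed + k)
        by = win.groupby("feature_class")[["delta_theta", "delta_pi"]].mean()
        if not {"ucne", "intergenic"} <= set(by.index):
            continue
        rows.append(
            {
                "seed": base_seed + k,
                "dtheta_ucne": by.loc["ucne", "delta_theta"],
                "dtheta_intergenic": by.loc["intergenic", "delta_theta"],
                "dpi_ucne": by.loc["ucne", "delta_pi"],
            }
        )
    df = pd.DataFrame(rows)
    both = (
        (df["dtheta_ucne"] > df["dtheta_intergenic"])
        & (df["dtheta_ucne"] > df["dpi_ucne"])
    )
    return {
        "fraction": float(both.mean()) if len(df) else np.nan,
        "n_seeds": int(len(df)),
        "detail": df,
    }
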