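"""Figures: per-feature delta bars, delta-theta vs delta-pi scatter, and
NB-vs-B regression heat maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from driftscape.deltas import bootstrap_delta_dispersion


def delta_by_feature(windows, path, n_boot: int = 1000, seed=None) -> None:
    """Bar plot of mean delta_thetaW and delta_pi per feature with bootstrap
    SD error bars."""
    feats = sorted(windows["feature_class"].unique())
    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(feats)), 4))
    xs = np.arange(len(feats))
    for off, (col, label) in enumerate(
        [("delta_theta", r"$\delta_{\theta_W}$"), ("delta_pi", r"$\delta_\pi$")]
    ):
        means, sds = [], []
        for f in feats:
            d = windows.loc[windows["feature_class"] == f, col]
            if len(d) >= 2:
                boot = bootstrap_delta_dispersion(d, n_boot, seed)
                means.append(boot["mean"])
                sds.append(boot["sd"])
            else:
                means.append(d.mean() if len(d) else np.nan)
                sds.append(0.0)
        ax.bar(xs + 0.4 * off - 0.2, means, width=0.38, yerr=sds,
               capsize=3, label=label)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(xs)
    ax.set_xticklabels(feats, rotation=45, ha="right")
    ax.set_ylabel(r"$\delta$ (B vs NB)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def delta_scatter(windows, path) -> None:
    """delta_thetaW against delta_pi per window, coloured by feature."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for f, grp in windows.groupby("feature_class"):
        ax.scatter(grp["delta_pi"], grp["delta_theta"], s=8, alpha=0.6,
                   label=f)
    lim = [-1.05, 1.05]
    ax.plot(lim, lim, "k--", lw=0.7)
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel(r"$\delta_\pi$")
    ax.set_ylabel(r"$\delta_{\theta_W}$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def regression_heatmap(nb_vs_b, path) -> None:
    """Slope and R^2 of B-on-NB regressions per region as a heat map."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, col in zip(axes, ["slope", "r_squared"]):
        pivot = nb_vs_b.pivot_table(index="region_class",
                                    columns="statistic", values=col)
        im = ax.imshow(pivot.to_numpy(), cmap="viridis", aspect="auto")
        ax.set_xticks(range(len(pivot.columns)))
        ax.set_xticklabels(pivot.columns)
        ax.set_yticks(range(len(pivot.index)))
        ax.set_yticklabels(pivot.index)
        for i in range(pivot.shape[0]):
            for j in range(pivot.shape[1]):
                ax.text(j, i, f"{pivot.iat[i, j]:.2f}", ha="center",
                        va="center", color="w", fontsize=8)
        ax.set_title(col)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
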