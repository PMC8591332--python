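"""End-to-end orchestration: simulate -> annotate -> diversity ->
covariates -> landscape -> windowed deltas, with validation and a run
report (JSON + markdown).

Every stage draws its randomness from named substreams of the single run
seed, so a full run is reproducible and any stage re-run in isolation with
the same seed reproduces its output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from driftscape import annotate, covariates, deltas, diversity, io, landscape
from driftscape.simulate import (
    FUNCTIONAL_CLASSES,
    SimConfig,
    config_from_dict,
    simulate,
)

log = logging.getLogger("driftscape")

POPULATIONS = ("NB", "B")


@dataclass
class RunConfig:
    """Single-run configuration; numeric defaults follow the study design:
    1000-site windows, 100-iteration unit bootstraps and 1000-iteration
    window bootstraps, 75% region overlap, >50-site / 20% unit filter,
    delta_thetaW > 0.1 gain class, 10-Mb PAR."""

    seed: int = 0
    out_dir: str = "driftscape_out"
    input_dir: str | None = None  # pre-existing inputs; else simulate
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    subsample_n: int = 12
    window_sites: int = 1000
    zero_threshold: object = "auto"
    gain_threshold: float = 0.1
    unit_bootstrap: int = 100
    window_bootstrap: int = 1000
    min_informative: int = 50
    min_fraction: float = 0.20
    region_min_overlap: float = 0.75
    par_bp: int = 10_000_000
    paired_feature_test: bool = True
    functional_window_bp: int = 2_000_000
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class InputBundle:
    panels: dict
    features: pd.DataFrame
    genes: pd.DataFrame
    regions: pd.DataFrame
    chrom_map: pd.DataFrame
    contig_lengths: dict
    x_contigs: set
    substitutions: pd.DataFrame
    sequences: dict
    recombination: pd.DataFrame
    rvis: pd.DataFrame


def load_inputs(input_dir) -> InputBundle:
    """Read a simulator-emitted (or equivalently structured) input dir."""
    p = lambda name: os.path.join(input_dir, name)
    with open(p("x_contigs.txt")) as fh:
        x_contigs = {line.strip() for line in fh if line.strip()}
    chrom_map = io.read_tsv(p("chromosomes.tsv"))
    contig_lengths = dict(zip(chrom_map["contig"], chrom_map["end"]))
    panels = {}
    for pop in POPULATIONS:
        sex = io.read_tsv(p(f"{pop}.sex.tsv"))
        panels[pop] = io.read_vcf(p(f"{pop}.vcf"), pop, sex, x_contigs)
    genes = io.read_bed(
        p("genes.bed"),
        ["contig", "start", "end", "name", "score", "strand", "kind"],
    )
    return InputBundle(
        panels=panels,
        features=io.read_bed(
            p("features.bed"), ["contig", "start", "end", "feature_class"]
        ).assign(entity_id=lambda d: d["feature_class"]),
        genes=genes,
        regions=io.read_bed(
            p("regions.bed"), ["contig", "start", "end", "region_class"]
        ),
        chrom_map=chrom_map,
        contig_lengths=contig_lengths,
        x_contigs=x_contigs,
        substitutions=io.read_bed(
            p("substitutions.bed"), ["contig", "start", "end"]
        ),
        sequences=io.read_fasta(p("genome.fa")),
        recombination=io.read_tsv(p("recombination.tsv")),
        rvis=io.read_tsv(p("rvis.tsv")),
    )


def validate_inputs(input_dir) -> list:
    """Consistency checks on an input dir; returns a list of error strings
    (empty when everything is coherent)."""
    errors = []
    required = [
        "NB.vcf", "B.vcf", "NB.sex.tsv", "B.sex.tsv", "genes.bed",
        "features.bed", "regions.bed", "chromosomes.tsv",
        "substitutions.bed", "recombination.tsv", "rvis.tsv", "genome.fa",
        "x_contigs.txt",
    ]
    missing = [f for f in required if not os.path.exists(
        os.path.join(input_dir, f))]
    if missing:
        return [f"missing file: {m}" for m in missing]
    chrom_map = io.read_tsv(os.path.join(input_dir, "chromosomes.tsv"))
    contigs = set(chrom_map["contig"])
    import pysam

    for pop in POPULATIONS:
        vf = pysam.VariantFile(os.path.join(input_dir, f"{pop}.vcf"))
        vcf_contigs = set(vf.header.contigs)
        vcf_samples = list(vf.header.samples)
        vf.close()
        extra = vcf_contigs - contigs
        if extra:
            errors.append(
                f"{pop}.vcf contig(s) absent from chromosomes.tsv: "
                f"{sorted(extra)}"
            )
        sex = io.read_tsv(os.path.join(input_dir, f"{pop}.sex.tsv"))
        unlabelled = set(vcf_samples) - set(sex["sample"])
        if unlabelled:
            errors.append(f"{pop}: samples without sex: {sorted(unlabelled)}")
        bad_sex = set(sex["sex"]) - {"M", "F"}
        if bad_sex:
            errors.append(f"{pop}: invalid sex labels: {sorted(bad_sex)}")
    for name, cols in (
        ("features.bed", ["contig", "start", "end", "feature_class"]),
        ("regions.bed", ["contig", "start", "end", "region_class"]),
    ):
        bed = io.read_bed(os.path.join(input_dir, name), cols)
        extra = set(bed["contig"]) - contigs
        if extra:
            errors.append(f"{name} contig(s) not in chromosomes.tsv: "
                          f"{sorted(extra)}")
        for contig, grp in bed.groupby("contig"):
            starts = grp["start"].to_numpy()
            if np.any(np.diff(starts) < 0):
                k = int(np.flatnonzero(np.diff(starts) < 0)[0]) + 1
                errors.append(
                    f"{name} unsorted on {contig}: line with start "
                    f"{starts[k]} after {starts[k - 1]}"
                )
                break
        if np.any(bed["start"] >= bed["end"]):
            errors.append(f"{name}: interval with start >= end")
    return errors


def _to_native(obj):
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all tables plus a JSON + markdown report;
    returns the report dict."""
    t_start = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": round(time.time() - t_start, 2)}
        return time.time()

    # -- inputs ------------------------------------------------------------
    t = stage("inputs")
    if config.input_dir is None:
        sim_cfg_dict = dict(config.simulate)
        sim_cfg_dict.setdefault("seed", config.seed)
        sim_cfg = config_from_dict(sim_cfg_dict)
        result = simulate(sim_cfg)
        input_dir = os.path.join(config.out_dir, "inputs")
        io.emit_panels(result, input_dir)
    else:
        input_dir = config.input_dir
    errors = validate_inputs(input_dir)
    if errors:
        raise ValueError("input validation failed: " + "; ".join(errors))
    bundle = load_inputs(input_dir)
    report["stages"]["inputs"]["seconds"] = round(time.time() - t, 2)

    # -- annotation --------------------------------------------------------
    t = stage("annotate")
    units = annotate.build_units(
        bundle.features, bundle.genes, bundle.regions, bundle.chrom_map,
        bundle.contig_lengths,
    )
    io.write_tsv(units, os.path.join(config.out_dir, "units.tsv"))
    report["stages"]["annotate"]["seconds"] = round(time.time() - t, 2)
    report["n_units"] = int(len(units))

    # -- diversity ---------------------------------------------------------
    t = stage("diversity")
    ss = np.random.SeedSequence([config.seed, 7])
    sub_boot = {pop: s for pop, s in zip(POPULATIONS, ss.spawn(2))}
    unit_div, summaries = {}, {}
    for pop in POPULATIONS:
        panel = bundle.panels[pop]
        counted = diversity.count_informative(panel, units)
        kept = annotate.filter_units(
            counted, config.min_informative, config.min_fraction
        )
        div = diversity.unit_diversity_table(panel, kept)
        unit_div[pop] = div
        io.write_tsv(
            div.drop(columns=["entity_id"], errors="ignore"),
            os.path.join(config.out_dir, f"unit_diversity_{pop}.tsv"),
        )
        seeds = sub_boot[pop].spawn(5)
        auto = div[~div["contig"].isin(bundle.x_contigs)]
        summaries[pop] = {
            "global_autosomal": landscape.pooled_summary(
                auto, config.unit_bootstrap, seeds[0]
            ),
            "by_feature": landscape.group_summary(
                auto, "feature_class", config.unit_bootstrap, seeds[1]
            ),
            "by_region": landscape.group_summary(
                auto[auto["region_class"] != "unassigned"], "region_class",
                config.unit_bootstrap, seeds[2],
            ),
            "by_chromosome": landscape.group_summary(
                div[div["chromosome"].notna()
                    & (div["chromosome"] != "excluded")],
                "chromosome", config.unit_bootstrap, seeds[3],
            ),
        }
        # X/A ratio (PAR excluded, theta_W corrected by per-site hap counts)
        x_units = div[div["contig"].isin(bundle.x_contigs)]
        x_units = diversity.exclude_par(x_units, bundle.chrom_map,
                                        config.par_bp)
        if len(x_units) >= 2 and len(auto) >= 2:
            sx = landscape.pooled_summary(x_units, config.unit_bootstrap,
                                          seeds[4])
            sa = summaries[pop]["global_autosomal"]
            summaries[pop]["xa"] = {
                "pi": dataclasses.asdict(
                    landscape.xa_ratio(sx["pi"], sx["pi_sd"],
                                       sa["pi"], sa["pi_sd"])
                ),
                "theta_w": dataclasses.asdict(
                    landscape.xa_ratio(sx["theta_w"], sx["theta_sd"],
                                       sa["theta_w"], sa["theta_sd"])
                ),
                "n_x_units": int(len(x_units)),
            }
        else:
            summaries[pop]["xa"] = None  # not applicable
    report["stages"]["diversity"]["seconds"] = round(time.time() - t, 2)

    # -- covariates --------------------------------------------------------
    t = stage("covariates")
    functional = bundle.features[
        bundle.features["feature_class"].isin(FUNCTIONAL_CLASSES)
    ]
    counted_nb = diversity.count_informative(bundle.panels["NB"], units)
    cov = covariates.unit_covariate_table(
        counted_nb, bundle.recombination, bundle.substitutions,
        bundle.sequences, bundle.genes, bundle.rvis, functional,
        bundle.contig_lengths, config.functional_window_bp,
    )
    io.write_tsv(cov, os.path.join(config.out_dir, "unit_covariates.tsv"))
    cov_cols = ["recombination", "divergence", "gc", "rvis", "functional_pct"]
    report["stages"]["covariates"]["seconds"] = round(time.time() - t, 2)

    # -- landscape ---------------------------------------------------------
    t = stage("landscape")
    regressions = []
    chrom_div = summaries["NB"]["by_chromosome"]
    if len(chrom_div) >= 3:
        cov_by_chrom = (
            cov[cov["chromosome"].notna() & (cov["chromosome"] != "excluded")]
            .groupby("chromosome")[cov_cols]
            .mean()
        )
        merged = chrom_div.set_index("chromosome").join(cov_by_chrom)
        for col in cov_cols:
            for stat in ("pi", "theta_w"):
                try:
                    fit = landscape.regress(merged[col], merged[stat])
                except ValueError:
                    continue
                regressions.append(
                    {"population": "NB", "response": stat, "covariate": col,
                     **dataclasses.asdict(fit)}
                )
    nb_vs_b = []
    shared = unit_div["NB"][unit_div["NB"]["region_class"] != "unassigned"]
    for stat in ("pi", "theta_w"):
        nb_vs_b.append(
            landscape.regress_nb_vs_b(shared, unit_div["B"], statistic=stat)
        )
    nb_vs_b = pd.concat(nb_vs_b, ignore_index=True)
    io.write_tsv(nb_vs_b, os.path.join(config.out_dir,
                                       "nb_vs_b_regressions.tsv"))
    report["stages"]["landscape"]["seconds"] = round(time.time() - t, 2)

    # -- windowed deltas ---------------------------------------------------
    t = stage("deltas")
    feat_order = [
        f for f in units["feature_class"].unique()
        if f in set(unit_div["NB"]["feature_class"])
        & set(unit_div["B"]["feature_class"])
    ]
    ss_delta = np.random.SeedSequence([config.seed, 11])
    match_seed, boot_seed = ss_delta.spawn(2)
    window_frames = []
    shared_units = unit_div["NB"].merge(
        unit_div["B"][["unit_id"]], on="unit_id"
    )
    # autosomal windows only: the X's different sample size would distort
    # the pooled delta distributions
    shared_units = shared_units[~shared_units["contig"].isin(bundle.x_contigs)]
    for feature in sorted(set(shared_units["feature_class"])):
        f_units = shared_units[shared_units["feature_class"] == feature]
        series = deltas.match_and_concatenate(
            bundle.panels["NB"], bundle.panels["B"], f_units,
            subsample_n=config.subsample_n, seed=match_seed,
        )
        win = deltas.make_windows(series, config.window_sites)
        if len(win):
            window_frames.append(win)
    delta_report = {}
    windows = pd.DataFrame()
    feature_tests = pd.DataFrame()
    contrasts = pd.DataFrame()
    if window_frames:
        windows = pd.concat(window_frames, ignore_index=True)
        windows = deltas.zero_transform(windows, config.zero_threshold)
        windows = deltas.classify_windows(windows, config.gain_threshold)
        # per-window covariates, site-weighted over contributing units
        cov_idx = cov.set_index("unit_id")
        for col in cov_cols:
            windows[col] = covariates.annotate_windows(
                list(windows["unit_sites"]), cov_idx[col]
            )
        # ancestral (NB) diversity of the window is itself a covariate
        windows["S_nb"] = diversity.skew_S(windows["pi_nb"].to_numpy(),
                                           windows["theta_nb"].to_numpy())
        boot_seeds = boot_seed.spawn(2 * max(1, windows["feature_class"]
                                             .nunique()))
        k = 0
        for feature, grp in windows.groupby("feature_class"):
            entry = {"n_windows": int(len(grp)),
                     "zeroed": int(grp["zeroed"].sum())}
            for stat in ("delta_theta", "delta_pi"):
                if len(grp) >= 2:
                    entry[stat] = deltas.bootstrap_delta_dispersion(
                        grp[stat], config.window_bootstrap, boot_seeds[k]
                    )
                k += 1
            delta_report[feature] = entry
        by_feat = {
            f: grp["delta_theta"].to_numpy()
            for f, grp in windows.groupby("feature_class")
        }
        if "intergenic" in by_feat and len(by_feat) > 1:
            feature_tests = deltas.compare_feature_deltas(
                by_feat, paired=config.paired_feature_test
            )
        contrasts = deltas.classify_and_contrast(
            windows, cov_cols + ["pi_nb", "theta_nb", "S_nb"]
        )
        out_win = windows.drop(columns=["unit_sites"])
        io.write_tsv(out_win, os.path.join(config.out_dir, "windows.tsv"))
        if len(feature_tests):
            io.write_tsv(feature_tests,
                         os.path.join(config.out_dir, "feature_tests.tsv"))
        if len(contrasts):
            io.write_tsv(contrasts,
                         os.path.join(config.out_dir, "window_contrasts.tsv"))
    report["stages"]["deltas"]["seconds"] = round(time.time() - t, 2)

    # -- report ------------------------------------------------------------
    report["summaries"] = {
        pop: {
            key: (val.to_dict("records") if isinstance(val, pd.DataFrame)
                  else val)
            for key, val in s.items()
        }
        for pop, s in summaries.items()
    }
    report["chromosome_regressions"] = regressions
    report["nb_vs_b_regressions"] = nb_vs_b.to_dict("records")
    report["delta"] = delta_report
    report["feature_tests"] = feature_tests.to_dict("records")
    report["window_contrasts"] = contrasts.to_dict("records")
    if "zero_threshold" in getattr(windows, "attrs", {}):
        report["zero_threshold"] = windows.attrs["zero_threshold"]
    report = _to_native(report)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_markdown(report, os.path.join(config.out_dir, "report.md"))
    if config.make_plots and len(windows):
        from driftscape import plots

        plots.delta_by_feature(
            windows, os.path.join(config.out_dir, "delta_by_feature.png"),
            n_boot=config.window_bootstrap, seed=config.seed,
        )
        plots.delta_scatter(
            windows, os.path.join(config.out_dir, "delta_scatter.png")
        )
        if len(nb_vs_b):
            plots.regression_heatmap(
                nb_vs_b, os.path.join(config.out_dir, "nb_vs_b_heatmap.png")
            )
    log.info("pipeline done in %.1fs", time.time() - t_start)
    return report


def _write_markdown(report: dict, path) -> None:
    lines = ["# driftscape run report", ""]
    lines.append(f"seed: {report['seed']}; units: {report.get('n_units')}")
    for pop, s in report.get("summaries", {}).items():
        g = s.get("global_autosomal", {})
        lines.append(
            f"\n## {pop}\n\n"
            f"autosomal pi = {g.get('pi'):.3e} (sd {g.get('pi_sd'):.1e}), "
            f"theta_W = {g.get('theta_w'):.3e} (sd {g.get('theta_sd'):.1e}), "
            f"S = {g.get('S'):.3f}"
        )
        xa = s.get("xa")
        if xa:
            lines.append(
                f"X/A: pi ratio {xa['pi']['ratio']:.3f} "
                f"(sd {xa['pi']['sd']:.3f}), theta ratio "
                f"{xa['theta_w']['ratio']:.3f} (sd {xa['theta_w']['sd']:.3f})"
            )
        else:
            lines.append("X/A: not applicable (no X units)")
    if report.get("delta"):
        lines.append("\n## windowed deltas (B vs NB)\n")
        lines.append("| feature | windows | zeroed | mean dTheta | 95% CI |")
        lines.append("|---|---|---|---|---|")
        for feat, entry in sorted(report["delta"].items()):
            dt = entry.get("delta_theta")
            if dt:
                lines.append(
                    f"| {feat} | {entry['n_windows']} | {entry['zeroed']} | "
                    f"{dt['mean']:.3f} | [{dt['ci_low']:.3f}, "
                    f"{dt['ci_high']:.3f}] |"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
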