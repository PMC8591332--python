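"""Genomic covariates: recombination, divergence, GC, RVIS, functional density.

Each unit (and later each 1-kb analysis window) is annotated with the
covariates used to dissect the diversity landscape: recombination rate of
the surrounding 2-Mb map window (cM/Mb), divergence to an outgroup
(substitutions per informative site, a mutation-rate proxy), GC fraction of
the unit sequence, the per-gene RVIS intolerance score (more negative =
less tolerant of functional variation), and the percentage of functional
sites per 2-Mb window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from driftscape.annotate import merge_intervals

__all__ = [
    "recombination_for_units",
    "divergence_for_units",
    "gc_for_units",
    "functional_pct",
    "rvis_for_units",
    "annotate_windows",
    "unit_covariate_table",
]


def recombination_for_units(units: pd.DataFrame, rec_track: pd.DataFrame) -> pd.Series:
    """Recombination rate per unit: the value of the containing map window,
    or the site-weighted mean when a unit spans several windows; NaN when
    the unit's contig is not covered by the track."""
    out = np.full(len(units), np.nan)
    by_contig = {c: g.sort_values("start") for c, g in rec_track.groupby("contig")}
    for i, u in enumerate(units.itertuples(index=False)):
        track = by_contig.get(u.contig)
        if track is None:
            continue
        lo = np.maximum(track["start"].to_numpy(), u.start)
        hi = np.minimum(track["end"].to_numpy(), u.end)
        w = np.maximum(hi - lo, 0).astype(float)
        if w.sum() == 0:
            continue
        out[i] = np.average(track["value"].to_numpy(), weights=w)
    return pd.Series(out, index=units.index, name="recombination")


def divergence_for_units(units: pd.DataFrame, substitutions: pd.DataFrame) -> pd.Series:
    """Divergence per unit: substitution count within the unit divided by its
    informative-site count (mutation-rate proxy); NaN when no informative
    sites are available."""
    out = np.full(len(units), np.nan)
    subs_by_contig = {
        c: np.sort(g["start"].to_numpy()) for c, g in substitutions.groupby("contig")
    }
    for i, u in enumerate(units.itertuples(index=False)):
        if u.n_informative <= 0:
            continue
        pos = subs_by_contig.get(u.contig, np.array([], dtype=np.int64))
        n_sub = np.searchsorted(pos, u.end) - np.searchsorted(pos, u.start)
        out[i] = n_sub / u.n_informative
    return pd.Series(out, index=units.index, name="divergence")


def gc_for_units(units: pd.DataFrame, sequences: dict) -> pd.Series:
    """GC fraction per unit, N bases excluded from the denominator."""
    out = np.full(len(units), np.nan)
    for i, u in enumerate(units.itertuples(index=False)):
        seq = sequences.get(u.contig)
        if seq is None:
            continue
        sub = seq[u.start: u.end].upper()
        acgt = sum(sub.count(b) for b in "ACGT")
        if acgt == 0:
            continue
        out[i] = (sub.count("G") + sub.count("C")) / acgt
    return pd.Series(out, index=units.index, name="gc")


def functional_pct(
    windows: pd.DataFrame,
    functional_features: pd.DataFrame,
    window_bp: int = 2_000_000,
) -> pd.Series:
    """Percent functional sites per window: 100 * (deduplicated functional
    bases in the window) / ``window_bp``."""
    merged = {
        c: merge_intervals(g["start"], g["end"])
        for c, g in functional_features.groupby("contig")
    }
    out = np.zeros(len(windows))
    for i, w in enumerate(windows.itertuples(index=False)):
        s, e = merged.get(w.contig, (np.array([]), np.array([])))
        if s.size == 0:
            continue
        lo = np.maximum(s, w.start)
        hi = np.minimum(e, w.end)
        out[i] = 100.0 * np.maximum(hi - lo, 0).sum() / window_bp
    return pd.Series(out, index=windows.index, name="functional_pct")


def functional_pct_for_units(
    units: pd.DataFrame,
    functional_features: pd.DataFrame,
    contig_lengths: dict,
    window_bp: int = 2_000_000,
) -> pd.Series:
    """Functional-site percentage of the window containing each unit
    (site-weighted across windows when a unit spans a boundary)."""
    win_rows = []
    for contig, length in contig_lengths.items():
        for w0 in range(0, length, window_bp):
            win_rows.append((contig, w0, min(length, w0 + window_bp)))
    windows = pd.DataFrame(win_rows, columns=["contig", "start", "end"])
    windows["value"] = functional_pct(windows, functional_features, window_bp)
    return recombination_for_units(units, windows).rename("functional_pct")


def rvis_for_units(units: pd.DataFrame, genes: pd.DataFrame,
                   rvis: pd.DataFrame) -> pd.Series:
    """Join the per-gene RVIS score to gene-body units (CDS, intron, UTRs)
    by overlap with the gene interval; other units get NaN."""
    score = dict(zip(rvis["gene"], rvis["rvis"]))
    out = np.full(len(units), np.nan)
    gene_body = {"cds", "intron", "utr5", "utr3"}
    by_contig = {c: g for c, g in genes.groupby("contig")}
    for i, u in enumerate(units.itertuples(index=False)):
        if u.feature_class not in gene_body:
            continue
        cand = by_contig.get(u.contig)
        if cand is None:
            continue
        hit = cand[(cand["start"] < u.end) & (cand["end"] > u.start)]
        if len(hit):
            out[i] = score.get(hit.iloc[0]["name"], np.nan)
    return pd.Series(out, index=units.index, name="rvis")


def unit_covariate_table(
    units: pd.DataFrame,
    rec_track: pd.DataFrame,
    substitutions: pd.DataFrame,
    sequences: dict,
    genes: pd.DataFrame,
    rvis: pd.DataFrame,
    functional_features: pd.DataFrame,
    contig_lengths: dict,
    window_bp: int = 2_000_000,
) -> pd.DataFrame:
    """All per-unit covariates in one table (indexed like ``units``)."""
    out = units.copy()
    out["recombination"] = recombination_for_units(units, rec_track)
    out["divergence"] = divergence_for_units(units, substitutions)
    out["gc"] = gc_for_units(units, sequences)
    out["rvis"] = rvis_for_units(units, genes, rvis)
    out["functional_pct"] = functional_pct_for_units(
        units, functional_features, contig_lengths, window_bp
    )
    return out


def annotate_windows(
    window_unit_sites: list,
    unit_values: pd.Series,
) -> np.ndarray:
    """Site-weighted mean covariate per analysis window.

    ``window_unit_sites`` holds, per window, a mapping unit_id -> number of
    window sites contributed by that unit.  Units with a missing covariate
    drop out of both numerator and weight; a window with no annotated
    overlap gets NaN.
    """
    out = np.full(len(window_unit_sites), np.nan)
    for i, contrib in enumerate(window_unit_sites):
        num = den = 0.0
        for unit_id, n in contrib.items():
            v = unit_values.get(unit_id, np.nan)
            if np.isnan(v):
                continue
            num += v * n
            den += n
        if den > 0:
            out[i] = num / den
    return out
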