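"""Genomic units: building, classifying and filtering annotated intervals.

A *unit* is one contiguous interval of a single feature class (a CDS block,
an intron, a promoter, an intergenic stretch, ...).  All coordinates are
0-based half-open (BED convention); VCF positions are converted on read.
Units are assigned to chromosomal regions (subtelomeric / pericentromeric /
interstitial) when they overlap one region class by at least 75% of their
length, to chromosomes when they do not span a chromosome boundary, and are
kept for analysis only when they retain more than 50 informative sites
covering at least 20% of their positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "derive_promoters",
    "derive_intergenic",
    "assign_region",
    "assign_chromosome",
    "filter_units",
    "build_units",
    "merge_intervals",
]


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping sorted-or-not intervals on one contig."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def _overlap_lengths(u_start, u_end, starts, ends) -> np.ndarray:
    """Total overlap of one interval with a merged, sorted interval set."""
    if starts.size == 0:
        return np.int64(0)
    lo = np.maximum(starts, u_start)
    hi = np.minimum(ends, u_end)
    return np.maximum(hi - lo, 0).sum()


def derive_promoters(
    genes: pd.DataFrame,
    contig_lengths: dict,
    upstream: int = 1000,
    feature_class: str = "gene_promoter",
) -> pd.DataFrame:
    """One promoter unit per gene: the ``upstream`` bp 5' of the TSS.

    On the + strand that is [start-upstream, start); on the - strand
    (end, end+upstream] i.e. [end, end+upstream) in half-open coordinates.
    Promoters are clipped to contig bounds; empty ones are dropped.
    """
    if "strand" not in genes.columns or genes["strand"].isna().any():
        raise ValueError("gene intervals must carry strand")
    rows = []
    for g in genes.itertuples(index=False):
        length = contig_lengths[g.contig]
        if g.strand == "+":
            s, e = g.start - upstream, g.start
        elif g.strand == "-":
            s, e = g.end, g.end + upstream
        else:
            raise ValueError(f"bad strand {g.strand!r} for gene {g.name!r}")
        s, e = max(0, s), min(length, e)
        if e > s:
            rows.append((g.contig, s, e, feature_class, g.name))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "feature_class", "entity_id"]
    )


def derive_intergenic(
    annotated: pd.DataFrame,
    contig_lengths: dict,
    buffer: int = 1000,
) -> pd.DataFrame:
    """Intergenic units: the complement of all annotated intervals extended
    by a +/- ``buffer`` bp guard against the influence of adjacent features."""
    rows = []
    for contig, length in contig_lengths.items():
        sub = annotated[annotated["contig"] == contig]
        s, e = merge_intervals(
            np.maximum(sub["start"].to_numpy() - buffer, 0),
            np.minimum(sub["end"].to_numpy() + buffer, length),
        )
        gaps_s = np.concatenate([[0], e])
        gaps_e = np.concatenate([s, [length]])
        for a, b in zip(gaps_s, gaps_e):
            if b > a:
                rows.append((contig, int(a), int(b), "intergenic",
                             f"intergenic@{contig}:{a}"))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "feature_class", "entity_id"]
    )


def assign_region(
    units: pd.DataFrame,
    regions: pd.DataFrame,
    min_overlap: float = 0.75,
) -> pd.Series:
    """Region class per unit: the label covering >= ``min_overlap`` of the
    unit's length, else 'unassigned'.

    Region intervals of different labels must not overlap each other.
    """
    by_label: dict[str, dict] = {}
    for label, sub in regions.groupby("region_class"):
        by_label[label] = {
            contig: merge_intervals(g["start"], g["end"])
            for contig, g in sub.groupby("contig")
        }
    # overlapping labels are a malformed partition
    for contig, sub in regions.groupby("contig"):
        s, e = merge_intervals(sub["start"], sub["end"])
        if (e - s).sum() != (sub["end"] - sub["start"]).sum():
            raise ValueError(
                f"region labels overlap each other on contig {contig!r}"
            )
    out = []
    for u in units.itertuples(index=False):
        length = u.end - u.start
        assigned = "unassigned"
        for label, per_contig in by_label.items():
            s, e = per_contig.get(u.contig, (np.array([]), np.array([])))
            ov = _overlap_lengths(u.start, u.end, s, e)
            if ov >= min_overlap * length:
                assigned = label
                break
        out.append(assigned)
    return pd.Series(out, index=units.index, name="region_class")


def assign_chromosome(units: pd.DataFrame, chrom_map: pd.DataFrame) -> pd.Series:
    """Chromosome label per unit; 'excluded' when a unit spans more than one
    chromosome, NaN when its contig is absent from the map (such units stay
    in feature-level summaries but drop out of chromosome-level ones)."""
    out = []
    by_contig = {c: g for c, g in chrom_map.groupby("contig")}
    for u in units.itertuples(index=False):
        spans = by_contig.get(u.contig)
        if spans is None:
            out.append(np.nan)
            continue
        hit = spans[(spans["start"] < u.end) & (spans["end"] > u.start)]
        labels = set(hit["chromosome"])
        if len(labels) == 0:
            out.append(np.nan)
        elif len(labels) == 1:
            out.append(labels.pop())
        else:
            out.append("excluded")
    return pd.Series(out, index=units.index, name="chromosome")


def filter_units(
    units: pd.DataFrame,
    min_informative: int = 50,
    min_fraction: float = 0.20,
) -> pd.DataFrame:
    """Keep units with *more than* ``min_informative`` informative sites and
    information for at least ``min_fraction`` of their positions."""
    n_inf = units["n_informative"].to_numpy()
    n_tot = units["n_total"].to_numpy()
    keep = (n_inf > min_informative) & (n_inf >= min_fraction * n_tot)
    return units.loc[keep].reset_index(drop=True)


def build_units(
    features: pd.DataFrame,
    genes: pd.DataFrame,
    regions: pd.DataFrame,
    chrom_map: pd.DataFrame,
    contig_lengths: dict,
    promoter_bp: int = 1000,
    intergenic_buffer: int = 1000,
) -> pd.DataFrame:
    """Assemble the full unit table from raw annotation.

    Promoters are derived upstream of protein-coding genes and lncRNAs,
    intergenic units as the buffered complement of everything annotated;
    every unit gets region and chromosome labels and a stable unit_id.
    """
    pieces = [features.copy()]
    if len(genes):
        coding = genes[genes.get("kind", "gene") == "gene"]
        lnc = genes[genes.get("kind", "gene") == "lncrna"]
        if len(coding):
            pieces.append(
                derive_promoters(coding, contig_lengths, promoter_bp,
                                 "gene_promoter")
            )
        if len(lnc):
            pieces.append(
                derive_promoters(lnc, contig_lengths, promoter_bp,
                                 "lnc_promoter")
            )
    annotated = pd.concat(pieces, ignore_index=True)
    intergenic = derive_intergenic(
        annotated[["contig", "start", "end"]], contig_lengths,
        buffer=intergenic_buffer,
    )
    units = pd.concat([annotated, intergenic], ignore_index=True)
    units = units.sort_values(["contig", "start", "end"]).reset_index(drop=True)
    units["unit_id"] = [
        f"u{i:06d}|{c}" for i, c in enumerate(units["feature_class"])
    ]
    units["region_class"] = assign_region(units, regions)
    units["chromosome"] = assign_chromosome(units, chrom_map)
    cols = ["unit_id", "feature_class", "contig", "start", "end",
            "chromosome", "region_class", "entity_id"]
    return units[cols]
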