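"""Unit building: promoters, intergenic complement, region/chromosome
assignment and the informative-site filter."""

import numpy as np
import pandas as pd
import pytest

from driftscape.annotate import (
    assign_chromosome,
    assign_region,
    build_units,
    derive_intergenic,
    derive_promoters,
    filter_units,
    merge_intervals,
)


def genes_df(rows):
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "name", "strand", "kind"]
    )


class TestPromoters:
    def test_plus_strand_upstream(self):
        genes = genes_df([("c", 5000, 8000, "g1", "+", "gene")])
        out = derive_promoters(genes, {"c": 10_000})
        assert out.iloc[0][["start", "end"]].tolist() == [4000, 5000]

    def test_minus_strand_downstream_of_end(self):
        genes = genes_df([("c", 5000, 8000, "g1", "-", "gene")])
        out = derive_promoters(genes, {"c": 10_000})
        assert out.iloc[0][["start", "end"]].tolist() == [8000, 9000]

    def test_clipped_empty_promoter_dropped(self):
        genes = genes_df([("c", 0, 8000, "g1", "+", "gene")])
        out = derive_promoters(genes, {"c": 10_000})
        assert len(out) == 0

    def test_missing_strand_errors(self):
        genes = genes_df([("c", 100, 200, "g1", None, "gene")])
        with pytest.raises(ValueError):
            derive_promoters(genes, {"c": 10_000})


class TestIntergenic:
    def test_complement_with_buffer(self):
        ann = pd.DataFrame([("c", 4000, 6000)],
                           columns=["contig", "start", "end"])
        out = derive_intergenic(ann, {"c": 10_000}, buffer=1000)
        assert out[["start", "end"]].values.tolist() == [[0, 3000], [7000, 10000]]

    def test_fully_annotated_contig_has_no_intergenic(self):
        ann = pd.DataFrame([("c", 0, 10_000)],
                           columns=["contig", "start", "end"])
        assert len(derive_intergenic(ann, {"c": 10_000})) == 0

    def test_empty_annotation_whole_contig(self):
        ann = pd.DataFrame(columns=["contig", "start", "end"])
        out = derive_intergenic(ann, {"c": 5000})
        assert out[["start", "end"]].values.tolist() == [[0, 5000]]

    def test_disjoint_from_buffered_annotation(self):
        rng = np.random.default_rng(3)
        starts = np.sort(rng.choice(50_000, size=10, replace=False))
        ann = pd.DataFrame(
            [("c", int(s), int(s + rng.integers(100, 2000))) for s in starts],
            columns=["contig", "start", "end"],
        )
        out = derive_intergenic(ann, {"c": 60_000}, buffer=1000)
        ms, me = merge_intervals(ann["start"] - 1000, ann["end"] + 1000)
        for row in out.itertuples(index=False):
            overlap = np.maximum(
                np.minimum(me, row.end) - np.maximum(ms, row.start), 0
            ).sum()
            assert overlap == 0


class TestRegions:
    regions = pd.DataFrame(
        [
            ("c", 0, 2000, "subtelomeric"),
            ("c", 2000, 8000, "interstitial"),
            ("c", 8000, 10_000, "pericentromeric"),
        ],
        columns=["contig", "start", "end", "region_class"],
    )

    def unit(self, s, e):
        return pd.DataFrame([{"unit_id": "u", "contig": "c",
                              "start": s, "end": e}])

    def test_eighty_percent_overlap_assigned(self):
        # 800 of 1000 bp subtelomeric
        assert assign_region(self.unit(1200, 2200), self.regions)[0] == \
            "subtelomeric"

    def test_below_threshold_unassigned(self):
        # 740 bp pericentromeric, 260 interstitial -> 0.74 < 0.75
        out = assign_region(self.unit(7260, 8260), self.regions)
        # 7260..8000 interstitial is 740, 8000..8260 peri is 260 -> swap
        assert out[0] == "unassigned"

    def test_fully_interstitial(self):
        assert assign_region(self.unit(3000, 4000), self.regions)[0] == \
            "interstitial"

    def test_overlapping_region_labels_error(self):
        bad = pd.DataFrame(
            [("c", 0, 2000, "subtelomeric"), ("c", 1000, 3000, "interstitial")],
            columns=["contig", "start", "end", "region_class"],
        )
        with pytest.raises(ValueError):
            assign_region(self.unit(0, 100), bad)


class TestChromosome:
    chrom_map = pd.DataFrame(
        [("c1", 0, 5000, "chrA1", 0), ("c1", 5000, 9000, "chrA2", 0),
         ("c2", 0, 4000, "chrA1", 5000)],
        columns=["contig", "start", "end", "chromosome", "chrom_start"],
    )

    def test_single_chromosome(self):
        units = pd.DataFrame([{"contig": "c2", "start": 10, "end": 20}])
        assert assign_chromosome(units, self.chrom_map)[0] == "chrA1"

    def test_breakpoint_spanning_excluded(self):
        units = pd.DataFrame([{"contig": "c1", "start": 4500, "end": 5500}])
        assert assign_chromosome(units, self.chrom_map)[0] == "excluded"

    def test_unmapped_contig_unlabelled(self):
        units = pd.DataFrame([{"contig": "c9", "start": 0, "end": 10}])
        assert pd.isna(assign_chromosome(units, self.chrom_map)[0])


class TestFilter:
    def frame(self, n_inf, n_tot):
        return pd.DataFrame(
            [{"unit_id": "u", "n_informative": n_inf, "n_total": n_tot}]
        )

    @pytest.mark.parametrize(
        "n_inf,n_tot,kept",
        [
            (51, 200, True),   # both rules pass (25.5%)
            (50, 100, False),  # "more than 50" is strict
            (120, 1000, False),  # 12% < 20%
            (51, 255, True),   # exactly 20%
        ],
    )
    def test_filter_rules(self, n_inf, n_tot, kept):
        out = filter_units(self.frame(n_inf, n_tot))
        assert (len(out) == 1) == kept


def test_build_units_covers_genome_consistently(tiny_sim):
    """Units from simulated annotation: one region label each, intergenic
    disjoint from buffered features, chromosome labels from the map."""
    g = tiny_sim.genome
    units = build_units(
        g.features, g.genes, g.regions, g.chrom_map,
        g.contig_lengths,
    )
    assert set(units["region_class"]) <= {
        "subtelomeric", "pericentromeric", "interstitial", "unassigned"
    }
    # promoters derived for every gene and lncRNA
    n_prom = (units["feature_class"] == "gene_promoter").sum()
    n_lncp = (units["feature_class"] == "lnc_promoter").sum()
    assert n_prom == (g.genes["kind"] == "gene").sum()
    assert n_lncp == (g.genes["kind"] == "lncrna").sum()
    # intergenic never within 1 kb of an annotated feature
    inter = units[units["feature_class"] == "intergenic"]
    feats = units[units["feature_class"] != "intergenic"]
    for contig, grp in inter.groupby("contig"):
        fs = feats[feats["contig"] == contig]
        ms, me = merge_intervals(fs["start"] - 1000, fs["end"] + 1000)
        for row in grp.itertuples(index=False):
            ov = np.maximum(
                np.minimum(me, row.end) - np.maximum(ms, row.start), 0
            ).sum()
            assert ov == 0
    # no base is covered by two units of the same build except promoters,
    # which may overlap other features by design; check intergenic+features
    core = units[units["feature_class"].isin(
        ["intergenic", "cds", "intron", "utr5", "utr3", "lnc_exon",
         "lnc_intron", "ncrna", "ucne"]
    )]
    for contig, grp in core.groupby("contig"):
        iv = grp.sort_values("start")
        assert (iv["start"].to_numpy()[1:] >= iv["end"].to_numpy()[:-1]).all()
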