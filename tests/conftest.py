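"""Shared fixtures: hand-built genotype panels and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from driftscape.panel import ABSENT, MISSING, ContigCalls, GenotypePanel


def make_panel(
    genotypes,
    sex=None,
    population="P",
    contig="ctg01",
    x_contig=False,
    positions=None,
):
    """Panel from a (n_sites, n_samples, 2) nested list of allele codes
    (0/1, None=missing slot, 'H'=hemizygous absent slot)."""
    arr = np.asarray(genotypes, dtype=object)
    n_sites, n_samples, _ = arr.shape
    alleles = np.empty((n_sites, 2 * n_samples), dtype=np.int8)
    for i in range(n_sites):
        for j in range(n_samples):
            for k in range(2):
                v = arr[i, j, k]
                if v is None:
                    alleles[i, 2 * j + k] = MISSING
                elif v == "H":
                    alleles[i, 2 * j + k] = ABSENT
                else:
                    alleles[i, 2 * j + k] = v
    if sex is None:
        sex = ["F"] * n_samples
    if positions is None:
        positions = np.arange(n_sites)
    panel = GenotypePanel(
        population=population,
        samples=[f"{population}{j + 1:02d}" for j in range(n_samples)],
        sex=np.asarray(sex, dtype="<U1"),
        x_contigs={contig} if x_contig else set(),
    )
    panel.calls[contig] = ContigCalls(positions=np.asarray(positions),
                                      alleles=alleles)
    return panel


def random_panel(rng, n_diploid, n_sites, missing_rate=0.0, contig="ctg01"):
    """Random biallelic panel with uniform allele frequencies per site."""
    f = rng.uniform(0.0, 1.0, size=n_sites)
    alleles = (rng.random((n_sites, 2 * n_diploid)) < f[:, None]).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((n_sites, n_diploid)) < missing_rate
        alleles[np.repeat(miss, 2, axis=1)] = MISSING
    panel = GenotypePanel(
        population="R",
        samples=[f"R{j:02d}" for j in range(n_diploid)],
        sex=np.asarray(["F"] * n_diploid, dtype="<U1"),
    )
    panel.calls[contig] = ContigCalls(positions=np.arange(n_sites),
                                      alleles=alleles)
    return panel


@pytest.fixture
def units_one_contig():
    def _make(intervals, contig="ctg01", feature="intergenic"):
        return pd.DataFrame(
            [
                {
                    "unit_id": f"u{i}",
                    "feature_class": feature,
                    "contig": contig,
                    "start": s,
                    "end": e,
                }
                for i, (s, e) in enumerate(intervals)
            ]
        )

    return _make


@pytest.fixture(scope="session")
def tiny_sim():
    """One small full simulation shared by read-only tests."""
    from driftscape.simulate import SimConfig, simulate

    cfg = SimConfig(
        seed=11,
        n_contigs=4,
        contig_length=20_000,
        feature_layout=[("gene", 2600, 1), ("lncrna", 1400, 1),
                        ("ucne", 250, 2), ("ncrna", 300, 1)],
    )
    return simulate(cfg)
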