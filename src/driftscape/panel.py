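"""In-memory genotype panels.

A :class:`GenotypePanel` holds, for one population, the called genotypes of
every site of every contig (variant and invariant alike), because the
"informative site" bookkeeping that weights all downstream diversity
estimates needs per-site missingness at monomorphic positions too.

Allele codes are ``int8``: 0 = ancestral/reference, 1 = derived/alternate,
``MISSING`` (-1) = genotype absent, ``ABSENT`` (-9) = slot does not exist
(the second allele slot of a hemizygous male on the X).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = np.int8(-1)
ABSENT = np.int8(-9)

MALE = "M"
FEMALE = "F"


@dataclass
class ContigCalls:
    """All per-site calls of one contig: positions (0-based, sorted) and an
    ``(n_sites, 2 * n_samples)`` int8 allele matrix."""

    positions: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != self.positions.size:
            raise ValueError("alleles must be (n_sites, 2*n_samples)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)


@dataclass
class SiteCountsArrays:
    """Vectorised per-site allele counts for one contig.

    ``ref + alt = n_hap`` (non-missing haploid calls); ``n_called`` counts
    individuals with a genotype; ``informative`` marks sites usable for
    diversity estimation.
    """

    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    n_hap: np.ndarray
    n_called: np.ndarray
    informative: np.ndarray


@dataclass
class GenotypePanel:
    """Diploid genotype panel of one population (hemizygous males on X)."""

    population: str
    samples: list[str]
    sex: np.ndarray  # '<U1' array of 'M'/'F', one per sample
    calls: dict[str, ContigCalls] = field(default_factory=dict)
    x_contigs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype="<U1")
        bad = set(self.sex) - {MALE, FEMALE}
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")
        if self.sex.size != len(self.samples):
            raise ValueError("one sex label per sample required")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def contigs(self) -> list[str]:
        return list(self.calls)

    def max_haplotypes(self, contig: str) -> int:
        """2 per female plus, on the X, 1 per male (else 2)."""
        if contig in self.x_contigs:
            n_f = int(np.sum(self.sex == FEMALE))
            n_m = int(np.sum(self.sex == MALE))
            return 2 * n_f + n_m
        return 2 * self.n_samples

    def site_counts(
        self, contig: str, individuals: np.ndarray | None = None
    ) -> SiteCountsArrays:
        """Per-site ref/alt counts among non-missing haploid calls.

        ``individuals`` optionally restricts to a subset (integer indices),
        e.g. after subsampling populations to a common size.  A site is
        *informative* when at least half of the (selected) individuals have a
        genotype and at least two haploid calls are present.
        """
        cc = self.calls[contig]
        alleles = cc.alleles
        n_ind = self.n_samples
        if individuals is not None:
            individuals = np.asarray(individuals, dtype=np.intp)
            cols = np.empty(individuals.size * 2, dtype=np.intp)
            cols[0::2] = individuals * 2
            cols[1::2] = individuals * 2 + 1
            alleles = alleles[:, cols]
            n_ind = individuals.size
        ref = np.count_nonzero(alleles == 0, axis=1)
        alt = np.count_nonzero(alleles == 1, axis=1)
        n_hap = ref + alt
        # an individual is "called" when any of its slots holds an allele
        called = (alleles >= 0).reshape(alleles.shape[0], n_ind, 2).any(axis=2)
        n_called = np.count_nonzero(called, axis=1)
        informative = (2 * n_called >= n_ind) & (n_hap >= 2)
        return SiteCountsArrays(
            positions=cc.positions,
            ref=ref.astype(np.int64),
            alt=alt.astype(np.int64),
            n_hap=n_hap.astype(np.int64),
            n_called=n_called.astype(np.int64),
            informative=informative,
        )
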