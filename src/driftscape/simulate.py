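"""Synthetic two-population genotype panels with the structure the
landscape analysis assumes.

The generator mimics a pair of conspecific populations sampled from one
ancestral pool: a non-bottlenecked population (NB) drawn directly from the
ancestral equilibrium, and a bottlenecked population (B) obtained by
drifting the same ancestral allele frequencies forward ``g_B`` generations
at a small diploid size ``Ne_B`` (Wright-Fisher binomial sampling with
additive selection against derived alleles and symmetric mutation).

Ancestral equilibrium frequencies are drawn from a discrete site-frequency
spectrum over ``2*Ne`` frequency classes: neutral weight 1/i per class i,
reweighted by exp(-4*Ne*s*i/(2*Ne)) for deleterious additive variants, so
selected feature classes are singleton-rich.  The per-site probability that
a site segregates at all is theta * sum(weights) with theta = 4*Ne*mu, the
infinite-sites expectation.

X-flagged contigs use an effective size of 3/4 of the autosomal one (male
hemizygosity) at both equilibrium and drift, and males receive a single
haploid call on X.  Feature classes differ in mutation rate (mu) and
selection strength (s); chromosomal regions modulate mu so subtelomeric
windows are more diverse than pericentromeric ones; covariate tracks
(divergence, GC, recombination, RVIS, functional-site density) are emitted
correlated with the underlying mu and s so downstream regressions have
signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from driftscape.panel import ABSENT, FEMALE, MALE, MISSING, ContigCalls, GenotypePanel

FEATURE_CLASSES = [
    "intergenic",
    "gene_promoter",
    "utr5",
    "cds",
    "intron",
    "utr3",
    "lnc_promoter",
    "lnc_exon",
    "lnc_intron",
    "ncrna",
    "ucne",
]

#: functional classes entering the functional-site density covariate
FUNCTIONAL_CLASSES = [c for c in FEATURE_CLASSES if c != "intergenic"]

REGION_CLASSES = ["subtelomeric", "pericentromeric", "interstitial"]

_DEFAULT_MU = {
    "intergenic": 2.5e-6,
    "gene_promoter": 3.0e-6,
    "utr5": 2.75e-6,
    "cds": 2.5e-6,
    "intron": 2.5e-6,
    "utr3": 2.5e-6,
    "lnc_promoter": 2.75e-6,
    "lnc_exon": 2.5e-6,
    "lnc_intron": 2.5e-6,
    "ncrna": 2.75e-6,
    "ucne": 2.25e-6,
}

# additive selection against the derived allele; ucne strongest (ultra
# conserved), cds strong, regulatory classes intermediate, intergenic neutral
_DEFAULT_S = {
    "intergenic": 0.0,
    "gene_promoter": 0.01,
    "utr5": 0.01,
    "cds": 0.02,
    "intron": 0.001,
    "utr3": 0.005,
    "lnc_promoter": 0.005,
    "lnc_exon": 0.002,
    "lnc_intron": 0.001,
    "ncrna": 0.01,
    "ucne": 0.04,
}


@dataclass
class SimConfig:
    """Study conditions for the two-population simulation.

    Defaults model an Iberian-lynx-like contrast: an NB population near
    ancestral equilibrium and a B population drifted ~40 generations at
    diploid Ne = 10, sampled at 12 diploids each, with a hemizygous X at 3/4
    autosomal effective size and 10% per-site per-individual missingness.
    """

    seed: int = 0
    n_contigs: int = 8
    contig_length: int = 50_000
    #: per contig: (entity class, entity length bp, copies); "gene" and
    #: "lncrna" expand into UTR/CDS/intron (resp. exon/intron) sub-features
    feature_layout: list = field(
        default_factory=lambda: [
            ("gene", 2600, 2),
            ("lncrna", 1400, 1),
            ("ucne", 250, 2),
            ("ncrna", 300, 1),
        ]
    )
    Ne_anc: int = 2000
    Ne_B: int = 10
    g_B: int = 40
    mu_per_class: dict = field(default_factory=lambda: dict(_DEFAULT_MU))
    s_per_class: dict = field(default_factory=lambda: dict(_DEFAULT_S))
    x_fraction: float = 0.25
    sample_NB: int = 12
    sample_B: int = 12
    sex_ratio: float = 0.5  # fraction female
    missing_rate: float = 0.10
    # layout of chromosomes and regions
    contigs_per_chromosome: int = 2
    subtelomeric_fraction: float = 0.15  # of chromosome length, each end
    pericentromeric_fraction: float = 0.20  # around the chromosome midpoint
    region_mu_multiplier: dict = field(
        default_factory=lambda: {
            "subtelomeric": 1.4,
            "pericentromeric": 0.7,
            "interstitial": 1.0,
        }
    )
    # covariate generation
    divergence_factor: float = 2000.0  # substitution prob per site = f * mu
    gc_base: float = 0.30
    gc_mu_slope: float = 30000.0  # gc = gc_base + slope * mu
    rec_window_bp: int = 25_000
    rvis_noise_sd: float = 0.3
    # per-gene constraint heterogeneity (lognormal sigma of the s multiplier)
    gene_s_sigma: float = 0.4

    def validate(self) -> None:
        if not (0 < self.Ne_B <= self.Ne_anc):
            raise ValueError("require 0 < Ne_B <= Ne_anc")
        if self.g_B < 0:
            raise ValueError("g_B must be >= 0")
        for name in ("x_fraction", "sex_ratio", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for cls, mu in self.mu_per_class.items():
            if not (0.0 <= mu <= 1.0):
                raise ValueError(f"mu_per_class[{cls}] out of [0, 1]")
        for cls, s in self.s_per_class.items():
            if s < 0:
                raise ValueError(f"s_per_class[{cls}] must be >= 0")
        if self.sample_NB < 2 or self.sample_B < 2:
            raise ValueError("sample sizes must be >= 2")
        per_contig = sum(n * c for _, n, c in self.feature_layout)
        if per_contig >= self.contig_length:
            raise ValueError("feature layout does not fit in contig_length")


# ---------------------------------------------------------------------------
# equilibrium site-frequency spectrum


def sfs_weights(n_classes: int, s: float = 0.0, ne: float | None = None) -> np.ndarray:
    """Unnormalised weights of derived-frequency classes i = 1..n_classes-1.

    Neutral weight is 1/i; deleterious additive variants are reweighted by
    exp(-4*Ne*s*i/n_classes), concentrating mass at low frequencies.
    """
    if n_classes < 2:
        raise ValueError("need at least two frequency classes")
    i = np.arange(1, n_classes)
    w = 1.0 / i
    if s > 0:
        if ne is None:
            raise ValueError("Ne required for selected equilibrium weights")
        w = w * np.exp(-4.0 * ne * s * i / n_classes)
    if not np.all(np.isfinite(w)):
        raise ValueError("nonfinite SFS weights")
    return w


def sample_equilibrium_frequency(
    n_classes: int,
    s: float = 0.0,
    ne: float | None = None,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Draw derived-allele frequencies i/n_classes from the equilibrium SFS,
    conditional on the site segregating."""
    rng = np.random.default_rng() if rng is None else rng
    w = sfs_weights(n_classes, s=s, ne=ne)
    p = w / w.sum()
    i = rng.choice(np.arange(1, n_classes), size=size, p=p)
    return i / n_classes


def segregating_probability(n_classes: int, mu: float, s: float = 0.0,
                            ne: float | None = None) -> float:
    """Infinite-sites probability that a site is polymorphic in the pool:
    theta * sum(weights) with theta = 2 * n_classes * mu (= 4*Ne*mu)."""
    theta = 2.0 * n_classes * mu
    p = theta * float(sfs_weights(n_classes, s=s, ne=ne).sum())
    return min(p, 0.95)


# ---------------------------------------------------------------------------
# forward drift


def drift_forward(
    freq,
    ne: int,
    g: int,
    s=0.0,
    mu=0.0,
    rng: np.random.Generator | None = None,
):
    """Drift derived-allele frequencies ``g`` Wright-Fisher generations.

    Each generation applies deterministic additive selection against the
    derived allele, p' = p(1-s)/(1-p*s), symmetric mutation
    p'' = p'(1-mu) + (1-p')mu, then binomial sampling of 2*Ne gametes.
    Accepts scalars or arrays (broadcast elementwise).
    """
    if g < 0:
        raise ValueError("generations must be >= 0")
    if ne < 1:
        raise ValueError("Ne must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    scalar = np.isscalar(freq) or np.ndim(freq) == 0
    p = np.atleast_1d(np.asarray(freq, dtype=float)).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    s = np.broadcast_to(np.asarray(s, dtype=float), p.shape)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), p.shape)
    n_gam = 2 * int(ne)
    for _ in range(int(g)):
        p = p * (1.0 - s) / (1.0 - p * s)
        p = p * (1.0 - mu) + (1.0 - p) * mu
        p = rng.binomial(n_gam, p) / n_gam
    return float(p[0]) if scalar else p


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class SimulatedGenome:
    """Annotation truth: contigs, feature/gene/region intervals, chromosome
    map, and per-site mutation/selection arrays."""

    contig_lengths: dict
    x_contigs: set
    features: pd.DataFrame  # contig,start,end,feature_class,entity_id
    genes: pd.DataFrame  # contig,start,end,name,strand,kind (gene|lncrna)
    regions: pd.DataFrame  # contig,start,end,region_class
    chrom_map: pd.DataFrame  # contig,start,end,chromosome,chrom_start
    site_class: dict  # contig -> int8 per-site feature-class code
    site_mu: dict  # contig -> float per-site mutation rate
    site_s: dict  # contig -> float per-site selection coefficient


_GENE_PARTS = [  # (class, fraction of gene span), 5' to 3'
    ("utr5", 0.06),
    ("cds", 0.12),
    ("intron", 0.26),
    ("cds", 0.12),
    ("intron", 0.26),
    ("cds", 0.12),
    ("utr3", 0.06),
]

_LNC_PARTS = [("lnc_exon", 0.3), ("lnc_intron", 0.4), ("lnc_exon", 0.3)]


def _split_entity(kind: str, start: int, length: int, strand: str):
    """Expand a gene/lncRNA span into sub-feature intervals."""
    parts = _GENE_PARTS if kind == "gene" else _LNC_PARTS
    if strand == "-":
        parts = parts[::-1]
    cum = np.cumsum([0.0] + [frac for _, frac in parts])
    bounds = start + np.round(length * cum / cum[-1]).astype(int)
    out = []
    for (cls, _), a, b in zip(parts, bounds[:-1], bounds[1:]):
        if b > a:
            out.append((cls, int(a), int(b)))
    return out


def build_genome(config: SimConfig) -> SimulatedGenome:
    """Lay out contigs, genes, standalone features, regions, chromosomes and
    the per-site mu/s arrays implied by them."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_x = int(round(config.x_fraction * config.n_contigs))
    contig_names = [f"ctg{i + 1:02d}" for i in range(config.n_contigs)]
    x_contigs = set(contig_names[config.n_contigs - n_x:])
    contig_lengths = {c: config.contig_length for c in contig_names}

    cls_code = {c: k for k, c in enumerate(FEATURE_CLASSES)}
    feat_rows, gene_rows = [], []
    site_class, site_mu, site_s = {}, {}, {}

    # chromosome map: autosomes group contigs_per_chromosome contigs; all X
    # contigs form chrX
    chrom_rows = []
    autosomes = [c for c in contig_names if c not in x_contigs]
    n_chrom = max(1, (len(autosomes) + config.contigs_per_chromosome - 1)
                  // config.contigs_per_chromosome)
    chrom_of = {}
    for k, contig in enumerate(autosomes):
        chrom_of[contig] = f"chr{k // config.contigs_per_chromosome + 1}"
    for contig in x_contigs:
        chrom_of[contig] = "chrX"
    offsets = {}
    for contig in contig_names:
        chrom = chrom_of[contig]
        off = offsets.get(chrom, 0)
        chrom_rows.append((contig, 0, contig_lengths[contig], chrom, off))
        offsets[chrom] = off + contig_lengths[contig]
    chrom_map = pd.DataFrame(
        chrom_rows, columns=["contig", "start", "end", "chromosome", "chrom_start"]
    )

    # regions: per chromosome, subtelomeric ends / pericentromeric middle
    region_rows = []
    for chrom, total in offsets.items():
        sub = int(round(config.subtelomeric_fraction * total))
        peri = int(round(config.pericentromeric_fraction * total))
        mid = total // 2
        spans = [
            (0, sub, "subtelomeric"),
            (sub, mid - peri // 2, "interstitial"),
            (mid - peri // 2, mid + peri - peri // 2, "pericentromeric"),
            (mid + peri - peri // 2, total - sub, "interstitial"),
            (total - sub, total, "subtelomeric"),
        ]
        cmap = chrom_map[chrom_map["chromosome"] == chrom]
        for cstart, cend, label in spans:
            if cend <= cstart:
                continue
            for row in cmap.itertuples(index=False):
                lo = max(cstart, row.chrom_start)
                hi = min(cend, row.chrom_start + (row.end - row.start))
                if hi > lo:
                    region_rows.append(
                        (row.contig, lo - row.chrom_start, hi - row.chrom_start, label)
                    )
    regions = (
        pd.DataFrame(region_rows, columns=["contig", "start", "end", "region_class"])
        .sort_values(["contig", "start"])
        .reset_index(drop=True)
    )

    # entities per contig, evenly spaced; promoters live in the gaps
    entities = []
    for kind, length, copies in config.feature_layout:
        entities.extend([(kind, length)] * copies)
    total_len = sum(ln for _, ln in entities)
    gene_counter = 0
    for contig in contig_names:
        L = contig_lengths[contig]
        gap = (L - total_len) // (len(entities) + 1)
        has_genes = any(kind in ("gene", "lncrna") for kind, _ in entities)
        if (has_genes and gap < 2100) or gap < 100:
            raise ValueError(
                "layout too dense: gaps must fit a 1-kb promoter plus buffers"
            )
        cls = np.zeros(L, dtype=np.int8)  # intergenic = code 0
        pos = gap
        for kind, length in entities:
            strand = "+" if (gene_counter % 2 == 0) else "-"
            if kind in ("gene", "lncrna"):
                gene_counter += 1
                name = f"{kind}{gene_counter:03d}"
                gene_rows.append((contig, pos, pos + length, name, strand, kind))
                promo_cls = "gene_promoter" if kind == "gene" else "lnc_promoter"
                if strand == "+":
                    cls[pos - 1000: pos] = cls_code[promo_cls]
                else:
                    cls[pos + length: pos + length + 1000] = cls_code[promo_cls]
                for sub_cls, a, b in _split_entity(kind, pos, length, strand):
                    cls[a:b] = cls_code[sub_cls]
                    feat_rows.append((contig, a, b, sub_cls, name))
            else:
                feat_rows.append((contig, pos, pos + length, kind, f"{kind}@{contig}:{pos}"))
                cls[pos: pos + length] = cls_code[kind]
            pos += length + gap
        site_class[contig] = cls

    features = pd.DataFrame(
        feat_rows, columns=["contig", "start", "end", "feature_class", "entity_id"]
    )
    genes = pd.DataFrame(
        gene_rows, columns=["contig", "start", "end", "name", "strand", "kind"]
    )

    # per-gene constraint multipliers (lognormal) create RVIS heterogeneity
    gene_mult = {
        name: float(m)
        for name, m in zip(
            genes["name"],
            np.exp(rng.normal(0.0, config.gene_s_sigma, size=len(genes))),
        )
    }

    mu_arr = np.array([config.mu_per_class[c] for c in FEATURE_CLASSES])
    s_arr = np.array([config.s_per_class[c] for c in FEATURE_CLASSES])
    for contig in contig_names:
        cls = site_class[contig]
        mu = mu_arr[cls].copy()
        s = s_arr[cls].copy()
        # region-modulated mutation rate
        for row in regions[regions["contig"] == contig].itertuples(index=False):
            mu[row.start: row.end] *= config.region_mu_multiplier[row.region_class]
        site_mu[contig] = mu
        site_s[contig] = s
    # gene-specific multiplier on gene-body selected classes
    body = {cls_code[c] for c in ("utr5", "cds", "intron", "utr3")}
    for row in genes[genes["kind"] == "gene"].itertuples(index=False):
        cls = site_class[row.contig][row.start: row.end]
        mask = np.isin(cls, list(body))
        seg = site_s[row.contig][row.start: row.end]
        seg[mask] *= gene_mult[row.name]

    genome = SimulatedGenome(
        contig_lengths=contig_lengths,
        x_contigs=x_contigs,
        features=features,
        genes=genes,
        regions=regions,
        chrom_map=chrom_map,
        site_class=site_class,
        site_mu=site_mu,
        site_s=site_s,
    )
    genome.gene_s_multiplier = gene_mult  # type: ignore[attr-defined]
    return genome


# ---------------------------------------------------------------------------
# population frequencies and panel sampling


def _ancestral_frequencies(genome, config, rng) -> dict:
    """Per-contig ancestral derived-allele frequencies at equilibrium."""
    freqs = {}
    for contig, mu in genome.site_mu.items():
        ne = config.Ne_anc * (0.75 if contig in genome.x_contigs else 1.0)
        n_classes = max(4, int(round(2 * ne)))
        s = genome.site_s[contig]
        f = np.zeros(mu.size)
        # group sites by (mu, s) so SFS weights are built once per combo
        combo = pd.unique(pd.Series(list(zip(mu, s))))
        for mu_i, s_i in combo:
            idx = np.flatnonzero((mu == mu_i) & (s == s_i))
            p_seg = segregating_probability(n_classes, mu_i, s=s_i, ne=ne)
            seg = idx[rng.random(idx.size) < p_seg]
            if seg.size:
                f[seg] = sample_equilibrium_frequency(
                    n_classes, s=s_i, ne=ne, rng=rng, size=seg.size
                )
        freqs[contig] = f
    return freqs


def _bottleneck_frequencies(genome, config, anc_freqs, rng) -> dict:
    freqs = {}
    for contig, f in anc_freqs.items():
        ne = config.Ne_B * (0.75 if contig in genome.x_contigs else 1.0)
        ne = max(2, int(round(ne)))
        freqs[contig] = drift_forward(
            f, ne, config.g_B, s=genome.site_s[contig], mu=genome.site_mu[contig],
            rng=rng,
        )
    return freqs


def _sample_sexes(n: int, sex_ratio: float, rng) -> np.ndarray:
    n_f = int(round(sex_ratio * n))
    sex = np.array([FEMALE] * n_f + [MALE] * (n - n_f), dtype="<U1")
    rng.shuffle(sex)
    return sex


def sample_panel(
    population: str,
    genome: SimulatedGenome,
    freqs: dict,
    n_diploid: int,
    sex: np.ndarray,
    missing_rate: float,
    rng: np.random.Generator,
) -> GenotypePanel:
    """Draw a diploid sample from population frequencies (binomial gametes);
    on X contigs males receive a single haploid call.  Missingness is i.i.d.
    per site per individual at ``missing_rate``."""
    samples = [f"{population}_{s}{i + 1:02d}" for i, s in enumerate(sex)]
    panel = GenotypePanel(
        population=population,
        samples=samples,
        sex=sex,
        x_contigs=set(genome.x_contigs),
    )
    male = sex == MALE
    for contig, f in freqs.items():
        L = f.size
        alleles = (
            rng.random((L, 2 * n_diploid)) < f[:, None]
        ).astype(np.int8)
        if contig in genome.x_contigs and male.any():
            alleles[:, np.flatnonzero(male) * 2 + 1] = ABSENT
        if missing_rate > 0:
            miss = rng.random((L, n_diploid)) < missing_rate
            miss2 = np.repeat(miss, 2, axis=1)
            alleles[miss2 & (alleles != ABSENT)] = MISSING
        panel.calls[contig] = ContigCalls(positions=np.arange(L), alleles=alleles)
    return panel


# ---------------------------------------------------------------------------
# covariate tracks


def _covariate_tracks(genome: SimulatedGenome, config: SimConfig, rng):
    """Substitution sites, GC-biased sequences, recombination windows and
    per-gene RVIS, all correlated with the underlying mu / s truth."""
    # substitutions: Bernoulli per site with prob divergence_factor * mu
    subs_rows = []
    seqs = {}
    bases_at = np.array(list("ATGC"))
    for contig, mu in genome.site_mu.items():
        p_sub = np.clip(config.divergence_factor * mu, 0, 0.5)
        hit = np.flatnonzero(rng.random(mu.size) < p_sub)
        for pos in hit:
            subs_rows.append((contig, int(pos), int(pos) + 1))
        # sequence with per-site GC probability tied to mu
        p_gc = np.clip(config.gc_base + config.gc_mu_slope * mu, 0.05, 0.95)
        is_gc = rng.random(mu.size) < p_gc
        which = rng.integers(0, 2, size=mu.size)  # A/T or G/C choice
        seqs[contig] = "".join(bases_at[2 * is_gc + which])
    substitutions = pd.DataFrame(subs_rows, columns=["contig", "start", "end"])

    # recombination: windowed track, elevated subtelomeric / suppressed
    # pericentromeric, lognormal noise
    rec_rows = []
    for contig, L in genome.contig_lengths.items():
        reg = genome.regions[genome.regions["contig"] == contig]
        for w0 in range(0, L, config.rec_window_bp):
            w1 = min(L, w0 + config.rec_window_bp)
            mult = 1.0
            ov = reg[(reg["start"] < w1) & (reg["end"] > w0)]
            if len(ov):
                # dominant region of the window sets the multiplier
                best = ov.assign(
                    ov_len=np.minimum(ov["end"], w1) - np.maximum(ov["start"], w0)
                ).sort_values("ov_len").iloc[-1]
                mult = {"subtelomeric": 2.0, "pericentromeric": 0.3,
                        "interstitial": 1.0}[best["region_class"]]
            value = mult * float(np.exp(rng.normal(0.0, 0.15)))
            rec_rows.append((contig, w0, w1, value))
    recombination = pd.DataFrame(
        rec_rows, columns=["contig", "start", "end", "value"]
    )

    # RVIS: per protein-coding gene, anticorrelated with realised gene s
    mult = getattr(genome, "gene_s_multiplier", {})
    rvis_rows = []
    for row in genome.genes[genome.genes["kind"] == "gene"].itertuples(index=False):
        s_gene = genome.site_s[row.contig][row.start: row.end].max()
        score = 1.0 - 60.0 * s_gene + rng.normal(0.0, config.rvis_noise_sd)
        rvis_rows.append((row.name, float(score)))
    rvis = pd.DataFrame(rvis_rows, columns=["gene", "rvis"])
    return substitutions, seqs, recombination, rvis


# ---------------------------------------------------------------------------
# top level


@dataclass
class SimResult:
    config: SimConfig
    genome: SimulatedGenome
    panels: dict  # {"NB": GenotypePanel, "B": GenotypePanel}
    substitutions: pd.DataFrame
    sequences: dict
    recombination: pd.DataFrame
    rvis: pd.DataFrame
    ancestral_freqs: dict
    bottleneck_freqs: dict


def simulate(config: SimConfig, null_pair: bool = False) -> SimResult:
    """Run the full simulation in memory.

    With ``null_pair=True`` the B panel is sampled from the *same* ancestral
    generation as NB (no drift), which calibrates the null distribution of
    the windowed delta statistics.
    """
    config.validate()
    genome = build_genome(config)
    ss = np.random.SeedSequence([config.seed, 202])
    rng_anc, rng_drift, rng_nb, rng_b, rng_cov, rng_sex = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]
    anc = _ancestral_frequencies(genome, config, rng_anc)
    if null_pair:
        b_freqs = anc
    else:
        b_freqs = _bottleneck_frequencies(genome, config, anc, rng_drift)
    sex_nb = _sample_sexes(config.sample_NB, config.sex_ratio, rng_sex)
    sex_b = _sample_sexes(config.sample_B, config.sex_ratio, rng_sex)
    panels = {
        "NB": sample_panel("NB", genome, anc, config.sample_NB, sex_nb,
                           config.missing_rate, rng_nb),
        "B": sample_panel("B", genome, b_freqs, config.sample_B, sex_b,
                          config.missing_rate, rng_b),
    }
    substitutions, seqs, recombination, rvis = _covariate_tracks(
        genome, config, rng_cov
    )
    return SimResult(
        config=config,
        genome=genome,
        panels=panels,
        substitutions=substitutions,
        sequences=seqs,
        recombination=recombination,
        rvis=rvis,
        ancestral_freqs=anc,
        bottleneck_freqs=b_freqs,
    )


def xa_equilibrium_ratio(
    n_rep: int = 30,
    n_sites: int = 2000,
    n_diploid: int = 20,
    ne_a: int = 500,
    ne_x: int = 375,
    mu: float = 5e-6,
    g: int = 10,
    seed=None,
) -> dict:
    """Neutral X/A theta_W ratio experiment.

    Simulates neutral equilibrium compartments at autosomal Ne ``ne_a`` and X
    Ne ``ne_x`` (3/4 of autosomal by default) with identical mutation rate,
    drifts each a few generations as a stationarity check, samples
    ``n_diploid`` individuals (X: half the sample male and hemizygous, so
    theta_W uses the 2F+M haploid size), and returns the mean
    theta_W(X)/theta_W(A) over ``n_rep`` replicates.  The mutation-drift
    equilibrium expectation is ne_x/ne_a (0.75 for a hemizygous X).
    """
    from driftscape.diversity import site_theta_w

    ss = np.random.SeedSequence(seed)
    thetas = {"A": [], "X": []}
    n_f = n_diploid // 2
    n_hap_x = 2 * n_f + (n_diploid - n_f)  # 2F + M
    for child in ss.spawn(n_rep):
        rng = np.random.default_rng(child)
        for label, ne, n_hap in (("A", ne_a, 2 * n_diploid),
                                 ("X", ne_x, n_hap_x)):
            nc = int(2 * ne)
            p_seg = segregating_probability(nc, mu)
            f = np.zeros(n_sites)
            seg = rng.random(n_sites) < p_seg
            if seg.any():
                f[seg] = sample_equilibrium_frequency(
                    nc, rng=rng, size=int(seg.sum())
                )
            f = drift_forward(f, ne, g, mu=mu, rng=rng)
            alt = rng.binomial(n_hap, f)
            thetas[label].append(
                float(np.mean(site_theta_w(n_hap - alt, alt)))
            )
    th_a = np.asarray(thetas["A"])
    th_x = np.asarray(thetas["X"])
    ratios = th_x / th_a
    return {
        # ratio of replicate-mean thetas: unbiased, the headline estimate
        "mean_ratio": float(th_x.mean() / th_a.mean()),
        # mean of per-replicate ratios (carries a small Jensen bias)
        "mean_of_ratios": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)),
        "n_rep": n_rep,
        "ratios": ratios,
    }


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-loaded) mapping, tolerating partial
    overrides of the dict-valued fields."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    cfg = SimConfig()
    for key, value in d.items():
        if key in ("mu_per_class", "s_per_class", "region_mu_multiplier"):
            merged = dict(getattr(cfg, key))
            merged.update(value)
            value = merged
        elif key == "feature_layout":
            value = [tuple(entry) for entry in value]
        setattr(cfg, key, value)
    return cfg
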