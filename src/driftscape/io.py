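"""File formats: VCFv4.2 genotype panels, BED intervals, TSV tables, FASTA.

The simulator emits *all-sites* VCFs (monomorphic positions included, ALT
'.') because informative-site accounting needs per-site missingness at
invariant positions; panels round-trip through :func:`write_vcf` /
:func:`read_vcf` losslessly.  Reading uses pysam; writing is plain text
(GT-only records, haploid male X calls written as single alleles).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from driftscape.panel import ABSENT, MISSING, ContigCalls, GenotypePanel

_BASES = "ACGT"


def write_vcf(panel: GenotypePanel, path, sequences=None, contig_lengths=None,
              ref_alt=None) -> None:
    """Write an all-sites GT-only VCFv4.2 file.

    ``ref_alt`` maps contig -> (ref array, alt array) of allele strings; when
    absent, REF is taken from ``sequences`` (or 'A') and ALT is a fixed
    transversion at polymorphic sites, '.' elsewhere.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=driftscape",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for contig in panel.contigs:
        length = (
            contig_lengths[contig]
            if contig_lengths
            else int(panel.calls[contig].positions[-1]) + 1
        )
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.samples)
    )
    # genotype string lookup by (a0, a1) code: 0 ref, 1 alt, 2 missing,
    # 3 absent slot (hemizygous males are written as single-allele calls)
    tok = {0: "0", 1: "1", 2: ".", 3: "."}
    gt_of = np.empty((4, 4), dtype=object)
    for ca in range(4):
        for cb in range(4):
            gt_of[ca, cb] = tok[ca] if cb == 3 else f"{tok[ca]}/{tok[cb]}"

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for contig in panel.contigs:
            cc = panel.calls[contig]
            n = cc.positions.size
            alleles = cc.alleles
            seg = ((alleles == 1).any(axis=1)) & ((alleles == 0).any(axis=1))
            has_alt = (alleles == 1).any(axis=1)
            if ref_alt and contig in ref_alt:
                ref, alt = ref_alt[contig]
            else:
                if sequences and contig in sequences:
                    seq = sequences[contig]
                    ref = np.array(
                        [seq[int(p)] for p in cc.positions], dtype="<U1"
                    )
                else:
                    ref = np.full(n, "A", dtype="<U1")
                # deterministic derived allele: next base in ACGT order
                alt_map = {b: _BASES[(_BASES.index(b) + 1) % 4] for b in _BASES}
                alt_map["N"] = "A"
                alt = np.array([alt_map[b] for b in ref], dtype="<U1")
            alt = np.where(seg | has_alt, alt, ".")
            codemat = np.empty(alleles.shape, dtype=np.int8)
            codemat[alleles == 0] = 0
            codemat[alleles == 1] = 1
            codemat[alleles == MISSING] = 2
            codemat[alleles == ABSENT] = 3
            cols = [
                np.asarray(contig, dtype=object).repeat(n),
                (cc.positions + 1).astype(str).astype(object),
                np.full(n, ".", dtype=object),
                ref.astype(object),
                alt.astype(object),
                np.full(n, ".", dtype=object),
                np.full(n, "PASS", dtype=object),
                np.full(n, ".", dtype=object),
                np.full(n, "GT", dtype=object),
            ]
            for j in range(panel.n_samples):
                cols.append(gt_of[codemat[:, 2 * j], codemat[:, 2 * j + 1]])
            block = cols[0]
            for col in cols[1:]:
                block = np.char.add(np.char.add(block.astype(str), "\t"),
                                    col.astype(str))
            fh.write("\n".join(block) + "\n")


def read_vcf(path, population: str, sex_table: pd.DataFrame,
             x_contigs=()) -> GenotypePanel:
    """Load a GT-only VCF into a :class:`GenotypePanel`.

    Sites with more than one ALT allele are dropped (triallelic filter).
    ``sex_table`` must carry columns sample/sex for every VCF sample.
    """
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    sex_map = dict(zip(sex_table["sample"], sex_table["sex"]))
    missing_sex = [s for s in samples if s not in sex_map]
    if missing_sex:
        raise ValueError(f"samples without sex label: {missing_sex}")
    sex = np.array([sex_map[s] for s in samples], dtype="<U1")
    panel = GenotypePanel(
        population=population, samples=samples, sex=sex,
        x_contigs=set(x_contigs),
    )
    per_contig: dict[str, list] = {}
    for rec in vf:
        alts = [a for a in (rec.alts or ()) if a not in (None, ".")]
        if len(alts) > 1:
            continue  # triallelic+ dropped
        row = np.full(2 * len(samples), int(ABSENT), dtype=np.int8)
        for j, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if gt is None:
                gt = (None,)
            for k, a in enumerate(gt[:2]):
                row[2 * j + k] = int(MISSING) if a is None else int(a)
        per_contig.setdefault(rec.chrom, []).append((rec.pos - 1, row))
    vf.close()
    for contig, rows in per_contig.items():
        pos = np.array([p for p, _ in rows], dtype=np.int64)
        mat = np.stack([r for _, r in rows])
        order = np.argsort(pos)
        panel.calls[contig] = ContigCalls(positions=pos[order],
                                          alleles=mat[order])
    return panel


# ---------------------------------------------------------------------------
# BED / TSV / FASTA


def write_bed(df: pd.DataFrame, path, columns=("contig", "start", "end")) -> None:
    df = df.sort_values([columns[0], columns[1]])
    df.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=list(names),
                     comment="#")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path) -> dict:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# simulation output bundle


def emit_panels(result, outdir) -> dict:
    """Write every simulator output (VCFs, sex tables, BEDs, tracks, FASTA,
    chromosome map) into ``outdir``; returns the path manifest."""
    os.makedirs(outdir, exist_ok=True)
    genome = result.genome
    paths = {}

    for pop, panel in result.panels.items():
        vcf = os.path.join(outdir, f"{pop}.vcf")
        write_vcf(panel, vcf, sequences=result.sequences,
                  contig_lengths=genome.contig_lengths)
        sex = os.path.join(outdir, f"{pop}.sex.tsv")
        write_tsv(pd.DataFrame({"sample": panel.samples, "sex": panel.sex}), sex)
        paths[f"vcf_{pop}"] = vcf
        paths[f"sex_{pop}"] = sex

    paths["genes_bed"] = os.path.join(outdir, "genes.bed")
    gb = genome.genes.copy()
    gb["score"] = 0
    write_bed(gb, paths["genes_bed"],
              columns=("contig", "start", "end", "name", "score", "strand", "kind"))

    paths["features_bed"] = os.path.join(outdir, "features.bed")
    write_bed(genome.features, paths["features_bed"],
              columns=("contig", "start", "end", "feature_class"))

    paths["regions_bed"] = os.path.join(outdir, "regions.bed")
    write_bed(genome.regions, paths["regions_bed"],
              columns=("contig", "start", "end", "region_class"))

    paths["chromosomes_tsv"] = os.path.join(outdir, "chromosomes.tsv")
    write_tsv(genome.chrom_map, paths["chromosomes_tsv"])

    paths["substitutions_bed"] = os.path.join(outdir, "substitutions.bed")
    write_bed(result.substitutions, paths["substitutions_bed"])

    paths["recombination_tsv"] = os.path.join(outdir, "recombination.tsv")
    write_tsv(result.recombination, paths["recombination_tsv"])

    paths["rvis_tsv"] = os.path.join(outdir, "rvis.tsv")
    write_tsv(result.rvis, paths["rvis_tsv"])

    paths["genome_fasta"] = os.path.join(outdir, "genome.fa")
    write_fasta(result.sequences, paths["genome_fasta"])

    xf = os.path.join(outdir, "x_contigs.txt")
    with open(xf, "w") as fh:
        for contig in sorted(genome.x_contigs):
            fh.write(contig + "\n")
    paths["x_contigs"] = xf
    return paths
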