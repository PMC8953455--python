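"""Readers and writers for the formats the pipeline touches.

Formats: VCF v4.2 with phased GT (read via cyvcf2, written as plain text);
the local-ancestry BED dialect ``#chrom start end sample hap ancestry``
(tab-separated, 0-based half-open); genetic-map TSV ``chrom pos cM`` (pos
1-based); gene BED6; GMT gene sets; per-variant score TSV
``chrom pos ref alt impact weight``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    AdmixtureModel,
    GeneModel,
    GeneSetCollection,
    GeneticMap,
    HaplotypeMatrix,
    LocalAncestryTrack,
    SiteTable,
    VariantScoreTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_local_ancestry",
    "write_local_ancestry",
    "read_genetic_map",
    "write_genetic_map",
    "read_gene_bed",
    "write_gene_bed",
    "read_gmt",
    "write_gmt",
    "read_scores",
    "write_scores",
]


def read_phased_vcf(path, region: str | None = None) -> tuple[SiteTable, HaplotypeMatrix]:
    """Load phased biallelic SNVs from a VCF.

    Multiallelic records, indels/MNPs, and sites with any missing or
    unphased genotype are dropped (drop counts logged). Returns a site
    table and a 0/1 haplotype matrix aligned row-for-row.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    it = vcf(region) if region else vcf
    chroms, poss, refs, alts, ancs, ids = [], [], [], [], [], []
    rows = []
    n_multi = n_notsnv = n_badgt = 0
    for var in it:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            n_notsnv += 1
            continue
        gts = var.genotypes  # per sample: [allele0, allele1, phased]
        if len(gts) != len(samples):
            raise ValueError(f"inconsistent sample count at {var.CHROM}:{var.POS}")
        hap = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        for i, g in enumerate(gts):
            if len(g) != 3 or g[0] < 0 or g[1] < 0 or not g[2]:
                ok = False
                break
            hap[2 * i] = g[0]
            hap[2 * i + 1] = g[1]
        if not ok:
            n_badgt += 1
            continue
        aa = var.INFO.get("AA")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(ref)
        alts.append(alt)
        ancs.append(aa if aa in (ref, alt) else ".")
        ids.append(var.ID or ".")
        rows.append(hap)
    if n_multi or n_notsnv or n_badgt:
        logger.info(
            "read_phased_vcf: dropped %d multiallelic, %d non-SNV, %d missing/unphased records",
            n_multi, n_notsnv, n_badgt,
        )
    if not rows:
        raise ValueError(f"no biallelic phased SNVs survive filtering in {path}")
    sites = SiteTable.from_arrays(chroms, poss, refs, alts, ancs, ids)
    matrix = HaplotypeMatrix(np.vstack(rows), samples)
    return sites, matrix


def write_phased_vcf(path, sites: SiteTable, matrix: HaplotypeMatrix,
                     contig_lengths: dict[str, int] | None = None) -> None:
    """Write sites + phased haplotypes as a minimal VCF v4.2 text file."""
    if len(sites) != matrix.n_sites:
        raise ValueError("site table / matrix row mismatch")
    if contig_lengths is None:
        contig_lengths = (
            sites.df.groupby("chrom", sort=False)["pos"].max().astype(int).to_dict()
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, L in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={int(L)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        al = matrix.alleles
        df = sites.df
        for s in range(len(sites)):
            info = "." if df.at[s, "anc"] == "." else f"AA={df.at[s, 'anc']}"
            gts = "\t".join(
                f"{al[s, 2 * i]}|{al[s, 2 * i + 1]}" for i in range(matrix.n_ind)
            )
            fh.write(
                f"{df.at[s, 'chrom']}\t{df.at[s, 'pos']}\t{df.at[s, 'id']}\t"
                f"{df.at[s, 'ref']}\t{df.at[s, 'alt']}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


_LA_HEADER = "#chrom\tstart\tend\tsample\thap\tancestry"


def read_local_ancestry(path, site_table: SiteTable, samples: Sequence[str],
                        labels: Sequence[str] | None = None) -> LocalAncestryTrack:
    """Read the local-ancestry BED dialect and densify onto ``site_table``.

    Every analyzed site must be covered by exactly one segment per
    haplotype. ``labels`` fixes the ancestry code order; default is the
    sorted set of labels present in the file.
    """
    seg = pd.read_csv(
        path, sep="\t", comment=None, header=0,
        names=["chrom", "start", "end", "sample", "hap", "ancestry"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "sample": str, "hap": np.int64, "ancestry": str},
    )
    if labels is None:
        labels = sorted(seg["ancestry"].unique())
    return LocalAncestryTrack.from_segments(seg, site_table, samples, labels)


def write_local_ancestry(path, segments: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_LA_HEADER + "\n")
        segments.to_csv(fh, sep="\t", header=False, index=False,
                        columns=["chrom", "start", "end", "sample", "hap", "ancestry"])


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    anchors = {
        str(c): (g["pos"].to_numpy(), g["cM"].to_numpy())
        for c, g in df.groupby("chrom", sort=False)
    }
    return GeneticMap(anchors)


def write_genetic_map(path, gmap: GeneticMap) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_bed(path) -> GeneModel:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "symbol", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "symbol": str},
    )
    return GeneModel(df)


def write_gene_bed(path, genes: GeneModel) -> None:
    out = genes.df.copy()
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> GeneSetCollection:
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
            desc[parts[0]] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_scores(path) -> VariantScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return VariantScoreTable(df)


def write_scores(path, scores: VariantScoreTable) -> None:
    scores.df.to_csv(path, sep="\t", index=False)
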