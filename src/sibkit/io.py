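"""Readers and writers for the on-disk formats.

Genotypes travel either as VCF (GT fields collapsed to alternate-allele
dosages) or as a plain dosage TSV with header
``variant_id  chrom  pos  sample1 ...`` and "." for missing. Genetic
maps use the 4-column HapMap convention (chr, position bp, rate cM/Mb,
cumulative cM). Break catalogs are BED-like: 0-based half-open
intervals. Internal coordinates are 1-based bp; only exported intervals
are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneticMap

__all__ = [
    "DosageTable",
    "read_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "write_breaks_bed",
    "read_breaks_bed",
    "read_pgs_weights",
    "read_pairs_tsv",
]

log = logging.getLogger("sibkit")

MISSING = -1


@dataclass
class DosageTable:
    """Variant metadata plus an individuals-implicit dosage matrix.

    variants: DataFrame with columns variant_id, chrom, pos (1-based);
    samples: sample ids in matrix column order; dosages: (variants,
    samples) int8 with -1 for missing.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray
    n_multiallelic_skipped: int = 0

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage matrix shape does not match metadata")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) < 0):
                raise ValueError(f"positions not sorted within chromosome {chrom}")

    def sample_matrix(self) -> np.ndarray:
        """Dosages as (individuals, variants)."""
        return self.dosages.T


def read_genotypes(path, fmt: str | None = None) -> DosageTable:
    """Read genotypes from VCF or dosage TSV (auto-detected by suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "dosage_tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_dosage_tsv(path) -> DosageTable:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    meta_cols = ["variant_id", "chrom", "pos"]
    if list(df.columns[:3]) != meta_cols:
        raise ValueError(f"dosage TSV must start with columns {meta_cols}")
    samples = list(df.columns[3:])
    mat = df[samples].replace(".", MISSING).astype(np.int8).to_numpy()
    if not np.all(np.isin(mat, [-1, 0, 1, 2])):
        raise ValueError("dosages must be 0/1/2 or '.'")
    return DosageTable(df[meta_cols].copy(), samples, mat)


def write_dosage_tsv(table: DosageTable, path) -> None:
    df = table.variants.copy()
    mat = table.dosages.astype(object)
    mat[table.dosages < 0] = "."
    for j, s in enumerate(table.samples):
        df[s] = mat[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> DosageTable:
    """Collapse VCF GT fields to alt-allele dosages via cyvcf2.

    Multi-allelic records are skipped and counted; missing genotypes
    become -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            skipped += 1
            log.info("skipping multi-allelic record %s at line-record %d", rec.ID, i)
            continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        dosages.append(g)
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", str(rec.CHROM), rec.POS))
    vcf.close()
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])
    mat = np.vstack(dosages) if dosages else np.empty((0, len(samples)), dtype=np.int8)
    return DosageTable(variants, samples, mat, n_multiallelic_skipped=skipped)


def write_vcf(table: DosageTable, path, phased_haplotypes: np.ndarray | None = None) -> None:
    """Write a minimal GT-only VCF.

    By default genotypes are unphased hard calls derived from dosages
    (0 -> 0/0, 1 -> 0/1, 2 -> 1/1, missing -> ./.). If
    phased_haplotypes (variants, samples, 2) is given, phased GTs are
    written instead — the truth sidecar for simulated data.
    """
    unphased = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in table.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for vi, row in enumerate(table.variants.itertuples(index=False)):
            if phased_haplotypes is not None:
                gts = [f"{a}|{b}" for a, b in phased_haplotypes[vi]]
            else:
                gts = [unphased[int(d)] for d in table.dosages[vi]]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_genetic_map(path) -> dict[str, GeneticMap]:
    """Read a HapMap-format map: chr, position, rate cM/Mb, cumulative cM.

    A header row is tolerated. Cumulative cM is re-anchored to 0 at each
    chromosome's first row; a decreasing cumulative value is an error
    naming the row.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    # drop a header row if the position column is not numeric
    if not df.iloc[0, 1].lstrip("-").replace(".", "", 1).isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 4:
        raise ValueError("genetic map needs 4 columns: chr pos rate cM")
    df.columns = ["chrom", "pos", "rate", "cM"] + list(df.columns[4:])
    df["pos"] = df["pos"].astype(np.int64)
    df["cM"] = df["cM"].astype(float)
    maps = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy()
        dec = np.flatnonzero(np.diff(cm) < 0)
        if dec.size:
            row = grp.index[int(dec[0]) + 1] + 1
            raise ValueError(f"cumulative cM decreases at row {row} (chromosome {chrom})")
        maps[str(chrom)] = GeneticMap(str(chrom), grp["pos"].to_numpy(), cm - cm[0])
    return maps


def write_genetic_map(maps: dict[str, GeneticMap], path) -> None:
    with open(path, "w") as fh:
        fh.write("chr\tposition\trate_cM_Mb\tcM\n")
        for chrom, m in maps.items():
            rate = np.zeros_like(m.cum_cM)
            if m.positions.size > 1:
                d_bp = np.diff(m.positions) / 1e6
                rate[:-1] = np.diff(m.cum_cM) / np.where(d_bp > 0, d_bp, np.nan)
            for p, r, c in zip(m.positions, rate, m.cum_cM):
                fh.write(f"{chrom}\t{p}\t{r:.6f}\t{c:.6f}\n")


def write_breaks_bed(calls, path) -> None:
    """BED-like catalog: chrom, start, end, pair_id, Z, direction."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.pair_id}\t"
                     f"{c.z:.4f}\t{c.direction}\n")


def read_breaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "pair_id", "z", "direction"],
                     dtype={"chrom": str})
    return df


def read_pgs_weights(path) -> pd.DataFrame:
    """PGS weight table: variant_id, effect_allele, beta."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "effect_allele": str})
    need = {"variant_id", "effect_allele", "beta"}
    if not need <= set(df.columns):
        raise ValueError(f"weights file must have columns {sorted(need)}")
    return df


def read_pairs_tsv(path) -> pd.DataFrame:
    """Relationship list: id1, id2, kind (sibling / parent_child / ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"id1", "id2", "kind"}
    if not need <= set(df.columns):
        raise ValueError(f"pairs file must have columns {sorted(need)}")
    return df
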