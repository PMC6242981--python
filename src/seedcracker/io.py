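"""On-disk interchange: phased VCF, phenotype TSV, pool TSV, BED genes.

Conventions: VCF and pool-table positions are 1-based; BED intervals are
half-open with 0-based starts; all spans are computed as end - start.
Writing and re-reading reproduces the in-memory objects exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simdata import CohortTable

__all__ = [
    "write_cohort_vcf",
    "read_cohort_vcf",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_cohort",
    "read_cohort",
    "write_pool_tsv",
    "read_pool_tsv",
    "write_region_bed",
    "read_region_bed",
    "write_genes_bed",
    "read_genes_bed",
]

_REF, _ALT = "A", "T"


def write_cohort_vcf(cohort: CohortTable, path) -> None:
    """Phased diploid genotypes as VCF v4.2 (GT only, `0|1` style)."""
    samples = list(cohort.table["individual_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f"##contig=<ID={cohort.chrom},length={int(cohort.positions[-1]) + 1}>\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, pos in enumerate(cohort.positions):
            gts = "\t".join(
                f"{int(a)}|{int(b)}" for a, b in zip(cohort.hap1[:, j], cohort.hap2[:, j])
            )
            fh.write(
                f"{cohort.chrom}\t{int(pos)}\t.\t{_REF}\t{_ALT}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_cohort_vcf(path):
    """Read back sample ids, phased haplotype matrices, positions, chrom."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, h1_cols, h2_cols = [], [], []
    chrom = None
    for variant in vcf:
        chrom = variant.CHROM
        positions.append(variant.POS)
        gts = variant.genotypes  # [allele1, allele2, phased] per sample
        h1_cols.append([g[0] for g in gts])
        h2_cols.append([g[1] for g in gts])
    vcf.close()
    hap1 = np.array(h1_cols, dtype=np.uint8).T
    hap2 = np.array(h2_cols, dtype=np.uint8).T
    return samples, hap1, hap2, np.array(positions, dtype=np.int64), chrom


def write_phenotypes_tsv(cohort: CohortTable, path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: CohortTable, vcf_path, tsv_path) -> None:
    write_cohort_vcf(cohort, vcf_path)
    write_phenotypes_tsv(cohort, tsv_path)


def read_cohort(vcf_path, tsv_path) -> CohortTable:
    samples, hap1, hap2, positions, chrom = read_cohort_vcf(vcf_path)
    table = read_phenotypes_tsv(tsv_path)
    if list(table["individual_id"]) != samples:
        raise ValueError("phenotype table and VCF disagree on samples")
    return CohortTable(
        table=table, hap1=hap1, hap2=hap2, positions=positions, chrom=chrom
    )


def write_pool_tsv(pool_table: pd.DataFrame, path) -> None:
    pool_table.to_csv(path, sep="\t", index=False)


def read_pool_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_region_bed(region, name, path) -> None:
    """Single-interval BED for a 1-based closed Region."""
    with open(path, "w") as fh:
        fh.write(f"{region.chrom}\t{region.start - 1}\t{region.end}\t{name}\n")


def read_region_bed(path):
    from .regions import Region

    chrom, start, end = open(path).readline().split("\t")[:3]
    return Region(chrom, int(start) + 1, int(end))


def write_genes_bed(annotation: pd.DataFrame, path) -> None:
    """BED3+1: chrom, start, end, gene_id."""
    annotation[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_genes_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"]
    )
    return bed[["gene_id", "chrom", "start", "end"]]
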