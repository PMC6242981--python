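"""Gene-length-weighted bootstrap null for morph-private allele counts.

Sites carrying alleles fixed in one morph and absent from the others are
assigned to annotated genes; each bootstrap replicate redistributes the M
in-gene private alleles across genes with probability proportional to gene
length, building a per-gene null distribution of counts.  A gene's p-value
is the fraction of replicates whose null count strictly exceeds the
observed count, so under the null each gene's count is marginally
Binomial(M, length_g / total_length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rng import child_rng

__all__ = [
    "private_fixed_sites",
    "assign_to_genes",
    "bootstrap_enrichment",
]


def private_fixed_sites(
    pool_table: pd.DataFrame,
    focal_pool: str,
    other_pools: list[str],
    fixation_tol: float = 0.0,
) -> pd.DataFrame:
    """Sites fixed in the focal pool for an allele absent from the others.

    Frequencies are reference-allele frequencies: a site qualifies when the
    focal pool is fixed (freq <= tol or >= 1 - tol) and the allele it is
    fixed for has frequency <= tol in every other pool.
    """
    cols = [f"freq_{p}" for p in [focal_pool] + list(other_pools)]
    for c in cols:
        if c not in pool_table.columns:
            raise KeyError(f"pool column {c!r} missing from table")
    f_focal = pool_table[f"freq_{focal_pool}"].to_numpy(dtype=float)
    others = np.column_stack(
        [pool_table[f"freq_{p}"].to_numpy(dtype=float) for p in other_pools]
    )
    tol = fixation_tol
    fixed_ref = (f_focal >= 1 - tol) & np.all(others <= tol, axis=1)
    fixed_alt = (f_focal <= tol) & np.all(others >= 1 - tol, axis=1)
    return pool_table.loc[fixed_ref | fixed_alt].copy()


def assign_to_genes(sites: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Count sites per gene under half-open [start, end) BED intervals.

    Returns the annotation with ``observed`` counts appended; intergenic
    sites are reported in ``df.attrs['n_intergenic']``.  Positions are
    1-based, BED starts 0-based, so position p is inside a gene when
    start < p <= end.
    """
    ann = annotation.reset_index(drop=True)
    counts = np.zeros(len(ann), dtype=np.int64)
    n_intergenic = 0
    for chrom, chunk in sites.groupby("chrom"):
        genes = ann[ann["chrom"] == chrom]
        pos = chunk["pos"].to_numpy(dtype=np.int64)
        hit = np.zeros(len(pos), dtype=bool)
        for idx, gene in genes.iterrows():
            inside = (pos > gene["start"]) & (pos <= gene["end"])
            counts[idx] += int(inside.sum())
            hit |= inside
        n_intergenic += int((~hit).sum())
    out = ann.copy()
    out["observed"] = counts
    out.attrs["n_intergenic"] = n_intergenic
    return out


def bootstrap_enrichment(
    per_gene_counts,
    gene_lengths,
    B: int = 10_000,
    seed: int = 0,
    greater_or_equal: bool = False,
) -> pd.DataFrame:
    """Length-weighted bootstrap null for per-gene private-allele counts.

    Each of the B replicates reassigns the M observed in-gene alleles to
    genes with probability proportional to gene length.  ``p`` is the
    proportion of replicates strictly exceeding the observed count (the
    printed convention); with ``greater_or_equal`` the conservative
    ``(1 + #{>=}) / (1 + B)`` variant is returned instead.
    """
    observed = np.asarray(per_gene_counts, dtype=np.int64)
    lengths = np.asarray(gene_lengths, dtype=float)
    if observed.shape != lengths.shape or observed.ndim != 1:
        raise ValueError("counts and lengths must be equal-length 1-D vectors")
    if B < 1:
        raise ValueError("B must be >= 1")
    M = int(observed.sum())
    if M < 1:
        raise ValueError("no in-gene alleles to redistribute")
    total = lengths.sum()
    if total <= 0:
        raise ValueError("all gene lengths are zero")
    rng = child_rng(seed, "bootstrap_enrichment")
    null = rng.multinomial(M, lengths / total, size=B)
    if greater_or_equal:
        p = (1 + (null >= observed).sum(axis=0)) / (1 + B)
    else:
        p = (null > observed).sum(axis=0) / B
    return pd.DataFrame(
        {
            "length": lengths,
            "observed": observed,
            "null_mean": null.mean(axis=0),
            "p": p,
        }
    )
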