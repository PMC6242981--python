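"""Descriptive haplotype statistics and the dosage-phenotype association.

From the phased cohort: sliding-window observed heterozygosity per morph
(200-SNP windows, 100-SNP step), within- and between-haplogroup mismatch
fractions, and the OLS association between derived-haplotype copy number
(0/1/2) and lower mandible width.

Usage: python analysis/05_haplotype_statistics.py [--data DIR] [--out DIR]
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from seedcracker import io as scio
from seedcracker.sumstats import (
    haplotype_dosage_association,
    mismatch_matrix,
    observed_heterozygosity_windows,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=pathlib.Path, default=pathlib.Path("results/data"))
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = scio.read_cohort(args.data / "cohort.vcf", args.data / "phenotypes.tsv")
    morph = cohort.table["morph"]

    ho, starts, ends, partial = observed_heterozygosity_windows(
        cohort.hap1, cohort.hap2, window=200, step=100
    )
    rows = {"window_start": starts, "window_end": ends, "partial": partial}
    for m in ("small", "large", "mega"):
        sel = (morph == m).to_numpy()
        if sel.any():
            rows[f"ho_{m}"] = ho[:, sel].mean(axis=1)
    pd.DataFrame(rows).to_csv(args.out / "ho_windows.tsv", sep="\t", index=False)

    print("mean observed heterozygosity per morph:")
    for m in ("small", "large", "mega"):
        sel = (morph == m).to_numpy()
        if sel.any():
            het = (cohort.hap1[sel] != cohort.hap2[sel]).mean()
            print(f"  {m}: {het:.3f}")

    # within/between haplogroup mismatches over the small (hom ancestral)
    # and mega (hom derived) haplotypes, restricted to the bounded candidate
    # region when step 02 has produced one
    region_bed = args.out / "candidate_region.bed"
    keep = np.ones(len(cohort.positions), dtype=bool)
    if region_bed.exists():
        region = scio.read_region_bed(region_bed)
        keep = (cohort.positions >= region.start) & (cohort.positions <= region.end)
        print(f"mismatch statistics over {keep.sum()} candidate-region SNPs")
    small = (morph == "small").to_numpy()
    mega = (morph == "mega").to_numpy()
    anc = np.vstack([cohort.hap1[small][:, keep], cohort.hap2[small][:, keep]])
    der = np.vstack([cohort.hap1[mega][:, keep], cohort.hap2[mega][:, keep]])
    both = np.vstack([anc, der])
    mm = mismatch_matrix(both)
    na = len(anc)
    iu_a = np.triu_indices(na, k=1)
    iu_d = np.triu_indices(len(der), k=1)
    print(f"mean within-ancestral mismatch: {mm[:na, :na][iu_a].mean():.1%}")
    print(f"mean within-derived mismatch: {mm[na:, na:][iu_d].mean():.1%}")
    print(f"mean between-haplogroup mismatch: {mm[:na, na:].mean():.1%}")

    # dosage association: copies of the derived (large-bill) haplogroup vs LMW,
    # scored from phased genotypes by majority allele state
    der_frac1 = cohort.hap1.mean(axis=1)
    der_frac2 = cohort.hap2.mean(axis=1)
    dosage = (der_frac1 > 0.5).astype(int) + (der_frac2 > 0.5).astype(int)
    res = haplotype_dosage_association(dosage, cohort.table["LMW"])
    print(
        f"dosage association: beta = {res.beta:.3f} +- {res.se:.3f} s.e., "
        f"T = {res.T:.2f}, R^2 = {res.r_squared:.3f}, p = {res.p_value:.3g} "
        f"(n = {res.n})"
    )


if __name__ == "__main__":
    main()
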