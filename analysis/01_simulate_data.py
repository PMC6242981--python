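"""Generate the truth-known synthetic study dataset.

Emulates the empirical data layout: a phased cohort of small-, large- and
mega-billed birds over a divergent two-haplogroup locus, a pooled
allele-frequency table with a high-Δ candidate region implanted on the
empirical coordinates (plus mega-private fixed differences), and a gene
annotation for the enrichment null.  Writes VCF / TSV / BED under
results/data/ and prints what was planted so later steps can be read
against the truth.

Usage: python analysis/01_simulate_data.py [--seed N] [--out DIR]
"""

import argparse
import pathlib

from seedcracker import io as scio
from seedcracker.regions import Region
from seedcracker.simdata import (
    generate_cohort,
    generate_gene_annotation,
    generate_haplotype_panel,
    generate_pool_af,
    merge_panels,
)

CANDIDATE = Region("TGU1A", 55_070_008, 55_371_638)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # Candidate interior: 972 assayed SNP sites, fully divergent founders,
    # within-class diversity ~9% mismatches carried on class-private sites
    # (a non-recombining interior shares no polymorphisms between classes);
    # five recombination events.
    core = generate_haplotype_panel(
        n_anc=12,
        n_der=12,
        L=972,
        divergence=1.0,
        intra_diversity=0.045,
        n_recombinants=5,
        seed=args.seed,
        position_start=CANDIDATE.start,
        position_step=300,
        disjoint_intra_sites=True,
    )
    # ~100 Kb freely recombining flanks: undifferentiated (divergence 0) and
    # diverse, so polymorphisms are shared between the classes
    flank_kwargs = dict(
        n_anc=12, n_der=12, divergence=0.0, intra_diversity=0.3, n_recombinants=5
    )
    left = generate_haplotype_panel(
        L=300, seed=args.seed + 1, position_start=54_971_008, position_step=330,
        **flank_kwargs,
    )
    right = generate_haplotype_panel(
        L=300, seed=args.seed + 2, position_start=55_371_938, position_step=330,
        **flank_kwargs,
    )
    panel = merge_panels(left, core, right)
    # breakpoint truth for the interior block, shifted past the left flank
    panel.breakpoints = {r: bp + left.L for r, bp in core.breakpoints.items()}
    cohort = generate_cohort(panel, n_small=12, n_large=12, n_mega=21, seed=args.seed)
    pool = generate_pool_af(
        cohort,
        CANDIDATE,
        background_sites=3000,
        delta_in_region=0.95,
        seed=args.seed,
        extent=Region("TGU1A", 54_800_000, 55_700_000),
        private_sites=1341,
    )
    genes = generate_gene_annotation(
        chrom_length=900_000,
        n_genes=28,
        length_range=(2_000, 16_000),
        seed=args.seed,
        offset=54_800_000,
    )

    scio.write_cohort(cohort, args.out / "cohort.vcf", args.out / "phenotypes.tsv")
    scio.write_pool_tsv(pool, args.out / "pool_af.tsv")
    scio.write_genes_bed(genes, args.out / "genes.bed")

    print(f"panel: {panel.n_haplotypes} haplotypes x {panel.L} sites, "
          f"{len(panel.breakpoints)} recombinants")
    print(f"cohort: {cohort.n_individuals} individuals "
          f"({(cohort.table['morph'] == 'small').sum()} small / "
          f"{(cohort.table['morph'] == 'large').sum()} large / "
          f"{(cohort.table['morph'] == 'mega').sum()} mega)")
    print(f"pool table: {len(pool)} sites "
          f"({(pool['kind'] == 'region').sum()} in the implanted candidate region "
          f"{CANDIDATE.start:,}-{CANDIDATE.end:,}, "
          f"{(pool['kind'] == 'private').sum()} mega-private)")
    print(f"genes: {len(genes)} non-overlapping intervals")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
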