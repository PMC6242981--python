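"""Truth-known synthetic datasets with the structure the analyses assume.

The generator emulates the empirical data layout: two divergent haplogroups
at a non-recombining locus segregating in one randomly mating population; a
dominant derived (large-bill) haplotype acting on lower mandible width
(LMW) with morph means 12.8 / 16.4 / 19.6 mm; pooled allele-frequency
tables with a high-Δ candidate region embedded in a low-differentiation
background; and non-overlapping gene intervals used as bootstrap weights.

Everything is seeded and reproducible; truth labels (haplotype classes,
recombination breakpoints, implanted region and private sites) are retained
so downstream scans can be checked against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import Region
from .rng import child_rng

__all__ = [
    "HaplotypePanel",
    "CohortTable",
    "MORPH_MEANS_MM",
    "generate_haplotype_panel",
    "merge_panels",
    "generate_cohort",
    "generate_pool_af",
    "generate_gene_annotation",
]

# Empirical mean lower mandible width per morph (mm).
MORPH_MEANS_MM = (12.8, 16.4, 19.6)

DEFAULT_CHROM = "TGU1A"


@dataclass
class HaplotypePanel:
    """Binary haplotypes with allelic-class labels and breakpoint truth."""

    haplotypes: np.ndarray  # (n_haplotypes, L) of 0/1
    classes: np.ndarray  # 'anc' | 'der' | 'rec' per haplotype
    breakpoints: dict[int, int]  # recombinant row -> first site of 3' segment
    positions: np.ndarray  # 1-based bp per site
    chrom: str = DEFAULT_CHROM

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def L(self) -> int:
        return self.haplotypes.shape[1]

    def rows_of(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.classes == cls)


@dataclass
class CohortTable:
    """Per-individual phenotypes and phased genotypes over the panel sites."""

    table: pd.DataFrame  # individual_id, morph, LMW, hap1_id, hap2_id
    hap1: np.ndarray  # (n_individuals, L)
    hap2: np.ndarray
    positions: np.ndarray
    chrom: str = DEFAULT_CHROM

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def derived_dosage(self, panel: HaplotypePanel) -> np.ndarray:
        """Copies (0/1/2) of derived-class haplotypes per individual."""
        der = set(panel.rows_of("der"))
        return np.array(
            [
                int(h1 in der) + int(h2 in der)
                for h1, h2 in zip(self.table["hap1_id"], self.table["hap2_id"])
            ]
        )

    def validate(self) -> None:
        if (self.table["LMW"] <= 0).any():
            raise ValueError("LMW must be positive")
        if self.hap1.shape != self.hap2.shape or len(self.table) != len(self.hap1):
            raise ValueError("genotype matrices inconsistent with the table")


def generate_haplotype_panel(
    n_anc: int,
    n_der: int,
    L: int,
    divergence: float,
    intra_diversity: float,
    n_recombinants: int = 0,
    seed: int = 0,
    chrom: str = DEFAULT_CHROM,
    position_start: int = 55_070_008,
    position_step: int = 300,
    disjoint_intra_sites: bool = False,
) -> HaplotypePanel:
    """Two divergent founder haplotypes plus mutated copies and recombinants.

    The founders differ at ``ceil(divergence * L)`` sites; each panel member
    is a founder copy with independent per-site flips at rate
    ``intra_diversity``; recombinants are single-breakpoint mosaics of one
    ancestral-class and one derived-class member, with the breakpoint
    recorded as truth.

    With ``disjoint_intra_sites`` the two classes mutate on disjoint halves
    of the site grid (infinite-sites-like private variation), so no site
    segregates within both classes — the signature of a non-recombining
    interior.  The flip rate is doubled on the allowed half so pairwise
    within-class mismatch stays comparable.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    if not 0.0 <= intra_diversity <= 1.0:
        raise ValueError("intra_diversity must be in [0, 1]")
    if L < 1:
        raise ValueError("L must be >= 1")
    if min(n_anc, n_der, n_recombinants) < 0:
        raise ValueError("counts must be >= 0")
    if n_recombinants > 0 and (n_anc == 0 or n_der == 0):
        raise ValueError("recombinants need both ancestral and derived members")
    rng = child_rng(seed, "generate_haplotype_panel")

    founder_anc = np.zeros(L, dtype=np.uint8)
    founder_der = np.zeros(L, dtype=np.uint8)
    n_div = int(np.ceil(divergence * L))
    founder_der[rng.choice(L, size=n_div, replace=False)] = 1

    if disjoint_intra_sites:
        half = rng.permutation(L)
        allowed = {
            "anc": np.isin(np.arange(L), half[: L // 2]),
            "der": np.isin(np.arange(L), half[L // 2 :]),
        }
        rate = min(2.0 * intra_diversity, 1.0)
    else:
        allowed = {"anc": np.ones(L, dtype=bool), "der": np.ones(L, dtype=bool)}
        rate = intra_diversity

    def members(founder: np.ndarray, n: int, cls: str) -> np.ndarray:
        copies = np.tile(founder, (n, 1))
        flips = (rng.random((n, L)) < rate) & allowed[cls]
        copies[flips] ^= 1
        return copies

    anc = members(founder_anc, n_anc, "anc")
    der = members(founder_der, n_der, "der")
    haps = [anc, der]
    classes = ["anc"] * n_anc + ["der"] * n_der
    breakpoints: dict[int, int] = {}
    recs = []
    for r in range(n_recombinants):
        a = anc[rng.integers(n_anc)]
        d = der[rng.integers(n_der)]
        bp = int(rng.integers(1, L)) if L > 1 else 1
        left, right = (a, d) if rng.random() < 0.5 else (d, a)
        recs.append(np.concatenate([left[:bp], right[bp:]]))
        breakpoints[n_anc + n_der + r] = bp
        classes.append("rec")
    if recs:
        haps.append(np.array(recs, dtype=np.uint8))

    positions = position_start + np.arange(L, dtype=np.int64) * position_step
    return HaplotypePanel(
        haplotypes=np.concatenate(haps, axis=0),
        classes=np.array(classes),
        breakpoints=breakpoints,
        positions=positions,
        chrom=chrom,
    )


def merge_panels(*panels: HaplotypePanel) -> HaplotypePanel:
    """Concatenate site blocks of row-aligned panels (e.g. flank + core).

    All panels must have the same haplotype count, class labels and
    chromosome, and strictly increasing positions across blocks.  Breakpoint
    truth is block-local and therefore dropped from the merged panel.
    """
    first = panels[0]
    for p in panels[1:]:
        if p.n_haplotypes != first.n_haplotypes or not np.array_equal(
            p.classes, first.classes
        ):
            raise ValueError("panels must be row-aligned with identical classes")
        if p.chrom != first.chrom:
            raise ValueError("panels must share a chromosome")
    positions = np.concatenate([p.positions for p in panels])
    if np.any(np.diff(positions) <= 0):
        raise ValueError("merged positions must be strictly increasing")
    return HaplotypePanel(
        haplotypes=np.concatenate([p.haplotypes for p in panels], axis=1),
        classes=first.classes.copy(),
        breakpoints={},
        positions=positions,
        chrom=first.chrom,
    )


def generate_cohort(
    panel: HaplotypePanel,
    n_small: int,
    n_large: int,
    n_mega: int = 0,
    morph_means: tuple[float, float, float] = MORPH_MEANS_MM,
    morph_sd: float = 0.5,
    het_lmw_offset: float = 0.5,
    seed: int = 0,
) -> CohortTable:
    """Diploid cohort obeying the dominance rule of the polymorphism.

    Small individuals carry two ancestral-class haplotypes; large
    individuals carry at least one derived-class haplotype, alternating
    heterozygous and homozygous-derived so both genotypes are represented;
    mega individuals are homozygous derived.  LMW is Normal(morph mean,
    ``morph_sd``); heterozygous large birds get a small negative offset
    (incomplete dominance).
    """
    if not morph_sd > 0:
        raise ValueError("morph_sd must be > 0")
    rng = child_rng(seed, "generate_cohort")
    anc_rows = panel.rows_of("anc")
    der_rows = panel.rows_of("der")
    if n_small > 0 and len(anc_rows) == 0:
        raise ValueError("panel has no ancestral-class haplotypes for small morphs")
    if (n_large > 0 or n_mega > 0) and len(der_rows) == 0:
        raise ValueError("panel has no derived-class haplotypes for large/mega morphs")
    if n_large >= 2 and len(anc_rows) == 0:
        raise ValueError("heterozygous large individuals need ancestral haplotypes")

    rows = []
    pick = lambda pool: int(rng.choice(pool))
    for i in range(n_small):
        rows.append((f"S{i + 1}", "small", pick(anc_rows), pick(anc_rows), 0.0))
    for i in range(n_large):
        het = i % 2 == 0 and len(anc_rows) > 0  # alternate het / hom-derived
        h1 = pick(anc_rows) if het else pick(der_rows)
        offset = -het_lmw_offset if het else 0.0
        rows.append((f"L{i + 1}", "large", h1, pick(der_rows), offset))
    for i in range(n_mega):
        rows.append((f"M{i + 1}", "mega", pick(der_rows), pick(der_rows), 0.0))

    means = dict(zip(("small", "large", "mega"), morph_means))
    table = pd.DataFrame(rows, columns=["individual_id", "morph", "hap1_id", "hap2_id", "_offset"])
    table["LMW"] = (
        table["morph"].map(means).to_numpy()
        + table.pop("_offset").to_numpy()
        + rng.normal(0.0, morph_sd, size=len(table))
    )
    table = table[["individual_id", "morph", "LMW", "hap1_id", "hap2_id"]]
    cohort = CohortTable(
        table=table,
        hap1=panel.haplotypes[table["hap1_id"].to_numpy(dtype=np.int64)].copy(),
        hap2=panel.haplotypes[table["hap2_id"].to_numpy(dtype=np.int64)].copy(),
        positions=panel.positions.copy(),
        chrom=panel.chrom,
    )
    cohort.validate()
    return cohort


def generate_pool_af(
    cohort: CohortTable,
    candidate_interval: Region | None,
    background_sites: int,
    delta_in_region: float,
    depth_range: tuple[int, int] = (10, 40),
    seed: int = 0,
    n_region_sites: int = 38,
    extent: Region | None = None,
    background_freq: float | None = None,
    private_sites: int = 0,
    private_pool: str = "mega",
) -> pd.DataFrame:
    """Pooled reference-allele frequencies with an implanted high-Δ region.

    Background sites draw a shared frequency per site (``background_freq``
    or Uniform(0.05, 0.95)) and add binomial sequencing noise at the pool's
    read depth, so between-pool differences are small.  Sites inside
    ``candidate_interval`` get exact frequencies with
    ``|freq_small - freq_large| = delta_in_region`` (reference allele high
    in the small pool), the first and last of them sitting exactly on the
    interval boundaries.  Optional ``private_sites`` are fixed differences
    between ``private_pool`` and the others, placed inside the extent.
    """
    if cohort.n_individuals == 0:
        raise ValueError("empty cohort")
    if not 0.0 <= delta_in_region <= 1.0:
        raise ValueError("delta_in_region must be in [0, 1]")
    lo_d, hi_d = depth_range
    if not 0 <= lo_d <= hi_d:
        raise ValueError("invalid depth_range")
    rng = child_rng(seed, "generate_pool_af")

    pools = sorted(cohort.table["morph"].unique(), key=["small", "large", "mega"].index)
    if private_sites > 0 and private_pool not in pools:
        raise ValueError(f"private pool {private_pool!r} absent from cohort")
    if extent is None:
        span = 1_000_000
        center = (
            (candidate_interval.start + candidate_interval.end) // 2
            if candidate_interval is not None
            else span // 2
        )
        extent = Region(cohort.chrom, max(1, center - span // 2), center + span // 2)

    records: list[tuple[int, str]] = []  # (pos, kind)
    taken: set[int] = set()
    if candidate_interval is not None and n_region_sites > 0:
        if n_region_sites < 2:
            raise ValueError("need >= 2 region sites to pin both boundaries")
        inner = rng.choice(
            np.arange(candidate_interval.start + 1, candidate_interval.end),
            size=n_region_sites - 2,
            replace=False,
        )
        for p in [candidate_interval.start, *sorted(inner), candidate_interval.end]:
            records.append((int(p), "region"))
            taken.add(int(p))

    def sample_positions(n: int) -> list[int]:
        out: list[int] = []
        while len(out) < n:
            p = int(rng.integers(extent.start, extent.end + 1))
            if p not in taken:
                taken.add(p)
                out.append(p)
        return out

    records += [(p, "background") for p in sample_positions(background_sites)]
    records += [(p, "private") for p in sample_positions(private_sites)]
    records.sort()

    rows = []
    for pos, kind in records:
        depths = {p: int(rng.integers(lo_d, hi_d + 1)) for p in pools}
        if kind == "region":
            f_small = float(rng.uniform(delta_in_region, 1.0))
            f_large = f_small - delta_in_region
            freqs = {"small": f_small, "large": f_large, "mega": f_large}
        elif kind == "private":
            freqs = {p: (0.0 if p == private_pool else 1.0) for p in pools}
        else:
            shared = (
                background_freq
                if background_freq is not None
                else float(rng.uniform(0.05, 0.95))
            )
            freqs = {
                p: rng.binomial(depths[p], shared) / depths[p] if depths[p] > 0 else 0.0
                for p in pools
            }
        row = {"chrom": cohort.chrom, "pos": pos, "ref": "A", "alt": "T", "kind": kind}
        for p in pools:
            row[f"freq_{p}"] = freqs[p]
            row[f"depth_{p}"] = depths[p]
        rows.append(row)

    table = pd.DataFrame(rows)
    freq_cols = [c for c in table.columns if c.startswith("freq_")]
    assert table[freq_cols].to_numpy().min() >= 0.0
    assert table[freq_cols].to_numpy().max() <= 1.0
    return table


def generate_gene_annotation(
    chrom_length: int,
    n_genes: int,
    length_range: tuple[int, int],
    seed: int = 0,
    chrom: str = DEFAULT_CHROM,
    offset: int = 0,
) -> pd.DataFrame:
    """Non-overlapping gene intervals (BED half-open, 0-based starts).

    Lengths are uniform in ``length_range``; genes are placed by spreading
    the free space between them at random.  ``offset`` shifts all
    coordinates (to drop genes onto an empirical-scale region).
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = child_rng(seed, "generate_gene_annotation")
    if n_genes == 0:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length_range")
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    total = int(lengths.sum())
    if total > chrom_length:
        raise ValueError(
            f"cannot pack {n_genes} genes totalling {total} bp into {chrom_length} bp"
        )
    free = chrom_length - total
    gaps = np.sort(rng.integers(0, free + 1, size=n_genes))
    starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])]) + offset
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts.astype(np.int64),
            "end": (starts + lengths).astype(np.int64),
        }
    )
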