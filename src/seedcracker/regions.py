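"""Candidate-region discovery and the shared-polymorphism density scan.

The Δ scan retains pooled-sequencing sites whose reference-allele frequency
differs between two morph pools by at least a threshold (default 0.9) after
depth filtering, and the candidate region is bounded by the densest cluster
of retained sites.  Region spans follow the ``end - start`` convention of
the empirical coordinates (55,371,638 - 55,070,008 = 301,630 bp).

The inversion screen counts polymorphisms shared between the two allelic
classes and smooths their positions with a rectangular kernel (half-width
1.5 kb by default); runs of depleted density relative to the flanking
median are candidate suppressed-recombination intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "DensityTrack",
    "DepthFilter",
    "delta_scan",
    "bound_candidate_region",
    "region_span",
    "shared_polymorphism_sites",
    "density_track",
    "predict_breakpoints",
]


@dataclass(frozen=True)
class Region:
    """Closed interval between two 1-based boundary SNP positions."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start in region {self}")


def region_span(region: Region) -> int:
    """Span in bp under the end - start convention."""
    return region.end - region.start


@dataclass
class DensityTrack:
    """Event density (per bp) on a fixed-step grid of positions."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    step: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("densities must be >= 0")


@dataclass(frozen=True)
class DepthFilter:
    """Pool-seq site filters: minor-allele depth and per-pool total depth.

    The minor-allele count is summed over the pools being compared, so a
    site fixed for opposite alleles in the two pools (Δ = 1) passes.
    """

    min_minor_depth: int = 2
    min_depth: int = 10
    max_depth: int = 40


def _pool_columns(pool_table: pd.DataFrame, pool: str) -> tuple[str, str]:
    fcol, dcol = f"freq_{pool}", f"depth_{pool}"
    if fcol not in pool_table.columns or dcol not in pool_table.columns:
        raise KeyError(f"pool {pool!r} not present in table")
    return fcol, dcol


def delta_scan(
    pool_table: pd.DataFrame,
    pool_a: str,
    pool_b: str,
    threshold: float = 0.9,
    depth_filter: DepthFilter = DepthFilter(),
) -> pd.DataFrame:
    """Sites with |freq_a - freq_b| >= threshold after depth filtering.

    Returns the passing rows with a ``delta`` column attached, preserving
    the input order (positions are sorted within chromosome upstream).
    """
    fa, da = _pool_columns(pool_table, pool_a)
    fb, db = _pool_columns(pool_table, pool_b)
    depth_a = pool_table[da].to_numpy(dtype=float)
    depth_b = pool_table[db].to_numpy(dtype=float)
    freq_a = pool_table[fa].to_numpy(dtype=float)
    freq_b = pool_table[fb].to_numpy(dtype=float)

    ok = (
        (depth_a >= depth_filter.min_depth)
        & (depth_a <= depth_filter.max_depth)
        & (depth_b >= depth_filter.min_depth)
        & (depth_b <= depth_filter.max_depth)
    )
    ref_count = np.rint(freq_a * depth_a) + np.rint(freq_b * depth_b)
    alt_count = np.rint((1 - freq_a) * depth_a) + np.rint((1 - freq_b) * depth_b)
    ok &= np.minimum(ref_count, alt_count) >= depth_filter.min_minor_depth

    delta = np.abs(freq_a - freq_b)
    keep = ok & (delta >= threshold)
    out = pool_table.loc[keep].copy()
    out["delta"] = delta[keep]
    return out


def bound_candidate_region(sites: pd.DataFrame, max_gap: int = 100_000) -> Region:
    """Bound the candidate region by the densest cluster of high-Δ sites.

    Sites are partitioned per chromosome into clusters separated by gaps
    larger than ``max_gap``; the cluster with the most sites wins (ties go
    to the smaller span), and the region runs from its first to its last
    boundary SNP.
    """
    if len(sites) == 0:
        raise ValueError("no sites to bound a region from")
    best = None  # (count, -span) maximized
    for chrom, chunk in sites.groupby("chrom"):
        pos = np.sort(chunk["pos"].to_numpy(dtype=np.int64))
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        for cluster in np.split(pos, breaks + 1):
            key = (len(cluster), -(cluster[-1] - cluster[0]))
            if best is None or key > best[0]:
                best = (key, Region(str(chrom), int(cluster[0]), int(cluster[-1])))
    return best[1]


def shared_polymorphism_sites(
    genotypes: np.ndarray,
    positions: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> np.ndarray:
    """Positions segregating within group A and within group B.

    ``genotypes`` is a (haplotypes x sites) binary matrix; the groups are
    row-index arrays (>= 2 rows each, e.g. the haplotypes of each allelic
    class).
    """
    ga = np.asarray(group_a)
    gb = np.asarray(group_b)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 haplotypes")
    m = np.asarray(genotypes)

    def segregating(rows) -> np.ndarray:
        count = m[rows].sum(axis=0)
        return (count > 0) & (count < len(rows))

    shared = segregating(ga) & segregating(gb)
    return np.asarray(positions)[shared]


def density_track(
    positions,
    extent: Region,
    bandwidth: float = 1500.0,
    step: float = 100.0,
) -> DensityTrack:
    """Rectangular-kernel density of event positions on a fixed grid.

    At grid point g the density is the number of positions within
    ``bandwidth`` (the kernel half-width) divided by ``2*bandwidth``.
    """
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")
    if region_span(extent) == 0:
        raise ValueError("zero-length extent")
    pos = np.sort(np.asarray(positions, dtype=float))
    grid = np.arange(extent.start, extent.end + step / 2, step, dtype=float)
    hi = np.searchsorted(pos, grid + bandwidth, side="right")
    lo = np.searchsorted(pos, grid - bandwidth, side="left")
    return DensityTrack(
        grid=grid,
        density=(hi - lo) / (2.0 * bandwidth),
        bandwidth=bandwidth,
        step=step,
    )


def predict_breakpoints(
    track: DensityTrack,
    depletion_threshold: float = 0.25,
    min_run: float = 10_000.0,
    flank_fraction: float = 0.15,
) -> list[tuple[float, float]]:
    """Maximal depleted runs of the density track, as (start, end) pairs.

    A grid point is depleted when its density falls below
    ``depletion_threshold`` times the flank median, where the flanks are the
    outermost ``flank_fraction`` of the extent on each side (the scan is run
    over a candidate region plus flanking sequence precisely so that the
    flanks calibrate the freely recombining background).  Runs shorter than
    ``min_run`` bp are discarded.
    """
    if len(track.grid) == 0:
        raise ValueError("empty track")
    k = max(int(len(track.grid) * flank_fraction), 1)
    flank = np.concatenate([track.density[:k], track.density[-k:]])
    if float(np.median(flank)) == 0.0:
        raise ValueError("flank median is zero; cannot normalize depletion")
    cutoff = depletion_threshold * float(np.median(flank))
    low = track.density < cutoff
    runs: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((track.grid[start], track.grid[i - 1]))
            start = None
    if start is not None:
        runs.append((track.grid[start], track.grid[-1]))
    return [(s, e) for s, e in runs if e - s >= min_run]
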