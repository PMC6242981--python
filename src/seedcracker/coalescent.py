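"""Structured coalescent conditional on an allele-frequency trajectory.

Lineages are partitioned into the derived (selected) and ancestral allelic
classes.  Going backward in time on the trajectory's own generation grid,
each pair of lineages in a class coalesces in a given generation with
probability ``1/(2*N_sim*x)`` where ``x`` is that class's frequency; there
is no migration between classes while the allele segregates (no
recombination within the locus).  At the allele's origin generation all
remaining derived lineages are merged and the resulting lineage joins the
ancestral class, after which a standard single-class (Kingman) coalescent
runs to the root.  Infinite-sites mutations are then dropped on the
genealogy with per-branch Poisson counts.

Event times are sampled exactly on the discrete grid: the waiting time to
the next coalescence is the first generation at which the cumulative hazard
``sum_t -C(k,2)*log(1 - p_t)`` exceeds an Exp(1) draw, which reproduces
per-generation Bernoulli trials with success probability
``1-(1-p_t)^C(k,2)`` without touching every generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rng import child_rng
from .trajectory import Trajectory, TrajectoryParams, simulate_trajectory

__all__ = [
    "SampleConfig",
    "Genealogy",
    "HaplotypeSample",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_sample",
    "write_ms",
]

# Non-recombinant analysis interval of the empirical locus (bp).
DEFAULT_LOCUS_LENGTH = 285_969


@dataclass(frozen=True)
class SampleConfig:
    """Sample sizes per allelic class, locus length, scaled mutation rate.

    Defaults mirror the empirical configuration: 20 ancestral-class and 10
    derived-class haplotypes (homozygous small- and large-billed birds) over
    the ~286 kb non-recombining interval at theta = 0.001 per bp.
    """

    n_anc: int = 20
    n_der: int = 10
    L: int = DEFAULT_LOCUS_LENGTH
    theta: float = 0.001

    def __post_init__(self) -> None:
        if self.n_anc < 0 or self.n_der < 0 or self.n_anc + self.n_der < 2:
            raise ValueError("need n_anc + n_der >= 2 non-negative sample sizes")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not self.theta > 0:
            raise ValueError("theta must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_anc + self.n_der


@dataclass
class Genealogy:
    """Binary genealogy as node arrays.

    Leaves are nodes ``0..n-1`` (ancestral class first, then derived);
    internal nodes follow in order of creation.  ``times`` are in
    generations before the present; ``parent`` is -1 at the root.
    """

    n_leaves: int
    times: np.ndarray
    parent: np.ndarray
    leaf_is_derived: np.ndarray
    origin_generation: int | None = None
    N_sim: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def leaf_sets(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves) matrix of descendant leaves."""
        below = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        below[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        # internal nodes are created children-first, so one ascending pass works
        for i, p in enumerate(self.parent):
            if p >= 0:
                below[p] |= below[i]
        return below

    def newick(self) -> str:
        kids = self.children()

        def fmt(node: int, parent_time: float | None) -> str:
            bl = "" if parent_time is None else f":{parent_time - self.times[node]:.6g}"
            if node < self.n_leaves:
                cls = "der" if self.leaf_is_derived[node] else "anc"
                return f"{cls}{node}{bl}"
            inner = ",".join(fmt(c, float(self.times[node])) for c in kids[node])
            return f"({inner}){bl}"

        return fmt(self.root, None) + ";"


@dataclass
class HaplotypeSample:
    """Binary infinite-sites haplotype matrix with allelic-class labels."""

    matrix: np.ndarray  # (n_haplotypes, n_sites) of 0/1
    positions: np.ndarray  # 1-based bp in [1, L], strictly increasing
    is_derived: np.ndarray  # per-haplotype class label
    L: int
    trajectory: Trajectory | None = field(default=None, repr=False)

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


def _pair_hazards(trajectory: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative per-pair coalescence hazards along the trajectory.

    Index t holds the hazard accumulated over backward steps 1..t; the step
    into the origin generation has per-pair probability 1 for the derived
    class (a single copy), clamped for the log.  Trajectories produced by
    the simulation kernel carry these arrays already.
    """
    if trajectory.cum_hazard_der is not None:
        return trajectory.cum_hazard_der, trajectory.cum_hazard_anc
    x = trajectory.freqs
    two_n = 2.0 * trajectory.N_sim
    eps = 1e-12
    p_der = np.clip(1.0 / (two_n * x), 0.0, 1.0 - eps)
    p_anc = np.clip(1.0 / (two_n * (1.0 - x)), 0.0, 1.0 - eps)
    hz_der = -np.log1p(-p_der)
    hz_anc = -np.log1p(-p_anc)
    hz_der[0] = 0.0
    hz_anc[0] = 0.0
    return np.cumsum(hz_der), np.cumsum(hz_anc)


def _first_crossing(cum_d, cum_a, cd, ca, t0, target):
    """Smallest t > t0 with cd*(D[t]-D[t0]) + ca*(A[t]-A[t0]) >= target.

    Returns None if the trajectory ends first.  Binary search on the
    implicit monotone combination (never materialized).
    """
    base = cd * cum_d[t0] + ca * cum_a[t0]
    T = len(cum_d) - 1

    def val(t: int) -> float:
        return cd * cum_d[t] + ca * cum_a[t] - base

    if val(T) < target:
        return None
    lo, hi = t0, T  # val(lo) < target <= val(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if val(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


class _TreeBuilder:
    def __init__(self, n_leaves: int):
        self.times = [0.0] * n_leaves
        self.parent = [-1] * n_leaves

    def merge(self, a: int, b: int, t: float) -> int:
        node = len(self.times)
        self.times.append(float(t))
        self.parent.append(-1)
        self.parent[a] = node
        self.parent[b] = node
        return node


def simulate_genealogy(
    trajectory: Trajectory | None,
    config: SampleConfig,
    seed: int = 0,
    N_sim: int | None = None,
) -> Genealogy:
    """Genealogy of n_anc + n_der lineages conditional on the trajectory.

    With ``n_der == 0`` the trajectory may be None (``N_sim`` must then be
    given) and the process is the plain Kingman coalescent at that size.
    """
    rng = child_rng(seed, "simulate_genealogy")
    if config.n_der > 0:
        if trajectory is None or trajectory.origin_generation < 0:
            raise ValueError("n_der > 0 requires a non-empty trajectory")
    if trajectory is not None:
        if trajectory.cum_hazard_der is None:
            trajectory.validate()  # kernel-produced trajectories are valid
        N_sim = trajectory.N_sim
    elif N_sim is None:
        raise ValueError("N_sim is required when no trajectory is given")
    two_n = 2.0 * N_sim
    T = trajectory.origin_generation if trajectory is not None else 0

    tb = _TreeBuilder(config.n_total)
    active_anc = list(range(config.n_anc))
    active_der = list(range(config.n_anc, config.n_total))
    leaf_is_derived = np.zeros(config.n_total, dtype=bool)
    leaf_is_derived[config.n_anc:] = True

    # all randomness pre-drawn: at most n_total - 1 merge events occur
    n_ev = max(config.n_total - 1, 1)
    expos = rng.exponential(size=n_ev)
    u_all = rng.random(size=(n_ev, 4))  # class choice, pair pick x2, waiting time
    ev = 0

    def pick_pair(pool: list[int], u1: float, u2: float) -> tuple[int, int]:
        k = len(pool)
        i = min(int(u1 * k), k - 1)
        j = min(int(u2 * (k - 1)), k - 2)
        if j >= i:
            j += 1
        return pool[i], pool[j]

    def merge_into(pool: list[int], a: int, b: int, when: float) -> None:
        node = tb.merge(a, b, when)
        pool.remove(a)
        pool.remove(b)
        pool.append(node)

    t = 0
    if config.n_der > 0:
        cum_d, cum_a = _pair_hazards(trajectory)
        # structured phase: present -> origin
        while t < T and (len(active_der) > 1 or len(active_anc) > 1):
            kd, ka = len(active_der), len(active_anc)
            cd = kd * (kd - 1) / 2.0
            ca = ka * (ka - 1) / 2.0
            tau = _first_crossing(cum_d, cum_a, cd, ca, t, expos[ev])
            if tau is None:
                t = T
                break
            # class choice by relative hazard in generation tau
            hd = cd * (cum_d[tau] - cum_d[tau - 1])
            ha = ca * (cum_a[tau] - cum_a[tau - 1])
            pool = active_der if u_all[ev, 0] * (hd + ha) < hd else active_anc
            a, b = pick_pair(pool, u_all[ev, 1], u_all[ev, 2])
            merge_into(pool, a, b, tau)
            t = tau
            ev += 1
        # origin: all remaining derived lineages merge, survivor joins ancestral
        while len(active_der) > 1:
            a, b = pick_pair(active_der, u_all[ev, 1], u_all[ev, 2])
            merge_into(active_der, a, b, T)
            ev += 1
        active_anc.append(active_der.pop())
        t = max(t, T)

    # single-class phase older than the origin (plain discrete coalescent)
    while len(active_anc) > 1:
        k = len(active_anc)
        p_any = min(k * (k - 1) / 2.0 / two_n, 1.0)
        # discrete geometric waiting time by inversion
        if p_any >= 1.0:
            t += 1
        else:
            t += int(np.ceil(np.log1p(-u_all[ev, 3]) / np.log1p(-p_any)))
        a, b = pick_pair(active_anc, u_all[ev, 1], u_all[ev, 2])
        merge_into(active_anc, a, b, t)
        ev += 1

    return Genealogy(
        n_leaves=config.n_total,
        times=np.asarray(tb.times),
        parent=np.asarray(tb.parent, dtype=np.int64),
        leaf_is_derived=leaf_is_derived,
        origin_generation=T if config.n_der > 0 else None,
        N_sim=N_sim,
    )


def drop_mutations(
    genealogy: Genealogy,
    config: SampleConfig,
    seed: int = 0,
) -> HaplotypeSample:
    """Poisson infinite-sites mutations on the genealogy's branches.

    Per-branch counts are Poisson(branch_generations * mu_sim * L) with
    ``mu_sim = theta/(4*N_sim)`` implied by the branch time scale; here the
    branch lengths already carry the generation scale of the trajectory, so
    the caller passes theta through ``config`` and ``N_sim`` via the rate
    below.  Each mutation takes a fresh uniform position in [1, L].
    """
    rng = child_rng(seed, "drop_mutations")
    n = genealogy.n_leaves
    bl = np.zeros(genealogy.n_nodes)
    has_parent = genealogy.parent >= 0
    bl[has_parent] = (
        genealogy.times[genealogy.parent[has_parent]] - genealogy.times[has_parent]
    )
    # theta = 4*N_sim*mu ; branch lengths are in generations of the same
    # N_sim, so the per-generation locus rate is theta*L/(4*N_sim).
    if genealogy.N_sim is None:
        raise ValueError("genealogy lacks its simulation population size")
    rate = config.theta * config.L / (4.0 * genealogy.N_sim)
    counts = rng.poisson(bl * rate)
    total = int(counts.sum())
    if total > config.L:
        raise ValueError("more mutations than sites; increase L or lower theta")
    below = genealogy.leaf_sets()
    node_of_site = np.repeat(np.arange(genealogy.n_nodes), counts)
    matrix = below[node_of_site].T.astype(np.uint8)
    positions = rng.choice(config.L, size=total, replace=False) + 1
    order = np.argsort(positions)
    return HaplotypeSample(
        matrix=np.ascontiguousarray(matrix[:, order]),
        positions=positions[order].astype(np.int64),
        is_derived=genealogy.leaf_is_derived.copy(),
        L=config.L,
    )


def simulate_sample(
    params: TrajectoryParams,
    config: SampleConfig,
    N_sim: int = 5000,
    seed: int = 0,
    max_rejects: int = 5000,
) -> HaplotypeSample:
    """Trajectory -> genealogy -> mutations, deterministically from ``seed``."""
    traj = simulate_trajectory(params, N_sim=N_sim, max_rejects=max_rejects, seed=seed)
    gen = simulate_genealogy(traj, config, seed=seed)
    sample = drop_mutations(gen, config, seed=seed)
    sample.trajectory = traj
    return sample


def write_ms(sample: HaplotypeSample, fh) -> None:
    """ms-style text block (//, segsites, positions, 0/1 rows).

    A leading comment line annotates the allelic class of each row.
    """
    close = False
    if isinstance(fh, (str, bytes)):
        fh = open(fh, "w")
        close = True
    try:
        labels = " ".join("der" if d else "anc" for d in sample.is_derived)
        fh.write(f"# classes: {labels}\n//\n")
        fh.write(f"segsites: {sample.n_sites}\n")
        rel = sample.positions / sample.L
        fh.write("positions: " + " ".join(f"{p:.6f}" for p in rel) + "\n")
        for row in sample.matrix:
            fh.write("".join("1" if v else "0" for v in row) + "\n")
    finally:
        if close:
            fh.close()
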