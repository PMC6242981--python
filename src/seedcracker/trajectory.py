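"""Allele-frequency trajectories under heterozygote advantage.

A balanced polymorphism maintained by overdominance is parameterized by the
scaled heterozygous selection coefficient ``S = 4*Ne*s2`` (the heterozygote's
advantage over the ancestral homozygote, scaled by population size), the
deterministic equilibrium frequency ``f_eq`` of the derived allele, and the
allele age ``T_age`` in coalescent units of ``4*Ne`` generations.  Given
those three numbers the relative fitnesses of the three genotypes are fully
determined (heterozygote fitness normalized to 1), and the allele's
frequency path from a single copy at its origin to the present is simulated
with a forward Wright-Fisher model: deterministic selection update followed
by binomial resampling of ``2*N_sim`` allele copies each generation.  Paths
that lose or fix the allele before the present are rejected and restarted,
so every returned trajectory segregates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import wf_trajectory
from .rng import child_seed

__all__ = [
    "TrajectoryParams",
    "GenotypeFitnesses",
    "Trajectory",
    "fitnesses_from_params",
    "equilibrium_frequency",
    "simulate_trajectory",
    "trajectory_to_tsv",
    "trajectory_from_tsv",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """(S, f_eq, T_age) triple describing an overdominant allele."""

    S: float
    f_eq: float
    T_age: float

    def __post_init__(self) -> None:
        if not self.S > 0:
            raise ValueError(f"S must be > 0, got {self.S}")
        if not 0.0 < self.f_eq < 1.0:
            raise ValueError(f"f_eq must be in (0, 1), got {self.f_eq}")
        if self.T_age < 0:
            raise ValueError(f"T_age must be >= 0, got {self.T_age}")


@dataclass(frozen=True)
class GenotypeFitnesses:
    """Relative fitnesses (ancestral hom, het, derived hom); overdominant."""

    w_anc_hom: float
    w_het: float
    w_der_hom: float

    def __post_init__(self) -> None:
        if not self.w_het > max(self.w_anc_hom, self.w_der_hom):
            raise ValueError(
                "not overdominant: w_het must exceed both homozygote fitnesses "
                f"(got {self.w_anc_hom}, {self.w_het}, {self.w_der_hom})"
            )


@dataclass
class Trajectory:
    """Derived-allele frequency per past generation.

    ``freqs[i]`` is the frequency ``i`` generations before the present;
    the last entry is the single-copy origin frequency ``1/(2*N_sim)``.
    """

    N_sim: int
    freqs: np.ndarray
    n_rejected: int = 0
    params: TrajectoryParams | None = field(default=None, repr=False)
    # cached cumulative per-pair coalescence hazards (filled by the kernel)
    cum_hazard_der: np.ndarray | None = field(default=None, repr=False)
    cum_hazard_anc: np.ndarray | None = field(default=None, repr=False)

    @property
    def origin_generation(self) -> int:
        return len(self.freqs) - 1

    @property
    def present_frequency(self) -> float:
        return float(self.freqs[0])

    def validate(self) -> None:
        if len(self.freqs) < 1:
            raise ValueError("empty trajectory")
        if not np.all((self.freqs > 0.0) & (self.freqs < 1.0)):
            raise ValueError("trajectory contains an absorbed (lost/fixed) state")
        origin = self.freqs[-1]
        if abs(origin - 1.0 / (2 * self.N_sim)) > 1e-12:
            raise ValueError("trajectory does not start from a single copy")


def fitnesses_from_params(S: float, f_eq: float, N_sim: int) -> GenotypeFitnesses:
    """Genotype fitnesses implied by (S, f_eq) at rescaled size ``N_sim``.

    With heterozygote fitness 1, the ancestral homozygote pays
    ``s2 = S/(4*N_sim)`` and the derived homozygote pays
    ``s1 = s2*(1-f_eq)/f_eq``, so the deterministic equilibrium
    ``s2/(s1+s2)`` equals ``f_eq``.
    """
    TrajectoryParams(S, f_eq, 0.0)  # validate S and f_eq
    s2 = S / (4.0 * N_sim)
    s1 = s2 * (1.0 - f_eq) / f_eq
    if s1 >= 1.0 or s2 >= 1.0:
        raise ValueError(
            f"selection too strong at N_sim={N_sim} (s1={s1:.4g}, s2={s2:.4g}); "
            "increase N_sim"
        )
    return GenotypeFitnesses(w_anc_hom=1.0 - s2, w_het=1.0, w_der_hom=1.0 - s1)


def equilibrium_frequency(fitnesses: GenotypeFitnesses) -> float:
    """Deterministic equilibrium ``s2/(s1+s2)`` of an overdominant locus."""
    s1 = (fitnesses.w_het - fitnesses.w_der_hom) / fitnesses.w_het
    s2 = (fitnesses.w_het - fitnesses.w_anc_hom) / fitnesses.w_het
    return s2 / (s1 + s2)


def n_generations(T_age: float, N_sim: int) -> int:
    """Trajectory duration in generations: round(T_age * 4 * N_sim)."""
    return int(round(T_age * 4 * N_sim))


def simulate_trajectory(
    params: TrajectoryParams,
    N_sim: int = 5000,
    max_rejects: int = 5000,
    seed: int = 0,
) -> Trajectory:
    """Simulate one segregating trajectory from a single copy to the present.

    Raises ``RuntimeError`` if ``max_rejects`` lost/fixed paths are discarded
    without a survivor (near-neutral, loss-dominated parameter corner).
    """
    if N_sim < 100:
        raise ValueError("N_sim must be >= 100")
    if max_rejects < 1:
        raise ValueError("max_rejects must be >= 1")
    fit = fitnesses_from_params(params.S, params.f_eq, N_sim)
    n_gen = n_generations(params.T_age, N_sim)
    freqs, cum_d, cum_a, rejects = wf_trajectory(
        n_gen,
        2 * N_sim,
        fit.w_der_hom,
        fit.w_anc_hom,
        max_rejects,
        child_seed(seed, "simulate_trajectory"),
    )
    if rejects < 0:
        raise RuntimeError(
            f"trajectory rejected {max_rejects} times without surviving "
            f"(S={params.S}, f_eq={params.f_eq}, T_age={params.T_age})"
        )
    traj = Trajectory(
        N_sim=N_sim,
        freqs=freqs,
        n_rejected=int(rejects),
        params=params,
        cum_hazard_der=cum_d,
        cum_hazard_anc=cum_a,
    )
    traj.validate()
    return traj


def trajectory_to_tsv(traj: Trajectory, path) -> None:
    """Write (generation_before_present, frequency) as two-column TSV."""
    with open(path, "w") as fh:
        fh.write("generation_before_present\tfrequency\n")
        for g, f in enumerate(traj.freqs):
            fh.write(f"{g}\t{float(f)!r}\n")


def trajectory_from_tsv(path, N_sim: int) -> Trajectory:
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    order = np.argsort(data[:, 0])
    traj = Trajectory(N_sim=N_sim, freqs=data[order, 1].copy())
    traj.validate()
    return traj
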