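"""Rejection ABC for the age of the balanced derived haplotype.

Parameters (S, f_eq, T_age) are drawn from independent uniform priors,
haplotype samples are simulated under the trajectory-conditional structured
coalescent, and the draws whose summary statistics (pi_anc, pi_der, d_xy)
lie closest to the observed statistics in Euclidean distance are retained
as the posterior sample.  Posterior modes come from a Gaussian KDE
(Silverman bandwidth) on a 512-point grid over the prior support.  The
scaled-time posterior is converted to generations and years through the
plug-in Watterson estimate of theta, the unscaled mutation rate, and the
generation time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalescent import SampleConfig, simulate_sample
from .rng import child_rng
from .sumstats import SummaryStats, summary_stats
from .trajectory import TrajectoryParams

__all__ = [
    "PriorSpec",
    "ABCConfig",
    "ScalingConstants",
    "ABCResult",
    "sample_prior",
    "run_reference_table",
    "rejection_select",
    "posterior_mode",
    "ne_from_theta",
    "round_to_thousand",
    "age_to_generations_years",
    "infer_age",
]


@dataclass(frozen=True)
class PriorSpec:
    """Uniform priors on S, f_eq and T_age (coalescent units of 4Ne)."""

    S_range: tuple[float, float] = (50.0, 1000.0)
    f_eq_range: tuple[float, float] = (0.2, 0.8)
    T_age_range: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("S_range", self.S_range),
            ("f_eq_range", self.f_eq_range),
            ("T_age_range", self.T_age_range),
        ):
            if not lo < hi:
                raise ValueError(f"{name} must have lower < upper, got ({lo}, {hi})")

    def range_of(self, parameter: str) -> tuple[float, float]:
        return {"S": self.S_range, "f_eq": self.f_eq_range, "T_age": self.T_age_range}[
            parameter
        ]


@dataclass(frozen=True)
class ABCConfig:
    n_sims: int = 20_000
    n_accept: int = 200
    distance: str = "raw_euclidean"  # or "normalized_euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accept > self.n_sims:
            raise ValueError("n_accept must be <= n_sims")
        if self.distance not in ("raw_euclidean", "normalized_euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass(frozen=True)
class ScalingConstants:
    """Unscaled per-generation mutation rate and generation time."""

    mu: float = 2.2e-9  # per bp per generation
    g: float = 5.0  # years per generation

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.g > 0):
            raise ValueError("mu and g must be > 0")


@dataclass
class ABCResult:
    accepted: pd.DataFrame  # columns S, f_eq, T_age, pi_anc, pi_der, d_xy, distance
    modes: dict[str, float]
    theta_hat: float
    Ne: float
    age_coalescent: float
    age_generations: float
    age_years: float
    n_sims: int
    n_failed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "modes": self.modes,
            "theta_hat": self.theta_hat,
            "Ne": self.Ne,
            "age_coalescent": self.age_coalescent,
            "age_generations": self.age_generations,
            "age_years": self.age_years,
            "n_sims": self.n_sims,
            "n_failed": self.n_failed,
            "accepted": self.accepted.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


PARAM_COLS = ["S", "f_eq", "T_age"]
STAT_COLS = ["pi_anc", "pi_der", "d_xy"]


def sample_prior(n: int, prior: PriorSpec = PriorSpec(), seed: int = 0) -> pd.DataFrame:
    """``n`` independent (S, f_eq, T_age) triples from the uniform priors."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = child_rng(seed, "sample_prior")
    return pd.DataFrame(
        {
            "S": rng.uniform(*prior.S_range, size=n),
            "f_eq": rng.uniform(*prior.f_eq_range, size=n),
            "T_age": rng.uniform(*prior.T_age_range, size=n),
        }
    )


def run_reference_table(
    draws: pd.DataFrame,
    config: SampleConfig,
    N_sim: int = 5000,
    seed: int = 0,
    max_rejects: int = 5000,
    max_failure_fraction: float = 0.1,
) -> pd.DataFrame:
    """Simulate one sample per draw and evaluate the three statistics.

    Draws whose trajectory exhausts the rejection budget are dropped (their
    count is recorded in ``df.attrs['n_failed']``); more than
    ``max_failure_fraction`` failures aborts with a diagnostic.
    """
    if len(draws) == 0:
        raise ValueError("draws must be non-empty")
    seed_rng = child_rng(seed, "run_reference_table")
    sim_seeds = seed_rng.integers(2**31, size=len(draws))
    rows = []
    n_failed = 0
    for (_, draw), sim_seed in zip(draws.iterrows(), sim_seeds):
        params = TrajectoryParams(draw["S"], draw["f_eq"], draw["T_age"])
        try:
            sample = simulate_sample(
                params, config, N_sim=N_sim, seed=int(sim_seed), max_rejects=max_rejects
            )
        except RuntimeError:
            n_failed += 1
            continue
        ss = summary_stats(sample)
        rows.append(
            (draw["S"], draw["f_eq"], draw["T_age"], ss.pi_anc, ss.pi_der, ss.d_xy)
        )
    if n_failed > max_failure_fraction * len(draws):
        raise RuntimeError(
            f"{n_failed}/{len(draws)} simulations failed their trajectory "
            "rejection budget; the prior mass sits in a loss-dominated regime"
        )
    table = pd.DataFrame(rows, columns=PARAM_COLS + STAT_COLS)
    table.attrs["n_failed"] = n_failed
    return table


def rejection_select(
    table: pd.DataFrame,
    observed: SummaryStats,
    config: ABCConfig,
) -> pd.DataFrame:
    """Retain the n_accept rows closest to the observed statistics.

    Distances are Euclidean over (pi_anc, pi_der, d_xy); with the
    normalized variant each statistic is first divided by its standard
    deviation in the reference table.  Ties break by draw index.
    """
    if len(table) < config.n_accept:
        raise ValueError("reference table smaller than n_accept")
    obs = observed.as_array()
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed statistics must be finite")
    stats = table[STAT_COLS].to_numpy(dtype=float)
    if config.distance == "normalized_euclidean":
        scale = stats.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        stats = stats / scale
        obs = obs / scale
    dist = np.sqrt(((stats - obs) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[: config.n_accept]
    out = table.iloc[order].copy()
    out["distance"] = dist[order]
    return out


def posterior_mode(
    accepted: pd.DataFrame,
    parameter: str,
    prior: PriorSpec = PriorSpec(),
    grid_size: int = 512,
) -> float:
    """KDE argmax of a parameter's accepted draws over the prior support."""
    values = np.asarray(accepted[parameter], dtype=float)
    if len(values) < 10:
        raise ValueError("need >= 10 accepted draws for a posterior mode")
    if values.max() == values.min():
        warnings.warn(
            f"degenerate accepted sample for {parameter}; returning its common value"
        )
        return float(values[0])
    lo, hi = prior.range_of(parameter)
    grid = np.linspace(lo, hi, grid_size)
    kde = gaussian_kde(values, bw_method="silverman")
    return float(grid[np.argmax(kde(grid))])


def ne_from_theta(theta_per_bp: float, constants: ScalingConstants = ScalingConstants()) -> float:
    """Effective population size Ne = theta / (4*mu)."""
    if not theta_per_bp > 0:
        raise ValueError("theta must be > 0")
    return theta_per_bp / (4.0 * constants.mu)


def round_to_thousand(x: float) -> int:
    """Reporting helper: nearest thousand individuals."""
    return int(round(x / 1000.0) * 1000)


def age_to_generations_years(
    T_age: float,
    Ne: float,
    constants: ScalingConstants = ScalingConstants(),
) -> tuple[float, float]:
    """Coalescent-unit age -> (generations, years): T*4*Ne and *g."""
    if T_age < 0 or not Ne > 0:
        raise ValueError("need T_age >= 0 and Ne > 0")
    generations = T_age * 4.0 * Ne
    return generations, generations * constants.g


def infer_age(
    observed: SummaryStats,
    theta_hat: float,
    sample_config: SampleConfig,
    abc_config: ABCConfig = ABCConfig(),
    prior: PriorSpec = PriorSpec(),
    constants: ScalingConstants = ScalingConstants(),
    N_sim: int = 5000,
) -> ABCResult:
    """Full pipeline: priors -> reference table -> rejection -> scaling."""
    draws = sample_prior(abc_config.n_sims, prior, seed=abc_config.seed)
    table = run_reference_table(
        draws, sample_config, N_sim=N_sim, seed=abc_config.seed
    )
    accepted = rejection_select(table, observed, abc_config)
    modes = {p: posterior_mode(accepted, p, prior) for p in PARAM_COLS}
    Ne = ne_from_theta(theta_hat, constants)
    generations, years = age_to_generations_years(modes["T_age"], Ne, constants)
    return ABCResult(
        accepted=accepted,
        modes=modes,
        theta_hat=theta_hat,
        Ne=Ne,
        age_coalescent=modes["T_age"],
        age_generations=generations,
        age_years=years,
        n_sims=abc_config.n_sims,
        n_failed=table.attrs.get("n_failed", 0),
    )
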