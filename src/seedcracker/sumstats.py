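"""Summary and descriptive statistics on haplotype matrices and genotypes.

The three statistics driving the allele-age inference are per-bp nucleotide
diversity within the ancestral class, within the derived class, and the
per-bp average divergence between the classes.  Descriptive statistics used
in the candidate-region analyses (pairwise mismatch fractions, Watterson's
theta, sliding-window observed heterozygosity, haplotype-dosage association
with the quantitative trait) live here too.

Missing data: all functions assume complete matrices; the empirical
pipeline filtered sites to <=10% missing upstream.  Per-bp values divide by
the locus length L, while mismatch fractions divide by the number of
assayed SNP sites (the convention used for "% mismatches" on SNP panels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .coalescent import HaplotypeSample

__all__ = [
    "SummaryStats",
    "nucleotide_diversity",
    "dxy",
    "watterson_theta",
    "mismatch_matrix",
    "observed_heterozygosity_windows",
    "haplotype_dosage_association",
    "summary_stats",
]


@dataclass(frozen=True)
class SummaryStats:
    """Per-bp (pi_anc, pi_der, d_xy)."""

    pi_anc: float
    pi_der: float
    d_xy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_anc, self.pi_der, self.d_xy])


def _as_matrix(haps) -> np.ndarray:
    m = np.asarray(haps)
    if m.ndim != 2:
        raise ValueError("haplotypes must be a 2-D (haplotypes x sites) matrix")
    return m.astype(np.float64)


def _pairwise_diff_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matrix of pairwise difference counts between rows of a and rows of b."""
    return a @ (1.0 - b).T + (1.0 - a) @ b.T


def nucleotide_diversity(haps, L: int) -> float:
    """Mean pairwise difference count over unordered pairs, per bp."""
    m = _as_matrix(haps)
    n = m.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 haplotypes")
    d = _pairwise_diff_sum(m, m)
    total = d[np.triu_indices(n, k=1)].sum()
    return float(total / (n * (n - 1) / 2) / L)


def dxy(haps_a, haps_b, L: int) -> float:
    """Mean pairwise difference count over between-group pairs, per bp."""
    a, b = _as_matrix(haps_a), _as_matrix(haps_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    return float(_pairwise_diff_sum(a, b).mean() / L)


def watterson_theta(haps, L: int) -> float:
    """Watterson's estimator: segregating sites / (a_n * L)."""
    m = _as_matrix(haps)
    n = m.shape[0]
    if n < 2:
        raise ValueError("Watterson's theta needs >= 2 haplotypes")
    # a site is segregating iff both alleles present among the n rows
    col = m.sum(axis=0)
    seg = int(np.count_nonzero((col > 0) & (col < n)))
    a_n = np.sum(1.0 / np.arange(1, n))
    return float(seg / (a_n * L))


def mismatch_matrix(haps) -> np.ndarray:
    """Symmetric matrix of pairwise mismatch fractions over assayed sites."""
    m = _as_matrix(haps)
    if m.shape[0] < 2:
        raise ValueError("mismatch matrix needs >= 2 haplotypes")
    if m.shape[1] < 1:
        raise ValueError("mismatch matrix needs >= 1 site")
    return _pairwise_diff_sum(m, m) / m.shape[1]


def observed_heterozygosity_windows(
    hap1,
    hap2,
    window: int = 200,
    step: int = 100,
):
    """Sliding-window observed heterozygosity per individual.

    ``hap1``/``hap2`` are (individuals x sites) phased haplotype matrices;
    a call is heterozygous where they differ.  Windows slide over the SNP
    index; the trailing partial window is retained and flagged.

    Returns ``(ho, starts, ends, partial)`` where ``ho`` has one row per
    window and one column per individual.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    het = np.asarray(hap1) != np.asarray(hap2)
    n_sites = het.shape[1]
    starts = list(range(0, max(n_sites - window, 0) + 1, step))
    if not starts:
        starts = [0]
    # a trailing partial window covers any sites the full windows miss
    if starts[-1] + window < n_sites:
        starts.append(starts[-1] + step)
    starts_arr = np.array(starts)
    ends = np.minimum(starts_arr + window, n_sites)
    ho = np.array([het[:, s:e].mean(axis=1) for s, e in zip(starts_arr, ends)])
    partial = (ends - starts_arr) < window
    return ho, starts_arr, ends, partial


@dataclass(frozen=True)
class DosageAssociation:
    beta: float
    se: float
    T: float
    r_squared: float
    p_value: float
    n: int


def haplotype_dosage_association(dosages, lmw) -> DosageAssociation:
    """OLS of the quantitative trait on haplotype copy number (0/1/2).

    Wald T = beta/SE with a two-sided p from the t distribution on n-2 df.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(lmw, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("dosages and trait must be equal-length 1-D vectors")
    if len(d) < 3:
        raise ValueError("need n >= 3 individuals")
    if np.var(d) == 0:
        raise ValueError("dosage has zero variance")
    res = sps.linregress(d, y)
    return DosageAssociation(
        beta=float(res.slope),
        se=float(res.stderr),
        T=float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(d),
    )


def summary_stats(sample: HaplotypeSample) -> SummaryStats:
    """The three ABC statistics from a class-labelled haplotype sample."""
    anc = sample.matrix[~sample.is_derived]
    der = sample.matrix[sample.is_derived]
    return SummaryStats(
        pi_anc=nucleotide_diversity(anc, sample.L),
        pi_der=nucleotide_diversity(der, sample.L),
        d_xy=dxy(anc, der, sample.L),
    )
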