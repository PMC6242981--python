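"""Numba kernels for the forward Wright-Fisher trajectory simulation.

The allele-age inference needs on the order of 10^5 trajectories of up to
10^5 generations each on one core, so the generation loop is JIT-compiled
and draws its binomial variates from a xoshiro256++ stream (seeded through
splitmix64) with Hormann's BTRS transformed-rejection sampler, whose heavy
setup (log / lgamma) is deferred to the rare non-squeeze branch.  The
sampler is exact — it targets the binomial distribution itself, not an
approximation — and is validated against scipy's binomial pmf in the test
suite.

The kernel also accumulates the per-pair coalescence hazards of the two
allelic classes along the path (``-log(1 - p_t)`` per generation), which
the structured coalescent consumes; computing them here avoids a second
pass over the trajectory in numpy.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, uint64

__all__ = ["wf_trajectory", "binomial_draws"]

_INV53 = 1.1102230246251565e-16  # 2^-53


@njit(inline="always")
def _rotl(x, k):
    return (x << k) | (x >> (uint64(64) - k))


@njit(inline="always")
def _next_u64(s):
    r = _rotl(s[0] + s[3], uint64(23)) + s[0]
    t = s[1] << uint64(17)
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], uint64(45))
    return r


@njit(inline="always")
def _uniform(s):
    return (_next_u64(s) >> uint64(11)) * _INV53


@njit
def _seed_state(seed):
    # splitmix64 expansion of a single integer seed into the 256-bit state
    s = np.empty(4, np.uint64)
    z = uint64(seed)
    for i in range(4):
        z = z + uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> uint64(27))) * uint64(0x94D049BB133111EB)
        s[i] = w ^ (w >> uint64(31))
    return s


@njit(inline="always")
def _binomial(n, p_in, s):
    """Exact Binomial(n, p) draw: CDF inversion for small means, BTRS else."""
    flip = p_in > 0.5
    p = 1.0 - p_in if flip else p_in
    mean = n * p
    if mean < 10.0:
        q = 1.0 - p
        f = q**n
        u = _uniform(s)
        k = 0
        cdf = f
        while u > cdf and k < n:
            k += 1
            f *= (n - k + 1) / k * (p / q)
            cdf += f
    else:
        q = 1.0 - p
        spq = math.sqrt(mean * q)
        b = 1.15 + 2.53 * spq
        a = -0.0873 + 0.0248 * b + 0.01 * p
        c = mean + 0.5
        v_r = 0.92 - 4.2 / b
        while True:
            u = _uniform(s) - 0.5
            v = _uniform(s)
            us = 0.5 - abs(u)
            k = int(math.floor((2.0 * a / us + b) * u + c))
            if us >= 0.07 and v <= v_r:
                if 0 <= k <= n:
                    break
                continue
            if k < 0 or k > n:
                continue
            # deferred setup; this branch is hit for ~1 in 7 draws
            lpq = math.log(p / q)
            m = math.floor((n + 1) * p)
            h = math.lgamma(m + 1.0) + math.lgamma(n - m + 1.0)
            alpha = (2.83 + 5.1 / b) * spq
            lv = math.log(v * alpha / (a / (us * us) + b))
            if lv <= h - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0) + (k - m) * lpq:
                break
    return n - k if flip else k


@njit(inline="always")
def _neg_log1m(p):
    # -log(1 - p); 3-term series below 0.01 (abs error < 3e-11)
    if p < 0.01:
        return p * (1.0 + p * (0.5 + p / 3.0))
    return -math.log1p(-p)


@njit(cache=True)
def wf_trajectory(n_gen, two_n, w_der_hom, w_anc_hom, max_rejects, seed):
    """Forward Wright-Fisher path of a derived allele under overdominance.

    Starts from a single copy ``n_gen`` generations before the present and
    runs to the present: deterministic selection update then binomial
    resampling of ``two_n`` copies each generation (heterozygote fitness 1).
    Paths that are lost or fixed are rejected and restarted.

    Returns ``(freqs, cum_hazard_der, cum_hazard_anc, n_rejected)`` where
    ``freqs[i]`` is the derived-allele frequency ``i`` generations before
    the present (``freqs[n_gen]`` is the single-copy origin) and the cum
    arrays hold ``sum_{tau<=t} -log(1 - 1/(two_n*x_tau))`` per allelic
    class.  ``n_rejected`` is -1 if ``max_rejects`` restarts were exhausted.
    """
    s = _seed_state(seed)
    inv_two_n = 1.0 / two_n
    cap = 1.0 - 1e-12
    freqs = np.empty(n_gen + 1)
    cum_d = np.zeros(n_gen + 1)
    cum_a = np.zeros(n_gen + 1)
    rejects = 0
    while rejects <= max_rejects:
        # forward pass fills freqs; the hazards (indexed by generations
        # before present) are accumulated backward afterwards from the
        # same array, over surviving paths only
        p = 1.0 / two_n
        freqs[n_gen] = p
        ok = True
        for g in range(n_gen - 1, -1, -1):
            q = 1.0 - p
            wbar = p * p * w_der_hom + 2.0 * p * q + q * q * w_anc_hom
            p_sel = p * (p * w_der_hom + q) / wbar
            k = _binomial(two_n, p_sel, s)
            if k == 0 or k == two_n:
                ok = False
                rejects += 1
                break
            p = k * inv_two_n
            freqs[g] = p
        if ok:
            acc_d = 0.0
            acc_a = 0.0
            for t in range(1, n_gen + 1):
                x = freqs[t]
                pd = inv_two_n / x
                pa = inv_two_n / (1.0 - x)
                acc_d += _neg_log1m(pd if pd < cap else cap)
                acc_a += _neg_log1m(pa if pa < cap else cap)
                cum_d[t] = acc_d
                cum_a[t] = acc_a
            return freqs, cum_d, cum_a, rejects
    return freqs, cum_d, cum_a, -1


@njit(cache=True)
def binomial_draws(niter, n, p, seed):
    """Vector of BTRS/inversion binomial draws (for distributional tests)."""
    s = _seed_state(seed)
    out = np.empty(niter, np.int64)
    for i in range(niter):
        out[i] = _binomial(n, p, s)
    return out
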