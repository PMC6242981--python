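"""Structured coalescent conditional on a trajectory, and mutation dropping."""

import io

import numpy as np
import pytest

from seedcracker.coalescent import (
    SampleConfig,
    drop_mutations,
    simulate_genealogy,
    simulate_sample,
    write_ms,
)
from seedcracker.sumstats import dxy, nucleotide_diversity, summary_stats
from seedcracker.trajectory import TrajectoryParams, simulate_trajectory


def _kingman(config, N_sim, seed):
    g = simulate_genealogy(None, config, seed=seed, N_sim=N_sim)
    g.N_sim = N_sim
    return g


def _derived_mrca(genealogy):
    below = genealogy.leaf_sets()
    der = genealogy.leaf_is_derived
    candidates = [i for i in range(genealogy.n_nodes) if below[i][der].all()]
    return min(candidates, key=lambda i: below[i].sum()), below


class TestGenealogy:
    def test_pairwise_coalescence_time_matches_kingman(self):
        """n=2, no derived class: E[T2] = 2*N_sim generations."""
        N = 2000
        cfg = SampleConfig(n_anc=2, n_der=0, L=100, theta=0.001)
        t2 = np.array([_kingman(cfg, N, s).times[-1] for s in range(3000)])
        se = t2.std(ddof=1) / np.sqrt(len(t2))
        assert abs(t2.mean() - 2 * N) < 3 * se

    def test_two_derived_forced_to_coalesce_by_origin(self):
        """A tiny T_age forces the derived pair to merge at/before origin."""
        traj = simulate_trajectory(TrajectoryParams(500, 0.5, 0.01), N_sim=500, seed=0)
        cfg = SampleConfig(n_anc=2, n_der=2, L=100, theta=0.001)
        for s in range(50):
            g = simulate_genealogy(traj, cfg, seed=s)
            mrca, below = _derived_mrca(g)
            assert g.times[mrca] <= traj.origin_generation
            assert not below[mrca][~g.leaf_is_derived].any()

    def test_all_derived_tree_capped_by_origin(self):
        """With no ancestral leaves the root is the forced origin merge."""
        traj = simulate_trajectory(TrajectoryParams(500, 0.5, 0.05), N_sim=500, seed=1)
        cfg = SampleConfig(n_anc=0, n_der=5, L=100, theta=0.001)
        for s in range(20):
            g = simulate_genealogy(traj, cfg, seed=s)
            assert g.times[g.root] <= traj.origin_generation

    def test_derived_class_monophyly(self):
        """Derived leaves always form a clade closing by the origin."""
        traj = simulate_trajectory(TrajectoryParams(300, 0.4, 1.0), N_sim=1000, seed=2)
        cfg = SampleConfig(n_anc=6, n_der=5, L=100, theta=0.001)
        for s in range(50):
            g = simulate_genealogy(traj, cfg, seed=s)
            assert g.n_leaves == 11
            mrca, below = _derived_mrca(g)
            assert not below[mrca][~g.leaf_is_derived].any()
            assert g.times[mrca] <= traj.origin_generation

    def test_requires_trajectory_with_derived_lineages(self):
        cfg = SampleConfig(n_anc=2, n_der=2, L=100, theta=0.001)
        with pytest.raises(ValueError, match="trajectory"):
            simulate_genealogy(None, cfg, seed=0, N_sim=1000)

    def test_newick_is_parseable(self):
        import dendropy

        traj = simulate_trajectory(TrajectoryParams(300, 0.4, 0.5), N_sim=500, seed=3)
        g = simulate_genealogy(traj, SampleConfig(3, 2, 100, 0.001), seed=4)
        tree = dendropy.Tree.get(data=g.newick(), schema="newick")
        assert len(tree.leaf_nodes()) == 5


class TestMutations:
    def test_tiny_theta_yields_no_sites(self):
        cfg = SampleConfig(n_anc=4, n_der=0, L=100, theta=1e-12)
        g = _kingman(cfg, 1000, 5)
        assert drop_mutations(g, cfg, seed=5).n_sites == 0

    def test_every_site_polymorphic_positions_unique(self):
        traj = simulate_trajectory(TrajectoryParams(300, 0.5, 1.0), N_sim=1000, seed=6)
        cfg = SampleConfig(n_anc=5, n_der=5, L=5000, theta=0.01)
        smp = simulate_sample(TrajectoryParams(300, 0.5, 1.0), cfg, N_sim=1000, seed=6)
        counts = smp.matrix.sum(axis=0)
        assert np.all((counts > 0) & (counts < smp.n_haplotypes))
        assert len(np.unique(smp.positions)) == smp.n_sites
        assert smp.positions.min() >= 1 and smp.positions.max() <= cfg.L

    def test_mean_pairwise_diversity_equals_locus_theta(self):
        """n=2 Kingman: E[pi_locus] = theta*L (here 5), within 3 SE."""
        cfg = SampleConfig(n_anc=2, n_der=0, L=1000, theta=0.005)
        pis = []
        for s in range(1500):
            g = _kingman(cfg, 2000, s)
            smp = drop_mutations(g, cfg, seed=s)
            pis.append(nucleotide_diversity(smp.matrix, cfg.L) * cfg.L)
        pis = np.array(pis)
        se = pis.std(ddof=1) / np.sqrt(len(pis))
        assert abs(pis.mean() - 5.0) < 3 * se

    def test_site_frequency_spectrum_neutral(self):
        """Kingman limit: E[xi_i] = theta_locus / i for n = 6."""
        n, theta_locus, reps = 6, 4.0, 3000
        cfg = SampleConfig(n_anc=n, n_der=0, L=1000, theta=theta_locus / 1000)
        sfs = np.zeros(n - 1)
        for s in range(reps):
            g = _kingman(cfg, 1000, s)
            smp = drop_mutations(g, cfg, seed=s)
            if smp.n_sites:
                counts = smp.matrix.sum(axis=0)
                sfs += np.bincount(counts, minlength=n)[1:n]
        sfs /= reps
        expected = theta_locus / np.arange(1, n)
        # generous per-class tolerance; singletons dominate the counts
        assert np.all(np.abs(sfs - expected) / expected < 0.1)


class TestSimulateSample:
    def test_seeded_determinism(self):
        p = TrajectoryParams(300, 0.4, 1.5)
        cfg = SampleConfig(n_anc=6, n_der=4, L=10_000, theta=0.002)
        a = simulate_sample(p, cfg, N_sim=2000, seed=42)
        b = simulate_sample(p, cfg, N_sim=2000, seed=42)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.positions, b.positions)

    def test_young_derived_class_less_diverse(self):
        """pi_der < pi_anc in expectation for a young balanced haplotype."""
        p = TrajectoryParams(1000, 0.5, 0.5)
        cfg = SampleConfig(n_anc=6, n_der=6, L=20_000, theta=0.002)
        pa, pd = [], []
        for s in range(300):
            smp = simulate_sample(p, cfg, N_sim=1000, seed=s)
            ss = summary_stats(smp)
            pa.append(ss.pi_anc)
            pd.append(ss.pi_der)
        assert np.mean(pd) < np.mean(pa)

    def test_between_class_divergence_grows_with_age(self):
        """Mean d_xy is non-decreasing in T_age (0.5, 2, 5)."""
        cfg = SampleConfig(n_anc=4, n_der=4, L=20_000, theta=0.002)
        means = []
        for T in (0.5, 2.0, 5.0):
            vals = [
                summary_stats(
                    simulate_sample(
                        TrajectoryParams(500, 0.5, T), cfg, N_sim=1000, seed=s
                    )
                ).d_xy
                for s in range(200)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_rescaling_invariance(self):
        """Identical (S, f_eq, T_age, theta) at N_sim 2000 vs 8000 agree."""
        p = TrajectoryParams(400, 0.5, 1.0)
        cfg = SampleConfig(n_anc=5, n_der=5, L=10_000, theta=0.003)

        def mean_stats(N, reps=250):
            arr = np.array(
                [
                    summary_stats(
                        simulate_sample(p, cfg, N_sim=N, seed=s)
                    ).as_array()
                    for s in range(reps)
                ]
            )
            return arr.mean(axis=0), arr.std(axis=0, ddof=1) / np.sqrt(len(arr))

        m_small, se_small = mean_stats(2000)
        m_big, se_big = mean_stats(8000)
        se = np.sqrt(se_small**2 + se_big**2)
        assert np.all(np.abs(m_small - m_big) < 4 * se)


def test_matches_independent_coalescent_simulator():
    """Kingman-limit integration oracle against msprime at equal parameters."""
    import msprime

    N, n, L, theta = 2000, 8, 1000, 0.004
    cfg = SampleConfig(n_anc=n, n_der=0, L=L, theta=theta)
    mine = []
    for s in range(800):
        g = _kingman(cfg, N, s)
        smp = drop_mutations(g, cfg, seed=s)
        mine.append(nucleotide_diversity(smp.matrix, L) * L)
    ref = []
    mu = theta / (4 * N)
    for i, ts in enumerate(
        msprime.sim_ancestry(
            samples=n // 2,  # diploid samples -> n haploid lineages
            ploidy=2,
            population_size=N,
            sequence_length=1,
            num_replicates=400,
            random_seed=99,
        )
    ):
        mts = msprime.sim_mutations(
            ts, rate=mu * L, random_seed=7 + i, discrete_genome=False
        )
        # per-unit-length diversity on a length-1 genome = locus diversity
        ref.append(mts.diversity(mode="site"))
    mine, ref = np.array(mine), np.array(ref)
    se = np.sqrt(mine.var(ddof=1) / len(mine) + ref.var(ddof=1) / len(ref))
    assert abs(mine.mean() - ref.mean()) < 3.5 * se


def test_ms_output_format():
    p = TrajectoryParams(300, 0.4, 0.5)
    cfg = SampleConfig(n_anc=3, n_der=2, L=1000, theta=0.01)
    smp = simulate_sample(p, cfg, N_sim=500, seed=8)
    buf = io.StringIO()
    write_ms(smp, buf)
    lines = buf.getvalue().splitlines()
    assert lines[0].startswith("# classes:")
    assert lines[1] == "//"
    assert lines[2] == f"segsites: {smp.n_sites}"
    assert lines[3].startswith("positions:")
    assert len(lines) == 4 + smp.n_haplotypes
    assert set(lines[4]) <= {"0", "1"}
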