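"""The synthetic-data generator: truth labels, invariants, round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedcracker import io as scio
from seedcracker.regions import Region
from seedcracker.simdata import (
    generate_cohort,
    generate_gene_annotation,
    generate_haplotype_panel,
    generate_pool_af,
)
from seedcracker.sumstats import mismatch_matrix


class TestHaplotypePanel:
    def test_full_divergence_founders_disagree_everywhere(self):
        panel = generate_haplotype_panel(2, 2, L=200, divergence=1.0, intra_diversity=0.0, seed=0)
        mm = mismatch_matrix(panel.haplotypes)
        anc, der = panel.rows_of("anc"), panel.rows_of("der")
        assert mm[anc[0], der[0]] == 1.0

    def test_zero_divergence_zero_diversity_all_identical(self):
        panel = generate_haplotype_panel(3, 3, L=50, divergence=0.0, intra_diversity=0.0, seed=1)
        assert np.all(mismatch_matrix(panel.haplotypes) == 0.0)

    def test_half_divergence_exact_site_count(self):
        panel = generate_haplotype_panel(1, 1, L=10, divergence=0.5, intra_diversity=0.0, seed=2)
        a = panel.haplotypes[panel.rows_of("anc")[0]]
        d = panel.haplotypes[panel.rows_of("der")[0]]
        assert (a != d).sum() == 5
        again = generate_haplotype_panel(1, 1, L=10, divergence=0.5, intra_diversity=0.0, seed=2)
        assert np.array_equal(panel.haplotypes, again.haplotypes)

    def test_recombinants_are_single_breakpoint_mosaics(self, panel):
        for row, bp in panel.breakpoints.items():
            rec = panel.haplotypes[row]
            anc = panel.haplotypes[panel.rows_of("anc")]
            der = panel.haplotypes[panel.rows_of("der")]
            left_anc = any(np.array_equal(rec[:bp], h[:bp]) for h in anc)
            left_der = any(np.array_equal(rec[:bp], h[:bp]) for h in der)
            right_anc = any(np.array_equal(rec[bp:], h[bp:]) for h in anc)
            right_der = any(np.array_equal(rec[bp:], h[bp:]) for h in der)
            assert (left_anc and right_der) or (left_der and right_anc)

    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError, match="divergence"):
            generate_haplotype_panel(1, 1, L=10, divergence=1.5, intra_diversity=0.0)


class TestCohort:
    def test_counts_and_slots(self, panel):
        cohort = generate_cohort(panel, n_small=12, n_large=12, seed=3)
        assert cohort.n_individuals == 24
        assert len(cohort.table[["hap1_id", "hap2_id"]].to_numpy().ravel()) == 48

    def test_dominance_consistency(self, panel, cohort):
        """morph == small iff the individual carries zero derived haplotypes."""
        dosage = cohort.derived_dosage(panel)
        small = (cohort.table["morph"] == "small").to_numpy()
        assert np.all((dosage == 0) == small)

    def test_large_morph_has_both_het_and_hom(self, panel):
        cohort = generate_cohort(panel, n_small=2, n_large=6, seed=4)
        dosage = cohort.derived_dosage(panel)
        large = (cohort.table["morph"] == "large").to_numpy()
        assert set(dosage[large]) == {1, 2}

    def test_morph_means_at_vanishing_sd(self, panel):
        cohort = generate_cohort(
            panel,
            n_small=30,
            n_large=30,
            n_mega=30,
            morph_sd=1e-9,
            het_lmw_offset=0.0,
            seed=5,
        )
        means = cohort.table.groupby("morph")["LMW"].mean()
        assert means["small"] == pytest.approx(12.8, abs=1e-6)
        assert means["large"] == pytest.approx(16.4, abs=1e-6)
        assert means["mega"] == pytest.approx(19.6, abs=1e-6)

    def test_het_offset_lowers_heterozygote_lmw(self, panel):
        cohort = generate_cohort(
            panel, n_small=0, n_large=40, morph_sd=1e-9, het_lmw_offset=0.5, seed=6
        )
        dosage = cohort.derived_dosage(panel)
        lmw = cohort.table["LMW"].to_numpy()
        assert lmw[dosage == 1].mean() == pytest.approx(15.9, abs=1e-6)
        assert lmw[dosage == 2].mean() == pytest.approx(16.4, abs=1e-6)

    def test_byte_identical_under_seed(self, panel):
        a = generate_cohort(panel, 5, 5, 3, seed=7)
        b = generate_cohort(panel, 5, 5, 3, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert np.array_equal(a.hap1, b.hap1) and np.array_equal(a.hap2, b.hap2)

    def test_impossible_mix_raises(self):
        panel = generate_haplotype_panel(2, 0, L=20, divergence=0.5, intra_diversity=0.0, seed=8)
        with pytest.raises(ValueError, match="derived"):
            generate_cohort(panel, n_small=1, n_large=1, seed=8)


class TestPoolAF:
    def test_forced_delta_one(self, cohort, candidate_region):
        table = generate_pool_af(
            cohort, candidate_region, background_sites=50, delta_in_region=1.0, seed=9
        )
        region = table[table["kind"] == "region"]
        delta = (region["freq_small"] - region["freq_large"]).abs()
        assert np.allclose(delta, 1.0)

    def test_region_sites_pass_downstream_threshold(self, pool_table):
        region = pool_table[pool_table["kind"] == "region"]
        delta = (region["freq_small"] - region["freq_large"]).abs()
        assert np.all(delta >= 0.9)

    def test_background_delta_matches_binomial_oracle(self, cohort):
        """Mean background Δ equals E|p1-p2|, p_i ~ Bin(30, 0.5)/30, exactly
        enumerated over the 31x31 outcome grid."""
        table = generate_pool_af(
            cohort,
            None,
            background_sites=1000,
            delta_in_region=0.9,
            depth_range=(30, 30),
            background_freq=0.5,
            seed=10,
        )
        from scipy.stats import binom

        k = np.arange(31)
        pmf = binom.pmf(k, 30, 0.5)
        diff = np.abs(k[:, None] - k[None, :]) / 30
        expected = (pmf[:, None] * pmf[None, :] * diff).sum()
        delta = (table["freq_small"] - table["freq_large"]).abs()
        se = delta.std(ddof=1) / np.sqrt(len(delta))
        assert abs(delta.mean() - expected) < 3 * se

    def test_bounds_and_depths(self, pool_table):
        for pool in ("small", "large", "mega"):
            assert pool_table[f"freq_{pool}"].between(0, 1).all()
            assert pool_table[f"depth_{pool}"].between(10, 40).all()
        assert pool_table["pos"].is_unique

    def test_positions_sorted_within_chrom(self, pool_table):
        assert pool_table["pos"].is_monotonic_increasing

    def test_empty_cohort_rejected(self, panel):
        empty = generate_cohort(panel, 0, 0, 0, seed=11)
        with pytest.raises(ValueError, match="empty"):
            generate_pool_af(empty, None, 10, 0.9, seed=11)


class TestGeneAnnotation:
    def test_empty_annotation(self):
        ann = generate_gene_annotation(1000, 0, (10, 20), seed=12)
        assert len(ann) == 0

    def test_fixed_length_genes(self):
        ann = generate_gene_annotation(10_000, 2, (1000, 1000), seed=13)
        assert list(ann["end"] - ann["start"]) == [1000, 1000]

    def test_non_overlapping_and_within_bounds(self, gene_annotation):
        ann = gene_annotation.sort_values("start")
        assert (ann["end"] > ann["start"]).all()
        assert (ann["start"].iloc[1:].to_numpy() >= ann["end"].iloc[:-1].to_numpy()).all()
        assert ann["start"].min() >= 0 and ann["end"].max() <= 1_000_000

    def test_infeasible_packing(self):
        with pytest.raises(ValueError, match="pack"):
            generate_gene_annotation(1000, 5, (300, 300), seed=14)

    def test_reproducible(self):
        a = generate_gene_annotation(50_000, 5, (100, 5000), seed=15)
        b = generate_gene_annotation(50_000, 5, (100, 5000), seed=15)
        pd.testing.assert_frame_equal(a, b)


class TestRoundTrips:
    def test_cohort_vcf_and_tsv(self, cohort, tmp_path):
        vcf, tsv = tmp_path / "c.vcf", tmp_path / "c.tsv"
        scio.write_cohort(cohort, vcf, tsv)
        back = scio.read_cohort(vcf, tsv)
        assert np.array_equal(back.hap1, cohort.hap1)
        assert np.array_equal(back.hap2, cohort.hap2)
        assert np.array_equal(back.positions, cohort.positions)
        assert back.chrom == cohort.chrom
        pd.testing.assert_frame_equal(back.table, cohort.table)

    def test_pool_tsv(self, pool_table, tmp_path):
        path = tmp_path / "pool.tsv"
        scio.write_pool_tsv(pool_table, path)
        back = scio.read_pool_tsv(path)
        pd.testing.assert_frame_equal(back, pool_table)

    def test_genes_bed(self, gene_annotation, tmp_path):
        path = tmp_path / "genes.bed"
        scio.write_genes_bed(gene_annotation, path)
        back = scio.read_genes_bed(path)
        pd.testing.assert_frame_equal(back, gene_annotation)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(
    n_anc=st.integers(1, 5),
    n_der=st.integers(1, 5),
    L=st.integers(1, 60),
    divergence=st.floats(0, 1),
    seed=st.integers(0, 1000),
)
def test_panel_founder_divergence_matches_ceil(n_anc, n_der, L, divergence, seed):
    panel = generate_haplotype_panel(
        n_anc, n_der, L=L, divergence=divergence, intra_diversity=0.0, seed=seed
    )
    a = panel.haplotypes[panel.rows_of("anc")[0]]
    d = panel.haplotypes[panel.rows_of("der")[0]]
    assert (a != d).sum() == int(np.ceil(divergence * L))
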