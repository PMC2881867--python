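import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stemprofiler import (
    ExpressionMatrix,
    GeneSet,
    SyntheticConfig,
    build_reference_profile,
    compare_universes,
    generate_cohort,
    heterogeneity_profile,
    pairwise_similarity,
    score_samples,
    universe_permutation_test,
)

from conftest import pearson_oracle


def _matrix(arr, probes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"P{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(arr, index=probes, columns=samples))


class TestPairwiseSimilarity:
    def test_duplicated_samples_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(1, 10, size=30)
        m = _matrix(np.column_stack([col, col, rng.uniform(1, 10, 30)]))
        psm = pairwise_similarity(m, ["S0", "S1", "S2"])
        assert psm.values.loc["S0", "S1"] == pytest.approx(1.0, abs=1e-12)

    def test_pair_count_is_k_choose_2(self, random_matrix):
        psm = pairwise_similarity(random_matrix, ["S0", "S1", "S2"])
        assert len(psm.upper_triangle()) == 3

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(1, 100, size=(100, 5))
        m = _matrix(arr)
        psm = pairwise_similarity(m, list(m.sample_ids))
        for i in range(5):
            for j in range(i + 1, 5):
                expected = pearson_oracle(arr[:, i], arr[:, j])
                assert psm.values.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self, random_matrix):
        psm = pairwise_similarity(random_matrix, list(random_matrix.sample_ids))
        v = psm.values.to_numpy()
        assert np.array_equal(v, v.T)
        assert np.all(np.diag(v) == 1.0)

    def test_universe_restriction(self, random_matrix):
        gs = GeneSet("u", "", frozenset(list(random_matrix.probe_ids[:10])))
        psm = pairwise_similarity(random_matrix, ["S0", "S1"], universe=gs)
        sub = random_matrix.values.iloc[:10]
        expected = pearson_oracle(sub["S0"], sub["S1"])
        assert psm.values.loc["S0", "S1"] == pytest.approx(expected, abs=1e-12)
        assert psm.universe_label == "u"

    def test_degenerate_sample_flagged_not_fatal(self, caplog):
        arr = np.column_stack([np.full(10, 3.0), np.arange(10.0),
                               np.arange(10.0) ** 2])
        m = _matrix(arr)
        with caplog.at_level("WARNING"):
            psm = pairwise_similarity(m, ["S0", "S1", "S2"])
        assert np.isnan(psm.values.loc["S0", "S1"])
        coeffs = psm.upper_triangle()
        assert len(coeffs) == 1  # only the S1-S2 pair survives


class TestCompareUniverses:
    def test_identical_lists_no_difference(self):
        rep = compare_universes([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert rep["F"] == 0.0 and rep["p_value"] == 1.0

    def test_hand_computed_anova_on_degenerate_lists(self):
        # {0.9,0.9,0.9} vs {0.5,0.5,0.5}: SSB=0.24, SSW=0 -> F infinite
        a, b = [0.9, 0.9, 0.9], [0.5, 0.5, 0.5]
        grand = np.mean(a + b)
        ssb = 3 * (np.mean(a) - grand) ** 2 + 3 * (np.mean(b) - grand) ** 2
        assert ssb == pytest.approx(0.24, abs=1e-12)
        rep = compare_universes(a, b)
        assert math.isinf(rep["F"]) and rep["p_value"] == 0.0
        assert rep["mean_difference"] == pytest.approx(-0.4)
        assert rep["direction"] == "subset_lower"

    def test_matches_scipy_on_random_lists(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0.8, 0.05, size=12)
            b = rng.normal(0.75, 0.08, size=9)
            rep = compare_universes(a, b)
            ref = stats.f_oneway(a, b)
            assert rep["F"] == pytest.approx(ref.statistic, rel=1e-10)
            assert rep["p_value"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_p_values_uniform(self):
        """Two draws from one distribution: ANOVA p-values should be
        uniform (KS sanity band over seeds)."""
        rng = np.random.default_rng(4)
        pvals = [compare_universes(rng.normal(0.8, 0.05, 50),
                                   rng.normal(0.8, 0.05, 50))["p_value"]
                 for _ in range(500)]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_universes([], [0.5])


class TestHeterogeneityProfile:
    @staticmethod
    def _cohort(inflation, seed, n_samples=50):
        cfg = SyntheticConfig(
            n_probes=800, n_samples=n_samples, n_reference=4, subset_size=160,
            inflation_factor=inflation, inflated_quantile=0.4, seed=seed,
        )
        m, a, t = generate_cohort(cfg)
        prof = build_reference_profile(m, t.reference_ids)
        scores = score_samples(m, prof, transform="log2")
        return m, scores, t

    def test_self_comparison_flags_nothing(self):
        m, scores, t = self._cohort(1.0, 0)
        summary = heterogeneity_profile(
            m, scores, n_groups=5,
            universes={"all_a": None, "all_b": None}, transform="log2")
        means = summary.table.pivot(index="group", columns="universe",
                                    values="mean")
        assert np.allclose(means["all_a"], means["all_b"], atol=1e-12)
        assert summary.pooled_test["p_value"] == 1.0

    def test_inflated_strata_show_subset_heterogeneity(self):
        """Variance inflation planted in the low-stemness samples must pull
        the subset-universe mean coefficient below the all-transcript mean
        in the strata holding those samples."""
        m, scores, t = self._cohort(2.0, 1)
        summary = heterogeneity_profile(m, scores, n_groups=5,
                                        subset=t.subset_gene_set(),
                                        transform="log2")
        means = summary.table.pivot(index="group", columns="universe",
                                    values="mean")
        # the two least stem-like strata hold the inflated samples
        for g in ("G01", "G02"):
            assert means.loc[g, "progenitor_differentiation"] < \
                means.loc[g, "all_transcripts"]

    def test_sample_order_invariance(self):
        m, scores, t = self._cohort(2.0, 2, n_samples=30)
        summary1 = heterogeneity_profile(m, scores, n_groups=3,
                                         subset=t.subset_gene_set(),
                                         transform="log2")
        shuffled_m = ExpressionMatrix(values=m.values.iloc[:, ::-1])
        shuffled_scores = scores.iloc[::-1].reset_index(drop=True)
        summary2 = heterogeneity_profile(shuffled_m, shuffled_scores,
                                         n_groups=3,
                                         subset=t.subset_gene_set(),
                                         transform="log2")
        assert np.allclose(summary1.table["mean"], summary2.table["mean"],
                           atol=1e-12)

    def test_sem_definition(self):
        m, scores, t = self._cohort(1.0, 3, n_samples=30)
        summary = heterogeneity_profile(m, scores, n_groups=3,
                                        subset=t.subset_gene_set(),
                                        transform="log2")
        for (group, universe), coeffs in summary.coefficients.items():
            row = summary.table[(summary.table["group"] == group) &
                                (summary.table["universe"] == universe)]
            k = row["n_samples"].iloc[0]
            assert row["n_pairs"].iloc[0] == k * (k - 1) // 2
            assert row["sem"].iloc[0] == pytest.approx(
                coeffs.std(ddof=1) / math.sqrt(len(coeffs)), abs=1e-12)

    def test_singleton_stratum_rejected(self):
        m, scores, t = self._cohort(1.0, 4, n_samples=30)
        with pytest.raises(ValueError, match="fewer groups"):
            heterogeneity_profile(m, scores.head(7), n_groups=4,
                                  subset=t.subset_gene_set())

    def test_permutation_null_detects_planted_inflation(self):
        """The probe-resampling universe test flags the planted subset as
        unusually dissimilar when variance inflation is on, and stays quiet
        on a matched homogeneous cohort."""
        m, scores, t = self._cohort(2.0, 6)
        summary = heterogeneity_profile(m, scores, n_groups=5,
                                        subset=t.subset_gene_set(),
                                        transform="log2",
                                        permutation_null=True,
                                        permutation_seed=6)
        assert summary.pooled_permutation_test["p_value"] < 0.05
        assert summary.pooled_permutation_test["observed_difference"] < 0

        m0, scores0, t0 = self._cohort(1.0, 6)
        null_summary = heterogeneity_profile(m0, scores0, n_groups=5,
                                             subset=t0.subset_gene_set(),
                                             transform="log2",
                                             permutation_null=True,
                                             permutation_seed=6)
        # single-seed spot check: the homogeneous cohort must not be flagged
        # at the strict threshold (rate-level calibration over many seeds is
        # asserted in the acceptance suite)
        assert null_summary.pooled_permutation_test["p_value"] > 0.01

    def test_permutation_test_deterministic(self):
        m, scores, t = self._cohort(2.0, 7, n_samples=30)
        groups = [g for g in
                  heterogeneity_profile(m, scores, n_groups=3,
                                        subset=t.subset_gene_set(),
                                        transform="log2").group_members.values()]
        r1 = universe_permutation_test(m, groups, t.subset_gene_set(),
                                       n_resamples=99, seed=3, transform="log2")
        r2 = universe_permutation_test(m, groups, t.subset_gene_set(),
                                       n_resamples=99, seed=3, transform="log2")
        assert r1 == r2

    def test_fisher_z_changes_scale_not_direction(self):
        m, scores, t = self._cohort(2.0, 5, n_samples=30)
        raw = heterogeneity_profile(m, scores, n_groups=3,
                                    subset=t.subset_gene_set(),
                                    transform="log2")
        z = heterogeneity_profile(m, scores, n_groups=3,
                                  subset=t.subset_gene_set(),
                                  transform="log2", fisher_z=True)
        assert np.sign(raw.pooled_test["mean_difference"]) == \
            np.sign(z.pooled_test["mean_difference"])
        assert (z.table["mean"] > raw.table["mean"]).all()  # arctanh expands
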