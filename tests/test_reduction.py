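"""Three-step predictor reduction and the frequency/power check."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from pharmforest.data_io import DriverGeneSet
from pharmforest.reduction import (
    binary_variance,
    correlation_distance,
    gene_of,
    min_frequency_for_power,
    power_of_frequency,
    reduce_predictors,
    step1_driver_filter,
    step2_variance_filter,
    step3_redundancy_clusters,
)

from conftest import binary_matrix


class TestGeneOf:
    @pytest.mark.parametrize(
        "label, gene",
        [
            ("BRAF_MUT", "BRAF"),
            ("BRAF.V600E_MUT", "BRAF"),
            ("KRAS.G12_13_MUT", "KRAS"),
            ("MAP2K4_DEL", "MAP2K4"),
            ("ERBB2_AMP", "ERBB2"),
        ],
    )
    def test_gene_extraction(self, label, gene):
        assert gene_of(label) == gene

    def test_unknown_suffix_rejected(self):
        with pytest.raises(ValueError, match="unknown alteration suffix"):
            gene_of("TP53_AMPX")


class TestDriverFilter:
    def test_keeps_only_driver_genes_in_order(self):
        alt = binary_matrix(np.eye(4, 3, dtype=int), labels=["BRAF_MUT", "XYZ9_DEL", "BRAF.V600E_AMP"])
        out = step1_driver_filter(alt, DriverGeneSet(frozenset({"BRAF"})))
        assert out.alterations == ["BRAF_MUT", "BRAF.V600E_AMP"]

    def test_superset_drivers_is_identity(self, random_binary_matrix):
        alt = random_binary_matrix(p=6)
        drivers = DriverGeneSet(frozenset(gene_of(a) for a in alt.alterations))
        assert step1_driver_filter(alt, drivers).alterations == alt.alterations


class TestVarianceFilter:
    def test_threshold_arithmetic(self):
        assert binary_variance(0.05) == pytest.approx(0.0475, abs=1e-15)
        assert binary_variance(0.5) == 0.25
        assert binary_variance(0.0) == 0.0

    def test_proportion_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binary_variance(1.2)

    def test_boundary_is_kept_below_is_strict(self):
        x = np.zeros((100, 2), dtype=int)
        x[:5, 0] = 1  # p = 0.05 -> variance exactly at threshold, kept
        x[:4, 1] = 1  # p = 0.04 -> variance 0.0384 < 0.0475, removed
        out = step2_variance_filter(binary_matrix(x), min_proportion=0.05)
        assert out.alterations == ["G001_MUT"]

    @given(p=st.floats(0.0, 1.0))
    @settings(deadline=None, derandomize=True)
    def test_variance_symmetric_in_p(self, p):
        assert binary_variance(p) == pytest.approx(binary_variance(1 - p), abs=1e-12)


class TestCorrelationDistance:
    def test_identical_and_complementary_columns_have_zero_distance(self):
        a = np.array([0, 1, 1, 0, 1, 0, 0, 1])
        x = np.column_stack([a, a, 1 - a])
        d = correlation_distance(binary_matrix(x))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(0.0, abs=1e-12)  # r = -1, 1 - r^2 = 0

    def test_phi_half_gives_distance_three_quarters(self):
        # 2x2 table (a,b,c,d) = (30,10,10,30): phi = (ad-bc)/sqrt(row*col) = 0.5
        a = np.repeat([1, 1, 0, 0], [30, 10, 10, 30])
        b = np.repeat([1, 0, 1, 0], [30, 10, 10, 30])
        d = correlation_distance(binary_matrix(np.column_stack([a, b])))
        assert d[0, 1] == pytest.approx(0.75, abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant column"):
            correlation_distance(binary_matrix(np.column_stack([np.ones(6, int), np.eye(6, 1, dtype=int)])))


class TestRedundancyClusters:
    def test_duplicate_columns_collapse_to_first(self):
        a = np.array([0, 1, 1, 0, 1, 0, 1, 1])
        c = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        alt = binary_matrix(np.column_stack([a, a, c]), labels=["A_MUT", "B_MUT", "C_MUT"])
        retained, cmap = step3_redundancy_clusters(alt)
        assert retained.alterations == ["A_MUT", "C_MUT"]
        assert cmap.members(cmap.cluster_of("A_MUT")) == ["A_MUT", "B_MUT"]
        assert cmap.sizes.sum() == 3

    def test_uncorrelated_columns_stay_singletons(self, random_binary_matrix):
        alt = random_binary_matrix(n=200, p=8, seed=3)
        retained, cmap = step3_redundancy_clusters(alt)
        assert retained.alterations == alt.alterations
        assert (cmap.sizes == 1).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_matches_scipy_complete_linkage(self, seed, random_binary_matrix):
        rng = np.random.default_rng(seed)
        alt = random_binary_matrix(n=60, p=12, seed=seed)
        x = alt.values.to_numpy().copy()
        x[:, 10] = x[:, 0]  # exact duplicate
        flip = rng.random(60) < 0.02
        x[:, 11] = np.where(flip, 1 - x[:, 1], x[:, 1])  # near duplicate
        for j in range(12):
            if x[:, j].std() == 0:
                x[0, j] = 1 - x[0, j]
        alt = binary_matrix(x)
        d = correlation_distance(alt)
        _, cmap = step3_redundancy_clusters(alt, 0.95)
        oracle = fcluster(
            linkage(squareform(d, checks=False), method="complete"),
            t=1 - 0.95**2,
            criterion="distance",
        )
        mine = {frozenset(np.flatnonzero(cmap.cluster_ids == c)) for c in np.unique(cmap.cluster_ids)}
        theirs = {frozenset(np.flatnonzero(oracle == c)) for c in np.unique(oracle)}
        assert mine == theirs
        # complete-linkage guarantee: within-cluster |r| >= 0.95
        r2 = 1 - d
        for members in mine:
            for i in members:
                for j in members:
                    if i < j:
                        assert r2[i, j] >= 0.95**2 - 1e-9


class TestPipelineOrdering:
    def test_steps_never_grow_and_are_idempotent(self, random_binary_matrix):
        alt = random_binary_matrix(n=150, p=10, seed=5)
        drivers = DriverGeneSet(frozenset(gene_of(a) for a in alt.alterations[:8]))
        s1 = step1_driver_filter(alt, drivers)
        s2 = step2_variance_filter(s1)
        s3, _ = step3_redundancy_clusters(s2)
        assert alt.n_alterations >= s1.n_alterations >= s2.n_alterations >= s3.n_alterations
        assert step1_driver_filter(s1, drivers).alterations == s1.alterations
        assert step2_variance_filter(s2).alterations == s2.alterations
        assert step3_redundancy_clusters(s3)[0].alterations == s3.alterations

    def test_reduce_predictors_counts_reconcile(self, random_binary_matrix):
        alt = random_binary_matrix(n=150, p=10, seed=6)
        drivers = DriverGeneSet(frozenset(gene_of(a) for a in alt.alterations))
        res = reduce_predictors(alt, drivers)
        assert res.step1_kept - res.step2_excluded == len(res.clusters.labels)
        assert res.retained.n_alterations == res.clusters.n_clusters
        assert res.variance_threshold == pytest.approx(0.0475)
        assert res.distance_threshold == pytest.approx(0.0975)

    def test_infeasible_min_proportion_rejected(self, random_binary_matrix):
        alt = random_binary_matrix()
        drivers = DriverGeneSet(frozenset({"G001"}))
        with pytest.raises(ValueError, match="infeasible threshold"):
            reduce_predictors(alt, drivers, min_proportion=0.6)


class TestPower:
    def test_reference_values(self):
        assert power_of_frequency(0.05, 523) == pytest.approx(0.70, abs=0.02)
        assert power_of_frequency(0.065, 523) >= 0.80
        assert min_frequency_for_power(0.80, 523, 0.5, 0.05) == pytest.approx(0.065)

    def test_balanced_design_maximizes_power(self):
        powers = [power_of_frequency(f, 200) for f in (0.1, 0.25, 0.5)]
        assert powers == sorted(powers)
        grid = [power_of_frequency(f, 200) for f in np.arange(0.05, 0.96, 0.05)]
        assert max(grid) == pytest.approx(power_of_frequency(0.5, 200))

    @pytest.mark.parametrize("freq", [0.1, 0.3])
    def test_monotone_in_n_and_effect(self, freq):
        assert power_of_frequency(freq, 400) > power_of_frequency(freq, 100)
        assert power_of_frequency(freq, 200, 0.8) > power_of_frequency(freq, 200, 0.3)

    def test_target_at_balanced_power_returns_half(self):
        target = power_of_frequency(0.5, 100)
        assert min_frequency_for_power(target, 100) == pytest.approx(0.5)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            min_frequency_for_power(0.9999, 10, 0.1, 0.05)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="degenerate group"):
            power_of_frequency(0.01, 50)
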