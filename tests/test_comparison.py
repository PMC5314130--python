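"""Permutation framework, functional-density statistics and FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covnet import (DegenerateDataError, DensityGrid, InputValidationError,
                    SyntheticConfig, fda_auc, fdr_correct,
                    generate_volume_table, normalize_nodal_by_group_mean,
                    permutation_null, two_tailed_p)
from covnet.comparison import (_corr_from_values, assemble_comparisons,
                               compute_group_curves)
from covnet.construction import edge_count


class TestTwoTailedP:
    def test_position_formula(self):
        assert two_tailed_p(2.0, [-1, 0, 1, -2, 3]) == pytest.approx(0.5)

    def test_extreme_observation_hits_floor(self):
        perms = np.linspace(-1, 1, 999)
        assert two_tailed_p(5.0, perms) == pytest.approx(1 / 1000)

    def test_zero_observation_gives_one(self):
        assert two_tailed_p(0.0, [-1, 0.5, 2]) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(-10, 10), st.integers(0, 10_000))
    def test_p_always_in_unit_interval_and_never_zero(self, obs, seed):
        perms = np.random.default_rng(seed).normal(size=50)
        p = two_tailed_p(obs, perms)
        assert 0 < p <= 1

    def test_symmetric_under_sign_flip(self, rng):
        perms = rng.normal(size=200)
        assert two_tailed_p(1.3, perms) == two_tailed_p(-1.3, -perms)


class TestFdaAuc:
    def test_trapezoid_example(self):
        assert fda_auc([1, 2, 3], [0.1, 0.2, 0.3]) == pytest.approx(0.4)

    def test_constant_curve(self):
        assert fda_auc([2.5] * 5, np.linspace(0.1, 0.5, 5)) == pytest.approx(1.0)

    def test_matches_fine_riemann_resampling(self, rng):
        x = np.linspace(0.1, 0.5, 9)
        y = rng.normal(size=9)
        fine_x = np.linspace(0.1, 0.5, 40_001)
        fine_y = np.interp(fine_x, x, y)
        riemann = np.sum((fine_y[1:] + fine_y[:-1]) / 2 * np.diff(fine_x))
        assert fda_auc(y, x) == pytest.approx(riemann, abs=1e-9)

    def test_single_point_grid_rejected(self):
        with pytest.raises(InputValidationError, match="2 grid points"):
            fda_auc([1.0], [0.3])


class TestFdrCorrect:
    def test_benjamini_hochberg_by_hand(self):
        np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_correct([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(fdr_correct([1.0, 1.0]), [1.0, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(1, 30))
    def test_q_at_least_p_and_monotone(self, seed, m):
        p = np.random.default_rng(seed).uniform(0.001, 1.0, size=m)
        q = fdr_correct(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestNodalNormalization:
    def test_divides_by_network_mean(self):
        np.testing.assert_allclose(
            normalize_nodal_by_group_mean([2.0, 4.0, 6.0]), [0.5, 1.0, 1.5])

    def test_uniform_values_become_ones(self):
        np.testing.assert_allclose(
            normalize_nodal_by_group_mean([3.0, 3.0, 3.0]), [1.0, 1.0, 1.0])

    def test_scale_invariance_of_comparison(self, rng):
        deg = rng.uniform(1, 10, size=12)
        np.testing.assert_allclose(normalize_nodal_by_group_mean(deg),
                                   normalize_nodal_by_group_mean(2 * deg))

    def test_nodal_metrics_object_normalized_fieldwise(self):
        from covnet import NodalMetrics
        nm = NodalMetrics(degree=np.array([2.0, 4.0, 6.0]),
                          betweenness=np.array([1.0, 1.0, 4.0]),
                          region_names=["x", "y", "z"])
        out = normalize_nodal_by_group_mean(nm)
        np.testing.assert_allclose(out.degree, [0.5, 1.0, 1.5])
        np.testing.assert_allclose(out.betweenness, [0.5, 0.5, 2.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateDataError, match="mean"):
            normalize_nodal_by_group_mean([0.0, 0.0])


def _null_table(seed, n=16, regions=12):
    cfg = SyntheticConfig(n_regions=regions, n_subjects_a=n, n_subjects_b=n,
                          n_modules=3, rho_within_a=0.5, rho_within_b=0.5,
                          seed=seed)
    return generate_volume_table(cfg)


class TestPermutationNull:
    def test_same_seed_reproduces_distributions(self):
        table = _null_table(2)
        grid = DensityGrid.regular(0.3, 0.1, 0.5)
        d1 = permutation_null(table, grid, n_perm=25, seed=4,
                              global_metrics=("clustering",),
                              nodal_metrics=("degree",))
        d2 = permutation_null(table, grid, n_perm=25, seed=4,
                              global_metrics=("clustering",),
                              nodal_metrics=("degree",))
        np.testing.assert_array_equal(d1.global_diffs["clustering"],
                                      d2.global_diffs["clustering"])
        np.testing.assert_array_equal(d1.nodal_auc_diffs["degree"],
                                      d2.nodal_auc_diffs["degree"])

    def test_normalized_metrics_deterministic_too(self):
        table = _null_table(3)
        grid = DensityGrid.regular(0.3, 0.1, 0.5)
        kwargs = dict(n_perm=10, seed=6,
                      global_metrics=("small_worldness",), n_null_perm=2)
        d1 = permutation_null(table, grid, **kwargs)
        d2 = permutation_null(table, grid, **kwargs)
        np.testing.assert_array_equal(d1.global_auc_diffs["small_worldness"],
                                      d2.global_auc_diffs["small_worldness"])

    def test_unknown_metric_rejected(self):
        with pytest.raises(InputValidationError, match="unknown metrics"):
            permutation_null(_null_table(1), DensityGrid.regular(0.3, 0.1, 0.5),
                             n_perm=5, seed=0, global_metrics=("efficiency",))

    def test_single_point_grid_auc_equals_density_comparison(self):
        table = _null_table(5)
        grid = DensityGrid(d_min=0.4, values=(0.4,))
        dist = permutation_null(table, grid, n_perm=30, seed=9,
                                global_metrics=("clustering",),
                                nodal_metrics=("degree",))
        np.testing.assert_array_equal(dist.global_auc_diffs["clustering"],
                                      dist.global_diffs["clustering"][:, 0])
        np.testing.assert_array_equal(dist.nodal_auc_diffs["degree"],
                                      dist.nodal_diffs["degree"][:, 0, :])

    def test_assembled_results_have_valid_p_q_structure(self):
        table = _null_table(7)
        grid = DensityGrid.regular(0.3, 0.1, 0.5)
        gm, nm = ("clustering", "path_length"), ("degree",)
        e = np.array([edge_count(table.n_regions, d) for d in grid])
        curves = {
            g: compute_group_curves(_corr_from_values(table.group_values(g)),
                                    e, grid.as_array(), gm, nm)
            for g in table.groups}
        dist = permutation_null(table, grid, n_perm=40, seed=1,
                                global_metrics=gm, nodal_metrics=nm)
        results = assemble_comparisons(curves["A"], curves["B"], dist,
                                       region_names=table.region_names)
        glob = [r for r in results if r.node is None]
        nodal = [r for r in results if r.node is not None]
        assert {r.metric_name for r in glob} == set(gm)
        assert len(nodal) == table.n_regions
        for r in results:
            assert 0 < r.p_auc <= 1
            assert r.q_auc >= r.p_auc - 1e-12
            assert np.all((r.p_per_density > 0) & (r.p_per_density <= 1))

    def test_null_data_p_values_roughly_uniform(self):
        # under exchangeability the AUC p-value should not pile up at the
        # extremes; a coarse Kolmogorov-Smirnov-style band on 60 replicates
        ps = []
        grid = DensityGrid.regular(0.2, 0.1, 0.5)
        for seed in range(60):
            table = _null_table(100 + seed)
            e = np.array([edge_count(table.n_regions, d) for d in grid])
            curves = {
                g: compute_group_curves(
                    _corr_from_values(table.group_values(g)), e,
                    grid.as_array(), ("clustering",))
                for g in table.groups}
            dist = permutation_null(table, grid, n_perm=99, seed=seed,
                                    global_metrics=("clustering",))
            res = assemble_comparisons(curves["A"], curves["B"], dist)
            ps.append(res[0].p_auc)
        ps = np.asarray(ps)
        grid_pts = np.linspace(0.1, 0.9, 9)
        ecdf = np.array([(ps <= t).mean() for t in grid_pts])
        assert np.max(np.abs(ecdf - grid_pts)) < 0.25
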