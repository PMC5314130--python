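"""Association matrices, density thresholding and the connectivity sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covnet import (AssociationMatrix, DegenerateDataError, DensityGrid,
                    InputValidationError, SubjectVolumeTable,
                    compute_association_matrix, density_sweep,
                    min_connected_density, threshold_to_density)
from covnet.construction import (adjacency_stack, edge_count, is_connected,
                                 pair_order)

from .oracles import pearson_two_pass


def _table(values, groups):
    values = np.asarray(values, dtype=float)
    return SubjectVolumeTable(
        values=values,
        subject_ids=[f"s{i}" for i in range(values.shape[0])],
        region_names=[f"r{i}" for i in range(values.shape[1])],
        group_labels=np.asarray(groups))


def _assoc(r, label="A"):
    r = np.asarray(r, dtype=float)
    return AssociationMatrix(r=r, region_names=[f"r{i}" for i in range(len(r))],
                             group_label=label, n_subjects=10)


class TestAssociationMatrix:
    def test_perfect_linear_dependence(self):
        # region 1 = 2 * region 0, region 2 = reversed region 0
        values = np.column_stack([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1],
                                  [1, 3, 2, 4]])
        table = _table(np.vstack([values, values + 0.01]),
                       ["A"] * 4 + ["B"] * 4)
        r = compute_association_matrix(table, "A").r
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        # hand computation: cov=4, sd^2=5 each -> r = 4/5
        assert r[0, 3] == pytest.approx(0.8)

    def test_agrees_with_two_pass_oracle(self, rng):
        values = rng.normal(size=(25, 8))
        table = _table(values, ["A"] * 13 + ["B"] * 12)
        r = compute_association_matrix(table, "A").r
        sub = values[:13]
        for i in range(8):
            for j in range(i + 1, 8):
                assert r[i, j] == pytest.approx(
                    pearson_two_pass(sub[:, i], sub[:, j]), abs=1e-12)

    def test_diagonal_stored_as_zero_and_symmetric(self, default_assoc):
        assert np.all(np.diag(default_assoc.r) == 0)
        assert np.array_equal(default_assoc.r, default_assoc.r.T)
        assert np.all(np.abs(default_assoc.r) <= 1)

    def test_constant_region_names_the_region(self, rng):
        values = rng.normal(size=(10, 4))
        values[:5, 2] = 7.0   # constant within group A
        with pytest.raises(Exception, match="r2"):
            table = _table(values, ["A"] * 5 + ["B"] * 5)
            compute_association_matrix(table, "A")

    def test_unknown_group_rejected(self, default_table):
        with pytest.raises(InputValidationError, match="unknown group"):
            compute_association_matrix(default_table, "C")


class TestThresholdToDensity:
    def test_top_three_of_six_pairs_kept(self):
        r = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.3,
                (1, 2): 0.7, (1, 3): 0.2, (2, 3): 0.1}
        for (i, j), v in vals.items():
            r[i, j] = r[j, i] = v
        g = threshold_to_density(_assoc(r), 0.5)
        assert g.n_edges == 3
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4)
                if g.adjacency[i, j]}
        assert kept == {(0, 1), (0, 2), (1, 2)}

    def test_density_one_gives_connected_complete_graph(self):
        r = np.abs(np.random.default_rng(0).normal(size=(5, 5)))
        r = (r + r.T) / 10
        np.fill_diagonal(r, 0)
        g = threshold_to_density(_assoc(r), 1.0)
        assert g.n_edges == 10
        assert g.connected

    def test_rounding_convention_at_92_nodes(self):
        # round-half-away-from-zero: 0.36 * 4186 = 1506.96 -> 1507
        assert edge_count(92, 0.36) == 1507
        assert edge_count(92, 0.50) == 2093

    def test_zero_edge_density_rejected(self):
        r = np.eye(4) * 0
        with pytest.raises(DegenerateDataError, match="too low"):
            threshold_to_density(_assoc(r), 0.01)

    def test_ties_broken_by_node_index_order(self):
        r = np.full((4, 4), 0.5)
        np.fill_diagonal(r, 0)
        g = threshold_to_density(_assoc(r), 0.5)
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4)
                if g.adjacency[i, j]}
        assert kept == {(0, 1), (0, 2), (0, 3)}

    def test_monotone_transform_invariance(self, default_assoc, standard_grid):
        # thresholding depends only on the ordering of off-diagonal values
        transformed = _assoc(np.tanh(2.0 * default_assoc.r))
        for d in (0.1, 0.3, 0.5):
            g1 = threshold_to_density(default_assoc, d)
            g2 = threshold_to_density(transformed, d)
            assert np.array_equal(g1.adjacency, g2.adjacency)


class TestDensitySweep:
    def test_edge_sets_nested_across_grid(self, default_assoc):
        grid = DensityGrid.regular(0.1, 0.1, 0.5)
        graphs = density_sweep(default_assoc, grid)
        for lo, hi in zip(graphs, graphs[1:]):
            assert np.all(lo.adjacency <= hi.adjacency)

    def test_single_density_grid(self, default_assoc):
        graphs = density_sweep(default_assoc, DensityGrid(d_min=0.3, values=(0.3,)))
        assert len(graphs) == 1

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_nestedness_holds_for_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-1, 1, size=(10, 10))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        e = np.array([edge_count(10, d) for d in (0.1, 0.25, 0.5, 0.9)])
        stack = adjacency_stack(r, e)
        for lo, hi in zip(stack, stack[1:]):
            assert np.all(lo <= hi)
        # stack agrees with one-at-a-time thresholding
        g = threshold_to_density(_assoc(r), 0.5)
        assert np.array_equal(stack[2], g.adjacency.astype(bool))


class TestMinConnectedDensity:
    def test_matches_brute_force_first_connected_grid_point(self, default_table,
                                                            standard_grid):
        a = compute_association_matrix(default_table, "A")
        b = compute_association_matrix(default_table, "B")
        d = min_connected_density(a, b, standard_grid)
        expected = next(
            dd for dd in standard_grid.values
            if is_connected(threshold_to_density(a, dd).adjacency)
            and is_connected(threshold_to_density(b, dd).adjacency))
        assert d == expected
        # strictly below, at least one group is fragmented
        below = [dd for dd in standard_grid.values if dd < d]
        if below:
            assert (not threshold_to_density(a, below[-1]).connected
                    or not threshold_to_density(b, below[-1]).connected)

    def test_block_diagonal_matrices_never_connect(self):
        # two 4-node blocks, zero correlation across: with E capped at the
        # within-block pair count the graph cannot bridge the blocks
        r = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        r[i, j] = 0.9
        assoc = _assoc(r)
        grid = DensityGrid.regular(0.02, 0.02, 0.42)  # E <= 12 of 28 pairs
        with pytest.raises(DegenerateDataError, match="largest components"):
            min_connected_density(assoc, assoc, grid)

    def test_complete_positive_matrix_connects_at_spanning_density(self):
        r = np.full((4, 4), 0.0)
        r[0, :] = r[:, 0] = 0.9    # star-like top correlations
        np.fill_diagonal(r, 0)
        assoc = _assoc(r)
        grid = DensityGrid.regular(0.1, 0.1, 1.0)
        d = min_connected_density(assoc, assoc, grid)
        assert edge_count(4, d) >= 3   # needs at least a spanning tree
        assert threshold_to_density(assoc, d).connected
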