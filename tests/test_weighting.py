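import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemfuse import apply_weights, build_quadrant_grid, quadrant_weight
from chemfuse.embedding import Embedding2D
from chemfuse.errors import ConfigurationError


def _emb(coords, rep="toy"):
    coords = np.asarray(coords, dtype=float)
    return Embedding2D(rep, coords, "tsne", {}, [f"m{i}" for i in range(len(coords))])


class TestQuadrantWeight:
    @pytest.mark.parametrize("a,na,n", [(0, 0, 5), (3, 3, 10), (7, 7, 30)])
    def test_balanced_counts_give_zero(self, a, na, n):
        assert quadrant_weight(a, na, n) == 0.0

    def test_boundary_values(self):
        assert quadrant_weight(8, 0, 8) == 50.0
        assert quadrant_weight(0, 8, 8) == -50.0

    def test_direct_arithmetic(self):
        assert quadrant_weight(10, 30, 400) == pytest.approx(-2.5)

    def test_literal_formula_option(self):
        # -(A*100)/n + (NA*100/n)/2
        assert quadrant_weight(10, 30, 400, formula="literal") == pytest.approx(
            -10 * 100 / 400 + (30 * 100 / 400) / 2
        )

    def test_invalid_counts_and_formula(self):
        with pytest.raises(ValueError):
            quadrant_weight(1, 0, 0)
        with pytest.raises(ValueError):
            quadrant_weight(5, 6, 10)
        with pytest.raises(ConfigurationError):
            quadrant_weight(1, 1, 2, formula="other")

    def test_exhaustive_closed_form_and_bounds(self):
        # every (A, NA, n) with n <= 30: match closed form, |QW| <= 50, QW(A=NA)=0
        for n in range(1, 31):
            for a in range(n + 1):
                for na in range(n - a + 1):
                    qw = quadrant_weight(a, na, n)
                    assert qw == ((a - na) * 100 / n) / 2
                    assert abs(qw) <= 50
                    if a == na:
                        assert qw == 0

    @given(st.integers(1, 1000), st.data())
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_counts(self, n, data):
        a = data.draw(st.integers(0, n - 1))
        na = data.draw(st.integers(0, n - 1 - a))
        base = quadrant_weight(a, na, n)
        assert quadrant_weight(a + 1, na, n) > base
        if a + na + 1 <= n:
            assert quadrant_weight(a, na + 1, n) < base


class TestBuildQuadrantGrid:
    def test_equal_thirds_of_positive_bounding_box(self):
        coords = [[0.0, 0.0], [3.0, 3.0], [1.5, 2.0], [9.0, -4.0]]
        labels = [True, True, True, False]
        grid = build_quadrant_grid(_emb(coords), labels)
        np.testing.assert_allclose(grid.x_edges, [0, 1, 2, 3])
        np.testing.assert_allclose(grid.y_edges, [0, 1, 2, 3])

    def test_outside_compounds_are_clamped_to_outer_cells(self):
        coords = [[0.0, 0.0], [3.0, 3.0], [-5.0, 1.0]]
        grid = build_quadrant_grid(_emb(coords), [True, True, False])
        row, col = grid.assign(np.array([[-5.0, 1.0]]))
        assert (row[0], col[0]) == (1, 0)

    def test_four_compound_cell_counts_and_qw(self):
        # 2 positives in one cell, 2 negatives in another, n=4 -> +/-25
        # coincident positives degenerate the box, so the grid falls back to
        # the full-dataset range and the negatives land in the far corner cell
        coords = [[0.1, 0.1], [0.1, 0.1], [2.9, 2.9], [2.8, 2.8]]
        labels = [True, True, False, False]
        grid = build_quadrant_grid(_emb(coords), labels)
        assert grid.cell_qw[0, 0] == 25.0
        assert grid.cell_qw[2, 2] == -25.0
        zero_cells = grid.cell_qw == 0
        assert zero_cells.sum() == 7

    def test_count_conservation(self, rng):
        coords = rng.normal(size=(200, 2))
        labels = rng.random(200) < 0.4
        grid = build_quadrant_grid(_emb(coords), labels)
        assert grid.cell_A.sum() == labels.sum()
        assert grid.cell_NA.sum() == (~labels).sum()
        assert grid.cell_A.sum() + grid.cell_NA.sum() == grid.n_total

    def test_degenerate_positive_axis_falls_back_to_dataset_range(self, caplog):
        coords = [[1.0, -2.0], [1.0, 3.0], [0.0, 0.0], [5.0, 1.0]]
        labels = [True, True, False, False]
        grid = build_quadrant_grid(_emb(coords), labels)
        np.testing.assert_allclose(grid.x_edges, np.linspace(0, 5, 4))
        np.testing.assert_allclose(grid.y_edges, np.linspace(-2, 3, 4))

    def test_zero_positives_is_an_error(self):
        with pytest.raises(ValueError):
            build_quadrant_grid(_emb(np.zeros((4, 2))), [False] * 4)

    def test_brute_force_oracle_equivalence(self, rng):
        """Cell assignment and QW match an explicit loop over compounds and cells."""
        for _ in range(20):
            n = int(rng.integers(5, 51))
            coords = rng.normal(scale=5, size=(n, 2))
            labels = rng.random(n) < 0.5
            if not labels.any():
                labels[0] = True
            grid = build_quadrant_grid(_emb(coords), labels)
            xe, ye = grid.x_edges, grid.y_edges

            def cell_of(v, edges):
                if v < edges[1]:
                    return 0
                if v < edges[2]:
                    return 1
                return 2

            A = np.zeros((3, 3), int)
            NA = np.zeros((3, 3), int)
            for (x, y), lab in zip(coords, labels):
                i, j = cell_of(y, ye), cell_of(x, xe)
                if lab:
                    A[i, j] += 1
                else:
                    NA[i, j] += 1
            np.testing.assert_array_equal(grid.cell_A, A)
            np.testing.assert_array_equal(grid.cell_NA, NA)
            np.testing.assert_allclose(grid.cell_qw, ((A - NA) * 100 / n) / 2)


class TestApplyWeights:
    def _grid_with_uniform_qw(self, emb, labels, qw_value):
        grid = build_quadrant_grid(emb, labels)
        grid.cell_qw[:] = qw_value
        return grid

    def test_unit_weight_leaves_coordinates_unchanged(self):
        emb = _emb([[1.0, 2.0], [3.0, -1.0], [0.5, 0.5], [2.0, 2.0]])
        grid = self._grid_with_uniform_qw(emb, [True, True, False, False], 1.0)
        np.testing.assert_array_equal(apply_weights(emb, grid).coords, emb.coords)

    def test_scalar_multiplication(self):
        emb = _emb([[2.0, -3.0], [0.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
        grid = self._grid_with_uniform_qw(emb, [True, False, True, False], -2.5)
        np.testing.assert_allclose(apply_weights(emb, grid).coords[0], [-5.0, 7.5])

    def test_zero_weight_collapses_to_origin(self):
        emb = _emb([[2.0, -3.0], [4.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
        grid = self._grid_with_uniform_qw(emb, [True, False, True, False], 0.0)
        assert (apply_weights(emb, grid).coords == 0).all()

    def test_qw_offset_restores_injectivity(self):
        emb = _emb([[2.0, -3.0], [4.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
        grid = self._grid_with_uniform_qw(emb, [True, False, True, False], 0.0)
        w = apply_weights(emb, grid, qw_offset=1.0)
        np.testing.assert_array_equal(w.coords, emb.coords)

    def test_weighting_matches_per_compound_cell_lookup(self, rng):
        coords = rng.normal(scale=4, size=(40, 2))
        labels = rng.random(40) < 0.4
        labels[0] = True
        emb = _emb(coords)
        grid = build_quadrant_grid(emb, labels)
        weighted = apply_weights(emb, grid)
        rows, cols = grid.assign(coords)
        expected = coords * grid.cell_qw[rows, cols][:, None]
        np.testing.assert_allclose(weighted.coords, expected)
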