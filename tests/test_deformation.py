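"""DR per branch, SGR along lineages, step charts, and trend fits."""

import numpy as np
import pytest

from morphorate.ancestral import NodeShape
from morphorate.deformation import (
    edge_deformations,
    edges_frame,
    fit_trend,
    sgr_along_paths,
    step_chart_series,
)
from morphorate.errors import ValidationError
from morphorate.io_formats import TimeTree
from morphorate.ordination import cva


def shapes_for(tree, values):
    return {
        lbl: NodeShape(node_label=lbl, points=np.asarray(v, float))
        for lbl, v in values.items()
    }


@pytest.fixture
def chain_tree():
    # A -> B -> C with ages 10 -> 5 -> 0
    return TimeTree.from_newick("((C[&age=0])B[&age=5])A[&age=10];")


class TestEdgeDeformations:
    def test_identical_shapes_zero_dr(self):
        tree = TimeTree.from_newick("(A:2,B:2)R;")
        pts = [[0, 0], [1, 0], [0, 1]]
        edges = edge_deformations(tree, shapes_for(tree, {"A": pts, "B": pts, "R": pts}))
        for e in edges:
            assert e.d_euclidean == 0 and e.dr_euclidean == 0
            assert e.d_mahalanobis == 0 and e.dr_mahalanobis == 0

    def test_dr_is_distance_over_time(self):
        tree = TimeTree.from_newick("(A[&age=0],B[&age=0])R[&age=2];")
        r = np.zeros((3, 2))
        a = np.zeros((3, 2))
        a[0, 0] = 4.0  # Euclidean distance 4 over dt = 2
        edges = edge_deformations(tree, shapes_for(tree, {"A": a, "B": r, "R": r}))
        e = {x.child_label: x for x in edges}["A"]
        assert e.d_euclidean == pytest.approx(4.0)
        assert e.dr_euclidean == pytest.approx(2.0)

    def test_identity_covariance_degenerates_to_euclidean(self):
        # whiten the pooled within-group covariance in the full 6-d shape
        # space: Mahalanobis edge distances then equal Euclidean ones
        rng = np.random.default_rng(0)
        n = 100
        x = rng.normal(size=(2 * n, 6))
        means = {0: x[:n].mean(axis=0), 1: x[n:].mean(axis=0)}
        resid = np.vstack([x[:n] - means[0], x[n:] - means[1]])
        w = resid.T @ resid / (2 * n - 2)
        xw = x @ np.linalg.inv(np.linalg.cholesky(w)).T
        xw[n:, 0] += 3
        labels = ["a"] * n + ["b"] * n
        space = cva(xw, labels)
        tree = TimeTree.from_newick("(A[&age=0],B[&age=0])R[&age=2];")
        rng2 = np.random.default_rng(1)
        pts = {lbl: rng2.normal(size=(3, 2)) for lbl in "ABR"}
        edges = edge_deformations(tree, shapes_for(tree, pts), distance_space=space)
        for e in edges:
            assert e.dr_mahalanobis == pytest.approx(e.dr_euclidean, abs=1e-9)

    def test_zero_dt_raises_or_epsilon(self):
        tree = TimeTree.from_newick("(A[&age=2],B[&age=0])R[&age=2];")
        pts = {"A": np.eye(3, 2), "B": np.eye(3, 2) * 2, "R": np.eye(3, 2) * 3}
        with pytest.raises(ValidationError, match="elapsed"):
            edge_deformations(tree, shapes_for(tree, pts))
        edges = edge_deformations(tree, shapes_for(tree, pts), zero_dt="epsilon")
        e = {x.child_label: x for x in edges}["A"]
        assert np.isfinite(e.dr_euclidean)

    def test_ci_bounds_carried(self):
        tree = TimeTree.from_newick(
            "(A[&age=0,age_95={0,0}],B[&age=0,age_95={0,0}])R[&age=93,age_95={58,115}];"
        )
        pts = {"A": np.eye(3, 2), "B": np.eye(3, 2), "R": np.eye(3, 2)}
        edges = edge_deformations(tree, shapes_for(tree, pts))
        assert edges[0].dt_ci == (58, 115)


class TestSgrAlongPaths:
    def _edges_with_dr(self, tree, dr_by_child):
        """Build node shapes whose Euclidean DRs match the requested values."""
        shapes = {}
        # chain construction: accumulate displacements along x of point 0
        for node in tree.preorder():
            if node.parent is None:
                shapes[node.label] = np.zeros((3, 2))
            else:
                dt = node.parent.age_mean - node.age_mean
                d = dr_by_child[node.label] * dt
                step = np.zeros((3, 2))
                step[0, 0] = d
                shapes[node.label] = shapes[node.parent.label] + step
        return edge_deformations(tree, shapes_for(tree, shapes))

    def test_simple_ratio(self, chain_tree):
        edges = self._edges_with_dr(chain_tree, {"B": 2.0, "C": 3.0})
        series = sgr_along_paths(chain_tree, edges, variant="euclidean")
        assert len(series) == 1
        np.testing.assert_allclose(series[0].sgr_values, [0.5])

    def test_constant_dr_zero_sgr(self):
        tree = TimeTree.from_newick("(((C[&age=0])B[&age=5])A[&age=10])R[&age=15];")
        edges = self._edges_with_dr(tree, {"A": 1.0, "B": 1.0, "C": 1.0})
        series = sgr_along_paths(tree, edges, variant="euclidean")
        np.testing.assert_allclose(series[0].sgr_values, [0, 0])

    def test_matches_formula_oracle(self):
        # a 10-edge chain with random positive DRs
        rng = np.random.default_rng(2)
        newick = "C10[&age=0]"
        for i in range(9, -1, -1):
            newick = f"({newick})C{i}[&age={(10 - i) * 3.0}]"
        newick = newick + ";"
        tree = TimeTree.from_newick(newick)
        dr = {f"C{i}": float(rng.uniform(0.5, 3)) for i in range(1, 11)}
        edges = self._edges_with_dr(tree, dr)
        series = sgr_along_paths(tree, edges, variant="euclidean")
        vals = [dr[f"C{i}"] for i in range(1, 11)]
        expected = [(vals[i + 1] - vals[i]) / vals[i] for i in range(9)]
        np.testing.assert_allclose(series[0].sgr_values, expected, atol=1e-12)

    def test_zero_previous_dr_gives_nan_not_inf(self, chain_tree):
        edges = self._edges_with_dr(chain_tree, {"B": 0.0, "C": 1.0})
        series = sgr_along_paths(chain_tree, edges, variant="euclidean")
        assert np.isnan(series[0].sgr_values[0])

    def test_time_rescaling_invariance(self):
        # multiplying all ages by c scales DR by 1/c and leaves SGR unchanged
        newick = "((A[&age=0],B[&age=0])X[&age={s}],C[&age=0])R[&age={r}];"
        rng = np.random.default_rng(3)
        pts = {lbl: rng.normal(size=(4, 2)) for lbl in ["A", "B", "C", "X", "R"]}
        t1 = TimeTree.from_newick(newick.format(s=5, r=12))
        t2 = TimeTree.from_newick(newick.format(s=15, r=36))
        e1 = edge_deformations(t1, shapes_for(t1, pts))
        e2 = edge_deformations(t2, shapes_for(t2, pts))
        for a, b in zip(e1, e2):
            assert b.dr_euclidean == pytest.approx(a.dr_euclidean / 3, rel=1e-12)
        s1 = sgr_along_paths(t1, e1, variant="euclidean")
        s2 = sgr_along_paths(t2, e2, variant="euclidean")
        for a, b in zip(s1, s2):
            np.testing.assert_allclose(a.sgr_values, b.sgr_values, atol=1e-12)

    def test_distance_scaling_invariance_of_sgr(self):
        newick = "((A[&age=0],B[&age=0])X[&age=5],C[&age=0])R[&age=12];"
        rng = np.random.default_rng(4)
        pts = {lbl: rng.normal(size=(4, 2)) for lbl in ["A", "B", "C", "X", "R"]}
        tree = TimeTree.from_newick(newick)
        e1 = edge_deformations(tree, shapes_for(tree, pts))
        scaled = {lbl: 7.5 * p for lbl, p in pts.items()}
        e2 = edge_deformations(tree, shapes_for(tree, scaled))
        s1 = sgr_along_paths(tree, e1, variant="euclidean")
        s2 = sgr_along_paths(tree, e2, variant="euclidean")
        for a, b in zip(s1, s2):
            np.testing.assert_allclose(a.sgr_values, b.sgr_values, atol=1e-12)


class TestDrScalingUnderBm:
    def test_dr_decreases_with_branch_duration(self):
        # constant-rate BM: displacement ~ sigma*sqrt(2k*t), so DR ~ 1/sqrt(t)
        # and rank-correlates negatively with elapsed time across edges
        from scipy.stats import spearmanr

        from morphorate.ancestral import reconstruct_shapes
        from morphorate.synthetic_data import SimulationConfig, simulate_bm_shapes

        drs, dts = [], []
        for seed in range(10):
            cfg = SimulationConfig(
                n_tips=16, k=60, base_rate=1e-4, noise_sd=0.0,
                n_specimens_per_tip=1, seed=seed, tree_kind="random",
            )
            records, truth = simulate_bm_shapes(cfg)
            tips = {
                r.taxon: NodeShape(node_label=r.taxon, points=r.landmarks)
                for r in records
            }
            shapes = reconstruct_shapes(truth.tree, tips)
            for e in edge_deformations(truth.tree, shapes, zero_dt="epsilon"):
                drs.append(e.dr_euclidean)
                dts.append(e.dt)
        rho = spearmanr(drs, dts).statistic
        assert rho < 0


class TestStepChart:
    def test_two_tip_series(self):
        tree = TimeTree.from_newick("(A[&age=0],B[&age=0])R[&age=10];")
        rng = np.random.default_rng(5)
        pts = {lbl: rng.normal(size=(3, 2)) for lbl in ["A", "B", "R"]}
        edges = edge_deformations(tree, shapes_for(tree, pts))
        chart = step_chart_series(edges, tree, variant="euclidean")
        assert set(chart["lineage"]) == {"A", "B"}
        assert (chart["age_start"] == 0).all()
        assert (chart["age_end"] == 10).all()

    def test_chain_intervals(self):
        tree = TimeTree.from_newick("((C[&age=0])B[&age=5])A[&age=10];")
        rng = np.random.default_rng(6)
        pts = {lbl: rng.normal(size=(3, 2)) for lbl in ["A", "B", "C"]}
        edges = edge_deformations(tree, shapes_for(tree, pts))
        chart = step_chart_series(edges, tree, variant="euclidean")
        assert len(chart) == 2
        assert list(chart["age_start"]) == [5.0, 0.0]
        assert list(chart["age_end"]) == [10.0, 5.0]

    def test_cells_join_edge_table(self, fixture_dir):
        from morphorate.io_formats import read_time_tree

        tree = read_time_tree(fixture_dir / "tree.nwk")
        rng = np.random.default_rng(7)
        pts = {n.label: rng.normal(size=(4, 2)) for n in tree.preorder()}
        edges = edge_deformations(tree, shapes_for(tree, pts))
        chart = step_chart_series(edges, tree, variant="mahalanobis")
        lookup = {e.child_label: e for e in edges}
        for _, row in chart.iterrows():
            e = lookup[row["child"]]
            assert row["dr"] == e.dr_mahalanobis
            assert row["age_start"] == e.child_age
            assert row["age_end"] == e.parent_age


class TestFitTrend:
    def test_collinear_points_zero_residual(self):
        x = np.linspace(0, 10, 8)
        pts = np.column_stack([x, 2 * x - 3])
        fit = fit_trend(pts, method="ols_poly", degree=1)
        np.testing.assert_allclose(np.polyval(fit["coefficients"], x), 2 * x - 3, atol=1e-9)

    def test_constant_input_constant_curve(self):
        pts = [(0, 1.5), (5, 1.5), (10, 1.5), (15, 1.5)]
        fit = fit_trend(pts, method="ols_poly", degree=2)
        np.testing.assert_allclose(fit["fitted"], 1.5, atol=1e-9)
        loess = fit_trend(pts, method="loess")
        np.testing.assert_allclose(loess["fitted"], 1.5, atol=1e-9)

    def test_quadratic_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 10, 20)
        y = 0.3 * x**2 - 2 * x + 1 + rng.normal(0, 0.5, 20)
        fit = fit_trend(np.column_stack([x, y]), method="ols_poly", degree=2)
        design = np.vander(x, 3)
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(fit["coefficients"], oracle, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_trend([(0, 1), (1, 2)], method="ols_poly", degree=2)
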