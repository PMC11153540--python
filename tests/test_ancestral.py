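"""Continuous (squared-change parsimony) and discrete ancestral reconstruction."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from morphorate.ancestral import NodeShape, fitch_sankoff, mk_ml_states, reconstruct_shapes
from morphorate.errors import ValidationError
from morphorate.io_formats import TimeTree


def shape(label, pts, terminal=True):
    return NodeShape(node_label=label, points=np.asarray(pts, float), is_terminal=terminal)


def numeric_scp_oracle(tree, tip_shapes, weighting="branch_length"):
    """Minimize the weighted sum of squared changes directly (per coordinate)."""
    internal = tree.internal_nodes()
    k2 = tip_shapes[tree.leaves()[0].label].flat.size
    idx = {n.label: i for i, n in enumerate(internal)}

    def objective(flat):
        vals = flat.reshape(len(internal), k2)
        total = 0.0
        for parent, child in tree.edges():
            dt = tree.elapsed(parent, child) if weighting == "branch_length" else 1.0
            dt = max(dt, 1e-8)
            pv = vals[idx[parent.label]]
            cv = (
                tip_shapes[child.label].flat
                if child.is_leaf
                else vals[idx[child.label]]
            )
            total += ((pv - cv) ** 2).sum() / dt
        return total

    x0 = np.tile(
        np.mean([tip_shapes[l.label].flat for l in tree.leaves()], axis=0),
        len(internal),
    )
    res = minimize(objective, x0, method="L-BFGS-B", tol=1e-14)
    return {n.label: res.x.reshape(len(internal), k2)[idx[n.label]] for n in internal}


class TestReconstructShapes:
    def test_two_tip_root_formula(self):
        # root = (x1/t1 + x2/t2) / (1/t1 + 1/t2) per coordinate
        tree = TimeTree.from_newick("(A[&age=0],B[&age=0])R[&age=3];")
        tree.node("A").age_mean = 0.0
        tree.node("B").age_mean = 1.0  # t1 = 3, t2 = 2
        x1 = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        x2 = np.array([[1.0, 1.0], [2.0, 0.0], [0.0, 3.0]])
        tips = {"A": shape("A", x1), "B": shape("B", x2)}
        rec = reconstruct_shapes(tree, tips)
        t1, t2 = 3.0, 2.0
        expected = (x1 / t1 + x2 / t2) / (1 / t1 + 1 / t2)
        np.testing.assert_allclose(rec["R"].points, expected, atol=1e-10)
        oracle = numeric_scp_oracle(tree, tips)
        np.testing.assert_allclose(rec["R"].flat, oracle["R"], atol=1e-6)

    def test_star_tree_equal_branches_gives_mean(self):
        tree = TimeTree.from_newick("(A:1,B:1,C:1,D:1)R;")
        rng = np.random.default_rng(0)
        tips = {l: shape(l, rng.normal(size=(4, 2))) for l in "ABCD"}
        rec = reconstruct_shapes(tree, tips)
        mean = np.mean([tips[l].points for l in "ABCD"], axis=0)
        np.testing.assert_allclose(rec["R"].points, mean, atol=1e-10)

    def test_identical_tips_propagate(self):
        tree = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        tips = {l: shape(l, pts) for l in "ABCD"}
        rec = reconstruct_shapes(tree, tips)
        for node in rec.values():
            np.testing.assert_allclose(node.points, pts, atol=1e-10)

    @pytest.mark.parametrize("weighting", ["branch_length", "equal"])
    def test_matches_numeric_minimization_on_random_trees(self, weighting):
        rng = np.random.default_rng(1)
        for rep in range(50):
            # random 4-tip dated topology
            ages = np.sort(rng.uniform(1, 10, 3))
            newick = (
                f"((A[&age=0],B[&age=0])X[&age={ages[0]}],"
                f"(C[&age=0],D[&age=0])Y[&age={ages[1]}])R[&age={ages[2]}];"
            )
            tree = TimeTree.from_newick(newick)
            tips = {l: shape(l, rng.normal(size=(3, 2))) for l in "ABCD"}
            rec = reconstruct_shapes(tree, tips, weighting)
            oracle = numeric_scp_oracle(tree, tips, weighting)
            for lbl, exp in oracle.items():
                np.testing.assert_allclose(rec[lbl].flat, exp, atol=1e-6)

    def test_linearity_in_tips(self):
        tree = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        rng = np.random.default_rng(2)
        tips_x = {l: shape(l, rng.normal(size=(5, 2))) for l in "ABCD"}
        tips_y = {l: shape(l, rng.normal(size=(5, 2))) for l in "ABCD"}
        a, b = 2.5, -1.25
        combo = {
            l: shape(l, a * tips_x[l].points + b * tips_y[l].points) for l in "ABCD"
        }
        rx = reconstruct_shapes(tree, tips_x)
        ry = reconstruct_shapes(tree, tips_y)
        rc = reconstruct_shapes(tree, combo)
        for lbl in rc:
            np.testing.assert_allclose(
                rc[lbl].points, a * rx[lbl].points + b * ry[lbl].points, atol=1e-9
            )

    def test_missing_tip_rejected(self):
        tree = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValidationError, match="without shapes"):
            reconstruct_shapes(tree, {"A": shape("A", np.eye(3, 2))})

    def test_root_converges_to_truth_with_many_tips(self):
        # BM simulation without noise: reconstruction error at the root is
        # well below the per-branch displacement scale at 32 tips
        from morphorate.synthetic_data import SimulationConfig, generate_tree, simulate_bm_shapes

        errs, scales = [], []
        for seed in range(20):
            cfg = SimulationConfig(
                n_tips=32, k=8, base_rate=1e-4, noise_sd=0.0,
                n_specimens_per_tip=1, seed=seed,
            )
            _, truth = simulate_bm_shapes(cfg)
            tree = truth.tree
            tips = {
                l.label: shape(l.label, truth.node_shapes[l.label]) for l in tree.leaves()
            }
            rec = reconstruct_shapes(tree, tips)
            root = tree.root.label
            errs.append(np.linalg.norm(rec[root].flat - truth.node_shapes[root].ravel()))
            scales.append(np.median(list(truth.edge_displacements.values())))
        assert np.median(errs) < np.median(scales)


def exhaustive_parsimony_oracle(tree, tip_states, states):
    """Minimum steps and per-node optimal state sets by full enumeration."""
    internal = tree.internal_nodes()
    best = np.inf
    sets = {n.label: set() for n in tree.preorder()}
    for assign in itertools.product(states, repeat=len(internal)):
        full = dict(tip_states)
        full.update({n.label: s for n, s in zip(internal, assign)})
        cost = sum(
            full[p.label] != full[c.label] for p, c in tree.edges()
        )
        if cost < best - 1e-12:
            best = cost
            sets = {lbl: {full[lbl]} for lbl in full}
        elif cost == best:
            for lbl in full:
                sets[lbl].add(full[lbl])
    return best, {lbl: frozenset(s) for lbl, s in sets.items()}


class TestFitchSankoff:
    def test_three_tip_example(self):
        tree = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        rec = fitch_sankoff(tree, {"A": "0", "B": "1", "C": "0"})
        assert rec.tree_length == 1
        root = tree.root.label
        assert rec.state_sets[root] == frozenset({"0"})

    def test_uniform_tips_zero_length(self):
        tree = TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        rec = fitch_sankoff(tree, dict.fromkeys("ABCD", "omnivory"))
        assert rec.tree_length == 0
        assert all(s == frozenset({"omnivory"}) for s in rec.state_sets.values())

    def test_cherry_tie_reported_as_set(self):
        tree = TimeTree.from_newick("(A:1,B:1)R;")
        rec = fitch_sankoff(tree, {"A": "0", "B": "1"})
        assert rec.state_sets["R"] == frozenset({"0", "1"})
        assert rec.tree_length == 1

    def test_matches_exhaustive_enumeration(self):
        topologies = [
            "((A:1,B:1):1,C:2);",
            "((A:1,B:1):1,(C:1,D:1):1);",
            "(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);",
            "((A:1,(B:0.5,C:0.5):0.5):1,((D:1,E:1):0.5,F:1.5):0.5);",
        ]
        states = ["0", "1", "2"]
        rng = np.random.default_rng(3)
        for newick in topologies:
            tree = TimeTree.from_newick(newick)
            tips = tree.leaf_labels
            for _ in range(10):
                tip_states = {t: states[rng.integers(3)] for t in tips}
                rec = fitch_sankoff(tree, tip_states, states=states)
                best, sets = exhaustive_parsimony_oracle(tree, tip_states, states)
                assert rec.tree_length == best
                for lbl, expected in sets.items():
                    assert rec.state_sets[lbl] == expected, (newick, lbl, tip_states)

    def test_length_invariant_under_relabeling(self):
        tree = TimeTree.from_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        states = ["x", "y", "z"]
        tip_states = {"A": "x", "B": "y", "C": "x", "D": "z", "E": "y"}
        base = fitch_sankoff(tree, tip_states, states=states).tree_length
        perm = {"x": "z", "y": "x", "z": "y"}
        relabeled = {t: perm[s] for t, s in tip_states.items()}
        assert fitch_sankoff(tree, relabeled, states=states).tree_length == base

    def test_state_outside_vocabulary_rejected(self):
        tree = TimeTree.from_newick("(A:1,B:1)R;")
        with pytest.raises(ValidationError, match="vocabulary"):
            fitch_sankoff(tree, {"A": "0", "B": "9"}, states=["0", "1"])


def mk_brute_force_marginals(tree, tip_states, states, rate):
    """Marginals by explicit summation over all internal-state assignments."""
    s = len(states)
    internal = tree.internal_nodes()

    def transition(t):
        decay = np.exp(-s * rate * t)
        return np.full((s, s), (1 - decay) / s) + np.eye(s) * decay

    sidx = {st: i for i, st in enumerate(states)}
    marg = {n.label: np.zeros(s) for n in tree.preorder()}
    total = 0.0
    for assign in itertools.product(range(s), repeat=len(internal)):
        full = {n.label: a for n, a in zip(internal, assign)}
        full.update({t: sidx[st] for t, st in tip_states.items()})
        lik = 1.0 / s  # uniform root prior
        for p, c in tree.edges():
            lik *= transition(tree.elapsed(p, c))[full[p.label], full[c.label]]
        total += lik
        for lbl, st in full.items():
            marg[lbl][st] += lik
    return {lbl: v / total for lbl, v in marg.items()}


class TestMkMlStates:
    def test_matches_brute_force_oracle(self):
        tree = TimeTree.from_newick(
            "((A[&age=0],B[&age=0])X[&age=40],(C[&age=0],D[&age=0])Y[&age=70])R[&age=100];"
        )
        states = ["omnivory", "coprophagy", "phytophagy"]
        tip_states = {"A": "omnivory", "B": "coprophagy", "C": "phytophagy", "D": "phytophagy"}
        rate = 0.01
        rec = mk_ml_states(tree, tip_states, states=states, rate=rate)
        oracle = mk_brute_force_marginals(tree, tip_states, states, rate)
        for lbl, expected in oracle.items():
            np.testing.assert_allclose(rec.weights[lbl], expected, atol=1e-10)

    def test_low_rate_limit_concentrates_on_shared_state(self):
        tree = TimeTree.from_newick("(A[&age=0],B[&age=0])R[&age=50];")
        rec = mk_ml_states(
            tree, {"A": "x", "B": "x"}, states=["x", "y"], rate=1e-9
        )
        assert rec.weights["R"][0] > 1 - 1e-6

    def test_rate_estimated_when_not_given(self):
        tree = TimeTree.from_newick(
            "((A:10,B:10):10,(C:15,D:15):5);"
        )
        rec = mk_ml_states(tree, {"A": "0", "B": "1", "C": "0", "D": "1"}, states=["0", "1"])
        assert rec.rate is not None and rec.rate > 0
        assert rec.converged
        for w in rec.weights.values():
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tip_weights_are_indicators(self):
        tree = TimeTree.from_newick("(A:1,B:1)R;")
        rec = mk_ml_states(tree, {"A": "0", "B": "1"}, states=["0", "1"], rate=0.1)
        np.testing.assert_allclose(rec.weights["A"], [1, 0], atol=1e-12)
        np.testing.assert_allclose(rec.weights["B"], [0, 1], atol=1e-12)
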