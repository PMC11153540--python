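"""Ancestral reconstruction on a dated tree: continuous shapes and discrete states.

Continuous landmark configurations at internal nodes are estimated by
branch-length-weighted squared-change parsimony: internal coordinates
minimize the sum over edges of (squared change) / (elapsed time), which is
solved exactly per coordinate as a sparse linear system and coincides with
the maximum-likelihood point estimate under Brownian motion.

Discrete characters (feeding types) are reconstructed by Fitch/Sankoff
parsimony (per-node sets of states attaining the minimal total cost) or,
optionally, by marginal likelihoods under an equal-rates Markov (Mk) model
with the rate fitted by 1-D likelihood maximization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from morphorate.errors import ValidationError

__all__ = [
    "DiscreteReconstruction",
    "NodeShape",
    "fitch_sankoff",
    "mk_ml_states",
    "reconstruct_shapes",
]

#: Elapsed time substituted for zero-length edges when weighting by branch length.
ZERO_LENGTH_EPSILON = 1e-8


@dataclass
class NodeShape:
    """A mean or reconstructed landmark configuration attached to one tree node."""

    node_label: str
    points: np.ndarray
    is_terminal: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def k(self) -> int:
        return len(self.points)

    @property
    def flat(self) -> np.ndarray:
        return self.points.ravel()


def reconstruct_shapes(
    tree,
    tip_shapes: Mapping[str, NodeShape],
    weighting: str = "branch_length",
) -> dict[str, NodeShape]:
    """Weighted squared-change parsimony reconstruction of internal shapes.

    Internal-node coordinates minimize

        sum over edges of ||x_parent - x_child||^2 / dt

    with dt the elapsed time on the edge (``weighting="equal"`` sets dt = 1).
    The minimizer is found exactly, coordinate by coordinate, from the linear
    system given by stationarity at each internal node; it equals the ML
    ancestral estimate under Brownian motion.

    Parameters
    ----------
    tree : TimeTree
        Dated tree; every terminal label must appear in ``tip_shapes``.
    tip_shapes : mapping terminal label -> NodeShape
        Tip values (typically terminal-group mean shapes in tangent space).
    weighting : {"branch_length", "equal"}
        Edge weights 1/dt or 1. Zero-length edges get dt = 1e-8 Ma.

    Returns
    -------
    dict mapping every node label (terminal and internal) to its NodeShape.
    """
    if weighting not in ("branch_length", "equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    leaves = tree.leaves()
    missing = [n.label for n in leaves if n.label not in tip_shapes]
    if missing:
        raise ValidationError(f"tips without shapes: {missing[:5]}")
    ks = {tip_shapes[n.label].k for n in leaves}
    if len(ks) != 1:
        raise ValidationError(f"tip shapes differ in landmark count: {sorted(ks)}")
    k = ks.pop()

    internal = tree.internal_nodes()
    index = {node.label: i for i, node in enumerate(internal)}
    m = len(internal)
    a = np.zeros((m, m))
    b = np.zeros((m, 2 * k))

    for parent, child in tree.edges():
        if weighting == "branch_length":
            dt = tree.elapsed(parent, child)
            if dt <= 0:
                dt = ZERO_LENGTH_EPSILON
            w = 1.0 / dt
        else:
            w = 1.0
        i = index[parent.label]
        a[i, i] += w
        if child.is_leaf:
            b[i] += w * tip_shapes[child.label].flat
        else:
            j = index[child.label]
            a[j, j] += w
            a[i, j] -= w
            a[j, i] -= w

    solution = np.linalg.solve(a, b) if m else np.empty((0, 2 * k))

    out: dict[str, NodeShape] = {}
    for node in internal:
        out[node.label] = NodeShape(
            node_label=node.label,
            points=solution[index[node.label]].reshape(-1, 2),
            is_terminal=False,
        )
    for leaf in leaves:
        tip = tip_shapes[leaf.label]
        out[leaf.label] = NodeShape(node_label=leaf.label, points=tip.points, is_terminal=True)
    return out


@dataclass
class DiscreteReconstruction:
    """Result of a discrete ancestral-state reconstruction.

    ``state_sets`` holds, per node label, the set of states attaining the
    global parsimony minimum (Fitch/Sankoff) — or, for the Mk model, the set
    of states with the highest marginal weight. ``weights`` holds per-node
    normalized marginal likelihoods (Mk only). ``tree_length`` is the
    minimal number of weighted steps (parsimony only).
    """

    states: tuple[str, ...]
    state_sets: dict[str, frozenset[str]]
    tree_length: float | None = None
    weights: dict[str, np.ndarray] | None = None
    rate: float | None = None
    log_likelihood: float | None = None
    converged: bool = True
    diagnostics: str = ""


def _check_states(tree, tip_states: Mapping[str, str], states: Sequence[str]) -> list[str]:
    order = list(dict.fromkeys(states))
    for leaf in tree.leaves():
        if leaf.label not in tip_states:
            raise ValidationError(f"tip {leaf.label!r} has no observed state")
        if tip_states[leaf.label] not in order:
            raise ValidationError(
                f"tip {leaf.label!r} has state {tip_states[leaf.label]!r} "
                f"outside the vocabulary {order}"
            )
    return order


def fitch_sankoff(
    tree,
    tip_states: Mapping[str, str],
    states: Sequence[str] | None = None,
    costs: np.ndarray | None = None,
) -> DiscreteReconstruction:
    """Sankoff parsimony with an arbitrary substitution-cost matrix.

    With uniform (0/1) costs this reduces to Fitch parsimony. For every node
    the set of states that participate in at least one globally minimal
    assignment is reported; ties are kept as sets, never broken.

    Parameters
    ----------
    tree : TimeTree
    tip_states : mapping terminal label -> state
    states : state vocabulary (defaults to the sorted set of observed states)
    costs : (s, s) cost matrix, zero diagonal (defaults to uniform 0/1)
    """
    if states is None:
        states = sorted(set(tip_states.values()))
    order = _check_states(tree, tip_states, states)
    s = len(order)
    sidx = {st: i for i, st in enumerate(order)}
    if costs is None:
        costs = 1.0 - np.eye(s)
    else:
        costs = np.asarray(costs, dtype=float)
        if costs.shape != (s, s):
            raise ValidationError(f"cost matrix must be {s}x{s}")

    inf = np.inf
    down: dict[str, np.ndarray] = {}  # min cost of subtree with node in state i
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.full(s, inf)
            vec[sidx[tip_states[node.label]]] = 0.0
        else:
            vec = np.zeros(s)
            for child in node.children:
                # child message: for each parent state, best child choice
                vec += (costs + down[child.label][None, :]).min(axis=1)
        down[node.label] = vec

    tree_length = float(down[tree.root.label].min())

    # Up pass: cost of the rest of the tree given this node's state.
    up: dict[str, np.ndarray] = {tree.root.label: np.zeros(s)}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        child_msgs = {
            c.label: (costs + down[c.label][None, :]).min(axis=1) for c in node.children
        }
        total_msg = sum(child_msgs.values())
        for child in node.children:
            # parent context excluding this child, then best parent-state choice
            context = up[node.label] + total_msg - child_msgs[child.label]
            up[child.label] = (context[:, None] + costs).min(axis=0)

    state_sets: dict[str, frozenset[str]] = {}
    for node in tree.preorder():
        total = down[node.label] + up[node.label]
        best = total.min()
        state_sets[node.label] = frozenset(
            order[i] for i in range(s) if total[i] <= best + 1e-9
        )

    return DiscreteReconstruction(
        states=tuple(order), state_sets=state_sets, tree_length=tree_length
    )


def _mk_transition(rate: float, s: int, t: float) -> np.ndarray:
    """Equal-rates Mk transition matrix over elapsed time t."""
    decay = np.exp(-s * rate * t)
    p_same = 1.0 / s + (s - 1.0) / s * decay
    p_diff = 1.0 / s - 1.0 / s * decay
    return np.full((s, s), p_diff) + np.eye(s) * (p_same - p_diff)


def _mk_loglik(tree, tip_idx: Mapping[str, int], s: int, rate: float) -> float:
    partial: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.zeros(s)
            vec[tip_idx[node.label]] = 1.0
        else:
            vec = np.ones(s)
            for child in node.children:
                p = _mk_transition(rate, s, max(tree.elapsed(node, child), 0.0))
                vec = vec * (p @ partial[child.label])
        partial[node.label] = vec
    root_lik = partial[tree.root.label].mean()  # uniform root prior
    return float(np.log(root_lik)) if root_lik > 0 else -np.inf


def mk_ml_states(
    tree,
    tip_states: Mapping[str, str],
    states: Sequence[str] | None = None,
    rate: float | None = None,
) -> DiscreteReconstruction:
    """Marginal ancestral states under an equal-rates Mk model.

    The single substitution rate (events per Ma per off-diagonal cell) is
    maximized by bounded 1-D likelihood optimization unless given. Per-node
    marginal likelihoods are computed by the standard two-pass algorithm and
    normalized to weights; the reported state set per node holds the
    highest-weight state(s).
    """
    if states is None:
        states = sorted(set(tip_states.values()))
    order = _check_states(tree, tip_states, states)
    s = len(order)
    sidx = {st: i for i, st in enumerate(order)}
    tip_idx = {leaf: sidx[st] for leaf, st in tip_states.items()}

    converged = True
    diagnostics = ""
    if rate is None:
        depth = max(tree.root.age_mean, 1e-6)
        res = minimize_scalar(
            lambda r: -_mk_loglik(tree, tip_idx, s, r),
            bounds=(1e-8, 100.0 / depth),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rate = float(res.x)
        converged = bool(res.success)
        if not converged:
            diagnostics = f"rate optimization did not converge: {res.message}"

    # Down pass (conditional likelihoods of subtrees).
    down: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.zeros(s)
            vec[tip_idx[node.label]] = 1.0
        else:
            vec = np.ones(s)
            for child in node.children:
                p = _mk_transition(rate, s, max(tree.elapsed(node, child), 0.0))
                vec = vec * (p @ down[child.label])
        down[node.label] = vec

    # Up pass (likelihood of everything outside the subtree, including prior).
    up: dict[str, np.ndarray] = {tree.root.label: np.full(s, 1.0 / s)}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        msgs = {}
        for child in node.children:
            p = _mk_transition(rate, s, max(tree.elapsed(node, child), 0.0))
            msgs[child.label] = (p, p @ down[child.label])
        for child in node.children:
            context = up[node.label].copy()
            for other in node.children:
                if other is not child:
                    context = context * msgs[other.label][1]
            up[child.label] = msgs[child.label][0].T @ context

    weights: dict[str, np.ndarray] = {}
    state_sets: dict[str, frozenset[str]] = {}
    for node in tree.preorder():
        marg = down[node.label] * up[node.label]
        total = marg.sum()
        if total <= 0:
            raise ValidationError(f"zero marginal likelihood at node {node.label!r}")
        marg = marg / total
        weights[node.label] = marg
        best = marg.max()
        state_sets[node.label] = frozenset(
            order[i] for i in range(s) if marg[i] >= best - 1e-12
        )

    return DiscreteReconstruction(
        states=tuple(order),
        state_sets=state_sets,
        weights=weights,
        rate=rate,
        log_likelihood=_mk_loglik(tree, tip_idx, s, rate),
        converged=converged,
        diagnostics=diagnostics,
    )
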