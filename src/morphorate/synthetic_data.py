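"""Synthetic tree-structured landmark data with known ground truth.

Group mean shapes evolve on a dated tree under multivariate Brownian motion
(per-coordinate variance ``base_rate`` per Ma, optionally multiplied on
selected branches), tips emit replicate specimens with i.i.d. Gaussian
digitization noise, and a discrete feeding-type character evolves under an
equal-rates Markov model. Everything is emitted in the pipeline's own input
formats (TPS, Newick with age annotations, CSV group table) together with a
truth record keyed by the same node labels, so every downstream stage can be
checked against the simulated truth.

Simulation operates directly in shape coordinates (the root template has
unit centroid size and perturbations are small), so Procrustes alignment of
a noise-free fixture is nearly the identity; an optional jitter mode applies
a random rotation/translation/scale to each emitted specimen to exercise
the superimposition step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from morphorate.errors import ValidationError
from morphorate.io_formats import SpecimenRecord, TimeTree, TreeNode, write_tps

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_tree",
    "make_fixture",
    "simulate_bm_shapes",
    "simulate_discrete_trait",
]

DEFAULT_STATES = ("omnivory", "coprophagy", "phytophagy")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    n_tips : int
        Number of terminal groups.
    tree_kind : {"balanced", "random"}
        Balanced trees split tips evenly with node ages proportional to
        topological height (equal edge lengths on power-of-two tip counts);
        random trees join lineages at sorted uniform ages.
    root_age : float
        Age of the root, Ma.
    k : int
        Landmarks per configuration (ignored when ``characters`` is given).
    characters : mapping name -> k, optional
        Multi-character fixtures; each character evolves independently.
    base_rate : float
        Brownian variance per coordinate per Ma (Procrustes units^2).
    shifts : mapping child node label -> rate multiplier
        Branch-specific multipliers on ``base_rate`` (the branch is the edge
        above the named node).
    noise_sd : float
        SD of i.i.d. per-coordinate specimen digitization noise.
    n_specimens_per_tip : int
    states : tuple of str
        Discrete feeding-type vocabulary.
    discrete_rate : float
        Markov substitution rate per Ma per off-diagonal cell.
    jitter : bool
        Apply random rotation/translation/scale to each emitted specimen.
    seed : int
        Root of a hierarchical random stream; sub-simulations draw from
        spawned substreams so each is independently reproducible.
    """

    n_tips: int = 8
    tree_kind: str = "balanced"
    root_age: float = 150.0
    k: int = 16
    characters: dict[str, int] | None = None
    base_rate: float = 1e-4
    shifts: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.005
    n_specimens_per_tip: int = 20
    states: tuple[str, ...] = DEFAULT_STATES
    discrete_rate: float = 0.005
    jitter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValidationError("need at least 2 tips")
        if self.k < 3 and self.characters is None:
            raise ValidationError("need at least 3 landmarks")
        if self.characters is not None and any(k < 3 for k in self.characters.values()):
            raise ValidationError("need at least 3 landmarks per character")
        if self.base_rate < 0 or self.noise_sd < 0 or self.discrete_rate < 0:
            raise ValidationError("rates and noise must be non-negative")
        if any(m <= 0 for m in self.shifts.values()):
            raise ValidationError("rate multipliers must be positive")
        if self.n_specimens_per_tip < 1:
            raise ValidationError("need at least 1 specimen per tip")
        if not self.states:
            raise ValidationError("state set must be non-empty")


@dataclass
class SimulationTruth:
    """Ground truth joined 1:1 with the emitted tree's nodes and edges."""

    tree: TimeTree
    node_shapes: dict[str, np.ndarray]
    edge_displacements: dict[str, float]  # keyed by child label
    realized_rates: dict[str, float]  # variance per coordinate per Ma on edge
    node_states: dict[str, str] | None = None

    def to_jsonable(self) -> dict:
        return {
            "node_shapes": {k: v.tolist() for k, v in self.node_shapes.items()},
            "edge_displacements": self.edge_displacements,
            "realized_rates": self.realized_rates,
            "node_states": self.node_states,
        }


def generate_tree(
    n_tips: int,
    kind: str = "balanced",
    root_age: float = 150.0,
    rng: np.random.Generator | None = None,
) -> TimeTree:
    """Generate a dated tree with tips ``T1..Tn`` at age 0.

    Balanced trees place each internal node at an age proportional to its
    topological height; random trees (requires ``rng``) join uniformly
    chosen lineage pairs at sorted uniform ages, the oldest at ``root_age``.
    """
    if n_tips < 2:
        raise ValidationError("need at least 2 tips")
    labels = [f"T{i + 1}" for i in range(n_tips)]
    if kind == "balanced":

        def build(tip_labels: list[str]) -> tuple[TreeNode, int]:
            if len(tip_labels) == 1:
                return TreeNode(label=tip_labels[0], age_mean=0.0), 0
            half = (len(tip_labels) + 1) // 2
            left, hl = build(tip_labels[:half])
            right, hr = build(tip_labels[half:])
            node = TreeNode(label="", children=[left, right])
            left.parent = node
            right.parent = node
            return node, max(hl, hr) + 1

        root, height = build(labels)
        for node in _preorder(root):
            h = _height(node)
            node.age_mean = root_age * h / height
        return TimeTree(root)
    if kind == "random":
        if rng is None:
            raise ValidationError("random trees need an rng")
        ages = np.sort(rng.uniform(0, root_age, n_tips - 1))
        ages[-1] = root_age
        lineages: list[TreeNode] = [TreeNode(label=l, age_mean=0.0) for l in labels]
        for age in ages:
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            node = TreeNode(label="", age_mean=float(age), children=[lineages[i], lineages[j]])
            lineages[i].parent = node
            lineages[j].parent = node
            lineages = [n for idx, n in enumerate(lineages) if idx not in (i, j)] + [node]
        return TimeTree(lineages[0])
    raise ValueError(f"unknown tree kind {kind!r}")


def _preorder(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def _height(node: TreeNode) -> int:
    if not node.children:
        return 0
    return 1 + max(_height(c) for c in node.children)


def regular_polygon(k: int) -> np.ndarray:
    """Regular k-gon, centered, scaled to unit centroid size (the root template)."""
    theta = 2 * np.pi * np.arange(k) / k
    pts = np.column_stack([np.cos(theta), np.sin(theta)])
    pts -= pts.mean(axis=0)
    return pts / np.sqrt((pts**2).sum())


def _bm_on_tree(
    tree: TimeTree,
    root_shape: np.ndarray,
    base_rate: float,
    shifts: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, float], dict[str, float]]:
    unknown = [lbl for lbl in shifts if lbl not in tree or tree.node(lbl).parent is None]
    if unknown:
        raise ValidationError(f"shift labels not matching a branch: {unknown}")
    shapes = {tree.root.label: root_shape.copy()}
    displacements: dict[str, float] = {}
    rates: dict[str, float] = {}
    for parent, child in tree.edges():
        dt = tree.elapsed(parent, child)
        rate = base_rate * shifts.get(child.label, 1.0)
        step = rng.normal(0.0, np.sqrt(max(rate * dt, 0.0)), size=root_shape.shape)
        shapes[child.label] = shapes[parent.label] + step
        displacements[child.label] = float(np.linalg.norm(step))
        rates[child.label] = rate
    return shapes, displacements, rates


def simulate_bm_shapes(
    config: SimulationConfig,
    tree: TimeTree | None = None,
    rng: np.random.Generator | None = None,
    character_name: str = "character",
    template: np.ndarray | None = None,
) -> tuple[list[SpecimenRecord], SimulationTruth]:
    """Simulate Brownian shape evolution and noisy tip specimens.

    The root shape is a regular k-gon (or a user template); each child shape
    adds an N(0, base_rate * multiplier * dt) perturbation per coordinate;
    each tip emits ``n_specimens_per_tip`` copies with i.i.d. Gaussian noise
    of SD ``noise_sd``. Deterministic under a fixed seed.

    Returns the specimen records (landmark configurations, one TPS block
    each) and the :class:`SimulationTruth`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = generate_tree(config.n_tips, config.tree_kind, config.root_age, rng)
    k = config.k if template is None else len(template)
    root_shape = regular_polygon(k) if template is None else np.asarray(template, float)
    shapes, displacements, rates = _bm_on_tree(
        tree, root_shape, config.base_rate, config.shifts, rng
    )

    records: list[SpecimenRecord] = []
    for leaf in tree.leaves():
        for j in range(config.n_specimens_per_tip):
            pts = shapes[leaf.label] + rng.normal(0.0, config.noise_sd, size=(k, 2))
            if config.jitter:
                angle = rng.uniform(0, 2 * np.pi)
                rot = np.array(
                    [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
                )
                scale = np.exp(rng.normal(0.0, 0.2))
                shift = rng.normal(0.0, 0.5, size=2)
                pts = pts @ rot.T * scale + shift
            records.append(
                SpecimenRecord(
                    specimen_id=f"{leaf.label}_sp{j + 1}",
                    taxon=leaf.label,
                    character_name=character_name,
                    landmarks=pts,
                )
            )
    truth = SimulationTruth(
        tree=tree,
        node_shapes=shapes,
        edge_displacements=displacements,
        realized_rates=rates,
    )
    return records, truth


def simulate_discrete_trait(
    tree: TimeTree,
    states: Sequence[str] = DEFAULT_STATES,
    rate: float = 0.005,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Simulate an equal-rates Markov discrete character on the tree.

    The root state is uniform over ``states``; along each edge the state
    jumps with probability ``1/s - exp(-s * rate * dt)/s`` to each other
    state. Returns the realized state at every node (tips and ancestors).
    """
    if not states:
        raise ValidationError("state set must be non-empty")
    if rate < 0:
        raise ValidationError("rate must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = len(states)
    out = {tree.root.label: states[int(rng.integers(s))]}
    for parent, child in tree.edges():
        dt = tree.elapsed(parent, child)
        decay = np.exp(-s * rate * dt)
        probs = np.full(s, (1.0 - decay) / s)
        probs[states.index(out[parent.label])] += decay
        out[child.label] = states[int(rng.choice(s, p=probs))]
    return out


def make_fixture(
    config: SimulationConfig,
    out_dir: str | Path,
    force: bool = False,
) -> dict:
    """Write a complete synthetic dataset in the pipeline's input formats.

    Emits one TPS file per character, a Newick tree with ``[&age=...]``
    annotations, a specimen group table CSV (feeding types from a simulated
    Markov character), and a ``truth.json`` keyed by the same node labels.

    Returns a dict with ``paths`` (per artifact) and ``truths`` (one
    :class:`SimulationTruth` per character).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ValidationError(
            f"output directory {out_dir} is not empty (pass force=True to overwrite)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    characters = config.characters or {"character": config.k}
    tree_rng = np.random.default_rng([config.seed, 0])
    tree = generate_tree(config.n_tips, config.tree_kind, config.root_age, tree_rng)

    truths: dict[str, SimulationTruth] = {}
    paths: dict[str, Path] = {}
    for idx, (name, k) in enumerate(sorted(characters.items()), start=1):
        sub = np.random.default_rng([config.seed, idx])
        records, truth = simulate_bm_shapes(
            config, tree=tree, rng=sub, character_name=name, template=regular_polygon(k)
        )
        path = out_dir / f"{name}.tps"
        write_tps(records, path)
        truths[name] = truth
        paths[f"tps:{name}"] = path

    states = simulate_discrete_trait(
        tree, config.states, config.discrete_rate,
        np.random.default_rng([config.seed, len(characters) + 1]),
    )
    for truth in truths.values():
        truth.node_states = states

    tree_path = out_dir / "tree.nwk"
    tree_path.write_text(tree.to_newick() + "\n", encoding="utf-8")
    paths["tree"] = tree_path

    rows = ["specimen_id,terminal_group,feeding_type"]
    for leaf in tree.leaves():
        for j in range(config.n_specimens_per_tip):
            rows.append(f"{leaf.label}_sp{j + 1},{leaf.label},{states[leaf.label]}")
    groups_path = out_dir / "groups.csv"
    groups_path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    paths["groups"] = groups_path

    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "seed": config.seed,
                "tree_newick": tree.to_newick(),
                "characters": {name: t.to_jsonable() for name, t in truths.items()},
            },
            indent=1,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    paths["truth"] = truth_path

    return {"paths": paths, "truths": truths, "tree": tree}
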