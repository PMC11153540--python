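"""Readers and writers for the pipeline's input formats.

Supports the tps-Dig dialect of the TPS landmark format (``LM=``, ``CURVES=``,
``POINTS=``, ``ID=``, ``IMAGE=``, ``SCALE=`` lines, plus opaque ``COMMENT=``
metadata), Newick/Nexus time trees with node ages, and CSV tables mapping
specimens to terminal groups and feeding types.

Coordinates are kept in raw digitized units by default; the optional
``SCALE=`` factor is applied only on request, since the downstream Procrustes
superimposition is size-free anyway.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

from morphorate.errors import ParseError, ValidationError

DEFAULT_FEEDING_TYPES = ("omnivory", "coprophagy", "phytophagy", "other")

_ULTRAMETRIC_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Specimens
# ---------------------------------------------------------------------------


@dataclass
class SpecimenRecord:
    """One digitized specimen: fixed landmarks and/or outline curves.

    Parameters
    ----------
    specimen_id : str
        Unique identifier within a dataset (the TPS ``ID=`` field).
    taxon : str
        Taxon or terminal-group name; may be empty when assignment comes
        from a separate group table.
    character_name : str
        Which anatomical character the configuration describes
        (e.g. ``"mandible"``, ``"pronotum"``, ``"elytron"``, ``"hindwing"``).
    curves : list of (m_i, 2) float arrays
        Ordered digitized polylines; each has at least two points.
    landmarks : (k, 2) float array
        Fixed landmark coordinates (may be empty when only curves exist).
    scale : float or None
        Units-per-pixel factor from the TPS ``SCALE=`` line, if present.
    image_ref : str or None
        The TPS ``IMAGE=`` field, carried as opaque metadata.
    comments : list of str
        ``COMMENT=`` lines, carried verbatim.
    """

    specimen_id: str
    taxon: str = ""
    character_name: str = ""
    curves: list[np.ndarray] = field(default_factory=list)
    landmarks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    scale: float | None = None
    image_ref: str | None = None
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float).reshape(-1, 2)
        self.curves = [np.asarray(c, dtype=float).reshape(-1, 2) for c in self.curves]
        for i, c in enumerate(self.curves):
            if len(c) < 2:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: curve {i} has fewer than 2 points"
                )

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks)

    def equals(self, other: "SpecimenRecord", decimals: int = 6) -> bool:
        """Equality of ids, structure, and coordinates to ``decimals`` places."""
        if self.specimen_id != other.specimen_id:
            return False
        if len(self.curves) != len(other.curves):
            return False
        tol = 10.0 ** (-decimals) / 2 * 1.0001
        if self.landmarks.shape != other.landmarks.shape:
            return False
        if self.landmarks.size and not np.allclose(
            self.landmarks, other.landmarks, atol=tol, rtol=0
        ):
            return False
        for a, b in zip(self.curves, other.curves):
            if a.shape != b.shape or not np.allclose(a, b, atol=tol, rtol=0):
                return False
        if (self.scale is None) != (other.scale is None):
            return False
        if self.scale is not None and abs(self.scale - other.scale) > tol:
            return False
        return self.image_ref == other.image_ref


_KEYVAL = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def _parse_point(line: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise ParseError(f"line {lineno}: expected 'x y' coordinate pair, got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric coordinate in {line!r}") from exc


def read_tps(
    path: str | Path | io.TextIOBase,
    character_name: str = "",
    apply_scale: bool = False,
) -> list[SpecimenRecord]:
    """Parse a TPS file into a list of :class:`SpecimenRecord`.

    Each block starts with ``LM=<n>`` followed by ``n`` coordinate lines;
    ``LM=0`` blocks may instead carry ``CURVES=<m>`` sections, each declared
    by ``POINTS=<p>`` and ``p`` coordinate lines. Trailing ``ID=``, ``IMAGE=``,
    ``SCALE=`` and ``COMMENT=`` lines attach to the block. Coordinates follow
    the TPS convention (y axis up).

    With ``apply_scale=True`` all coordinates of a block are multiplied by its
    ``SCALE=`` factor; by default coordinates are returned raw.

    Raises
    ------
    ParseError
        Malformed header or coordinate line (message names the line number).
    ValidationError
        Duplicate specimen ids, or landmark counts differing across blocks.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    lines = text.splitlines()

    records: list[SpecimenRecord] = []
    i = 0
    n_lines = len(lines)

    def next_content(j: int) -> int:
        while j < n_lines and not lines[j].strip():
            j += 1
        return j

    while True:
        i = next_content(i)
        if i >= n_lines:
            break
        m = _KEYVAL.match(lines[i])
        if not m or m.group(1).upper() != "LM":
            raise ParseError(f"line {i + 1}: expected 'LM=' block header, got {lines[i]!r}")
        try:
            n_lm = int(m.group(2))
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: non-integer LM count {m.group(2)!r}") from exc
        if n_lm < 0:
            raise ParseError(f"line {i + 1}: negative LM count")
        i += 1

        landmarks = []
        for _ in range(n_lm):
            i = next_content(i)
            if i >= n_lines:
                raise ParseError(f"line {i}: file ends inside a {n_lm}-landmark block")
            landmarks.append(_parse_point(lines[i], i + 1))
            i += 1

        curves: list[np.ndarray] = []
        meta: dict[str, str] = {}
        comments: list[str] = []

        j = next_content(i)
        if j < n_lines:
            m = _KEYVAL.match(lines[j])
            if m and m.group(1).upper() == "CURVES":
                try:
                    n_curves = int(m.group(2))
                except ValueError as exc:
                    raise ParseError(f"line {j + 1}: non-integer CURVES count") from exc
                i = j + 1
                for c in range(n_curves):
                    i = next_content(i)
                    m = _KEYVAL.match(lines[i]) if i < n_lines else None
                    if not m or m.group(1).upper() != "POINTS":
                        raise ParseError(
                            f"line {i + 1}: expected 'POINTS=' header for curve {c + 1}"
                        )
                    try:
                        n_pts = int(m.group(2))
                    except ValueError as exc:
                        raise ParseError(f"line {i + 1}: non-integer POINTS count") from exc
                    if n_pts < 2:
                        raise ParseError(f"line {i + 1}: curve with fewer than 2 points")
                    i += 1
                    pts = []
                    for _ in range(n_pts):
                        i = next_content(i)
                        if i >= n_lines:
                            raise ParseError(f"line {i}: file ends inside a curve block")
                        pts.append(_parse_point(lines[i], i + 1))
                        i += 1
                    curves.append(np.asarray(pts))

        # trailing metadata lines until the next LM= header
        while True:
            i = next_content(i)
            if i >= n_lines:
                break
            m = _KEYVAL.match(lines[i])
            if not m:
                raise ParseError(f"line {i + 1}: unrecognized line {lines[i]!r}")
            key = m.group(1).upper()
            if key == "LM":
                break
            if key == "COMMENT":
                comments.append(m.group(2))
            elif key in ("ID", "IMAGE", "SCALE"):
                meta[key] = m.group(2)
            else:
                raise ParseError(f"line {i + 1}: unknown TPS key {m.group(1)!r}")
            i += 1

        scale = None
        if "SCALE" in meta:
            try:
                scale = float(meta["SCALE"])
            except ValueError as exc:
                raise ParseError(f"non-numeric SCALE value {meta['SCALE']!r}") from exc
            if scale <= 0:
                raise ValidationError(f"non-positive SCALE value {scale}")

        lm_arr = np.asarray(landmarks, dtype=float).reshape(-1, 2)
        if apply_scale and scale is not None:
            lm_arr = lm_arr * scale
            curves = [c * scale for c in curves]

        records.append(
            SpecimenRecord(
                specimen_id=meta.get("ID", f"specimen_{len(records) + 1}"),
                character_name=character_name,
                curves=curves,
                landmarks=lm_arr,
                scale=scale,
                image_ref=meta.get("IMAGE"),
                comments=comments,
            )
        )

    seen: set[str] = set()
    for rec in records:
        if rec.specimen_id in seen:
            raise ValidationError(f"duplicate specimen id {rec.specimen_id!r}")
        seen.add(rec.specimen_id)
    counts = {rec.n_landmarks for rec in records}
    if len(counts) > 1:
        raise ValidationError(
            f"inconsistent landmark counts across blocks: {sorted(counts)}"
        )
    return records


def write_tps(records: Sequence[SpecimenRecord], path: str | Path | io.TextIOBase) -> None:
    """Write records as TPS blocks (coordinates at 6 decimal places).

    ``read_tps(write_tps(R))`` reproduces ``R`` up to that precision.
    """
    chunks: list[str] = []
    for rec in records:
        lines = [f"LM={rec.n_landmarks}"]
        for x, y in rec.landmarks:
            lines.append(f"{x:.6f} {y:.6f}")
        if rec.curves:
            lines.append(f"CURVES={len(rec.curves)}")
            for curve in rec.curves:
                lines.append(f"POINTS={len(curve)}")
                for x, y in curve:
                    lines.append(f"{x:.6f} {y:.6f}")
        for comment in rec.comments:
            lines.append(f"COMMENT={comment}")
        if rec.image_ref is not None:
            lines.append(f"IMAGE={rec.image_ref}")
        lines.append(f"ID={rec.specimen_id}")
        if rec.scale is not None:
            lines.append(f"SCALE={rec.scale:.6f}")
        chunks.append("\n".join(lines))
    text = "\n".join(chunks) + ("\n" if chunks else "")
    if isinstance(path, (str, Path)):
        Path(path).write_text(text, encoding="utf-8")
    else:
        path.write(text)


# ---------------------------------------------------------------------------
# Time trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """One node of a :class:`TimeTree`."""

    label: str
    age_mean: float = 0.0
    age_lo: float | None = None
    age_hi: float | None = None
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, age={self.age_mean:g})"


class TimeTree:
    """Rooted, dated tree: topology plus node ages in Ma.

    Mean node ages drive all elapsed-time computations; optional 95% CI
    bounds are carried through for reporting only. Unlabeled internal nodes
    receive stable ``NodeK`` labels in preorder so outputs are joinable
    across runs.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._label_autofill()
        self._index = {n.label: n for n in self.preorder()}
        if len(self._index) != len(list(self.preorder())):
            raise ValidationError("duplicate node labels in tree")
        self._validate_ages()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        """Build a dated tree from a Newick string.

        Node ages are taken from ``[&age=..., age_95={lo,hi}]`` comment
        annotations when present on every internal node; otherwise branch
        lengths must describe an ultrametric tree, and ages are computed as
        depth from the tips.
        """
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        def label_of(dnode) -> str:
            if dnode.taxon is not None and dnode.taxon.label:
                return dnode.taxon.label
            return dnode.label or ""

        ages: dict[int, tuple[float, float | None, float | None]] = {}
        for dnode in dtree.preorder_node_iter():
            parsed = _parse_age_comment(dnode.comments)
            if parsed is not None:
                ages[id(dnode)] = parsed

        internal = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
        annotated = all(id(n) in ages for n in internal) and len(internal) > 0

        if not annotated:
            for dnode in dtree.preorder_node_iter():
                el = dnode.edge.length
                if el is not None and el < 0:
                    raise ValidationError(f"negative branch length {el}")
            depths: dict[int, float] = {}
            for dnode in dtree.preorder_node_iter():
                el = dnode.edge.length or 0.0
                depths[id(dnode)] = (
                    0.0 if dnode.parent_node is None else depths[id(dnode.parent_node)] + el
                )
            leaf_depths = [depths[id(n)] for n in dtree.leaf_node_iter()]
            height = max(leaf_depths)
            span = height - min(leaf_depths)
            if height > 0 and span > _ULTRAMETRIC_RTOL * height:
                raise ValidationError(
                    "tree is not ultrametric and carries no age annotations; "
                    "node ages are ambiguous"
                )

        def build(dnode) -> TreeNode:
            if annotated:
                mean, lo, hi = ages.get(id(dnode), (0.0, None, None))
            else:
                mean, lo, hi = height - depths[id(dnode)], None, None
                if abs(mean) < 1e-12:
                    mean = 0.0
            node = TreeNode(label=label_of(dnode), age_mean=mean, age_lo=lo, age_hi=hi)
            for child in dnode.child_nodes():
                cn = build(child)
                cn.parent = node
                node.children.append(cn)
            return node

        return cls(build(dtree.seed_node))

    def _label_autofill(self) -> None:
        k = 0
        for node in self.preorder():
            if not node.is_leaf:
                k += 1
                if not node.label:
                    node.label = f"Node{k}"

    def _validate_ages(self) -> None:
        for parent, child in self.edges():
            if parent.age_mean < child.age_mean - 1e-9:
                raise ValidationError(
                    f"node {child.label!r} (age {child.age_mean}) is older than its "
                    f"parent {parent.label!r} (age {parent.age_mean})"
                )
        for node in self.preorder():
            if node.age_mean < 0:
                raise ValidationError(f"negative age at node {node.label!r}")
            if (
                node.age_lo is not None
                and node.age_hi is not None
                and not (node.age_lo <= node.age_mean + 1e-9 and node.age_mean <= node.age_hi + 1e-9)
            ):
                raise ValidationError(
                    f"age CI [{node.age_lo}, {node.age_hi}] does not bracket the mean "
                    f"{node.age_mean} at node {node.label!r}"
                )

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def edges(self) -> list[tuple[TreeNode, TreeNode]]:
        """All (parent, child) pairs in preorder of the child."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no node labeled {label!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self._index)

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def elapsed(self, parent: TreeNode, child: TreeNode) -> float:
        """Elapsed time on the edge, Ma (mean parent age minus mean child age)."""
        return parent.age_mean - child.age_mean

    def root_to_tip_paths(self) -> list[list[TreeNode]]:
        """One node list per tip, ordered root -> tip."""
        paths = []
        for leaf in self.leaves():
            path = [leaf]
            while path[-1].parent is not None:
                path.append(path[-1].parent)
            paths.append(path[::-1])
        return paths

    # -- output -------------------------------------------------------------

    def to_newick(self, annotate_ages: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            ann = ""
            if annotate_ages:
                ann = f"[&age={node.age_mean:.10g}"
                if node.age_lo is not None and node.age_hi is not None:
                    ann += f",age_95={{{node.age_lo:.10g},{node.age_hi:.10g}}}"
                ann += "]"
            bl = ""
            if node.parent is not None:
                bl = f":{node.parent.age_mean - node.age_mean:.10g}"
            if node.is_leaf:
                return f"{node.label}{ann}{bl}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.label}{ann}{bl}"

        return fmt(self.root) + ";"


_AGE_RE = re.compile(r"age\s*=\s*([0-9.eE+-]+)")
_AGE95_RE = re.compile(r"age_95\s*=\s*\{\s*([0-9.eE+-]+)\s*,\s*([0-9.eE+-]+)\s*\}")


def _parse_age_comment(comments: Iterable[str]) -> tuple[float, float | None, float | None] | None:
    for comment in comments or []:
        m = _AGE_RE.search(comment)
        if m:
            mean = float(m.group(1))
            m95 = _AGE95_RE.search(comment)
            if m95:
                return mean, float(m95.group(1)), float(m95.group(2))
            return mean, None, None
    return None


def read_time_tree(path: str | Path, dialect: str = "newick") -> TimeTree:
    """Read a single rooted dated tree from a Newick or Nexus file."""
    if dialect not in ("newick", "nexus"):
        raise ValueError(f"unknown tree dialect {dialect!r}")
    dtree = dendropy.Tree.get(
        path=str(path),
        schema=dialect,
        suppress_internal_node_taxa=True,
        extract_comment_metadata=False,
    )
    return TimeTree._from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Group tables
# ---------------------------------------------------------------------------


@dataclass
class GroupTable:
    """Maps specimens to terminal groups and terminal groups to feeding types."""

    group_of: dict[str, str]
    feeding_type_of: dict[str, str]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for spec, grp in self.group_of.items():
            out.setdefault(grp, []).append(spec)
        return out

    def labels_for(self, specimen_ids: Sequence[str]) -> np.ndarray:
        """Terminal-group label per specimen, raising on unknown specimens."""
        missing = [s for s in specimen_ids if s not in self.group_of]
        if missing:
            raise ValidationError(f"specimens missing from group table: {missing[:5]}")
        return np.asarray([self.group_of[s] for s in specimen_ids])

    def feeding_labels_for(self, specimen_ids: Sequence[str]) -> np.ndarray:
        return np.asarray(
            [self.feeding_type_of[self.group_of[s]] for s in specimen_ids]
        )


def read_group_table(
    path: str | Path | io.TextIOBase,
    vocabulary: Sequence[str] | None = None,
) -> GroupTable:
    """Read a specimen -> (terminal_group, feeding_type) CSV.

    Requires header columns ``specimen_id``, ``terminal_group``,
    ``feeding_type``. Feeding types must come from ``vocabulary``
    (default: omnivory, coprophagy, phytophagy, other) and be constant
    within each terminal group.
    """
    vocab = set(vocabulary if vocabulary is not None else DEFAULT_FEEDING_TYPES)
    df = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "terminal_group", "feeding_type"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"group table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"specimen assigned to two groups: {dup.iloc[0]!r}")
    bad = df.loc[~df["feeding_type"].isin(vocab), "feeding_type"]
    if len(bad):
        raise ValidationError(
            f"unknown feeding type {bad.iloc[0]!r}; declared vocabulary: {sorted(vocab)}"
        )
    feeding: dict[str, str] = {}
    for grp, sub in df.groupby("terminal_group"):
        types = sub["feeding_type"].unique()
        if len(types) > 1:
            raise ValidationError(
                f"terminal group {grp!r} has inconsistent feeding types {list(types)}"
            )
        feeding[str(grp)] = str(types[0])
    group_of = dict(zip(df["specimen_id"].astype(str), df["terminal_group"].astype(str)))
    return GroupTable(group_of=group_of, feeding_type_of=feeding)


def cross_validate(
    table: GroupTable, tree: TimeTree, specimen_ids: Sequence[str] | None = None
) -> list[str]:
    """Cross-consistency warnings between group table, tree, and specimens.

    Returns human-readable warning strings; an empty list means the three
    inputs are mutually consistent.
    """
    warnings = []
    tips = set(tree.leaf_labels)
    groups = set(table.groups)
    for grp in sorted(groups - tips):
        warnings.append(f"group {grp!r} in table but not a tree terminal")
    for tip in sorted(tips - groups):
        warnings.append(f"tree terminal {tip!r} has no specimens in the group table")
    if specimen_ids is not None:
        for s in specimen_ids:
            if s not in table.group_of:
                warnings.append(f"specimen {s!r} missing from group table")
    return warnings
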