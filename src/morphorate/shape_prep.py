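"""Outline resampling, Procrustes superimposition, and group mean shapes.

Curves are resampled to equally spaced semi-landmarks by arc length and then
treated as fixed landmarks (no sliding); all configurations are superimposed
by Generalized Procrustes Analysis (full Procrustes: unit centroid size, no
reflection) and projected orthogonally onto the tangent space at the
consensus before any linear multivariate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from morphorate.ancestral import NodeShape
from morphorate.errors import DegenerateInputError, ValidationError
from morphorate.io_formats import GroupTable, SpecimenRecord

__all__ = [
    "AlignedShapes",
    "centroid_size",
    "curves_to_landmarks",
    "gpa_align",
    "group_mean_shapes",
    "procrustes_distance",
    "resample_polyline",
]


def resample_polyline(curve: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length spacing.

    The first and last output points coincide with the curve's endpoints.

    Parameters
    ----------
    curve : (m, 2) array
        Ordered vertices, m >= 2, with nonzero total length.
    n : int
        Number of output semi-landmarks, n >= 2.

    Returns
    -------
    (n, 2) array of resampled points.
    """
    curve = np.asarray(curve, dtype=float).reshape(-1, 2)
    if len(curve) < 2:
        raise ValidationError("polyline needs at least 2 points")
    if n < 2:
        raise ValidationError("need at least 2 output points")
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise DegenerateInputError("zero-length curve cannot be resampled")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n)
    x = np.interp(targets, s, curve[:, 0])
    y = np.interp(targets, s, curve[:, 1])
    out = np.column_stack([x, y])
    out[0] = curve[0]
    out[-1] = curve[-1]
    return out


def curves_to_landmarks(
    record: SpecimenRecord,
    resample_counts: Sequence[int],
    reverse_curves: Sequence[bool] | None = None,
) -> np.ndarray:
    """Convert a record's curves into one fixed-landmark configuration.

    Each curve ``i`` is resampled to ``resample_counts[i]`` equally spaced
    semi-landmarks (optionally after reversing its vertex order) and the
    results are concatenated after any existing fixed landmarks. This is the
    semi-landmark-to-landmark conversion step: from here on the points are
    ordinary landmarks.
    """
    if len(resample_counts) != len(record.curves):
        raise ValidationError(
            f"specimen {record.specimen_id!r}: {len(record.curves)} curves but "
            f"{len(resample_counts)} resample counts"
        )
    parts = [record.landmarks] if record.landmarks.size else []
    for i, (curve, n) in enumerate(zip(record.curves, resample_counts)):
        if reverse_curves is not None and reverse_curves[i]:
            curve = curve[::-1]
        parts.append(resample_polyline(curve, n))
    if not parts:
        raise ValidationError(f"specimen {record.specimen_id!r} has no coordinates")
    return np.vstack(parts)


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared deviations of points from their centroid."""
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


@dataclass
class AlignedShapes:
    """Procrustes-superimposed sample of landmark configurations.

    Attributes
    ----------
    coords : (n, 2k) array
        Aligned coordinates, one row per specimen, columns x1,y1,...,xk,yk.
        Each row has its centroid at the origin and unit centroid size.
    centroid_sizes : (n,) array
        Original centroid sizes removed during scaling.
    consensus : (k, 2) array
        Arithmetic mean of the aligned configurations.
    specimen_ids : list of str
        Row order of ``coords``.
    iterations : int
        GPA iterations performed.
    converged : bool
        Whether the consensus moved less than the tolerance.
    """

    coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)
    iterations: int = 0
    converged: bool = True

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1] // 2

    def configuration(self, i: int) -> np.ndarray:
        return self.coords[i].reshape(-1, 2)

    def tangent_coordinates(self) -> np.ndarray:
        """Orthogonal projection of aligned rows onto the tangent space.

        The component of each row along the unit consensus vector is removed
        and replaced by the consensus itself, linearizing shape space at the
        consensus; standard multivariate statistics are valid on the result.
        """
        c = self.consensus.ravel()
        c = c / np.linalg.norm(c)
        proj = self.coords - np.outer(self.coords @ c, c)
        return proj + c * np.linalg.norm(self.consensus.ravel())

    def to_frame(self):
        """Aligned coordinates as a DataFrame (columns x1,y1,...,xk,yk)."""
        import pandas as pd

        cols = [f"{axis}{i + 1}" for i in range(self.k) for axis in ("x", "y")]
        return pd.DataFrame(self.coords, index=self.specimen_ids, columns=cols)


def _center_and_scale(config: np.ndarray) -> np.ndarray:
    centered = config - config.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs <= 0:
        raise DegenerateInputError("configuration with zero centroid size")
    return centered / cs


def _optimal_rotation(config: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||config @ R - reference||_F."""
    h = config.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Deterministic rotation pinning the sample's overall orientation.

    Rotates the consensus onto its principal axes with signs fixed by the
    largest-magnitude coordinate, so repeated alignment of already-aligned
    data is an exact fixed point.
    """
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    r = vt.T
    if np.linalg.det(r) < 0:
        r[:, 1] = -r[:, 1]
    first = consensus @ r[:, 0]
    if first[np.argmax(np.abs(first))] < 0:
        r = -r  # 180-degree rotation keeps det +1
    return r


def gpa_align(
    configs: Sequence[np.ndarray],
    specimen_ids: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapes:
    """Generalized Procrustes Analysis of 2-D landmark configurations.

    Removes translation (centroid to origin), size (unit centroid size) and
    rotation (proper rotations only, no reflection) by iteratively rotating
    every configuration to the current consensus and recomputing the
    consensus until it moves less than ``tol`` or ``max_iter`` is reached.
    """
    if len(configs) < 2:
        raise ValidationError("GPA needs at least 2 configurations")
    ks = {np.asarray(c).reshape(-1, 2).shape[0] for c in configs}
    if len(ks) != 1:
        raise ValidationError(f"configurations differ in landmark count: {sorted(ks)}")
    k = ks.pop()
    if k < 3:
        raise ValidationError("configurations need at least 3 landmarks")

    arrs = [np.asarray(c, dtype=float).reshape(-1, 2) for c in configs]
    if any(np.isnan(a).any() for a in arrs):
        raise ValidationError("NaN coordinates in input configurations")
    sizes = np.array([centroid_size(a) for a in arrs])
    shapes = [_center_and_scale(a) for a in arrs]

    reference = shapes[0]
    consensus = reference
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        shapes = [s @ _optimal_rotation(s, consensus) for s in shapes]
        new_consensus = np.mean(shapes, axis=0)
        ncs = np.sqrt((new_consensus**2).sum())
        if ncs <= 0:
            raise DegenerateInputError("degenerate consensus (zero centroid size)")
        new_consensus = new_consensus / ncs
        delta = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if delta < tol:
            converged = True
            break

    r = _canonical_orientation(np.mean(shapes, axis=0))
    shapes = [s @ r for s in shapes]

    coords = np.stack([s.ravel() for s in shapes])
    ids = list(specimen_ids) if specimen_ids is not None else [
        f"specimen_{i + 1}" for i in range(len(shapes))
    ]
    return AlignedShapes(
        coords=coords,
        centroid_sizes=sizes,
        consensus=np.mean(shapes, axis=0),
        specimen_ids=ids,
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    Both are centered, scaled to unit centroid size and optimally rotated
    (no reflection) before taking the Euclidean norm of the difference.
    """
    sa = _center_and_scale(np.asarray(a, dtype=float).reshape(-1, 2))
    sb = _center_and_scale(np.asarray(b, dtype=float).reshape(-1, 2))
    rot = _optimal_rotation(sa, sb)
    return float(np.linalg.norm(sa @ rot - sb))


def group_mean_shapes(
    aligned: AlignedShapes,
    groups: GroupTable | Mapping[str, str],
    use_tangent: bool = True,
) -> dict[str, NodeShape]:
    """Per-terminal-group arithmetic mean of aligned (tangent) coordinates.

    The returned mean shapes are labeled by terminal group and serve as the
    tip values for ancestral shape reconstruction.
    """
    group_of = groups.group_of if isinstance(groups, GroupTable) else dict(groups)
    labels = []
    for sid in aligned.specimen_ids:
        if sid not in group_of:
            raise ValidationError(f"specimen {sid!r} not assigned to any group")
        labels.append(group_of[sid])
    labels = np.asarray(labels)
    data = aligned.tangent_coordinates() if use_tangent else aligned.coords
    out: dict[str, NodeShape] = {}
    for grp in sorted(set(labels)):
        mask = labels == grp
        if not mask.any():
            raise ValidationError(f"group {grp!r} has no specimens")
        mean = data[mask].mean(axis=0)
        out[grp] = NodeShape(node_label=grp, points=mean.reshape(-1, 2), is_terminal=True)
    return out
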