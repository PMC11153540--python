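"""Branch-wise morphological rate indices on a dated tree.

Two indices summarize morphological diversification in time:

* **DR (deformation ratio)** — per branch: the morphological distance
  between the parent and child node shapes (Mahalanobis in CVA space, or
  Euclidean in Procrustes/tangent units) divided by the elapsed mean
  divergence time of the branch, giving distance per Ma.
* **SGR (sequential growth rate)** — along each root-to-tip lineage: the
  relative change between consecutive DR values,
  ``SGR_i = (DR_{i+1} - DR_i) / DR_i``, dimensionless.

Step-chart tables expose each edge's DR as a constant over its age interval,
and trend curves (polynomial least squares or LOESS) summarize SGR against
age for plotting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from morphorate.ancestral import NodeShape
from morphorate.errors import ValidationError
from morphorate.ordination import CVAResult

__all__ = [
    "EdgeDeformation",
    "SGRSeries",
    "edge_deformations",
    "fit_trend",
    "sgr_along_paths",
    "step_chart_series",
]

logger = logging.getLogger(__name__)

#: Elapsed time substituted for zero-length edges when configured.
DT_EPSILON = 1e-8


@dataclass
class EdgeDeformation:
    """Per-branch deformation record.

    ``dr_* = d_* / dt`` exactly, with ``dt`` the difference of mean node
    ages (Ma); optional CI bounds on the elapsed time are carried for
    reporting only.
    """

    parent_label: str
    child_label: str
    d_mahalanobis: float
    d_euclidean: float
    dt: float
    dr_mahalanobis: float
    dr_euclidean: float
    parent_age: float
    child_age: float
    dt_ci: tuple[float, float] | None = None

    def dr(self, variant: str) -> float:
        if variant == "mahalanobis":
            return self.dr_mahalanobis
        if variant == "euclidean":
            return self.dr_euclidean
        raise ValueError(f"unknown DR variant {variant!r}")


def edge_deformations(
    tree,
    node_shapes: Mapping[str, NodeShape],
    distance_space: CVAResult | None = None,
    zero_dt: str = "error",
) -> list[EdgeDeformation]:
    """Compute both DR variants for every branch of the tree.

    Parameters
    ----------
    tree : TimeTree
    node_shapes : mapping node label -> NodeShape
        Shapes at every node (terminal group means and reconstructed
        ancestors) in a common tangent space.
    distance_space : CVAResult, optional
        Space for Mahalanobis distances: node shapes are projected with the
        CVA reduction fitted on terminal specimens and measured under the
        terminal pooled within-group covariance. Without it the Mahalanobis
        fields fall back to the Euclidean values.
    zero_dt : {"error", "epsilon"}
        Whether a non-positive elapsed time raises or is replaced by 1e-8 Ma
        (logged).

    Returns
    -------
    One :class:`EdgeDeformation` per tree edge, in preorder of the child.
    """
    missing = [n.label for n in tree.preorder() if n.label not in node_shapes]
    if missing:
        raise ValidationError(f"nodes without shapes: {missing[:5]}")
    out = []
    for parent, child in tree.edges():
        dt = tree.elapsed(parent, child)
        if dt <= 0:
            if zero_dt == "epsilon":
                logger.warning(
                    "edge %s -> %s has elapsed time %g; substituting %g Ma",
                    parent.label, child.label, dt, DT_EPSILON,
                )
                dt = DT_EPSILON
            else:
                raise ValidationError(
                    f"edge {parent.label!r} -> {child.label!r} has non-positive "
                    f"elapsed time {dt}"
                )
        pa = node_shapes[parent.label].flat
        ch = node_shapes[child.label].flat
        d_euc = float(np.linalg.norm(pa - ch))
        if distance_space is not None:
            d_mah = distance_space.mahalanobis_between(pa, ch)
        else:
            d_mah = d_euc
        dt_ci = None
        if (
            parent.age_lo is not None
            and parent.age_hi is not None
            and child.age_lo is not None
            and child.age_hi is not None
        ):
            dt_ci = (parent.age_lo - child.age_hi, parent.age_hi - child.age_lo)
        out.append(
            EdgeDeformation(
                parent_label=parent.label,
                child_label=child.label,
                d_mahalanobis=d_mah,
                d_euclidean=d_euc,
                dt=dt,
                dr_mahalanobis=d_mah / dt,
                dr_euclidean=d_euc / dt,
                parent_age=parent.age_mean,
                child_age=child.age_mean,
                dt_ci=dt_ci,
            )
        )
    return out


def edges_frame(edges: Sequence[EdgeDeformation]) -> pd.DataFrame:
    """Edge deformations as a tidy table."""
    return pd.DataFrame(
        {
            "parent": [e.parent_label for e in edges],
            "child": [e.child_label for e in edges],
            "parent_age": [e.parent_age for e in edges],
            "child_age": [e.child_age for e in edges],
            "d_mahalanobis": [e.d_mahalanobis for e in edges],
            "d_euclidean": [e.d_euclidean for e in edges],
            "dt": [e.dt for e in edges],
            "dr_mahalanobis": [e.dr_mahalanobis for e in edges],
            "dr_euclidean": [e.dr_euclidean for e in edges],
        }
    )


@dataclass
class SGRSeries:
    """Sequential growth rates along one root-to-tip lineage.

    ``sgr_values[i] = (dr_values[i+1] - dr_values[i]) / dr_values[i]``; when
    the previous DR is zero the entry is NaN (missing), never infinite.
    ``midpoint_ages`` are edge interval midpoints in Ma (for plotting; the
    i-th SGR is conventionally plotted at the midpoint of edge i+1).
    """

    path: list[str]
    dr_values: np.ndarray
    sgr_values: np.ndarray
    midpoint_ages: np.ndarray

    @property
    def tip_label(self) -> str:
        return self.path[-1]


def sgr_along_paths(
    tree,
    edges: Sequence[EdgeDeformation],
    variant: str = "mahalanobis",
) -> list[SGRSeries]:
    """One SGR series per root-to-tip path, edges ordered by decreasing age.

    Basal edges shared between tips are repeated in every path that crosses
    them. SGR entries whose previous DR is zero are NaN with a logged
    warning.
    """
    by_child = {e.child_label: e for e in edges}
    series = []
    for path in tree.root_to_tip_paths():
        labels = [n.label for n in path]
        path_edges = []
        for child_label in labels[1:]:
            if child_label not in by_child:
                raise ValidationError(f"no DR computed for edge above {child_label!r}")
            path_edges.append(by_child[child_label])
        dr = np.array([e.dr(variant) for e in path_edges])
        mid = np.array([(e.parent_age + e.child_age) / 2 for e in path_edges])
        sgr = np.full(max(len(dr) - 1, 0), np.nan)
        for i in range(len(sgr)):
            if dr[i] > 0:
                sgr[i] = (dr[i + 1] - dr[i]) / dr[i]
            else:
                logger.warning(
                    "SGR undefined after edge %s -> %s (previous DR is zero)",
                    path_edges[i].parent_label, path_edges[i].child_label,
                )
        series.append(
            SGRSeries(path=labels, dr_values=dr, sgr_values=sgr, midpoint_ages=mid)
        )
    return series


def sgr_frame(series: Sequence[SGRSeries]) -> pd.DataFrame:
    """SGR series as a tidy table (one row per lineage edge transition)."""
    rows = []
    for s in series:
        for i, val in enumerate(s.sgr_values):
            rows.append(
                {
                    "lineage": s.tip_label,
                    "edge_index": i + 1,
                    "from_child": s.path[i + 1],
                    "to_child": s.path[i + 2],
                    "age": s.midpoint_ages[i + 1],
                    "sgr": val,
                }
            )
    return pd.DataFrame(rows, columns=["lineage", "edge_index", "from_child", "to_child", "age", "sgr"])


def step_chart_series(
    edges: Sequence[EdgeDeformation],
    tree,
    variant: str = "mahalanobis",
) -> pd.DataFrame:
    """Piecewise-constant DR series per root-to-tip lineage.

    Each edge contributes its DR as a constant over the age interval
    [child age, parent age]; the ``lineage`` column (tip label) keeps
    overlapping branches of different lineages distinguishable.
    """
    by_child = {e.child_label: e for e in edges}
    rows = []
    for path in tree.root_to_tip_paths():
        tip = path[-1].label
        for node in path[1:]:
            e = by_child[node.label]
            rows.append(
                {
                    "lineage": tip,
                    "parent": e.parent_label,
                    "child": e.child_label,
                    "age_start": e.child_age,
                    "age_end": e.parent_age,
                    "dr": e.dr(variant),
                }
            )
    return pd.DataFrame(rows, columns=["lineage", "parent", "child", "age_start", "age_end", "dr"])


def fit_trend(
    points: Sequence[tuple[float, float]] | np.ndarray,
    method: str = "ols_poly",
    degree: int = 2,
    loess_frac: float = 0.5,
    n_grid: int = 200,
) -> dict:
    """Deterministic best-fit curve through (age, SGR) points.

    ``ols_poly`` fits a degree-``degree`` polynomial by least squares and
    reports its coefficients (highest order first); ``loess`` runs a
    locally weighted regression with span ``loess_frac``. Either way the
    curve is sampled on a uniform age grid for plotting.

    Returns a dict with keys ``method``, ``grid``, ``fitted``, and (for
    polynomials) ``coefficients``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if not np.isfinite(pts).all():
        raise ValidationError("non-finite ages in trend input")
    x, y = pts[:, 0], pts[:, 1]
    if method == "ols_poly":
        if len(pts) < degree + 1:
            raise ValidationError(
                f"need at least {degree + 1} points for a degree-{degree} polynomial"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            coeffs = np.polyfit(x, y, degree)
        grid = np.linspace(x.min(), x.max(), n_grid)
        return {
            "method": "ols_poly",
            "degree": degree,
            "coefficients": coeffs,
            "grid": grid,
            "fitted": np.polyval(coeffs, grid),
        }
    if method == "loess":
        if len(pts) < 3:
            raise ValidationError("need at least 3 points for loess")
        from statsmodels.nonparametric.smoothers_lowess import lowess

        smoothed = lowess(y, x, frac=loess_frac, return_sorted=True)
        grid = np.linspace(x.min(), x.max(), n_grid)
        fitted = np.interp(grid, smoothed[:, 0], smoothed[:, 1])
        return {"method": "loess", "frac": loess_frac, "grid": grid, "fitted": fitted}
    raise ValueError(f"unknown trend method {method!r}")
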