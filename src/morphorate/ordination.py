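"""Ordination and discrimination of aligned shapes: PCA, CVA, confusion matrices.

Procrustes shape data are rank-deficient (at most 2k - 4 informative
dimensions, frequently fewer than the specimen count), so canonical variate
analysis is computed in a PCA-reduced subspace in which the pooled
within-group covariance is invertible; Mahalanobis distances between group
means are taken in that subspace, Euclidean distances in the original
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from morphorate.errors import ValidationError

__all__ = ["CVAResult", "ConfusionMatrix", "OrdinationResult", "classify_confusion", "cva", "pca"]

_RANK_TOL = 1e-9


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    """Accept an AlignedShapes (uses tangent coordinates) or a plain matrix."""
    if hasattr(data, "tangent_coordinates"):
        return np.asarray(data.tangent_coordinates(), dtype=float), list(data.specimen_ids)
    arr = np.asarray(data, dtype=float)
    return arr, [f"specimen_{i + 1}" for i in range(arr.shape[0])]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading per axis positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


@dataclass
class OrdinationResult:
    """Principal component decomposition of a centered data matrix.

    ``scores = (data - mean) @ loadings``; eigenvalues are sample variances
    along each axis (non-increasing); ``variance_explained`` are fractions of
    the total variance and sum to 1 over all retained axes (0 for constant
    data, which is flagged by ``degenerate``).
    """

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    mean: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)
    degenerate: bool = False

    def project(self, rows: np.ndarray, n_axes: int | None = None) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        load = self.loadings if n_axes is None else self.loadings[:, :n_axes]
        return (rows - self.mean) @ load


def pca(data, n_axes: int | None = None) -> OrdinationResult:
    """Principal component analysis of aligned shapes (or any data matrix).

    Axes are eigenvectors of the sample covariance, returned with a
    deterministic sign convention; at most min(n - 1, p) axes carry variance.
    """
    x, ids = _as_matrix(data)
    n, p = x.shape
    if n < 3:
        raise ValidationError("PCA needs at least 3 specimens")
    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (n - 1)
    m = min(n - 1, p) if n_axes is None else min(n_axes, min(n - 1, p))
    eig = eig[:m]
    loadings = _fix_signs(vt[:m].T)
    total = float(centered.var(axis=0, ddof=1).sum())
    degenerate = total <= _RANK_TOL * max(1.0, float(np.abs(x).max()) ** 2)
    if degenerate:
        var_frac = np.zeros(m)
    else:
        var_frac = eig / total
    return OrdinationResult(
        scores=centered @ loadings,
        loadings=loadings,
        eigenvalues=eig,
        variance_explained=var_frac,
        mean=mean,
        specimen_ids=ids,
        degenerate=degenerate,
    )


@dataclass
class CVAResult:
    """Canonical variate analysis in a PCA-reduced subspace.

    ``reduction_mean``/``reduction_components`` map full-space rows into the
    reduced space where the pooled within-group covariance ``within_cov`` is
    invertible; ``axes`` are the canonical directions there (at most
    min(g - 1, reduced dimension)). ``mahalanobis`` and ``euclidean`` are
    symmetric group-by-group distance matrices (Mahalanobis in the reduced
    space, Euclidean between full-space group means).
    """

    groups: list[str]
    axes: np.ndarray
    scores: np.ndarray
    centroids: np.ndarray
    within_cov: np.ndarray
    mahalanobis: pd.DataFrame
    euclidean: pd.DataFrame
    reduction_mean: np.ndarray
    reduction_components: np.ndarray
    group_means_reduced: np.ndarray
    group_means_full: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def project(self, rows: np.ndarray) -> np.ndarray:
        """Project full-space rows into the reduced (Mahalanobis) space."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return (rows - self.reduction_mean) @ self.reduction_components

    def mahalanobis_between(self, a: np.ndarray, b: np.ndarray) -> float:
        """Mahalanobis distance between two full-space shape vectors.

        Both are projected into the reduced space and measured under the
        pooled within-group covariance of the fitted terminal specimens.
        """
        diff = (self.project(a) - self.project(b)).ravel()
        cf = cho_factor(self.within_cov)
        return float(np.sqrt(diff @ cho_solve(cf, diff)))


def cva(data, labels: Sequence[str], prior_reduction: int | str = "auto") -> CVAResult:
    """Canonical variate analysis with pairwise Mahalanobis distances.

    Parameters
    ----------
    data : AlignedShapes or (n, p) array
        Specimen coordinates (tangent space when an AlignedShapes is given).
    labels : sequence of str
        Group label per specimen; every group needs >= 2 specimens.
    prior_reduction : int or "auto"
        Dimension of the PCA subspace in which the pooled within-group
        covariance is estimated. "auto" keeps min(n - g, data rank).

    Returns
    -------
    CVAResult with canonical axes, per-specimen canonical scores, group
    centroids, and pairwise Mahalanobis/Euclidean distance matrices.
    """
    x, ids = _as_matrix(data)
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != x.shape[0]:
        raise ValidationError("one label per specimen required")
    groups = sorted(set(labels))
    g = len(groups)
    if g < 2:
        raise ValidationError("CVA needs at least 2 groups")
    counts = {grp: int((labels == grp).sum()) for grp in groups}
    small = [grp for grp, c in counts.items() if c < 2]
    if small:
        raise ValidationError(f"groups with fewer than 2 specimens: {small}")
    n = x.shape[0]

    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > _RANK_TOL * max(s[0], 1.0)).sum()) if s.size else 0
    if prior_reduction == "auto":
        # one df is held back so the pooled covariance stays invertible when
        # a specimen is left out during cross-validated classification
        r = min(n - g - 1, rank)
    else:
        r = int(prior_reduction)
        if r < 1 or r > rank:
            raise ValidationError(f"prior_reduction must be in [1, {rank}]")
    if r < 1:
        raise ValidationError("no informative dimensions left after reduction")
    components = _fix_signs(vt[:r].T)
    y = centered @ components

    means_reduced = np.stack([y[labels == grp].mean(axis=0) for grp in groups])
    means_full = np.stack([x[labels == grp].mean(axis=0) for grp in groups])
    within = np.zeros((r, r))
    for gi, grp in enumerate(groups):
        resid = y[labels == grp] - means_reduced[gi]
        within += resid.T @ resid
    within /= n - g

    evals = np.linalg.eigvalsh(within)
    if evals[0] <= evals[-1] * 1e-10 or evals[-1] <= 0:
        raise ValidationError(
            "pooled within-group covariance is singular after reduction; "
            "reduce dimensions further (lower prior_reduction)"
        )

    grand = y.mean(axis=0)
    between = np.zeros((r, r))
    for gi, grp in enumerate(groups):
        d = means_reduced[gi] - grand
        between += counts[grp] * np.outer(d, d)
    between /= max(g - 1, 1)

    n_can = min(g - 1, r)
    eigvals, eigvecs = eigh(between, within)
    order = np.argsort(eigvals)[::-1][:n_can]
    axes = _fix_signs(eigvecs[:, order])

    maha = np.zeros((g, g))
    cf = cho_factor(within)
    for i in range(g):
        for j in range(i + 1, g):
            d = means_reduced[i] - means_reduced[j]
            maha[i, j] = maha[j, i] = np.sqrt(d @ cho_solve(cf, d))
    euc = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            euc[i, j] = euc[j, i] = np.linalg.norm(means_full[i] - means_full[j])

    return CVAResult(
        groups=groups,
        axes=axes,
        scores=y @ axes,
        centroids=means_reduced @ axes,
        within_cov=within,
        mahalanobis=pd.DataFrame(maha, index=groups, columns=groups),
        euclidean=pd.DataFrame(euc, index=groups, columns=groups),
        reduction_mean=mean,
        reduction_components=components,
        group_means_reduced=means_reduced,
        group_means_full=means_full,
        specimen_ids=ids,
    )


@dataclass
class ConfusionMatrix:
    """Group classification summary (true rows x predicted columns)."""

    counts: pd.DataFrame
    per_group_correct: pd.Series
    total_correct: float
    mode: str

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)


def _nearest_centroid(
    y: np.ndarray, means: np.ndarray, within: np.ndarray
) -> np.ndarray:
    cf = cho_factor(within)
    d2 = np.empty((y.shape[0], means.shape[0]))
    for gi in range(means.shape[0]):
        diff = y - means[gi]
        d2[:, gi] = np.einsum("ij,ij->i", diff, cho_solve(cf, diff.T).T)
    return d2.argmin(axis=1)


def classify_confusion(
    cvares: CVAResult,
    data,
    labels: Sequence[str],
    mode: str = "leave_one_out",
) -> ConfusionMatrix:
    """Confusion matrix for nearest-centroid Mahalanobis classification.

    Each specimen is assigned to the group whose mean is nearest in the
    reduced space under the pooled within-group covariance. In
    ``leave_one_out`` mode, group means and the pooled covariance are refit
    without the focal specimen (the PCA reduction stays fixed);
    ``resubstitution`` classifies against the full-sample fit.
    """
    if mode not in ("resubstitution", "leave_one_out"):
        raise ValueError(f"unknown classification mode {mode!r}")
    x, _ = _as_matrix(data)
    labels = np.asarray([str(l) for l in labels])
    groups = cvares.groups
    gidx = {grp: i for i, grp in enumerate(groups)}
    y = cvares.project(x)
    n = y.shape[0]
    g = len(groups)

    if mode == "resubstitution":
        pred = _nearest_centroid(y, cvares.group_means_reduced, cvares.within_cov)
    else:
        pred = np.empty(n, dtype=int)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            yk, lk = y[keep], labels[keep]
            means = np.stack([yk[lk == grp].mean(axis=0) for grp in groups])
            within = np.zeros((y.shape[1], y.shape[1]))
            for gi, grp in enumerate(groups):
                resid = yk[lk == grp] - means[gi]
                within += resid.T @ resid
            within /= len(yk) - g
            pred[i] = _nearest_centroid(y[i : i + 1], means, within)[0]

    counts = np.zeros((g, g), dtype=int)
    for i in range(n):
        counts[gidx[labels[i]], pred[i]] += 1
    counts_df = pd.DataFrame(counts, index=groups, columns=groups)
    row_sums = counts_df.sum(axis=1)
    per_group = pd.Series(np.diag(counts) / np.maximum(row_sums, 1), index=groups)
    total = float(np.trace(counts)) / n
    return ConfusionMatrix(
        counts=counts_df, per_group_correct=per_group, total_correct=total, mode=mode
    )
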