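"""Spatial neighborhood statistics for per-cell FRET ratios.

Implements the neighbor analysis applied to segmented neurons: Euclidean
distances between cell centroids in physical μm, kNN and fixed-radius
neighborhoods, each cell's neighbor-mean ratio, and the Pearson
correlation between a cell's 720/670 ratio and the mean ratio of its
neighbors — the statistic used to detect spatial clustering of
γ-secretase activity.  A seeded permutation test provides a
distribution-free confirmation of the parametric p-value.

All functions here operate on plain arrays (labels, centroids, ratios) so
that the imaging pipeline and the synthetic ground-truth oracle share one
code path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodSpec",
    "NeighborhoodAssignment",
    "CorrelationResult",
    "pairwise_distances",
    "assign_neighbors",
    "pearson_correlation",
    "correlate_with_neighbors",
    "permutation_null",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """How a cell's neighborhood is defined.

    ``knn`` mode takes the ``k`` nearest other cells by centroid distance
    (default 5, with 2 and 10 as standard alternates); ``radius`` mode
    takes every other cell within ``radius_um`` (inclusive, default 20 μm).
    """

    mode: Literal["knn", "radius"] = "knn"
    k: int = 5
    radius_um: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("knn", "radius"):
            raise ValueError(f"unknown neighborhood mode {self.mode!r}")
        if self.mode == "knn" and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode == "radius" and self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")

    def describe(self) -> str:
        return f"knn(k={self.k})" if self.mode == "knn" else f"radius({self.radius_um}um)"


@dataclass
class NeighborhoodAssignment:
    """One cell's neighbor set and the neighbors' mean ratio."""

    cell_label: int
    neighbor_labels: list[int]
    neighbor_mean_ratio: float
    usable: bool


@dataclass
class CorrelationResult:
    """Pearson correlation between cell ratios and neighbor-mean ratios.

    ``degenerate`` flags zero variance in either variable, in which case
    ``r`` and ``p_value`` are NaN and ``significant`` is False.
    """

    r: float
    p_value: float
    n: int
    alpha: float = 0.001
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "r": None if self.degenerate else float(self.r),
            "p_value": None if self.degenerate else float(self.p_value),
            "n": int(self.n),
            "alpha": float(self.alpha),
            "significant": bool(self.significant),
            "degenerate": bool(self.degenerate),
        }


def pairwise_distances(centroids_um: np.ndarray, *, projected_2d: bool = False) -> np.ndarray:
    """Symmetric matrix of Euclidean distances between centroids, in μm.

    Centroids are (n, 3) arrays ordered (z, y, x) in physical μm.  With
    ``projected_2d`` the z coordinate is ignored (lateral distances only).
    """
    pts = np.asarray(centroids_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("centroids_um must be an (n, 3) array of (z, y, x) in um")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 centroids")
    if projected_2d:
        pts = pts[:, 1:]
    d = cdist(pts, pts)
    np.fill_diagonal(d, 0.0)
    return d


def assign_neighbors(
    labels: Sequence[int],
    centroids_um: np.ndarray,
    ratios: Sequence[float],
    spec: NeighborhoodSpec,
    *,
    projected_2d: bool = False,
) -> list[NeighborhoodAssignment]:
    """Assign each cell its neighborhood and neighbor-mean ratio.

    kNN mode returns exactly ``k`` neighbors per cell, nearest first, with
    distance ties broken by ascending label so results are deterministic
    across platforms.  Radius mode returns all other cells within
    ``radius_um`` (inclusive); cells with an empty radius neighborhood are
    marked unusable.  A cell is never its own neighbor.
    """
    labels = np.asarray(labels, dtype=int)
    ratios = np.asarray(ratios, dtype=float)
    n = len(labels)
    if len(ratios) != n or len(centroids_um) != n:
        raise ValueError("labels, centroids and ratios must have equal length")
    if spec.mode == "knn" and n < spec.k + 1:
        raise ValueError(
            f"kNN neighborhoods with k={spec.k} need at least {spec.k + 1} cells, got {n}"
        )
    d = pairwise_distances(centroids_um, projected_2d=projected_2d)

    out: list[NeighborhoodAssignment] = []
    if spec.mode == "knn":
        # lexsort: primary key distance, secondary key label (deterministic ties)
        for i in range(n):
            order = np.lexsort((labels, d[i]))
            order = order[order != i][: spec.k]
            out.append(
                NeighborhoodAssignment(
                    cell_label=int(labels[i]),
                    neighbor_labels=[int(labels[j]) for j in order],
                    neighbor_mean_ratio=float(np.mean(ratios[order])),
                    usable=True,
                )
            )
    else:
        for i in range(n):
            mask = (d[i] <= spec.radius_um) & (np.arange(n) != i)
            idx = np.flatnonzero(mask)
            idx = idx[np.lexsort((labels[idx], d[i, idx]))]
            usable = idx.size > 0
            out.append(
                NeighborhoodAssignment(
                    cell_label=int(labels[i]),
                    neighbor_labels=[int(labels[j]) for j in idx],
                    neighbor_mean_ratio=float(np.mean(ratios[idx])) if usable else math.nan,
                    usable=usable,
                )
            )
    return out


def pearson_correlation(
    x_values: Sequence[float], y_values: Sequence[float], alpha: float = 0.001
) -> CorrelationResult:
    """Sample Pearson r with a two-sided p-value (t transform, n−2 df).

    Zero variance in either input yields an explicit degenerate result
    rather than a silent NaN.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"Pearson correlation needs at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("degenerate variance: Pearson r is undefined")
        return CorrelationResult(r=math.nan, p_value=math.nan, n=n, alpha=alpha, degenerate=True)
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n, alpha=alpha)


def correlate_with_neighbors(
    labels: Sequence[int],
    centroids_um: np.ndarray,
    ratios: Sequence[float],
    spec: NeighborhoodSpec,
    alpha: float = 0.001,
    *,
    projected_2d: bool = False,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Correlate each cell's ratio with its neighbors' mean ratio.

    Returns the :class:`CorrelationResult` over all usable cells and the
    per-cell scatter table (label, ratio, neighbor_mean_ratio, n_neighbors)
    used for the standard scatter-plot rendering of the analysis.
    """
    assignments = assign_neighbors(labels, centroids_um, ratios, spec, projected_2d=projected_2d)
    ratios = np.asarray(ratios, dtype=float)
    rows = []
    for i, a in enumerate(assignments):
        if a.usable:
            rows.append(
                {
                    "label": a.cell_label,
                    "ratio": float(ratios[i]),
                    "neighbor_mean_ratio": a.neighbor_mean_ratio,
                    "n_neighbors": len(a.neighbor_labels),
                }
            )
    table = pd.DataFrame(rows, columns=["label", "ratio", "neighbor_mean_ratio", "n_neighbors"])
    if len(table) < 3:
        raise ValueError(
            f"correlation needs at least 3 usable cells, got {len(table)} "
            f"for neighborhood {spec.describe()}"
        )
    result = pearson_correlation(table["ratio"], table["neighbor_mean_ratio"], alpha=alpha)
    return result, table


def permutation_null(
    labels: Sequence[int],
    centroids_um: np.ndarray,
    ratios: Sequence[float],
    spec: NeighborhoodSpec,
    n_perm: int = 999,
    seed: int = 0,
    *,
    projected_2d: bool = False,
) -> tuple[float, np.ndarray, CorrelationResult]:
    """Permutation test of the neighbor-mean correlation.

    Ratios are permuted across the fixed cell positions ``n_perm`` times;
    the neighbor means and Pearson r are recomputed for each permutation.
    The empirical two-sided p-value is ``(1 + #{|r_perm| >= |r_obs|}) /
    (n_perm + 1)``.  Returns (empirical p, null r distribution, observed
    result).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(labels, dtype=int)
    ratios = np.asarray(ratios, dtype=float)
    n = len(labels)
    assignments = assign_neighbors(labels, centroids_um, ratios, spec, projected_2d=projected_2d)
    usable = np.array([a.usable for a in assignments])
    if usable.sum() < 3:
        raise ValueError("permutation test needs at least 3 usable cells")
    # row-normalized neighbor matrix: neighbor means are W @ values
    label_to_pos = {int(l): i for i, l in enumerate(labels)}
    rows, cols, weights = [], [], []
    for i, a in enumerate(assignments):
        for l in a.neighbor_labels:
            rows.append(i)
            cols.append(label_to_pos[l])
            weights.append(1.0 / len(a.neighbor_labels))
    W = sparse.csr_matrix((weights, (rows, cols)), shape=(n, n))

    def _r_batch(vals: np.ndarray) -> np.ndarray:
        """Pearson r of (x, Wx) over usable cells for each row of vals."""
        x = vals[:, usable]
        y = (W @ vals.T).T[:, usable]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (xc * yc).sum(axis=1) / denom

    r_obs = float(_r_batch(ratios[None])[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(ratios) for _ in range(n_perm)])
    null = _r_batch(perms)
    p_emp = (1.0 + np.sum(np.abs(null) >= abs(r_obs))) / (n_perm + 1.0)
    observed = CorrelationResult(r=r_obs, p_value=p_emp, n=int(usable.sum()))
    return float(p_emp), null, observed
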