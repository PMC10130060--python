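"""Steady-state RNA velocity, cosine velocity graph, fate potential, and
simplex arrow binning.

The steady-state model treats splicing as a two-step process with splicing
rate beta = 1 and per-gene degradation rate gamma: at equilibrium the
unspliced abundance satisfies u = gamma * s, so the residual v = u - gamma * s
is the inferred direction of change (positive for genes being induced).
gamma is fitted by regression through the origin on the cells at the extremes
of total (s + u) abundance, where the steady-state assumption is most
defensible. The velocity graph scores, for each cell i and each of its KNN
neighbors j, how well v_i points toward neighbor j's expression state
(clipped cosine, in [0, 1]).

The fate potential of cell i toward fate f is the average velocity-graph edge
weight from i to all cells of apex cluster f (absent edges counting as zero),
normalized within each cell so the three potentials sum to one. For display,
cells are binned on the projected simplex into a fixed number of grid
locations (default 40, an 8 x 5 grid over the triangle's bounding box) and
each bin carries the mean potential of its member cells as three arrow
lengths toward the vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import NeighborGraph
from .simplex import ApexSpec, SimplexCoordinates, VERTICES

logger = logging.getLogger(__name__)


@dataclass
class VelocityField:
    """Per-gene degradation ratios and the per-cell velocity residuals."""

    gamma: np.ndarray  # per gene; NaN where undefined
    velocity: np.ndarray  # cells x genes, v = u - gamma * s (0 in invalid genes)
    valid: np.ndarray  # per-gene bool: gamma defined


@dataclass
class FatePotential:
    """Raw and per-cell-normalized mean edge weights toward each apex."""

    raw: np.ndarray  # n x 3 mean edge weight to each apex cluster
    normalized: np.ndarray  # n x 3, rows sum to 1 unless flagged
    zero_flag: np.ndarray  # per-cell bool: no outgoing weight to any apex


@dataclass
class BinnedArrowField:
    """Mean fate potentials of cells grouped on a grid over the triangle."""

    n_bins_x: int
    n_bins_y: int
    centroids: np.ndarray  # (nx * ny) x 2 bin centroid coordinates
    counts: np.ndarray  # contributing (unflagged) cells per bin
    arrows: np.ndarray  # (nx * ny) x 3 mean normalized potentials
    fate_names: list[str]
    bin_of_cell: np.ndarray  # per-cell flat bin index (row-major)

    def to_frame(self) -> pd.DataFrame:
        n_bins = self.n_bins_x * self.n_bins_y
        df = pd.DataFrame(
            {
                "bin_id": np.arange(n_bins),
                "bin_x": self.centroids[:, 0],
                "bin_y": self.centroids[:, 1],
                "n_cells": self.counts,
            }
        )
        for f, name in enumerate(self.fate_names):
            df[f"len_{name}"] = self.arrows[:, f]
        return df


def fit_gamma_steady_state(
    spliced: np.ndarray, unspliced: np.ndarray, extreme_quantile: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene degradation rate from extreme-abundance cells.

    For each gene, cells in the bottom and top extreme_quantile of s + u are
    taken as near-steady-state; gamma is the through-origin least-squares
    slope gamma = sum(u * s) / sum(s^2) over those cells. Genes whose extreme
    set has sum(s^2) = 0 are flagged undefined (gamma = NaN).
    Returns (gamma, valid_mask).
    """
    S = np.asarray(spliced, dtype=float)
    U = np.asarray(unspliced, dtype=float)
    if S.shape != U.shape:
        raise ValueError(f"layer shapes differ: {S.shape} vs {U.shape}")
    if not 0.0 < extreme_quantile < 0.5:
        raise ValueError("extreme_quantile must lie in (0, 0.5)")
    T = S + U
    lo = np.quantile(T, extreme_quantile, axis=0)
    hi = np.quantile(T, 1.0 - extreme_quantile, axis=0)
    mask = (T <= lo) | (T >= hi)
    ss = np.sum(S * S * mask, axis=0)
    us = np.sum(U * S * mask, axis=0)
    valid = ss > 0
    gamma = np.full(S.shape[1], np.nan)
    gamma[valid] = us[valid] / ss[valid]
    return gamma, valid


def compute_velocity(
    spliced: np.ndarray, unspliced: np.ndarray, gamma: np.ndarray, valid: np.ndarray | None = None
) -> VelocityField:
    """Velocity residual v = u - gamma * s on the normalized (log-free) layers.

    Genes with undefined gamma get zero velocity and stay flagged so
    downstream cosines ignore them.
    """
    S = np.asarray(spliced, dtype=float)
    U = np.asarray(unspliced, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if valid is None:
        valid = ~np.isnan(gamma)
    g = np.where(valid, gamma, 0.0)
    v = U - g * S
    v[:, ~valid] = 0.0
    return VelocityField(gamma=gamma, velocity=v, valid=np.asarray(valid, dtype=bool))


def velocity_graph(
    field: VelocityField, expression: np.ndarray, knn: NeighborGraph
) -> sp.csr_matrix:
    """Clipped-cosine edge weights between each cell's velocity and its neighbors.

    For j in KNN(i): w_ij = max(0, cos(v_i, x_j - x_i)) over velocity-valid
    genes, where x is the normalized spliced expression. The cosine involving
    a zero vector is defined as 0. Weights lie in [0, 1]; the diagonal is
    structurally zero (KNN excludes self).
    """
    X = np.asarray(expression, dtype=float)[:, field.valid]
    V = field.velocity[:, field.valid]
    n, k = knn.indices.shape
    rows = np.repeat(np.arange(n), k)
    cols = knn.indices.ravel()
    data = np.zeros(n * k)
    v_norm = np.linalg.norm(V, axis=1)
    for i in range(n):
        if v_norm[i] == 0:
            continue
        nbrs = knn.indices[i]
        delta = X[nbrs] - X[i]
        d_norm = np.linalg.norm(delta, axis=1)
        ok = d_norm > 0
        cos = np.zeros(k)
        cos[ok] = (delta[ok] @ V[i]) / (d_norm[ok] * v_norm[i])
        data[i * k : (i + 1) * k] = np.clip(cos, 0.0, 1.0)
    graph = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    graph.eliminate_zeros()
    return graph


def fate_potential(
    graph: sp.spmatrix, labels, apex: ApexSpec, edge_mean: bool = False
) -> FatePotential:
    """Mean velocity-graph edge weight from each cell to each apex cluster.

    P[i, f] = (1/|C_f|) sum_{j in C_f} w_ij with absent edges contributing 0
    (dense-mean semantics). edge_mean=True averages over existing edges into
    C_f instead. Rows are normalized to sum to one; cells with zero total
    potential are flagged and left at zero.
    """
    labels = np.asarray(labels)
    graph = sp.csr_matrix(graph)
    n = graph.shape[0]
    raw = np.zeros((n, 3))
    for f, label in enumerate(apex.cluster_labels):
        members = np.flatnonzero(labels == label)
        if members.size == 0:
            raise ValueError(f"apex cluster {label!r} is empty")
        sub = graph[:, members]
        sums = np.asarray(sub.sum(axis=1)).ravel()
        if edge_mean:
            nnz = sub.getnnz(axis=1)
            raw[:, f] = np.where(nnz > 0, sums / np.maximum(nnz, 1), 0.0)
        else:
            raw[:, f] = sums / members.size
    totals = raw.sum(axis=1)
    zero = totals == 0
    normalized = np.zeros_like(raw)
    normalized[~zero] = raw[~zero] / totals[~zero, None]
    return FatePotential(raw=raw, normalized=normalized, zero_flag=zero)


def _grid_shape(n_bins: int) -> tuple[int, int]:
    """Factor n_bins into (nx, ny) with aspect nearest 8:5 (default 40 -> 8 x 5)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    best = None
    for ny in range(1, n_bins + 1):
        if n_bins % ny:
            continue
        nx = n_bins // ny
        score = abs(np.log(nx / ny) - np.log(8.0 / 5.0))  # symmetric in aspect
        if best is None or score < best[0] or (score == best[0] and nx > best[1]):
            best = (score, nx, ny)
    assert best is not None
    return best[1], best[2]


def bin_arrows(
    coords: SimplexCoordinates, potential: FatePotential, n_bins: int = 40
) -> BinnedArrowField:
    """Average normalized fate potentials over a grid on the projected simplex.

    The grid covers the bounding box of the reference triangle with exactly
    n_bins rectangular locations (nx x ny, aspect nearest 8:5). Every cell is
    assigned to exactly one bin (right/top edges inclusive in the last
    column/row); flagged zero-potential cells are excluded from the bin means
    and counts. Arrow lengths are the per-bin mean normalized potentials
    toward each vertex, anchored at the bin centroid.
    """
    nx, ny = _grid_shape(n_bins)
    x0, x1 = VERTICES[:, 0].min(), VERTICES[:, 0].max()
    y0, y1 = VERTICES[:, 1].min(), VERTICES[:, 1].max()
    xy = coords.cartesian
    if xy.shape[0] != potential.normalized.shape[0]:
        raise ValueError("coords and potential cover different numbers of cells")
    ix = np.clip(((xy[:, 0] - x0) / (x1 - x0) * nx).astype(int), 0, nx - 1)
    iy = np.clip(((xy[:, 1] - y0) / (y1 - y0) * ny).astype(int), 0, ny - 1)
    flat = iy * nx + ix  # row-major

    n_total = nx * ny
    counts = np.zeros(n_total, dtype=int)
    arrows = np.zeros((n_total, 3))
    use = ~potential.zero_flag
    np.add.at(counts, flat[use], 1)
    np.add.at(arrows, flat[use], potential.normalized[use])
    nonempty = counts > 0
    arrows[nonempty] /= counts[nonempty, None]

    gx = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    gy = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    cx, cy = np.meshgrid(gx, gy)  # row-major: y outer, x inner
    centroids = np.column_stack([cx.ravel(), cy.ravel()])
    return BinnedArrowField(
        n_bins_x=nx,
        n_bins_y=ny,
        centroids=centroids,
        counts=counts,
        arrows=arrows,
        fate_names=list(coords.fate_names),
        bin_of_cell=flat,
    )
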