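"""Barycentric fate-affinity coordinates over a three-fate simplex.

Each cell's affinity to three terminal ("apex") fates is scored by averaging
its Euclidean distance to all cells of each apex cluster in a marker-restricted
scaled expression space, transforming distances with -log10, min-max scaling
each fate column to [0, 1] so modalities are comparable, and renormalizing per
cell so the three coordinates sum to unity (100%). The resulting barycentric
weights are projected into a reference equilateral triangle for ternary
display: a cell near the centroid has near-equal affinity to all three fates
(an uncommitted state), a cell near a vertex is committed to that fate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .preprocess import ScaledMatrix

logger = logging.getLogger(__name__)

SQRT3 = np.sqrt(3.0)

#: reference triangle: fate1 at top, fate2 bottom-left, fate3 bottom-right
VERTICES = np.array([[0.5, SQRT3 / 2.0], [0.0, 0.0], [1.0, 0.0]])

#: floor applied to distances before -log10
DISTANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class ApexSpec:
    """Ordered mapping of exactly three fate names to apex cluster labels."""

    fates: tuple[tuple[str, str], ...]  # ((fate_name, cluster_label), x3)

    def __post_init__(self) -> None:
        if len(self.fates) != 3:
            raise ValueError(f"ApexSpec needs exactly 3 fates, got {len(self.fates)}")
        labels = [lab for _, lab in self.fates]
        if len(set(labels)) != 3:
            raise ValueError(f"apex cluster labels must be distinct, got {labels}")

    @property
    def fate_names(self) -> list[str]:
        return [name for name, _ in self.fates]

    @property
    def cluster_labels(self) -> list[str]:
        return [lab for _, lab in self.fates]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ApexSpec":
        return cls(tuple(mapping.items()))


@dataclass
class SimplexCoordinates:
    """Barycentric weights (rows sum to 1) plus their 2-D triangle projection."""

    barycentric: np.ndarray  # n x 3, nonnegative, rows sum to 1
    cartesian: np.ndarray  # n x 2
    fate_names: list[str]
    barcodes: list[str]
    uniform_fallback: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.barycentric, columns=[f"w_{f}" for f in self.fate_names],
            index=pd.Index(self.barcodes, name="barcode"),
        )
        df["x"] = self.cartesian[:, 0]
        df["y"] = self.cartesian[:, 1]
        return df


def fate_feature_space(
    marker_lists: Mapping[str, Sequence[str]], apex: ApexSpec, k: int | None = None
) -> list[str]:
    """Union of each apex cluster's top markers, deduplicated in stable order.

    marker_lists maps apex cluster label -> ranked marker feature ids; when k
    is given only the first k per cluster enter the union. Order of first
    appearance follows the ApexSpec fate order.
    """
    out: list[str] = []
    seen: set[str] = set()
    for label in apex.cluster_labels:
        if label not in marker_lists:
            raise KeyError(f"no marker list for apex cluster {label!r}")
        lst = list(marker_lists[label])
        if k is not None:
            lst = lst[:k]
        for f in lst:
            if f not in seen:
                seen.add(f)
                out.append(f)
    if not out:
        raise ValueError("fate feature space is empty")
    return out


def mean_distance_to_apex(
    scaled: ScaledMatrix, labels: Sequence[str], apex: ApexSpec, exclude_self: bool = False
) -> np.ndarray:
    """Mean Euclidean distance from every cell to all cells of each apex cluster.

    D[i, f] = mean_{j in C_f} ||x_i - x_j||. A cell belonging to C_f is by
    default included in its own cluster's average (contributing a zero term);
    exclude_self drops that term instead.
    """
    X = scaled.values
    labels = np.asarray(labels)
    n = X.shape[0]
    D = np.zeros((n, 3))
    for f, label in enumerate(apex.cluster_labels):
        members = labels == label
        size = int(members.sum())
        if size == 0:
            raise ValueError(f"apex cluster {label!r} is empty")
        dist = cdist(X, X[members])
        total = dist.sum(axis=1)
        if exclude_self:
            denom = np.where(members, size - 1, size)
            if (denom == 0).any():
                raise ValueError(f"exclude_self with singleton apex cluster {label!r}")
            D[:, f] = total / denom
        else:
            D[:, f] = total / size
    return D


def similarity_transform(D: np.ndarray, floor: float = DISTANCE_FLOOR) -> np.ndarray:
    """-log10 of floored distances, then per-column min-max scaling to [0, 1].

    Larger values mean greater similarity. A constant column (min == max)
    carries no information and is set to 0.5 with a warning.
    """
    if (np.asarray(D) < 0).any():
        raise ValueError("distances must be nonnegative")
    S = -np.log10(np.maximum(D, floor))
    lo = S.min(axis=0)
    hi = S.max(axis=0)
    span = hi - lo
    out = np.empty_like(S)
    for f in range(S.shape[1]):
        if span[f] == 0:
            logger.warning("similarity column %d is constant; set to 0.5", f)
            out[:, f] = 0.5
        else:
            out[:, f] = (S[:, f] - lo[f]) / span[f]
    return out


def renormalize_rows(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each row by its sum so the three coordinates sum to unity.

    All-zero rows carry no affinity signal; they fall back to (1/3, 1/3, 1/3)
    and are flagged. Returns (weights, fallback_flags).
    """
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise ValueError("similarities must be nonnegative")
    sums = S.sum(axis=1)
    zero = sums == 0
    if zero.any():
        logger.warning("%d all-zero similarity rows set to uniform", int(zero.sum()))
    W = np.where(zero[:, None], 1.0 / 3.0, S / np.where(zero, 1.0, sums)[:, None])
    return W, zero


def to_cartesian(W: np.ndarray) -> np.ndarray:
    """Project barycentric weights into the reference triangle.

    Vertices: fate1 = (0.5, sqrt(3)/2), fate2 = (0, 0), fate3 = (1, 0); the
    image of a weight vector is the convex combination of the vertices.
    """
    W = np.asarray(W, dtype=float)
    if not np.allclose(W.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("barycentric rows must sum to 1")
    return W @ VERTICES


def compute_simplex(
    scaled: ScaledMatrix,
    labels: Sequence[str],
    apex: ApexSpec,
    exclude_self: bool = False,
    floor: float = DISTANCE_FLOOR,
) -> SimplexCoordinates:
    """Distances -> similarities -> barycentric weights -> triangle projection."""
    D = mean_distance_to_apex(scaled, labels, apex, exclude_self=exclude_self)
    S = similarity_transform(D, floor=floor)
    W, flags = renormalize_rows(S)
    return SimplexCoordinates(
        barycentric=W,
        cartesian=to_cartesian(W),
        fate_names=apex.fate_names,
        barcodes=list(scaled.barcodes),
        uniform_fallback=flags,
    )
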