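"""Count filtering, normalization, feature selection, scaling, ATAC gene
activity, and KNN graph construction.

Conventions match the standard single-cell workflow: genes are filtered on
total spliced counts, per-cell normalization targets the median cell total,
variable features are ranked by the variance-to-mean dispersion of the
log-normalized values, and scaling divides by the root-mean-square without
centering, so values keep their sign (here, stay nonnegative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA

from .io import FragmentRecord, GeneInterval

logger = logging.getLogger(__name__)


@dataclass
class ScaledMatrix:
    """Cells x selected-features matrix scaled per feature (no centering)."""

    values: np.ndarray  # cells x features, nonnegative when input is
    scale_factors: np.ndarray  # per-feature RMS divisor, > 0
    feature_ids: list[str]
    barcodes: list[str]


@dataclass
class NeighborGraph:
    """Exact K-nearest-neighbor graph on a PCA embedding."""

    indices: np.ndarray  # n x k neighbor indices (no self)
    distances: np.ndarray  # n x k Euclidean distances
    embedding: np.ndarray  # n x n_pcs PCA scores


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def filter_genes(adata: AnnData, min_counts: int = 10) -> AnnData:
    """Keep genes whose total spliced count is >= min_counts (inclusive bound).

    All layers and X are subset identically. Raises if nothing survives.
    """
    spliced = adata.layers["spliced"] if "spliced" in adata.layers else adata.X
    totals = np.asarray(spliced.sum(axis=0)).ravel()
    keep = totals >= min_counts
    if not keep.any():
        raise ValueError(f"all genes removed at min_counts={min_counts}")
    return adata[:, keep].copy()


def _normalize_per_cell(X: np.ndarray, target: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Scale each row to `target` (default: the median row total)."""
    totals = X.sum(axis=1)
    if target is None:
        target = float(np.median(totals))
    factors = np.where(totals > 0, target / np.where(totals > 0, totals, 1.0), 0.0)
    return X * factors[:, None], factors


def normalize_and_log(adata: AnnData) -> AnnData:
    """Median-total normalization followed by log1p on X.

    Cells with zero total counts are removed with a warning. The spliced and
    unspliced layers are each normalized to their own median per-cell total
    and stored un-logged as "spliced_norm" / "unspliced_norm" for the velocity
    stage; X becomes log1p of the normalized totals.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals == 0).any():
        n_zero = int((totals == 0).sum())
        logger.warning("removing %d zero-total cells", n_zero)
        adata = adata[totals > 0].copy()
    else:
        adata = adata.copy()
    Xn, _ = _normalize_per_cell(_dense(adata.X).astype(float))
    out = AnnData(X=np.log1p(Xn))
    out.obs_names = adata.obs_names.copy()
    out.var_names = adata.var_names.copy()
    out.obs = adata.obs.copy()
    out.var = adata.var.copy()
    for layer in ("spliced", "unspliced"):
        if layer in adata.layers:
            Ln, _ = _normalize_per_cell(_dense(adata.layers[layer]).astype(float))
            out.layers[layer + "_norm"] = Ln
    return out


def select_variable_features(adata: AnnData, n_target: int = 3000) -> list[str]:
    """Top n_target features by variance-to-mean dispersion of normalized values.

    Features with zero mean (never observed) are never selected while
    informative alternatives exist; if fewer than n_target informative
    features exist, all of them are returned with a warning.
    """
    X = _dense(adata.X)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, -np.inf)
    informative = int((dispersion > 0).sum())
    if informative < n_target:
        logger.warning("only %d informative features for n_target=%d", informative, n_target)
    order = np.argsort(-dispersion, kind="stable")
    chosen = [i for i in order[: max(n_target, 0)] if dispersion[i] > 0]
    return [adata.var_names[i] for i in chosen]


def scale_no_center(
    adata_or_matrix, features: Sequence[str] | None = None, feature_ids=None, barcodes=None
) -> ScaledMatrix:
    """Divide each feature by its root-mean-square (denominator n - 1).

    factor_g = sqrt(sum_i x_ig^2 / (n - 1)). No centering is applied, so
    nonnegative inputs stay nonnegative. An all-zero feature gets factor 1
    with a warning.
    """
    if isinstance(adata_or_matrix, AnnData):
        feature_ids = list(adata_or_matrix.var_names)
        barcodes = list(adata_or_matrix.obs_names)
        X = _dense(adata_or_matrix.X).astype(float)
    else:
        X = _dense(adata_or_matrix).astype(float)
        feature_ids = list(feature_ids) if feature_ids is not None else [str(j) for j in range(X.shape[1])]
        barcodes = list(barcodes) if barcodes is not None else [str(i) for i in range(X.shape[0])]
    if features is not None:
        pos = {f: j for j, f in enumerate(feature_ids)}
        missing = [f for f in features if f not in pos]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        cols = [pos[f] for f in features]
        X = X[:, cols]
        feature_ids = list(features)
    n = X.shape[0]
    denom = max(n - 1, 1)
    factors = np.sqrt((X**2).sum(axis=0) / denom)
    zero = factors == 0
    if zero.any():
        logger.warning("%d all-zero features scaled with factor 1", int(zero.sum()))
        factors = np.where(zero, 1.0, factors)
    return ScaledMatrix(X / factors, factors, feature_ids, barcodes)


def gene_activity_from_fragments(
    fragments: Sequence[FragmentRecord],
    annotation: Sequence[GeneInterval],
    upstream_bp: int = 3000,
    barcodes: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Count fragments overlapping each gene body + upstream promoter window.

    The window is [start - upstream_bp, end) for + strand genes and
    [start, end + upstream_bp) for - strand genes (clipped at 0). A fragment
    contributes its duplicate count to every gene whose window it overlaps by
    at least 1 bp. Fragments on contigs absent from the annotation are ignored
    (logged). Returns (cells x genes int matrix, barcodes, gene_ids).
    """
    gene_ids = [g.gene_id for g in annotation]
    if barcodes is None:
        barcodes = sorted({fr.barcode for fr in fragments})
    barcodes = list(barcodes)
    bc_index = {b: i for i, b in enumerate(barcodes)}

    by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for j, g in enumerate(annotation):
        if g.strand == "+":
            lo, hi = max(g.start - upstream_bp, 0), g.end
        else:
            lo, hi = g.start, g.end + upstream_bp
        los, his, idx = by_contig.setdefault(g.contig, ([], [], []))  # type: ignore[arg-type]
        los.append(lo)
        his.append(hi)
        idx.append(j)
    by_contig = {
        c: (np.array(l), np.array(h), np.array(i)) for c, (l, h, i) in by_contig.items()
    }

    counts = np.zeros((len(barcodes), len(gene_ids)), dtype=np.int64)
    n_skipped = 0
    for fr in fragments:
        win = by_contig.get(fr.contig)
        if win is None:
            n_skipped += 1
            continue
        los, his, idx = win
        hit = idx[(fr.start < his) & (fr.end > los)]  # >= 1 bp overlap, half-open
        if hit.size and fr.barcode in bc_index:
            counts[bc_index[fr.barcode], hit] += fr.count
    if n_skipped:
        logger.info("ignored %d fragments on contigs absent from annotation", n_skipped)
    return counts, barcodes, gene_ids


def knn_smooth(X, knn: NeighborGraph) -> np.ndarray:
    """First-order moments over the KNN graph: mean of each cell and its neighbors.

    Averaging a layer over the neighborhood before regression-based kinetics
    estimation suppresses count noise that would otherwise attenuate the
    fitted slopes (errors-in-variables bias).
    """
    X = _dense(X).astype(float)
    n, k = knn.indices.shape
    out = X.copy()
    for i in range(n):
        out[i] += X[knn.indices[i]].sum(axis=0)
    return out / (k + 1)


def pca_knn_graph(scaled: ScaledMatrix, n_pcs: int = 30, k: int = 30, seed: int = 0) -> NeighborGraph:
    """PCA to n_pcs scores, then exact Euclidean KNN with smallest-index ties.

    PCA centers internally (scaling upstream deliberately did not). Distances
    are computed exactly; ties are broken toward the smaller cell index so the
    graph is deterministic.
    """
    X = scaled.values
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    n_comp = min(n_pcs, n - 1 if n > 1 else 1, X.shape[1])
    emb = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(X)
    sq = (emb**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (emb @ emb.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    dist = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return NeighborGraph(indices=order, distances=dist, embedding=emb)
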