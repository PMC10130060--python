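"""One-vs-rest Wilcoxon rank-sum marker selection.

The test is the two-sided rank-sum (Mann-Whitney U) with the normal
approximation, tie correction, and a 0.5 continuity correction, applied per
feature to one cluster against all remaining cells. P values are adjusted by
Benjamini-Hochberg. Two ranking variants are provided: "genes" (rank by p,
break ties by absolute log fold-change, take the top k, default 30) and
"peaks" (keep adjusted p below a threshold, rank by log fold-change, take the
top k, default 1000).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: pseudocount in the log fold-change ratio
LOGFC_EPS = 1e-9


def wilcoxon_one_vs_rest(
    X, feature_ids: Sequence[str], labels: Sequence[str], cluster: str
) -> pd.DataFrame:
    """Rank-sum test of `cluster` cells against all other cells, per feature.

    X is cells x features (normalized values). Returns a DataFrame indexed by
    feature with columns U, z, p, p_adj, logFC. logFC is the natural log of
    the ratio of within/outside mean expression with a small pseudocount.
    Both groups must have at least two cells.
    """
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    in_grp = labels == cluster
    n1 = int(in_grp.sum())
    n2 = int((~in_grp).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"cluster {cluster!r}: group sizes {n1} vs {n2} too small (need >= 2 each)")
    n = n1 + n2

    ranks = rankdata(X, axis=0)
    r1 = ranks[in_grp].sum(axis=0)
    U = r1 - n1 * (n1 + 1) / 2.0

    # tie correction: sigma^2 = n1 n2 / 12 * (n + 1 - sum(t^3 - t) / (n (n-1)))
    tie_term = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, cnt = np.unique(X[:, j], return_counts=True)
        tie_term[j] = float((cnt**3 - cnt).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))

    mu = n1 * n2 / 2.0
    diff = U - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (diff - 0.5 * np.sign(diff)) / np.where(sigma > 0, sigma, 1.0), 0.0)
    z = np.where(diff == 0, 0.0, z)
    p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    mean_in = X[in_grp].mean(axis=0)
    mean_out = X[~in_grp].mean(axis=0)
    logfc = np.log((mean_in + LOGFC_EPS) / (mean_out + LOGFC_EPS))

    return pd.DataFrame(
        {"U": U, "z": z, "p": p, "p_adj": adjust_bh(p), "logFC": logfc},
        index=pd.Index(feature_ids, name="feature"),
    )


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def top_k_markers(stats: pd.DataFrame, k: int = 30, mode: str = "genes", alpha: float = 0.05,
                  rank_by: str | None = None) -> list[str]:
    """Select marker features from a :func:`wilcoxon_one_vs_rest` table.

    genes mode: rank by p ascending, ties by |logFC| descending, take k
    (default 30). peaks mode: keep adjusted p < alpha, rank by logFC
    descending, take k (default 1000 is the caller's choice). rank_by
    overrides the primary genes-mode key ("p" or "logFC"). If fewer than k
    features qualify, all of them are returned with a warning.
    """
    if mode not in ("genes", "peaks"):
        raise ValueError(f"mode must be 'genes' or 'peaks', got {mode!r}")
    df = stats.copy()
    if mode == "genes":
        key = rank_by or "p"
        if key == "p":
            df = df.assign(_abs=df["logFC"].abs())
            df = df.sort_values(["p", "_abs"], ascending=[True, False], kind="stable")
        elif key == "logFC":
            df = df.sort_values("logFC", ascending=False, kind="stable")
        else:
            raise ValueError(f"unknown rank_by {key!r}")
        out = list(df.index[:k])
    else:
        df = df[df["p_adj"] < alpha].sort_values("logFC", ascending=False, kind="stable")
        out = list(df.index[:k])
    if len(out) < k:
        logger.warning("only %d of %d requested markers available", len(out), k)
    return out


def markers_table(
    X, feature_ids: Sequence[str], labels: Sequence[str], clusters: Sequence[str],
    k: int = 30, mode: str = "genes", alpha: float = 0.05,
) -> pd.DataFrame:
    """Stack per-cluster marker stats into one table with a `selected` flag."""
    frames = []
    for c in clusters:
        stats = wilcoxon_one_vs_rest(X, feature_ids, labels, c)
        chosen = set(top_k_markers(stats, k=k, mode=mode, alpha=alpha))
        stats = stats.reset_index()
        stats.insert(0, "cluster", c)
        stats["selected"] = stats["feature"].isin(chosen)
        frames.append(stats)
    return pd.concat(frames, ignore_index=True)
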