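"""Synthetic three-fate single-cell datasets with known ground truth.

The generator emulates sorted bone-marrow stromal populations: three terminal
("apex") clusters — osteoblast-like, chondrocyte-like and reticular-like —
plus transitional cells of intermediate identity. Spliced/unspliced kinetics
are built so that each transitional cell's steady-state velocity points toward
its destined fate, and an optional fragment simulator produces per-cell ATAC
records for the gene-activity path.

Model
-----
Each fate f has an archetype expression profile ``a_f`` (log-normal gene
means, with that fate's marker genes multiplied by a fold-change). A cell with
barycentric identity ``w`` has spliced mean ``sum_f w_f a_f``. Apex cells are
one-hot; transitional cells draw interior weights biased toward a destined
fate. Unspliced means are ``gamma_g`` times spliced means (splicing rate beta
fixed at 1, so the steady state is u = gamma * s); transitional cells get the
unspliced mean of their destined fate's markers inflated by a factor
``1 + induction_delta``, which is what makes the velocity residual
``v = u - gamma*s`` positive along that fate's markers. Counts are negative
binomial with a single inverse-dispersion shared by both layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from anndata import AnnData

from .io import FragmentRecord, GeneInterval

logger = logging.getLogger(__name__)

FATE_NAMES = ("osteoblast", "chondrocyte", "reticular")
APEX_LABELS = ("Osteoblast", "Chondrocyte", "Reticular")
TRANSITIONAL_LABEL = "Transitional"

#: simulated fragment length in bp (short, so windows dominate placement)
FRAGMENT_LENGTH = 50


@dataclass
class SimParams:
    """Parameters of the synthetic fate landscape.

    fate_fractions is (apex1, apex2, apex3, transitional) and must sum to 1.
    dispersion is the negative-binomial inverse-dispersion (larger = less
    noisy). induction_delta in [0, 1] is the multiplicative unspliced offset
    applied to a transitional cell's destined-fate markers. noise is "nb"
    (sample counts) or "none" (return the exact means, for oracle checks).
    """

    n_cells: int = 600
    n_genes: int = 1000
    fate_fractions: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.4)
    archetype_scale: float = 2.0
    n_markers_per_fate: int = 50
    marker_fold_change: float = 8.0
    dispersion: float = 10.0
    induction_delta: float = 0.5
    gamma_range: tuple[float, float] = (0.1, 2.0)
    noise: str = "nb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if len(self.fate_fractions) != 4:
            raise ValueError("fate_fractions must have 4 entries (3 apexes + transitional)")
        if abs(sum(self.fate_fractions) - 1.0) > 1e-9:
            raise ValueError(f"fate_fractions must sum to 1, got {sum(self.fate_fractions)!r}")
        if any(f < 0 for f in self.fate_fractions):
            raise ValueError("fate_fractions must be nonnegative")
        if self.archetype_scale <= 0:
            raise ValueError("archetype_scale must be positive")
        if 3 * self.n_markers_per_fate > self.n_genes:
            raise ValueError("3 * n_markers_per_fate must not exceed n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.induction_delta <= 1.0:
            raise ValueError("induction_delta must lie in [0, 1]")
        lo, hi = self.gamma_range
        if not 0 < lo <= hi:
            raise ValueError("gamma_range must satisfy 0 < lo <= hi")
        if self.noise not in ("nb", "none"):
            raise ValueError("noise must be 'nb' or 'none'")


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth of a simulated landscape."""

    true_barycentric: np.ndarray  # n x 3, rows sum to 1, apex rows one-hot
    destined_fate: list  # per cell: fate name (transitional cells) or None
    true_gamma: np.ndarray  # per gene degradation rate
    apex_label: np.ndarray  # per cell cluster label
    marker_genes: dict = field(default_factory=dict)  # fate name -> gene index array


def _group_sizes(n_cells: int, fractions: Sequence[float]) -> list[int]:
    sizes = [int(np.floor(f * n_cells)) for f in fractions[:3]]
    sizes.append(n_cells - sum(sizes))  # remainder to transitional
    return sizes


def simulate_fate_landscape(params: SimParams) -> tuple[AnnData, GroundTruth]:
    """Simulate a three-fate count landscape with spliced/unspliced kinetics.

    Returns an AnnData (X = spliced + unspliced, layers "spliced" and
    "unspliced", obs["cluster"]) and the :class:`GroundTruth`. Identical
    params (including seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    g, n = params.n_genes, params.n_cells
    m = params.n_markers_per_fate

    base = rng.lognormal(mean=np.log(params.archetype_scale), sigma=1.0, size=g)
    marker_genes = {
        FATE_NAMES[f]: np.arange(f * m, (f + 1) * m) for f in range(3)
    }
    archetypes = np.tile(base, (3, 1))
    for f in range(3):
        archetypes[f, marker_genes[FATE_NAMES[f]]] *= params.marker_fold_change

    sizes = _group_sizes(n, params.fate_fractions)
    n_trans = sizes[3]
    labels = np.concatenate(
        [np.repeat(APEX_LABELS[f], sizes[f]) for f in range(3)]
        + [np.repeat(TRANSITIONAL_LABEL, n_trans)]
    )

    W = np.zeros((n, 3))
    row = 0
    for f in range(3):
        W[row : row + sizes[f], f] = 1.0
        row += sizes[f]
    destined_idx = rng.integers(0, 3, size=n_trans)
    if n_trans:
        interior = rng.dirichlet((2.0, 2.0, 2.0), size=n_trans)
        onehot = np.eye(3)[destined_idx]
        W[row:] = 0.6 * onehot + 0.4 * interior

    gamma = rng.uniform(params.gamma_range[0], params.gamma_range[1], size=g)
    s_mean = W @ archetypes
    u_mean = s_mean * gamma
    for i, f in enumerate(destined_idx):
        u_mean[row + i, marker_genes[FATE_NAMES[f]]] *= 1.0 + params.induction_delta

    if params.noise == "nb":
        spliced = _sample_nb(rng, s_mean, params.dispersion)
        unspliced = _sample_nb(rng, u_mean, params.dispersion)
    else:
        spliced, unspliced = s_mean, u_mean

    adata = AnnData(
        X=sp.csr_matrix(spliced + unspliced),
        layers={"spliced": sp.csr_matrix(spliced), "unspliced": sp.csr_matrix(unspliced)},
    )
    adata.obs_names = [f"cell_{i:05d}" for i in range(n)]
    adata.var_names = [f"gene_{j:05d}" for j in range(g)]
    adata.obs["cluster"] = labels
    fate_of_gene = np.full(g, "", dtype=object)
    for fate, idx in marker_genes.items():
        fate_of_gene[idx] = fate
    adata.var["fate_marker"] = fate_of_gene

    destined: list = [None] * n
    for i, f in enumerate(destined_idx):
        destined[row + i] = FATE_NAMES[f]
    truth = GroundTruth(
        true_barycentric=W,
        destined_fate=destined,
        true_gamma=gamma,
        apex_label=labels,
        marker_genes=marker_genes,
    )
    return adata, truth


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, inverse-dispersion r): var = mean + mean^2 / r."""
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def default_apex_spec():
    """ApexSpec matching the simulator's cluster labels."""
    from .simplex import ApexSpec

    return ApexSpec(tuple(zip(FATE_NAMES, APEX_LABELS)))


# ---------------------------------------------------------------------------
# ATAC fragments
# ---------------------------------------------------------------------------


def make_annotation(
    n_genes: int, gene_length: int = 2000, spacing: int = 10000, contig: str = "chr1"
) -> list[GeneInterval]:
    """Regularly spaced, non-overlapping gene intervals for simulation.

    Spacing exceeds gene_length + the 3 kb promoter window, so gene-activity
    windows never overlap and fragment counting round-trips exactly. Strands
    alternate so both window orientations are exercised.
    """
    if spacing < gene_length + 4000:
        raise ValueError("spacing too small: activity windows would overlap")
    out = []
    for j in range(n_genes):
        start = 5000 + j * spacing
        strand = "+" if j % 2 == 0 else "-"
        out.append(GeneInterval(f"gene_{j:05d}", contig, start, start + gene_length, strand))
    return out


def simulate_fragments(
    params: SimParams,
    activity: np.ndarray,
    annotation: Sequence[GeneInterval],
    upstream_bp: int = 3000,
    barcodes: Sequence[str] | None = None,
) -> list[FragmentRecord]:
    """Place Poisson fragments inside each gene's activity window.

    activity is a cells x genes matrix of mean fragment counts (genes in
    annotation order). For each cell/gene a Poisson(activity) number of
    fragments is placed uniformly within the strand-aware window
    [start - upstream_bp, end) (+ strand) or [start, end + upstream_bp)
    (- strand), clipped at contig position 0. Each record carries duplicate
    count 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xF2A6)))
    activity = np.asarray(activity, dtype=float)
    n_cells, n_genes = activity.shape
    if n_genes != len(annotation):
        raise ValueError(f"activity has {n_genes} genes but annotation has {len(annotation)}")
    if barcodes is None:
        barcodes = [f"cell_{i:05d}" for i in range(n_cells)]
    records: list[FragmentRecord] = []
    counts = rng.poisson(activity)
    for j, gene in enumerate(annotation):
        if gene.strand == "+":
            lo, hi = max(gene.start - upstream_bp, 0), gene.end
        else:
            lo, hi = gene.start, gene.end + upstream_bp
        frag_len = min(FRAGMENT_LENGTH, hi - lo)
        for i in range(n_cells):
            k = counts[i, j]
            if k == 0:
                continue
            starts = rng.integers(lo, hi - frag_len + 1, size=k)
            for s in np.sort(starts):
                records.append(FragmentRecord(gene.contig, int(s), int(s) + frag_len, barcodes[i], 1))
    return records
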