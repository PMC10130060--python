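# Methods

This note documents the models and procedures implemented in `fatesimplex`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions that affect results.

## Simplex fate-affinity score

Given cluster labels and an ordered choice of three apex clusters (the
purest terminal cluster per fate; vertex order is fate1 = top,
fate2 = bottom-left, fate3 = bottom-right), the score proceeds:

1. **Marker space.** One-vs-rest Wilcoxon rank-sum per apex cluster on the
   log-normalized matrix; the top 30 features per cluster (p ascending, ties
   by |logFC| descending) are unioned with order-of-first-appearance
   deduplication. The distance space is this union after per-feature
   root-mean-square scaling without centering, `factor_g = sqrt(Σ x²/(n−1))`.
   Distances are therefore computed in scaled gene space; a factorization
   space (e.g. a joint NMF embedding) would be a valid alternative reading,
   but gene space keeps the score interpretable and self-contained.
2. **Distance.** `D[i,f]` = mean Euclidean distance from cell *i* to *all*
   cells of apex cluster *f*. A cell belonging to `C_f` is included in its
   own cluster's average and contributes a zero self-distance; `exclude_self`
   switches this off (it then requires ≥ 2 cells per apex cluster).
3. **Similarity.** `S = −log10(max(D, δ))` with floor `δ = 1e-12` (−log10 of
   zero is undefined; δ is far below any realistic mean distance), then
   per-fate min–max scaling to [0, 1]. Min–max is computed over the cells of
   the one dataset being scored; pooled scaling across modalities is not
   implemented. A constant similarity column carries no information and is
   set to 0.5 with a warning.
4. **Normalization and projection.** Rows are divided by their sums
   (all-zero rows fall back to (⅓, ⅓, ⅓) and are flagged), and projected
   onto the triangle with vertices (0.5, √3/2), (0, 0), (1, 0).

Useful consequences, all under test: permuting the apex order permutes the
coordinate columns identically; multiplying all distances by a constant
leaves coordinates unchanged (the −log10 shift cancels in min–max); and
coordinates from 30 markers per cluster agree with 500-marker runs at
Spearman ≥ 0.9 per fate on synthetic data.

## Steady-state velocity and fate potential

The kinetic model is the steady-state one: transcription feeds an unspliced
pool that converts to spliced at rate β and degrades at rate γ; at
equilibrium `u = (γ/β)·s`. β is fixed at 1 because only the ratio γ/β is
identifiable here, so "γ" throughout means that ratio.

- **Moment smoothing.** Both normalized layers are averaged over each cell's
  K-nearest-neighborhood (self plus K = 30 neighbors) before fitting.
  Without this, regressing one noisy count layer on another attenuates the
  slope (errors-in-variables); smoothing reduces the per-observation noise
  variance roughly K-fold and removes the bias at the sample sizes used
  here. This mirrors standard practice in velocity toolchains.
- **γ fit.** Per gene, cells in the bottom and top `extreme_quantile`
  (default 0.05) of s + u are treated as near-steady-state, and
  `γ = Σus / Σs²` (least squares through the origin) over those cells.
  Genes with `Σs² = 0` on the extreme set are flagged and excluded from all
  downstream cosines.
- **Velocity graph.** For each cell *i* and each KNN neighbor *j*:
  `w_ij = max(0, cos(v_i, x_j − x_i))` over γ-valid genes, with x the
  (smoothed) normalized spliced layer and cos of a zero vector defined as 0.
  Raw clipped cosines are averaged, not row-normalized transition
  probabilities; a row-normalized variant would change only the per-cell
  scale, which the subsequent per-cell normalization removes anyway.
- **Fate potential.** `P[i,f]` = mean edge weight from *i* into apex cluster
  *f*, where absent KNN edges count as zero (dense-mean semantics; the
  `edge_mean` option averages over existing edges only). Rows are
  normalized to sum to 1; cells with no positive weight toward any apex are
  flagged rather than assigned a uniform pull — "no information" is not
  "equal pull" — and excluded from bin averages.
- **Arrow binning.** The bounding box of the reference triangle is divided
  into exactly `n_bins` rectangles (default 40 as 8 × 5; other counts use
  the divisor pair minimizing |log(nx/ny) − log(8/5)|, ties to the wider
  grid, so any n_bins gives a deterministic layout). Cells on the right/top
  boundary fall into the last column/row. Each bin stores its centroid, its
  contributing-cell count, and three mean normalized potentials as arrow
  lengths toward the vertices.

## Preprocessing defaults

| parameter | default | meaning |
|---|---|---|
| `min_counts` | 10 | keep genes with total spliced count ≥ 10 (inclusive boundary) |
| normalization target | median per-cell total | each layer normalized to its own median |
| `n_features` | 3000 | variable features by variance/mean dispersion of log-normalized values |
| `n_pcs` | 30 | PCA scores used for the KNN graph (PCA centers internally) |
| `knn_k` | 30 | exact Euclidean KNN; ties broken toward the smaller index |
| `top_k` | 30 | markers per apex cluster (genes mode); peaks mode filters BH-adjusted p < 0.05 and ranks by logFC |
| `upstream_bp` | 3000 | promoter window upstream of the TSS, strand-aware |
| `extreme_quantile` | 0.05 | steady-state cell fraction per tail in the γ fit |
| `n_bins` | 40 | arrow grid locations |

Gene-activity counting: the window is `[start − 3000, end)` on the + strand
and `[start, end + 3000)` on the − strand (0-based half-open, clipped at 0);
a fragment contributes its full duplicate count to every gene window it
overlaps by ≥ 1 bp. Partial-overlap proration was considered and rejected:
counts stay integers and the rule is unambiguous at boundaries.

Wilcoxon details: normal approximation with midrank tie correction and 0.5
continuity correction; two-sided p; `logFC = ln((mean_in + ε)/(mean_out + ε))`
with ε = 1e-9 (guards division by zero without moving moderate means).
Benjamini–Hochberg is the adjustment procedure — the convention of the
surrounding toolchain. The normal approximation tracks exhaustive
enumeration to < 0.05 absolute for continuous samples of six or more total
observations; below that the exact null is too granular for any
approximation, and the exact/permutation route should be used directly.

## Synthetic data: what it emulates and what it does not

The generator emulates sorted three-fate stromal populations. Per-gene base
means are log-normal(ln `archetype_scale`, 1); each fate's archetype
multiplies its own `n_markers_per_fate` marker genes by `marker_fold_change`
(8). Apex cells carry one-hot barycentric identity; transitional cells draw
Dirichlet(2, 2, 2) weights blended 60/40 toward a uniformly drawn destined
fate — interior but directional. Spliced means are the barycentric mixture
of archetypes; unspliced means are γ·s with γ ~ Uniform(`gamma_range`), and
the destined fate's markers are inflated by (1 + `induction_delta`) so the
steady-state residual points toward that fate. Both layers are sampled
negative-binomially with one shared inverse-dispersion; `noise="none"`
returns the exact means for oracle tests. Fragment records place
Poisson-distributed 50 bp fragments uniformly inside each gene's activity
window, strand-aware and clipped at the contig start, over non-overlapping
annotation windows so counting round-trips exactly.

Defaults — 600 cells, 1000 genes, fractions (0.2, 0.2, 0.2, 0.4), scale 2.0
(≈ 3 counts/gene, a few thousand counts per cell, 10x-like at desk scale),
50 markers per fate, dispersion 10, `induction_delta` 0.5, γ ∈ [0.1, 2] —
were fixed once as the package's study conditions; they give clearly
separated apexes without being noise-free.

Deliberately **not** emulated: transcription bursting and branching ODE
kinetics, doublets, batch effects, ambient RNA, modality-specific depth
differences, and a realistic noise model for sorted populations (the single
shared NB dispersion is a stand-in). Tests passing on this generator
demonstrate the pipeline's correctness and internal consistency — marker
recovery, γ recovery, fate-direction recovery — not robustness to the full
noise structure of real experiments.

## Degenerate inputs and numerical choices

- Gene filtering with nothing left, empty apex clusters, and KNN with
  k ≥ n are fatal errors; zero-total cells are dropped with a warning.
- All-zero features get scale factor 1 (warned); all-zero similarity rows
  become uniform and flagged; constant similarity columns become 0.5.
- Determinism: one global seed fans out to per-stage child seeds via
  SHA-256 (`pipeline.stage_seed`), KNN ties break by index, sorts are
  stable, and identical configurations produce bit-identical output files.
- Problem sizes in the test and acceptance runs (600 × 1000 default, 500
  cells for γ recovery) are desk-scale choices that keep every property
  checkable in seconds while leaving all estimators in their intended
  regime.

## Known limitations

- The steady-state γ substitutes for likelihood-based dynamical kinetics;
  genes far from equilibrium in all cells will fit poorly. An externally
  computed velocity graph can be supplied (`graph_in` / `--graph-in`) to
  bypass the internal estimator entirely.
- Min–max similarity scaling is per dataset; comparing simplexes across
  modalities scaled separately is qualitative, not quantitative.
- The simplex is strictly three-fate; more vertices would need a different
  projection and are out of scope.
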