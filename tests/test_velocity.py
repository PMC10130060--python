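"""Steady-state kinetics, velocity graph, fate potential, arrow binning."""

import numpy as np
import pytest
import scipy.sparse as sp

from fatesimplex import preprocess as pp
from fatesimplex import velocity as vl
from fatesimplex.simplex import ApexSpec, SimplexCoordinates, VERTICES, to_cartesian

APEX = ApexSpec((("f1", "A"), ("f2", "B"), ("f3", "C")))


class TestFitGamma:
    def test_noiseless_proportional_layers_recover_slope(self, rng):
        S = rng.gamma(2.0, 2.0, (60, 5))
        U = 0.7 * S
        gamma, valid = vl.fit_gamma_steady_state(S, U)
        assert valid.all()
        np.testing.assert_allclose(gamma, 0.7, atol=1e-12)

    def test_all_zero_spliced_gene_flagged(self, rng):
        S = np.column_stack([np.zeros(30), rng.gamma(2.0, 1.0, 30)])
        U = np.column_stack([np.ones(30), 0.5 * S[:, 1]])
        gamma, valid = vl.fit_gamma_steady_state(S, U)
        assert not valid[0] and np.isnan(gamma[0])
        assert valid[1]

    def test_extreme_quantile_validated(self, rng):
        S = rng.gamma(2.0, 1.0, (20, 2))
        for q in (0.0, 0.5, 0.9):
            with pytest.raises(ValueError):
                vl.fit_gamma_steady_state(S, S, extreme_quantile=q)

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError):
            vl.fit_gamma_steady_state(np.zeros((3, 2)), np.zeros((3, 3)))

    def test_recovery_on_simulation_within_ten_percent(self):
        """Pipeline-path gamma estimates stay within 10% median relative error
        of the simulator's true degradation rates (n = 500, dispersion 10)."""
        from fatesimplex.simulate import SimParams, simulate_fate_landscape

        params = SimParams(n_cells=500, dispersion=10.0, seed=7)
        adata, truth = simulate_fate_landscape(params)
        norm = pp.normalize_and_log(pp.filter_genes(adata, 10))
        feats = pp.select_variable_features(norm, 3000)
        knn = pp.pca_knn_graph(pp.scale_no_center(norm, feats), 30, 30)
        Ms = pp.knn_smooth(norm.layers["spliced_norm"], knn)
        Mu = pp.knn_smooth(norm.layers["unspliced_norm"], knn)
        gamma, valid = vl.fit_gamma_steady_state(Ms, Mu)
        kept = [list(adata.var_names).index(g) for g in norm.var_names]
        tg = truth.true_gamma[kept]
        rel = np.abs(gamma[valid] - tg[valid]) / tg[valid]
        assert np.median(rel) <= 0.10


class TestComputeVelocity:
    def test_steady_state_gives_zero_velocity(self, rng):
        S = rng.gamma(2.0, 1.0, (10, 4))
        gamma = np.array([0.2, 0.5, 1.0, 2.0])
        field = vl.compute_velocity(S, gamma * S, gamma)
        np.testing.assert_allclose(field.velocity, 0.0, atol=1e-12)

    def test_arithmetic(self):
        field = vl.compute_velocity(np.array([[2.0]]), np.array([[2.0]]), np.array([0.5]))
        assert field.velocity[0, 0] == 1.0

    def test_linearity_in_unspliced(self, rng):
        S = rng.gamma(2.0, 1.0, (8, 3))
        U = rng.gamma(2.0, 1.0, (8, 3))
        gamma = rng.uniform(0.1, 2.0, 3)
        v1 = vl.compute_velocity(S, U, gamma).velocity
        v2 = vl.compute_velocity(S, 2 * U, gamma).velocity
        np.testing.assert_allclose(v2, v1 + U, atol=1e-12)

    def test_invalid_genes_zeroed_and_flagged(self):
        gamma = np.array([0.5, np.nan])
        field = vl.compute_velocity(np.ones((4, 2)), np.ones((4, 2)), gamma)
        assert field.valid.tolist() == [True, False]
        np.testing.assert_array_equal(field.velocity[:, 1], 0.0)


def knn_of(indices):
    idx = np.asarray(indices)
    return pp.NeighborGraph(indices=idx, distances=np.ones(idx.shape), embedding=np.zeros((idx.shape[0], 1)))


class TestVelocityGraph:
    def test_zero_velocity_cell_has_zero_row(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        field = vl.VelocityField(
            gamma=np.zeros(2), velocity=np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0]]),
            valid=np.array([True, True]),
        )
        g = vl.velocity_graph(field, X, knn_of([[1, 2], [0, 2], [0, 1]]))
        assert g[0].nnz == 0

    def test_velocity_equal_to_displacement_gives_unit_weight(self):
        """v_0 exactly the displacement to neighbor 1: cosine = 1."""
        X = np.array([[0.0, 0.0], [3.0, 4.0], [-1.0, 0.0]])
        v = np.array([[3.0, 4.0], [0.0, 0.0], [0.0, 0.0]])
        field = vl.VelocityField(gamma=np.zeros(2), velocity=v, valid=np.array([True, True]))
        g = vl.velocity_graph(field, X, knn_of([[1, 2], [0, 2], [0, 1]]))
        assert g[0, 1] == pytest.approx(1.0)
        assert g[0, 2] == 0.0  # opposite direction clipped

    def test_weights_clipped_to_unit_interval(self, rng):
        n, k, gdim = 25, 6, 7
        X = rng.normal(size=(n, gdim))
        v = rng.normal(size=(n, gdim))
        idx = np.array([rng.choice([j for j in range(n) if j != i], k, replace=False) for i in range(n)])
        field = vl.VelocityField(gamma=np.zeros(gdim), velocity=v, valid=np.ones(gdim, bool))
        g = vl.velocity_graph(field, X, knn_of(idx))
        assert g.data.min() >= 0.0 and g.data.max() <= 1.0
        assert np.all(g.diagonal() == 0)

    def test_sparsity_bounded_by_n_times_k(self, rng):
        n, k = 30, 5
        X = rng.normal(size=(n, 4))
        v = rng.normal(size=(n, 4))
        idx = np.array([rng.choice([j for j in range(n) if j != i], k, replace=False) for i in range(n)])
        field = vl.VelocityField(gamma=np.zeros(4), velocity=v, valid=np.ones(4, bool))
        g = vl.velocity_graph(field, X, knn_of(idx))
        assert g.nnz <= n * k


class TestFatePotential:
    labels = np.array(["A", "A", "B", "C", "T"])

    def test_zero_graph_all_flagged(self):
        pot = vl.fate_potential(sp.csr_matrix((5, 5)), self.labels, APEX)
        assert pot.zero_flag.all()
        np.testing.assert_array_equal(pot.raw, 0.0)
        np.testing.assert_array_equal(pot.normalized, 0.0)

    def test_hand_set_sparse_weights_dense_mean(self):
        """Absent edges count as zeros in the apex average (dense semantics)."""
        g = sp.lil_matrix((5, 5))
        g[4, 0] = 0.8  # T -> one of two A cells
        g[4, 2] = 0.4  # T -> the single B cell
        g[0, 1] = 1.0  # A -> A
        pot = vl.fate_potential(sp.csr_matrix(g), self.labels, APEX)
        np.testing.assert_allclose(pot.raw[4], [0.8 / 2, 0.4 / 1, 0.0])
        np.testing.assert_allclose(pot.normalized[4], [0.5, 0.5, 0.0])
        assert not pot.zero_flag[4]

    def test_edge_mean_variant_averages_existing_edges(self):
        g = sp.lil_matrix((5, 5))
        g[4, 0] = 0.8
        pot = vl.fate_potential(sp.csr_matrix(g), self.labels, APEX, edge_mean=True)
        assert pot.raw[4, 0] == pytest.approx(0.8)  # mean over the one existing edge

    def test_unflagged_rows_sum_to_one(self, rng):
        g = sp.random(40, 40, density=0.1, random_state=1, data_rvs=lambda k: rng.uniform(0.1, 1, k))
        labels = np.array(["A", "B", "C"] * 10 + ["T"] * 10)
        pot = vl.fate_potential(sp.csr_matrix(g), labels, APEX)
        sums = pot.normalized.sum(axis=1)
        np.testing.assert_allclose(sums[~pot.zero_flag], 1.0, atol=1e-12)
        np.testing.assert_array_equal(sums[pot.zero_flag], 0.0)

    def test_empty_apex_cluster_fatal(self):
        with pytest.raises(ValueError, match="'C'"):
            vl.fate_potential(sp.csr_matrix((4, 4)), ["A", "A", "B", "B"], APEX)


def coords_of(W, barcodes=None):
    W = np.asarray(W, float)
    return SimplexCoordinates(
        barycentric=W, cartesian=to_cartesian(W), fate_names=["f1", "f2", "f3"],
        barcodes=barcodes or [f"c{i}" for i in range(len(W))],
    )


def potential_of(P, flags=None):
    P = np.asarray(P, float)
    flags = np.zeros(len(P), bool) if flags is None else np.asarray(flags)
    return vl.FatePotential(raw=P.copy(), normalized=P, zero_flag=flags)


class TestBinArrows:
    def test_default_grid_has_forty_locations(self):
        field = vl.bin_arrows(coords_of(np.full((4, 3), 1 / 3)), potential_of(np.full((4, 3), 1 / 3)))
        assert field.n_bins_x * field.n_bins_y == 40
        assert (field.n_bins_x, field.n_bins_y) == (8, 5)

    @pytest.mark.parametrize("n_bins,shape", [(40, (8, 5)), (1, (1, 1)), (12, (4, 3)), (7, (7, 1))])
    def test_factor_pair_nearest_aspect(self, n_bins, shape):
        assert vl._grid_shape(n_bins) == shape

    def test_invalid_bin_count_fatal(self):
        with pytest.raises(ValueError):
            vl._grid_shape(0)

    def test_single_cell_bin_carries_its_potential(self):
        W = np.array([[1.0, 0.0, 0.0]])  # top vertex, last row of the grid
        P = np.array([[0.2, 0.3, 0.5]])
        field = vl.bin_arrows(coords_of(W), potential_of(P))
        b = field.bin_of_cell[0]
        np.testing.assert_allclose(field.arrows[b], P[0])
        assert field.counts[b] == 1

    def test_flagged_cells_excluded_from_means(self):
        W = np.full((2, 3), 1 / 3)
        P = np.array([[0.9, 0.05, 0.05], [0.0, 0.0, 0.0]])
        field = vl.bin_arrows(coords_of(W), potential_of(P, flags=[False, True]))
        b = field.bin_of_cell[0]
        assert field.counts[b] == 1
        np.testing.assert_allclose(field.arrows[b], P[0])

    def test_matches_brute_force_binning_oracle(self, rng):
        W = rng.dirichlet((1, 1, 1), 300)
        P = rng.dirichlet((1, 1, 1), 300)
        coords = coords_of(W)
        field = vl.bin_arrows(coords, potential_of(P), n_bins=40)
        # independent floor-index arithmetic over the triangle bounding box
        x0, x1 = 0.0, 1.0
        y0, y1 = 0.0, np.sqrt(3) / 2
        xy = coords.cartesian
        ix = np.minimum((xy[:, 0] - x0) / (x1 - x0) * 8, 8 - 1e-9).astype(int)
        iy = np.minimum((xy[:, 1] - y0) / (y1 - y0) * 5, 5 - 1e-9).astype(int)
        flat = iy * 8 + ix
        for b in range(40):
            members = flat == b
            assert field.counts[b] == members.sum()
            if members.any():
                np.testing.assert_allclose(field.arrows[b], P[members].mean(axis=0), atol=1e-12)

    def test_conservation_of_total_potential(self, rng):
        """Sum over bins of count x arrow equals the sum of unflagged potentials."""
        W = rng.dirichlet((1, 1, 1), 150)
        P = rng.dirichlet((1, 1, 1), 150)
        flags = rng.random(150) < 0.2
        P[flags] = 0.0
        field = vl.bin_arrows(coords_of(W), potential_of(P, flags=flags))
        np.testing.assert_allclose(
            (field.counts[:, None] * field.arrows).sum(axis=0),
            P[~flags].sum(axis=0),
            atol=1e-9,
        )
        assert field.counts.sum() == (~flags).sum()

    def test_mismatched_cell_counts_fatal(self):
        with pytest.raises(ValueError):
            vl.bin_arrows(coords_of(np.full((3, 3), 1 / 3)), potential_of(np.full((2, 3), 1 / 3)))


class TestDirectionalityOnSimulation:
    def run_potential(self, induction_delta, seed=3):
        from fatesimplex.simulate import (
            FATE_NAMES,
            SimParams,
            default_apex_spec,
            simulate_fate_landscape,
        )

        params = SimParams(induction_delta=induction_delta, seed=seed)
        adata, truth = simulate_fate_landscape(params)
        norm = pp.normalize_and_log(pp.filter_genes(adata, 10))
        feats = pp.select_variable_features(norm, 3000)
        knn = pp.pca_knn_graph(pp.scale_no_center(norm, feats), 30, 30)
        Ms = pp.knn_smooth(norm.layers["spliced_norm"], knn)
        Mu = pp.knn_smooth(norm.layers["unspliced_norm"], knn)
        gamma, valid = vl.fit_gamma_steady_state(Ms, Mu)
        field = vl.compute_velocity(Ms, Mu, gamma, valid)
        graph = vl.velocity_graph(field, Ms, knn)
        pot = vl.fate_potential(graph, np.asarray(norm.obs["cluster"]), default_apex_spec())
        fate_idx = {f: i for i, f in enumerate(FATE_NAMES)}
        trans = np.array([f is not None for f in truth.destined_fate])
        dest = np.array([fate_idx.get(f, -1) for f in truth.destined_fate])
        return pot, trans, dest

    def test_mean_destined_potential_monotone_in_induction(self):
        """Stronger induction offsets do not weaken the destined-fate pull."""
        means = []
        for delta in (0.2, 0.5, 0.8):
            pot, trans, dest = self.run_potential(delta)
            sel = trans & ~pot.zero_flag
            means.append(pot.normalized[sel, dest[sel]].mean())
        assert means[0] <= means[1] + 1e-12 and means[1] <= means[2] + 1e-12
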