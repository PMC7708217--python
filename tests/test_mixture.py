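import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mrmimpute import (design_matrix, em_fit, fit_least_squares, icl_score,
                       impute_unit, permute_clusters, predict, select_model)
from mrmimpute.mixture import (_Stacked, default_k_max, default_lambda_grid,
                               _fold_ids)
from mrmimpute.simulate import SimConfig, simulate


def region_units(truth, ridx, include_all=True):
    import mrmimpute as m
    region = truth.dataset.regions[ridx]
    x = m.scale_positions(region.positions, region.start, region.end)
    units = [(x[region.mask[s]], region.values[s][region.mask[s]])
             for s in range(region.n_subjects)]
    return region, x, units


class TestEMFit:
    def test_two_group_recovery(self, basis, two_cluster_units):
        units, labels = two_cluster_units
        fit = em_fit(units, basis, K=2, lam=1e-3, seed=0)
        assert adjusted_rand_score(labels, fit.hard_labels()) == 1.0
        np.testing.assert_allclose(fit.pi, [0.5, 0.5], atol=1e-6)
        assert fit.responsibilities.shape == (20, 2)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0)

    def test_k1_lam0_reduces_to_pooled_least_squares(self):
        from mrmimpute import RBFBasis
        b = RBFBasis.equally_spaced(8, 10.0)  # well-conditioned Gram
        rng = np.random.default_rng(2)
        units = [(np.sort(rng.uniform(-1, 1, 25)), rng.uniform(0.2, 0.8, 25))
                 for _ in range(4)]
        fit = em_fit(units, b, K=1, lam=0.0, seed=0, restarts=1)
        xs = np.concatenate([u[0] for u in units])
        ys = np.concatenate([u[1] for u in units])
        ls = fit_least_squares(xs, ys, b, ridge=1e-8)
        np.testing.assert_allclose(fit.weights[0], ls.weights, atol=1e-8)
        np.testing.assert_array_equal(fit.pi, [1.0])

    @pytest.mark.parametrize("lam", [0.0, 0.05, 2.0])
    def test_objective_monotone_up_to_tol(self, basis, two_cluster_units, lam):
        units, _ = two_cluster_units
        fit = em_fit(units, basis, K=2, lam=lam, seed=0, restarts=1)
        trace = fit.objective_trace
        assert trace.size >= 2
        dips = np.diff(trace)
        scale = 1e-6 * (1.0 + np.abs(trace[:-1]))
        assert np.all(dips >= -scale)
        assert trace[-1] >= trace[0]

    def test_large_lambda_shrinks_weights_to_zero(self, basis,
                                                  two_cluster_units):
        units, _ = two_cluster_units
        fit = em_fit(units, basis, K=2, lam=1e6, seed=0, restarts=1)
        assert np.abs(fit.weights).sum() < 1e-6

    def test_empty_clusters_dropped(self, basis):
        rng = np.random.default_rng(4)
        units = [(np.sort(rng.uniform(-1, 1, 8)),
                  np.full(8, 0.5) + rng.normal(0, 0.01, 8)) for _ in range(4)]
        fit = em_fit(units, basis, K=6, lam=0.01, seed=0, restarts=1)
        assert fit.K <= 4
        assert fit.n_dropped >= 2
        np.testing.assert_allclose(fit.pi.sum(), 1.0)

    def test_label_permutation_invariance(self, basis, two_cluster_units):
        units, _ = two_cluster_units
        fit = em_fit(units, basis, K=2, lam=0.05, seed=0)
        flipped = permute_clusters(fit, [1, 0])
        assert flipped.loglik == fit.loglik
        assert icl_score(flipped) == pytest.approx(icl_score(fit))
        x_new = np.linspace(-1, 1, 9)
        for n in (0, 5, 15):
            np.testing.assert_allclose(impute_unit(flipped, n, x_new),
                                       impute_unit(fit, n, x_new))


class TestICL:
    def test_hard_responsibilities_reduce_to_bic(self, basis,
                                                 two_cluster_units):
        units, _ = two_cluster_units
        fit = em_fit(units, basis, K=2, lam=0.0, seed=0, restarts=1)
        fit.responsibilities = np.round(fit.responsibilities)  # exactly hard
        k, j = fit.weights.shape
        p = k * j + (k - 1) + 1
        bic = -2 * fit.loglik_raw + p * np.log(fit.n_obs)
        assert icl_score(fit, df="all", n_basis="points") == pytest.approx(bic)

    def test_k1_formula_instantiation(self, basis):
        rng = np.random.default_rng(6)
        units = [(np.sort(rng.uniform(-1, 1, 20)), rng.uniform(0, 1, 20))
                 for _ in range(3)]
        fit = em_fit(units, basis, K=1, lam=0.0, seed=0, restarts=1)
        expected = -2 * fit.loglik + (basis.J + 1) * np.log(60)
        assert icl_score(fit, df="all", n_basis="points") == pytest.approx(expected)


class TestSelectModel:
    def test_kmax1_equals_em_fit_at_chosen_lambda(self, basis):
        rng = np.random.default_rng(8)
        units = [(np.sort(rng.uniform(-1, 1, 15)), rng.uniform(0.3, 0.7, 15))
                 for _ in range(5)]
        sel = select_model(units, basis, K_max=1, lambda_grid=[0.01, 1.0],
                           seed=0, n_folds=4)
        direct = em_fit(units, basis, K=1, lam=sel.lam, seed=0)
        np.testing.assert_allclose(sel.weights, direct.weights, atol=1e-10)

    def test_noisefree_single_cluster_prefers_smallest_lambda(self, basis):
        x = np.linspace(-1, 1, 40)
        w0 = np.random.default_rng(9).standard_normal(50)
        curve = design_matrix(x, basis) @ w0
        curve = 0.05 + 0.9 * (curve - curve.min()) / np.ptp(curve)
        units = [(x, curve.copy()) for _ in range(4)]
        sel = select_model(units, basis, K_max=1,
                           lambda_grid=[1e-6, 0.5, 5.0], seed=0, n_folds=5)
        assert sel.lam == pytest.approx(1e-6)

    def test_four_cluster_data_selects_at_least_four(self, basis):
        truth = simulate(SimConfig(n_regions=1, n_cpg=50, n_subjects=40,
                                   cluster_props=(0.1, 0.2, 0.3, 0.4),
                                   noise_sd=0.1, missing_rate=0.0, seed=21))
        _, _, units = region_units(truth, 0)
        sel = select_model(units, basis, K_max=8,
                           lambda_grid=[0.3, 3.0, 10.0], seed=0, n_folds=5)
        assert sel.K >= 4


class TestImputeUnit:
    def test_k1_identical_to_rbf_predict(self, basis):
        rng = np.random.default_rng(10)
        x = np.sort(rng.uniform(-1, 1, 30))
        y = rng.uniform(0.2, 0.8, 30)
        fit = em_fit([(x, y)], basis, K=1, lam=0.0, seed=0, restarts=1)
        ls = fit_least_squares(x, y, basis, ridge=1e-8)
        x_new = np.linspace(-1, 1, 17)
        np.testing.assert_allclose(impute_unit(fit, 0, x_new),
                                   predict(ls, x_new), atol=1e-8)

    def test_recovers_cluster_curve_and_stays_bounded(self, basis,
                                                      two_cluster_units):
        units, labels = two_cluster_units
        fit = em_fit(units, basis, K=2, lam=0.05, seed=0)
        x_new = np.linspace(-0.9, 0.9, 25)
        idx = int(np.nonzero(labels == 1)[0][0])
        pred = impute_unit(fit, idx, x_new)
        assert np.all((pred >= 0) & (pred <= 1))
        assert np.allclose(pred, 0.9, atol=0.05)  # within the noise scale
        soft = impute_unit(fit, idx, x_new, assignment="soft")
        np.testing.assert_allclose(soft, pred, atol=0.02)


class TestDefaults:
    def test_k_max_proportional_to_n(self):
        assert default_k_max(4) == 2
        assert default_k_max(20) == 4
        assert default_k_max(200) == 10  # capped

    def test_lambda_grid_scales_with_sd(self):
        y = np.random.default_rng(0).uniform(0, 1, 500)
        grid = default_lambda_grid(y)
        assert grid.size == 8 and np.all(np.diff(grid) > 0)
        np.testing.assert_allclose(grid / np.std(y),
                                   np.geomspace(1e-3, 30, 8))

    def test_fold_ids_partition_points_within_units(self, basis):
        rng = np.random.default_rng(1)
        units = [(np.sort(rng.uniform(-1, 1, n)), rng.uniform(0, 1, n))
                 for n in (1, 2, 7, 23)]
        st = _Stacked(units, basis)
        ids = _fold_ids(st, 10, np.random.default_rng(0))
        # singleton units are never held out
        assert ids[0] == -1
        # every multi-point unit keeps >= 1 training point in every fold
        for n in range(1, 4):
            sl = slice(st.starts[n], st.starts[n + 1])
            for f in range(10):
                assert (ids[sl] != f).sum() >= 1
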