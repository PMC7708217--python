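import numpy as np
import pytest

from mrmimpute import (MethylationDataset, MRMConfig, design_matrix,
                       fit_stacking, impute_regional, impute_stacked,
                       impute_subject, run_method)
from mrmimpute.imputation import StackingWeights, _solve_stacking
from mrmimpute.simulate import SimConfig, simulate
from mrmimpute.evaluation import score_subject

from conftest import make_region


def nnls_two_var_oracle(a1, a2, y):
    """Closed-form NNLS for two columns: solve unconstrained, else clamp."""
    A = np.column_stack([a1, a2])
    try:
        beta = np.linalg.solve(A.T @ A, A.T @ y)
    except np.linalg.LinAlgError:
        beta = np.array([-1.0, -1.0])
    if np.all(beta >= 0):
        return beta
    cands = []
    for keep, other in ((0, 1), (1, 0)):
        b = max(0.0, float(A[:, keep] @ y) / float(A[:, keep] @ A[:, keep]))
        v = np.zeros(2)
        v[keep] = b
        cands.append((np.sum((y - A @ v) ** 2), v))
    return min(cands, key=lambda c: c[0])[1]


@pytest.fixture()
def fast_config():
    # tiny grids keep the full selection pipeline cheap in unit tests
    return MRMConfig(lambda_grid=[0.05, 3.0], n_folds=4)


class TestRegionalModel:
    def test_no_missing_is_identity(self, fast_config):
        truth = simulate(SimConfig(n_regions=2, n_cpg=20, n_subjects=6,
                                   cluster_props=(0.5, 0.5), noise_sd=0.1,
                                   missing_rate=0.0, rbf_centers=20, seed=2))
        res = impute_regional(truth.dataset, fast_config, seed=0)
        for orig, new in zip(truth.dataset, res.dataset):
            np.testing.assert_array_equal(orig.values, new.values)
            assert np.all(res.source[orig.region_id] == "observed")

    def test_two_cluster_recovery(self, fast_config):
        truth = simulate(SimConfig(n_regions=1, n_cpg=50, n_subjects=12,
                                   cluster_props=(0.5, 0.5), noise_sd=0.1,
                                   missing_rate=0.2, seed=3))
        res = impute_regional(truth.dataset, fast_config, seed=0)
        region = truth.dataset.regions[0]
        rid = region.region_id
        hid = ~region.mask
        corr = score_subject(truth.noisy_values[rid][hid],
                             res.dataset.get(rid).values[hid]).correlation
        assert corr >= 0.9
        assert np.all(res.source[rid][hid] == "regional")
        obs = res.dataset.get(rid).values[region.mask]
        np.testing.assert_array_equal(obs, region.values[region.mask])

    def test_single_subject_region_skipped(self, fast_config):
        region = make_region([[0.1, np.nan, 0.3, 0.4]])
        ds = MethylationDataset([region])
        with pytest.warns(UserWarning, match="skipped"):
            res = impute_regional(ds, fast_config, seed=0)
        assert np.isnan(res.dataset.regions[0].values[0, 1])

    def test_subject_order_invariance(self, fast_config):
        truth = simulate(SimConfig(n_regions=1, n_cpg=30, n_subjects=8,
                                   cluster_props=(0.5, 0.5), noise_sd=0.05,
                                   missing_rate=0.2, rbf_centers=30, seed=4))
        ds = truth.dataset
        res = impute_regional(ds, fast_config, seed=0)
        perm = [3, 1, 7, 0, 6, 2, 5, 4]
        region = ds.regions[0]
        permuted = MethylationDataset([make_region(
            region.values[perm], positions=region.positions,
            subject_ids=[region.subject_ids[p] for p in perm])])
        res_p = impute_regional(permuted, fast_config, seed=0)
        np.testing.assert_allclose(res_p.dataset.regions[0].values,
                                   res.dataset.regions[0].values[perm],
                                   atol=1e-8)

    def test_threads_match_serial(self, fast_config):
        truth = simulate(SimConfig(n_regions=2, n_cpg=20, n_subjects=6,
                                   cluster_props=(0.5, 0.5), noise_sd=0.1,
                                   missing_rate=0.3, rbf_centers=20, seed=5))
        serial = impute_regional(truth.dataset, fast_config, seed=0)
        threaded = impute_regional(truth.dataset,
                                   fast_config.replace(threads=2), seed=0)
        for a, b in zip(serial.dataset, threaded.dataset):
            np.testing.assert_array_equal(a.values, b.values)


class TestSubjectModel:
    def _shared_curve_dataset(self, noise_sd=0.1, seed=6):
        """Each subject keeps one curve across all regions; no clusters."""
        rng = np.random.default_rng(seed)
        basis_x = np.linspace(-1, 1, 30)
        n_subj, n_regions = 3, 6
        curves = []
        from mrmimpute import RBFBasis
        b = RBFBasis.equally_spaced(15, 5.0)
        for _ in range(n_subj):
            w = rng.standard_normal(15)
            c = design_matrix(basis_x, b) @ w
            c = 0.1 + 0.8 * (c - c.min()) / np.ptp(c)
            curves.append(c)
        regions = []
        noisy = {}
        for m in range(n_regions):
            vals = np.array([np.clip(c + rng.normal(0, noise_sd, 30), 0, 1)
                             for c in curves])
            mask = np.ones_like(vals, dtype=bool)
            for s in range(n_subj):
                mask[s, rng.choice(30, size=9, replace=False)] = False
            region = make_region(np.where(mask, vals, np.nan),
                                 region_id=f"r{m}",
                                 positions=100 + m * 10_000 + 20 * np.arange(30))
            regions.append(region)
            noisy[f"r{m}"] = vals
        return MethylationDataset(regions), noisy

    def test_recovers_shared_curve(self, fast_config):
        ds, noisy = self._shared_curve_dataset()
        res = impute_subject(ds, fast_config, seed=0)
        t_all, p_all = [], []
        for region in ds:
            hid = ~region.mask
            t_all.append(noisy[region.region_id][hid])
            p_all.append(res.dataset.get(region.region_id).values[hid])
        corr = score_subject(np.concatenate(t_all),
                             np.concatenate(p_all)).correlation
        assert corr >= 0.9

    def test_no_missing_identity(self, fast_config):
        truth = simulate(SimConfig(n_regions=3, n_cpg=15, n_subjects=4,
                                   cluster_props=(1.0,), noise_sd=0.1,
                                   missing_rate=0.0, rbf_centers=15, seed=7))
        res = impute_subject(truth.dataset, fast_config, seed=0)
        for orig, new in zip(truth.dataset, res.dataset):
            np.testing.assert_array_equal(orig.values, new.values)

    def test_single_region_subject_flagged_fallback(self, fast_config):
        region = make_region(np.array([[0.1, 0.5, np.nan, 0.7],
                                       [0.2, 0.4, 0.6, 0.8]]))
        ds = MethylationDataset([region])
        reg = impute_regional(ds, fast_config, seed=0)
        res = impute_subject(ds, fast_config, seed=0, regional_fallback=reg)
        assert any("fewer than 2 usable regions" in f for f in res.flags)
        # filled from the regional model
        assert np.isfinite(res.dataset.regions[0].values[0, 2])
        assert res.source["r0"][0, 2] == "regional"


class TestStacking:
    def test_nnls_matches_two_var_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            yr = rng.uniform(0, 1, 30)
            ys = rng.uniform(0, 1, 30)
            y = rng.uniform(0, 1, 30)
            beta = _solve_stacking(y, yr, ys)
            oracle = nnls_two_var_oracle(yr, ys, y)
            np.testing.assert_allclose(beta, oracle, atol=1e-8)
            assert np.all(beta >= 0)

    def test_perfect_regional_noise_subject(self):
        rng = np.random.default_rng(21)
        y = rng.uniform(0.1, 0.9, 500)
        beta = _solve_stacking(y, y.copy(), rng.uniform(0, 1, 500))
        assert abs(beta[0] - 1.0) < 0.05
        assert beta[1] < 0.05

    def test_collinear_degeneracy_total_weight(self):
        rng = np.random.default_rng(22)
        yhat = rng.uniform(0.1, 0.9, 200)
        y = 0.8 * yhat
        beta = _solve_stacking(y, yhat, yhat.copy())
        assert beta.sum() == pytest.approx(0.8, abs=1e-8)

    def test_fit_stacking_end_to_end(self, fast_config):
        truth = simulate(SimConfig(n_regions=3, n_cpg=20, n_subjects=6,
                                   cluster_props=(0.5, 0.5), noise_sd=0.1,
                                   missing_rate=0.2, rbf_centers=20, seed=8))
        cfg = fast_config.replace(k_fixed=1, lambda_fixed=0.1)
        weights = fit_stacking(truth.dataset, cfg, n_boot=3, seed=0)
        assert weights.per_boot.shape == (3, 2)
        assert weights.beta_r >= 0 and weights.beta_s >= 0
        assert weights.beta_r == pytest.approx(weights.per_boot[:, 0].mean())
        with pytest.raises(ValueError, match="n_boot"):
            fit_stacking(truth.dataset, cfg, n_boot=0, seed=0)

    def test_stacked_with_unit_regional_weight_equals_regional(self,
                                                               fast_config):
        truth = simulate(SimConfig(n_regions=3, n_cpg=20, n_subjects=6,
                                   cluster_props=(0.5, 0.5), noise_sd=0.1,
                                   missing_rate=0.2, rbf_centers=20, seed=9))
        cfg = fast_config.replace(k_fixed=1, lambda_fixed=0.1)
        w = StackingWeights(1.0, 0.0, 1, np.array([[1.0, 0.0]]))
        stacked = impute_stacked(truth.dataset, cfg, seed=0, weights=w)
        regional = impute_regional(truth.dataset, cfg, seed=0)
        for a, b in zip(stacked.dataset, regional.dataset):
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        for region in stacked.dataset:
            assert np.all((region.values >= 0) & (region.values <= 1))


def test_run_method_dispatch(small_sim):
    for method in ("average", "knn"):
        filled = run_method(small_sim.dataset, method, seed=0)
        for region in small_sim.dataset:
            out = filled[region.region_id]
            np.testing.assert_array_equal(out[region.mask],
                                          region.values[region.mask])
            assert np.isfinite(out).all()
    with pytest.raises(ValueError, match="unknown method"):
        run_method(small_sim.dataset, "nope", seed=0)
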