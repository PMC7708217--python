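"""Finite mixture of RBF regressions fitted by penalized EM.

Each unit (a subject's profile in a region, or a region's profile within a
subject) carries observed pairs (x, y) with x rescaled to [-1, 1].  Unit n
belongs to one of K latent clusters with prior pi_k; given cluster k its
values are Gaussian around H(x) w_k with noise variance sigma^2.  The
fitted objective is the l1-penalized log-likelihood

    sum_n log sum_k pi_k prod_i N(y_in; H(x_in) w_k, sigma^2)
        - lambda * sum_k pi_k ||w_k||_1,

maximized by EM with an exact coordinate-descent M-step for the weights.
The number of clusters is chosen by ICL (BIC plus twice the assignment
entropy; lower is better) and lambda by n-fold cross-validation over
held-out observed points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
from numba import njit
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .rbf import RBFBasis, design_matrix

__all__ = [
    "MixtureFit", "em_fit", "icl_score", "select_model",
    "impute_unit", "impute_population", "permute_clusters",
]

_EMPTY_CLUSTER_EPS = 1e-6
_SIGMA2_FLOOR = 1e-6
_LOG_2PI = math.log(2.0 * math.pi)


class EMNumericalError(FloatingPointError):
    """Non-finite likelihood during EM; message carries the iteration index."""


# ---------------------------------------------------------------------------
# weighted-lasso coordinate descent (M-step inner solver)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _cd_lasso(gram, lin, alpha, w, max_pass, tol):  # pragma: no cover - numba
    """Minimize 0.5 w'Gw - lin'w + alpha ||w||_1 by cyclic soft-thresholding."""
    n = gram.shape[0]
    for _ in range(max_pass):
        delta = 0.0
        for j in range(n):
            gjj = gram[j, j]
            old = w[j]
            rho = lin[j] + gjj * old
            for l in range(n):
                rho -= gram[j, l] * w[l]
            if rho > alpha:
                new = (rho - alpha) / gjj
            elif rho < -alpha:
                new = (rho + alpha) / gjj
            else:
                new = 0.0
            d = abs(new - old)
            if d > delta:
                delta = d
            w[j] = new
        if delta < tol:
            break
    return w


# ---------------------------------------------------------------------------
# data staging
# ---------------------------------------------------------------------------

class _Stacked:
    """All units' observed points stacked row-wise with unit bookkeeping.

    Per-unit Gram blocks H_n'H_n and moments H_n'y_n are precomputed once so
    that each EM iteration's weighted normal equations cost O(N J^2) rather
    than O(R J^2) (R = total observed points).
    """

    def __init__(self, units: Sequence[Tuple[np.ndarray, np.ndarray]],
                 basis: RBFBasis):
        xs, ys, sizes = [], [], []
        for x, y in units:
            x = np.atleast_1d(np.asarray(x, dtype=float))
            y = np.atleast_1d(np.asarray(y, dtype=float))
            if x.size != y.size or x.size < 1:
                raise ValueError("every unit needs >= 1 observed (x, y) pair")
            xs.append(x)
            ys.append(y)
            sizes.append(x.size)
        self.sizes = np.asarray(sizes, dtype=np.int64)
        self.n_units = len(units)
        self.starts = np.concatenate([[0], np.cumsum(self.sizes)])
        self.x = np.concatenate(xs)
        self.y = np.concatenate(ys)
        self.h = design_matrix(self.x, basis)
        self.unit_index = np.repeat(np.arange(self.n_units), self.sizes)
        self.basis = basis
        j = self.h.shape[1]
        self.unit_gram = np.empty((self.n_units, j, j))
        self.unit_moment = np.empty((self.n_units, j))
        for n in range(self.n_units):
            sl = slice(self.starts[n], self.starts[n + 1])
            hn = self.h[sl]
            self.unit_gram[n] = hn.T @ hn
            self.unit_moment[n] = hn.T @ self.y[sl]

    @property
    def n_obs(self) -> int:
        return self.y.size


@dataclass
class MixtureFit:
    """A fitted mixture of RBF regressions."""

    K: int
    pi: np.ndarray                # (K,)
    weights: np.ndarray           # (K, J)
    sigma2: np.ndarray            # scalar array () or per-cluster (K,)
    responsibilities: np.ndarray  # (N_units, K)
    lam: float
    loglik: float                 # penalized log-likelihood at convergence
    loglik_raw: float             # unpenalized log-likelihood
    icl: float
    converged: bool
    n_iter: int
    n_obs: int
    basis: RBFBasis
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dropped: int = 0            # clusters removed for emptiness

    def __post_init__(self) -> None:
        assert abs(float(self.pi.sum()) - 1.0) < 1e-10
        assert np.all(self.pi >= 0)
        assert np.all(self.sigma2 > 0)

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)

    def penalty(self) -> float:
        return float(self.lam * (self.pi * np.abs(self.weights).sum(axis=1)).sum())


def _sigma2_per_point(sigma2: np.ndarray, K: int) -> np.ndarray:
    """Broadcast the noise variance to shape (K,) regardless of sharing."""
    s = np.asarray(sigma2, dtype=float)
    return np.full(K, float(s)) if s.ndim == 0 else s


def _unit_sse(st: _Stacked, weights) -> np.ndarray:
    """Per-unit, per-cluster sums of squared residuals, shape (N, K)."""
    resid = st.y[:, None] - st.h @ weights.T          # (R, K)
    return np.add.reduceat(resid * resid, st.starts[:-1], axis=0)


def _e_step_from_sse(st: _Stacked, pi, sse, sigma2):
    s2 = _sigma2_per_point(sigma2, pi.size)
    with np.errstate(divide="ignore"):
        logp = (np.log(pi)[None, :]
                - 0.5 * sse / s2[None, :]
                - 0.5 * st.sizes[:, None] * (np.log(s2)[None, :] + _LOG_2PI))
    norm = logsumexp(logp, axis=1)
    z = np.exp(logp - norm[:, None])
    return z, float(norm.sum())


def _e_step(st: _Stacked, pi, weights, sigma2):
    sse = _unit_sse(st, weights)
    z, loglik = _e_step_from_sse(st, pi, sse, sigma2)
    return z, loglik, sse


def _m_step_weights(st: _Stacked, z, pi, sigma2, lam, weights, ridge,
                    cd_pass: int = 50, cd_tol: float = 1e-8):
    k = pi.size
    s2 = _sigma2_per_point(sigma2, k)
    eye = ridge * np.eye(st.h.shape[1])
    grams = np.tensordot(z.T, st.unit_gram, axes=1) + eye   # (K, J, J)
    lins = z.T @ st.unit_moment                             # (K, J)
    for j in range(k):
        alpha = lam * pi[j] * s2[j]
        if alpha == 0.0:
            # unpenalized: the normal equations solved exactly (CD would crawl
            # along the RBF Gram's tiny eigdirections)
            weights[j] = scipy.linalg.solve(grams[j], lins[j], assume_a="pos")
        else:
            weights[j] = _cd_lasso(grams[j], lins[j], alpha, weights[j].copy(),
                                   cd_pass, cd_tol)
    return weights


def _em_once(st: _Stacked, k: int, lam: float, z_init: np.ndarray,
             max_iter: int, tol: float, ridge: float,
             per_cluster_variance: bool, sigma2_floor: float,
             weights_init: Optional[np.ndarray] = None):
    z = z_init.copy()
    weights = np.zeros((k, st.h.shape[1])) if weights_init is None \
        else weights_init.copy()
    sigma2 = np.asarray(max(float(np.var(st.y)), sigma2_floor))
    if per_cluster_variance:
        sigma2 = np.full(k, float(sigma2))
    obj_prev = -np.inf
    trace = []
    converged = False
    n_dropped = 0
    it = 0
    for it in range(1, max_iter + 1):
        pi = z.mean(axis=0)
        keep = z.sum(axis=0) >= _EMPTY_CLUSTER_EPS
        if not keep.all():
            n_dropped += int((~keep).sum())
            z = z[:, keep]
            z = z / z.sum(axis=1, keepdims=True)
            weights = weights[keep]
            if np.asarray(sigma2).ndim:
                sigma2 = sigma2[keep]
            pi = z.mean(axis=0)
        k_eff = pi.size
        weights = _m_step_weights(st, z, pi, sigma2, lam, weights, ridge)
        sse = _unit_sse(st, weights)
        per_k = (z * sse).sum(axis=0)
        if per_cluster_variance:
            denom = np.maximum((z * st.sizes[:, None]).sum(axis=0), 1e-12)
            sigma2 = np.maximum(per_k / denom, sigma2_floor)
        else:
            sigma2 = np.maximum(np.asarray(per_k.sum() / st.n_obs), sigma2_floor)
        z, loglik = _e_step_from_sse(st, pi, sse, sigma2)
        pen = lam * (pi * np.abs(weights).sum(axis=1)).sum()
        obj = loglik - pen
        if not np.isfinite(obj):
            raise EMNumericalError(f"non-finite penalized likelihood at EM iteration {it}")
        trace.append(obj)
        if abs(obj - obj_prev) < tol * (1.0 + abs(obj)):
            converged = True
            break
        obj_prev = obj
    return dict(pi=pi, weights=weights, sigma2=np.asarray(sigma2), z=z,
                loglik_raw=loglik, obj=obj, converged=converged, n_iter=it,
                trace=np.asarray(trace), n_dropped=n_dropped, k=k_eff)


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    z = np.zeros((labels.size, k))
    z[np.arange(labels.size), labels] = 1.0
    return z


def _unit_features(st: _Stacked, init_ridge: float = 1e-2,
                   grid_size: int = 25) -> np.ndarray:
    """Ridge-smoothed per-unit curves on a common grid (cached on the stack)."""
    cached = getattr(st, "_init_feats", None)
    if cached is not None:
        return cached
    grid = np.linspace(-1.0, 1.0, grid_size)
    hg = design_matrix(grid, st.basis)
    feats = np.empty((st.n_units, grid_size))
    for n in range(st.n_units):
        w = np.linalg.solve(
            st.unit_gram[n] + init_ridge * np.eye(st.basis.J),
            st.unit_moment[n])
        feats[n] = hg @ w
    st._init_feats = feats
    return feats


def _init_labels(st: _Stacked, k: int, seed: int, use_kmeans: bool) -> np.ndarray:
    """Cluster per-unit ridge-smoothed curves with k-means++ (fallback: random).

    Units are processed in a canonical (lexicographic-by-feature) order so the
    initialization — and hence the fit — is invariant to unit ordering.
    """
    rng = np.random.default_rng(seed)
    labels = np.empty(st.n_units, dtype=np.int64)
    if k == 1:
        return np.zeros(st.n_units, dtype=np.int64)
    feats = _unit_features(st)
    order = np.lexsort(feats.T[::-1])
    if k >= st.n_units:
        labels[order] = np.arange(st.n_units) % k
        return labels
    if use_kmeans:
        try:
            km = KMeans(n_clusters=k, n_init=1,
                        random_state=int(seed) % (2**32 - 1))
            labels[order] = km.fit_predict(feats[order]).astype(np.int64)
            return labels
        except Exception:
            pass
    lab = rng.integers(0, k, st.n_units)
    lab[rng.permutation(st.n_units)[:k]] = np.arange(k)  # no empty init
    labels[order] = lab
    return labels


def em_fit(units, basis: RBFBasis, K: int, lam: float, seed: int = 0,
           max_iter: int = 200, tol: float = 1e-6, restarts: int = 5,
           ridge: float = 1e-8, per_cluster_variance: bool = False,
           icl_df: str = "active") -> MixtureFit:
    """Fit a K-cluster mixture of RBF regressions by penalized EM.

    ``restarts`` independent initializations are run with seeds
    seed .. seed+restarts-1 (k-means++ on smoothed per-unit curves, the last
    two restarts randomized) and the best penalized log-likelihood kept.
    Empty clusters (total responsibility below 1e-6) are dropped and K
    reduced, recorded in ``n_dropped``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    st = units if isinstance(units, _Stacked) else _Stacked(units, basis)
    n_random = min(2, max(0, restarts - 1))
    best = None
    for r in range(max(1, restarts)):
        use_kmeans = r < max(1, restarts) - n_random
        labels = _init_labels(st, K, seed + r, use_kmeans)
        res = _em_once(st, K, lam, _one_hot(labels, K), max_iter, tol, ridge,
                       per_cluster_variance, _SIGMA2_FLOOR)
        if best is None or res["obj"] > best["obj"]:
            best = res
    fit = MixtureFit(
        K=best["k"], pi=best["pi"], weights=best["weights"],
        sigma2=best["sigma2"], responsibilities=best["z"], lam=lam,
        loglik=best["obj"], loglik_raw=best["loglik_raw"], icl=np.nan,
        converged=best["converged"], n_iter=best["n_iter"], n_obs=st.n_obs,
        basis=basis, objective_trace=best["trace"], n_dropped=best["n_dropped"],
    )
    fit.icl = icl_score(fit, df=icl_df)
    return fit


def icl_score(fit: MixtureFit, units=None, df: str = "active",
              n_basis: str = "units") -> float:
    """Integrated completed likelihood: BIC plus twice the assignment entropy.

    ICL = -2 loglik + p log(n) - 2 sum_nk z_nk log z_nk with 0 log 0 = 0,
    where loglik is the unpenalized maximized log-likelihood; lower is
    better.  The mixture draws are the units, so the BIC sample size n is
    the number of units by default (``n_basis="points"`` uses the total
    observed points instead).  ``df="active"`` counts only the nonzero RBF
    weights as free parameters, the usual convention for l1-penalized fits;
    ``df="all"`` counts p = K*J + (K-1) + n_variance.
    """
    k, j = fit.weights.shape
    n_var = k if np.asarray(fit.sigma2).ndim else 1
    if df == "active":
        p = int(np.count_nonzero(fit.weights)) + (k - 1) + n_var
    else:
        p = k * j + (k - 1) + n_var
    n = fit.responsibilities.shape[0] if n_basis == "units" else fit.n_obs
    z = fit.responsibilities
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(z > 0, z * np.log(z), 0.0))
    return float(-2.0 * fit.loglik_raw + p * math.log(n) + 2.0 * ent)


def default_k_max(n_units: int) -> int:
    """Cluster-count cap proportional to sample size: max(2, N // 5), <= 10."""
    return min(10, max(2, n_units // 5))


def default_lambda_grid(units_or_y, n: int = 8) -> np.ndarray:
    """8 values log-spaced in [1e-3, 30], scaled by the pooled sd of y.

    The grid is wide on purpose: the coordinate-wise soft threshold of the
    M-step is lambda * pi_k * sigma^2, so with K clusters and noise-scale
    variances an effective amount of shrinkage needs lambda well above the
    data's sd.
    """
    if isinstance(units_or_y, np.ndarray):
        y = units_or_y
    else:
        y = np.concatenate([np.atleast_1d(np.asarray(u[1], float))
                            for u in units_or_y])
    sd = float(np.std(y))
    return np.geomspace(1e-3, 30.0, n) * (sd if sd > 0 else 1.0)


def _fold_ids(st: _Stacked, n_folds: int, rng) -> np.ndarray:
    """Assign each observed point a fold, partitioning within units.

    Units with a single point are never held out (fold -1) so that every
    training fold keeps at least one point per unit.  Units are visited in
    a canonical (feature-sorted) order so the folds — and everything
    downstream — are invariant to unit ordering.
    """
    ids = np.full(st.n_obs, -1, dtype=np.int64)
    order = np.lexsort(_unit_features(st).T[::-1])
    for n in order:
        sl = slice(st.starts[n], st.starts[n + 1])
        size = st.sizes[n]
        if size < 2:
            continue
        perm = rng.permutation(size)
        ids[sl] = perm % n_folds
    return ids


def _cv_errors_path(st, basis, k, grid_desc, fold_ids, n_folds, seed,
                    cv_restarts, max_iter, tol, ridge,
                    per_cluster_variance) -> np.ndarray:
    """CV squared error for each lambda in ``grid_desc`` (descending).

    Within each fold the lambda path is fitted with warm starts: the first
    (largest) lambda initializes from scratch, every later one continues
    from the previous solution.
    """
    errs = np.zeros(grid_desc.size)
    for f in range(n_folds):
        held = fold_ids == f
        if not held.any():
            continue
        train_units, test_parts = [], []
        for n in range(st.n_units):
            sl = slice(st.starts[n], st.starts[n + 1])
            tr = ~held[sl]
            train_units.append((st.x[sl][tr], st.y[sl][tr]))
            test_parts.append((st.x[sl][~tr], st.y[sl][~tr]))
        st_train = _Stacked(train_units, basis)
        warm = None
        for li, lam in enumerate(grid_desc):
            if warm is None:
                best = None
                for r in range(max(1, cv_restarts)):
                    labels = _init_labels(st_train, k, _child_seed(seed, k, f) + r,
                                          use_kmeans=True)
                    res = _em_once(st_train, k, lam, _one_hot(labels, k),
                                   max_iter, tol, ridge, per_cluster_variance,
                                   _SIGMA2_FLOOR)
                    if best is None or res["obj"] > best["obj"]:
                        best = res
                res = best
            else:
                res = _em_once(st_train, warm["k"], lam, warm["z"], max_iter,
                               tol, ridge, per_cluster_variance, _SIGMA2_FLOOR,
                               weights_init=warm["weights"])
            warm = res
            hw = res["weights"][np.argmax(res["z"], axis=1)]     # (N, J)
            for n, (xt, yt) in enumerate(test_parts):
                if xt.size:
                    pred = np.clip(design_matrix(xt, basis) @ hw[n], 0.0, 1.0)
                    errs[li] += float(np.sum((pred - yt) ** 2))
    return errs


def _child_seed(seed: int, k: int, fold: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31),
                                spawn_key=(k, fold))
    return int(ss.generate_state(1)[0] % (2**31))


def select_model(units, basis: RBFBasis, K_max: Optional[int] = None,
                 lambda_grid=None, seed: int = 0, n_folds: int = 10,
                 restarts: int = 5, cv_restarts: int = 1,
                 max_iter: int = 200, tol: float = 1e-6, ridge: float = 1e-8,
                 per_cluster_variance: bool = False,
                 icl_df: str = "active", cv_max_iter: int = 40,
                 K_values: Optional[Sequence[int]] = None) -> MixtureFit:
    """Pick lambda by n-fold CV (per K) and K by lowest ICL; refit on all data.

    Held-out observed points within each unit are predicted from the fit on
    the remaining points and scored by squared error; ties on the CV error
    resolve to the smallest lambda.  ``K_values`` restricts the candidate
    cluster counts (default 1..K_max).
    """
    st = _Stacked(units, basis)
    if K_max is None:
        K_max = default_k_max(st.n_units)
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    grid = np.sort(np.asarray(
        default_lambda_grid(st.y) if lambda_grid is None else lambda_grid,
        dtype=float))
    if grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    rng = np.random.default_rng(seed)
    fold_ids = _fold_ids(st, n_folds, rng)

    best_fit = None
    failures = []
    if K_values is None:
        K_values = range(1, K_max + 1)
    for k in K_values:
        try:
            if grid.size == 1:
                lam_star = float(grid[0])
            else:
                grid_desc = grid[::-1]
                errs = _cv_errors_path(st, basis, k, grid_desc, fold_ids,
                                       n_folds, seed, cv_restarts,
                                       cv_max_iter, tol, ridge,
                                       per_cluster_variance)
                # ties (within numerical noise) resolve to the smallest lambda
                lam_star = float(grid_desc[np.nonzero(
                    errs <= errs.min() * (1 + 1e-12))[0][-1]])
            fit = em_fit(st, basis, k, lam_star, seed=seed, restarts=restarts,
                         max_iter=max_iter, tol=tol, ridge=ridge,
                         per_cluster_variance=per_cluster_variance,
                         icl_df=icl_df)
        except EMNumericalError as exc:
            failures.append((k, exc))
            continue
        if best_fit is None or fit.icl < best_fit.icl:
            best_fit = fit
    if best_fit is None:
        raise EMNumericalError(f"all candidate fits failed: {failures}")
    return best_fit


def impute_unit(fit: MixtureFit, unit_index: int, x_missing,
                assignment: str = "hard", clip: bool = True) -> np.ndarray:
    """Predict a fitted unit's values at new scaled coordinates.

    "hard" uses the argmax-responsibility cluster (ties break to the lowest
    cluster index); "soft" mixes the cluster curves by the posterior.
    """
    h = design_matrix(x_missing, fit.basis)
    z = fit.responsibilities[unit_index]
    if assignment == "hard":
        pred = h @ fit.weights[int(np.argmax(z))]
    elif assignment == "soft":
        pred = (h @ fit.weights.T) @ z
    else:
        raise ValueError("assignment must be 'hard' or 'soft'")
    return np.clip(pred, 0.0, 1.0) if clip else pred


def impute_population(fit: MixtureFit, x, clip: bool = True) -> np.ndarray:
    """Prior-weighted population mean curve, for units with no observed data."""
    pred = (design_matrix(x, fit.basis) @ fit.weights.T) @ fit.pi
    return np.clip(pred, 0.0, 1.0) if clip else pred


def permute_clusters(fit: MixtureFit, perm) -> MixtureFit:
    """Relabel clusters; the likelihood, ICL and imputations are unchanged."""
    perm = np.asarray(perm)
    s2 = fit.sigma2[perm] if np.asarray(fit.sigma2).ndim else fit.sigma2
    return MixtureFit(
        K=fit.K, pi=fit.pi[perm], weights=fit.weights[perm], sigma2=s2,
        responsibilities=fit.responsibilities[:, perm], lam=fit.lam,
        loglik=fit.loglik, loglik_raw=fit.loglik_raw, icl=fit.icl,
        converged=fit.converged, n_iter=fit.n_iter, n_obs=fit.n_obs,
        basis=fit.basis, objective_trace=fit.objective_trace,
        n_dropped=fit.n_dropped,
    )
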