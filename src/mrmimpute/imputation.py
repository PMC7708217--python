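"""Regional and subject-wise mixture imputation, and their stacked blend.

The regional model clusters subjects within each region; the subject model
clusters each subject's regions (each region's positions rescaled to
[-1, 1] independently so profiles are comparable).  The two predictions at
a missing cell are combined as beta_r * yhat_r + beta_s * yhat_s, where the
non-negative weights solve a least-squares stacking problem trained on
artificially masked observed cells and averaged over bootstrap replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import lsq_linear, nnls

from .config import DEFAULT_CONFIG, MRMConfig
from .io import MethylationDataset, RegionMatrix
from .mixture import (MixtureFit, em_fit, impute_population, impute_unit,
                      select_model)
from .rbf import RBFBasis, scale_positions

__all__ = ["StackingWeights", "ImputationResult", "impute_regional",
           "impute_subject", "fit_stacking", "impute_stacked", "run_method"]


@dataclass
class StackingWeights:
    beta_r: float
    beta_s: float
    n_boot: int
    per_boot: np.ndarray  # (n_boot, 2) per-replicate (beta_r, beta_s)

    def __post_init__(self) -> None:
        assert self.beta_r >= 0 and self.beta_s >= 0
        assert np.allclose([self.beta_r, self.beta_s],
                           self.per_boot.mean(axis=0))


@dataclass
class ImputationResult:
    dataset: MethylationDataset
    source: Dict[str, np.ndarray]            # region_id -> (N, I) cell tags
    regional_values: Dict[str, np.ndarray] = field(default_factory=dict)
    subject_values: Dict[str, np.ndarray] = field(default_factory=dict)
    fits: Dict[str, dict] = field(default_factory=dict)
    stacking: Optional[StackingWeights] = None
    flags: List[str] = field(default_factory=list)

    def filled(self) -> Dict[str, np.ndarray]:
        return {r.region_id: r.values for r in self.dataset}


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def _basis(config: MRMConfig) -> RBFBasis:
    return RBFBasis.equally_spaced(config.rbf_centers, config.rbf_scale)


def _fit_units(units, basis, config: MRMConfig, seed: int, n_units: int
               ) -> MixtureFit:
    """Dispatch to a fixed-K/fixed-lambda fit or full model selection."""
    if config.k_fixed is not None and config.lambda_fixed is not None:
        return em_fit(units, basis, config.k_fixed, config.lambda_fixed,
                      seed=seed, max_iter=config.em_max_iter, tol=config.em_tol,
                      restarts=config.restarts, ridge=config.ridge,
                      per_cluster_variance=config.per_cluster_variance,
                      icl_df=config.icl_df)
    k_values = [config.k_fixed] if config.k_fixed is not None else None
    grid = [config.lambda_fixed] if config.lambda_fixed is not None \
        else config.lambda_grid
    return select_model(units, basis, K_max=config.k_max, K_values=k_values,
                        lambda_grid=grid, seed=seed, n_folds=config.n_folds,
                        restarts=config.restarts, cv_restarts=config.cv_restarts,
                        max_iter=config.em_max_iter, tol=config.em_tol,
                        cv_max_iter=config.cv_max_iter,
                        ridge=config.ridge,
                        per_cluster_variance=config.per_cluster_variance,
                        icl_df=config.icl_df)


def _fit_summary(fit: MixtureFit) -> dict:
    return dict(K=int(fit.K), lam=float(fit.lam), icl=float(fit.icl),
                loglik=float(fit.loglik), n_iter=int(fit.n_iter),
                converged=bool(fit.converged), n_dropped=int(fit.n_dropped))


# ---------------------------------------------------------------------------
# regional model
# ---------------------------------------------------------------------------

def _impute_one_region(region: RegionMatrix, config: MRMConfig, seed: int):
    x = scale_positions(region.positions, region.start, region.end)
    unit_subjects = [s for s in range(region.n_subjects) if region.mask[s].any()]
    n_rich = sum(region.mask[s].sum() >= 2 for s in unit_subjects)
    if len(unit_subjects) < 2 or n_rich < 2:
        return None  # caller warns and skips
    units = [(x[region.mask[s]], region.values[s][region.mask[s]])
             for s in unit_subjects]
    fit = _fit_units(units, _basis(config), config, seed, len(units))
    filled = region.values.copy()
    source = np.where(region.mask, "observed", "missing").astype("<U10")
    flags = []
    index_of = {s: u for u, s in enumerate(unit_subjects)}
    for s in range(region.n_subjects):
        miss = ~region.mask[s]
        if not miss.any():
            continue
        if s in index_of:
            pred = impute_unit(fit, index_of[s], x[miss],
                               assignment=config.assignment, clip=config.clip)
        else:
            pred = impute_population(fit, x[miss], clip=config.clip)
            flags.append(f"{region.region_id}/{region.subject_ids[s]}: "
                         f"no observed points; population-mean curve")
        filled[s, miss] = pred
        source[s, miss] = "regional"
    return filled, source, _fit_summary(fit), flags


def impute_regional(dataset: MethylationDataset, config: MRMConfig = None,
                    seed: Optional[int] = None) -> ImputationResult:
    """Fit the mixture per region across subjects and fill missing cells.

    Regions with fewer than 2 subjects carrying >= 2 observed points are
    skipped with a warning and their cells left missing.  Per-region fits
    are independent; with ``config.threads > 1`` they run in parallel with
    results identical to serial execution (seeds are fixed per region).
    """
    config = config or DEFAULT_CONFIG
    seed = config.seed if seed is None else seed
    out = dataset.copy()
    seeds = [_child_seed(seed, 0, m) for m in range(len(out.regions))]
    jobs = (delayed(_impute_one_region)(r, config, s)
            for r, s in zip(out.regions, seeds))
    if config.threads > 1:
        results = Parallel(n_jobs=config.threads)(jobs)
    else:
        results = [f(*a, **k) for f, a, k in jobs]
    source, fits, all_flags = {}, {}, []
    for region, res in zip(out.regions, results):
        if res is None:
            warnings.warn(f"region {region.region_id}: fewer than 2 subjects "
                          f"with >= 2 observed points; skipped")
            source[region.region_id] = np.where(
                region.mask, "observed", "missing").astype("<U10")
            continue
        filled, src, summary, flags = res
        region.values = filled
        source[region.region_id] = src
        fits[region.region_id] = summary
        all_flags.extend(flags)
    regional_values = {r.region_id: r.values.copy() for r in out.regions}
    return ImputationResult(dataset=out, source=source,
                            regional_values=regional_values,
                            fits={"regional": fits}, flags=all_flags)


# ---------------------------------------------------------------------------
# subject model
# ---------------------------------------------------------------------------

def impute_subject(dataset: MethylationDataset, config: MRMConfig = None,
                   seed: Optional[int] = None,
                   regional_fallback: Optional[ImputationResult] = None
                   ) -> ImputationResult:
    """Fit the mixture per subject across that subject's regions.

    Units are the subject's regions, each region's positions scaled to
    [-1, 1] independently.  A subject with fewer than 2 usable regions is
    flagged and, when a regional result is supplied, filled from it.
    """
    config = config or DEFAULT_CONFIG
    seed = config.seed if seed is None else seed
    out = dataset.copy()
    source = {r.region_id: np.where(r.mask, "observed", "missing").astype("<U10")
              for r in out.regions}
    fits, flags = {}, []
    scaled = {r.region_id: scale_positions(r.positions, r.start, r.end)
              for r in out.regions}
    for s in range(out.n_subjects):
        sid = out.subject_ids[s]
        usable = [r for r in out.regions if r.mask[s].any()]
        if len(usable) < 2:
            flags.append(f"{sid}: fewer than 2 usable regions; "
                         f"regional fallback")
            if regional_fallback is not None:
                for region in out.regions:
                    miss = ~region.mask[s]
                    fb = regional_fallback.dataset.get(region.region_id)
                    good = miss & np.isfinite(fb.values[s])
                    region.values[s, good] = fb.values[s, good]
                    source[region.region_id][s, good] = "regional"
            continue
        units = [(scaled[r.region_id][r.mask[s]], r.values[s][r.mask[s]])
                 for r in usable]
        fit = _fit_units(units, _basis(config), config,
                         _child_seed(seed, 1, s), len(units))
        fits[sid] = _fit_summary(fit)
        index_of = {r.region_id: u for u, r in enumerate(usable)}
        for region in out.regions:
            miss = ~region.mask[s]
            if not miss.any():
                continue
            x_miss = scaled[region.region_id][miss]
            if region.region_id in index_of:
                pred = impute_unit(fit, index_of[region.region_id], x_miss,
                                   assignment=config.assignment,
                                   clip=config.clip)
            else:
                pred = impute_population(fit, x_miss, clip=config.clip)
                flags.append(f"{region.region_id}/{sid}: no observed points; "
                             f"population-mean curve")
            region.values[s, miss] = pred
            source[region.region_id][s, miss] = "subject"
    subject_values = {r.region_id: r.values.copy() for r in out.regions}
    return ImputationResult(dataset=out, source=source,
                            subject_values=subject_values,
                            fits={"subject": fits}, flags=flags)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

def _solve_stacking(y, yr, ys, intercept: bool = False) -> np.ndarray:
    """Non-negative least squares for y ~ beta_r yr + beta_s ys.

    The printed constraint is strict (beta > 0); it is implemented as
    beta >= 0 so the minimum is attained, and exact zeros are reported.
    """
    a = np.column_stack([yr, ys])
    if intercept:
        a = np.column_stack([a, np.ones_like(yr)])
        res = lsq_linear(a, y, bounds=([0, 0, -np.inf], [np.inf] * 3))
        return res.x[:2]
    beta, _ = nnls(a, y)
    return beta


def fit_stacking(dataset: MethylationDataset, config: MRMConfig = None,
                 n_boot: Optional[int] = None,
                 artificial_frac: Optional[float] = None,
                 seed: Optional[int] = None) -> StackingWeights:
    """Estimate the stacking weights by bootstrapped artificial masking.

    Each replicate masks a fraction of the observed cells (disjoint from the
    truly missing ones), runs both component models, and solves the
    non-negative least-squares problem on (truth, yhat_r, yhat_s) triples at
    the artificial cells; the final weights are the means over replicates.
    """
    config = config or DEFAULT_CONFIG
    n_boot = config.n_boot if n_boot is None else n_boot
    frac = config.artificial_frac if artificial_frac is None else artificial_frac
    seed = config.seed if seed is None else seed
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cells = [(m, s, i)
             for m, region in enumerate(dataset.regions)
             for s, i in zip(*np.nonzero(region.mask))]
    if not cells:
        raise ValueError("dataset has no observed cells")
    n_art = max(1, int(np.floor(frac * len(cells))))
    per_boot = np.empty((n_boot, 2))
    for b in range(n_boot):
        rng = np.random.default_rng(_child_seed(seed, 2, b))
        picks = rng.choice(len(cells), size=n_art, replace=False)
        masked = dataset.copy()
        for c in picks:
            m, s, i = cells[c]
            masked.regions[m].values[s, i] = np.nan
            masked.regions[m].mask[s, i] = False
        reg = impute_regional(masked, config, seed=_child_seed(seed, 3, b))
        subj = impute_subject(masked, config, seed=_child_seed(seed, 4, b),
                              regional_fallback=reg)
        y, yr, ys = [], [], []
        for c in picks:
            m, s, i = cells[c]
            vr = reg.dataset.regions[m].values[s, i]
            vs = subj.dataset.regions[m].values[s, i]
            if np.isfinite(vr) and np.isfinite(vs):
                y.append(dataset.regions[m].values[s, i])
                yr.append(vr)
                ys.append(vs)
        if not y:
            raise ValueError("no artificial cells received both predictions")
        per_boot[b] = _solve_stacking(np.asarray(y), np.asarray(yr),
                                      np.asarray(ys),
                                      intercept=config.stack_intercept)
    beta = per_boot.mean(axis=0)
    return StackingWeights(beta_r=float(beta[0]), beta_s=float(beta[1]),
                           n_boot=n_boot, per_boot=per_boot)


def impute_stacked(dataset: MethylationDataset, config: MRMConfig = None,
                   seed: Optional[int] = None,
                   weights: Optional[StackingWeights] = None
                   ) -> ImputationResult:
    """Fill missing cells with the stacked regional + subject prediction."""
    config = config or DEFAULT_CONFIG
    seed = config.seed if seed is None else seed
    if weights is None:
        weights = fit_stacking(dataset, config, seed=seed)
    reg = impute_regional(dataset, config, seed=seed)
    subj = impute_subject(dataset, config, seed=seed, regional_fallback=reg)
    out = dataset.copy()
    source = {}
    for region, r_reg, r_sub in zip(out.regions, reg.dataset.regions,
                                    subj.dataset.regions):
        src = np.where(region.mask, "observed", "missing").astype("<U10")
        miss = ~region.mask
        vr, vs = r_reg.values, r_sub.values
        both = miss & np.isfinite(vr) & np.isfinite(vs) \
            & (np.asarray(subj.source[region.region_id]) == "subject")
        stacked = weights.beta_r * vr + weights.beta_s * vs
        if config.clip:
            stacked = np.clip(stacked, 0.0, 1.0)
        region.values[both] = stacked[both]
        src[both] = "stacked"
        reg_only = miss & ~both & np.isfinite(vr)
        region.values[reg_only] = vr[reg_only]
        src[reg_only] = "regional"
        source[region.region_id] = src
    return ImputationResult(
        dataset=out, source=source,
        regional_values={r.region_id: r.values.copy() for r in reg.dataset},
        subject_values={r.region_id: r.values.copy() for r in subj.dataset},
        fits={**reg.fits, **subj.fits}, stacking=weights,
        flags=reg.flags + subj.flags)


# ---------------------------------------------------------------------------
# method dispatch (used by the evaluation harness and the CLI)
# ---------------------------------------------------------------------------

def run_method(dataset: MethylationDataset, method: str,
               config: MRMConfig = None, seed: int = 0
               ) -> Dict[str, np.ndarray]:
    """Run one imputer; returns region_id -> (N, I) filled value arrays."""
    from .baselines import knn_impute, weighted_neighbor_average

    config = config or DEFAULT_CONFIG
    if method == "regional":
        return impute_regional(dataset, config, seed=seed).filled()
    if method == "subject":
        reg = impute_regional(dataset, config, seed=seed)
        return impute_subject(dataset, config, seed=seed,
                              regional_fallback=reg).filled()
    if method == "stacked":
        return impute_stacked(dataset, config, seed=seed).filled()
    if method == "average":
        return {r.region_id: weighted_neighbor_average(r) for r in dataset}
    if method == "knn":
        return {r.region_id: knn_impute(r, k=config.knn_k,
                                        scaled_distance=config.knn_scaled_distance)
                for r in dataset}
    raise ValueError(f"unknown method {method!r}")
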