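"""Competing imputers used for benchmarking.

Two simple strategies from the methylation-imputation literature: the
distance-weighted average of the closest flanking CpGs within a subject,
and row-wise k-nearest-neighbour imputation on the CpG x subject matrix.
Both only ever average observed values, so their outputs stay in [0, 1]
and observed cells are never modified.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import RegionMatrix

__all__ = ["weighted_neighbor_average", "knn_impute"]


def weighted_neighbor_average(region: RegionMatrix) -> np.ndarray:
    """Fill missing cells from the closest observed up/downstream CpGs.

    With upstream value v_u at distance d_u and downstream v_d at d_d the
    imputed value is (v_u/d_u + v_d/d_d) / (1/d_u + 1/d_d); with a single
    flanking neighbour its value is copied.  A subject with no observed
    value in the region falls back to the region-wide mean of observed
    values (flagged with a warning).
    """
    pos = region.positions.astype(float)
    out = region.values.copy()
    overall = np.nanmean(region.values) if region.mask.any() else 0.5
    for s in range(region.n_subjects):
        obs = np.nonzero(region.mask[s])[0]
        miss = np.nonzero(~region.mask[s])[0]
        if miss.size == 0:
            continue
        if obs.size == 0:
            warnings.warn(
                f"region {region.region_id}, subject {region.subject_ids[s]!r}: "
                f"no observed values; using region mean")
            out[s, miss] = overall
            continue
        # index of the first observed site strictly downstream of each miss
        nxt = np.searchsorted(obs, miss)
        for j, i in zip(nxt, miss):
            up = obs[j - 1] if j > 0 else None
            down = obs[j] if j < obs.size else None
            if up is not None and down is not None:
                du = pos[i] - pos[up]
                dd = pos[down] - pos[i]
                out[s, i] = ((region.values[s, up] / du + region.values[s, down] / dd)
                             / (1.0 / du + 1.0 / dd))
            elif up is not None:
                out[s, i] = region.values[s, up]
            else:
                out[s, i] = region.values[s, down]
    return out


def knn_impute(region: RegionMatrix, k: int = 10,
               scaled_distance: bool = False) -> np.ndarray:
    """k-nearest-neighbour imputation on the CpG x subject matrix.

    Rows are CpGs, columns subjects.  For each CpG row with missing entries,
    Euclidean distances to every other row are computed over the columns
    where the target row is observed (restricted to co-observed entries;
    ``scaled_distance`` divides by the number of such entries).  Each
    missing entry is the mean of the k nearest rows' observed entries in
    that column; if all k neighbours are missing there, the target CpG's own
    observed mean is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mat = region.values.T.copy()     # (I, N): CpGs x subjects
    msk = region.mask.T
    n_rows = mat.shape[0]
    if k > n_rows - 1:
        warnings.warn(f"k={k} reduced to {n_rows - 1} available CpG rows")
        k = max(1, n_rows - 1)
    out = mat.copy()
    overall = np.nanmean(mat) if msk.any() else 0.5
    for i in range(n_rows):
        miss_cols = np.nonzero(~msk[i])[0]
        if miss_cols.size == 0:
            continue
        row_obs = msk[i]
        if not row_obs.any():
            out[i, miss_cols] = overall
            continue
        co = row_obs[None, :] & msk                      # (I, N) co-observed
        diff = np.where(co, mat[i][None, :] - np.where(msk, mat, 0.0), 0.0)
        d2 = np.einsum("ij,ij->i", diff, diff)
        n_co = co.sum(axis=1)
        if scaled_distance:
            with np.errstate(invalid="ignore", divide="ignore"):
                d2 = d2 / n_co
        d2 = np.where(n_co > 0, d2, np.inf)
        d2[i] = np.inf
        order = np.argsort(d2, kind="stable")
        neighbors = order[:k]
        neighbors = neighbors[np.isfinite(d2[neighbors])]
        row_mean = float(np.mean(mat[i][row_obs]))
        for c in miss_cols:
            vals = mat[neighbors, c][msk[neighbors, c]]
            out[i, c] = float(vals.mean()) if vals.size else row_mean
    return out.T
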