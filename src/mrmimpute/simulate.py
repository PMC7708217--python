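"""Synthetic methylation data drawn from the mixture-of-RBF model.

The benchmark generator: per region, K cluster weight vectors are drawn
i.i.d. standard normal, turned into curves on equally spaced positions with
the configured RBF basis, and affinely rescaled into [0.05, 0.95] so each
curve is a valid probability profile with visible dynamic range.  Subjects
are assigned clusters from Multinomial(pi) independently per region,
Gaussian noise is added to the probabilities (clipped back to [0, 1]), and
a fixed fraction of cells per subject is masked by exact-count subsampling.

The default configuration matches the benchmark conditions: 100 regions of
50 CpGs, cluster proportions (0.1, 0.2, 0.3, 0.4), 50 RBF centers at scale
10.  A smooth-profile generator (shared spline mean curve + beta-distributed
subject noise) is included as a synthetic stand-in for read-level simulators,
for model-misspecification tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .io import MethylationDataset, RegionMatrix
from .rbf import RBFBasis, design_matrix

logger = logging.getLogger(__name__)

_CURVE_LO, _CURVE_HI = 0.05, 0.95
_CPG_SPACING = 20      # bp between simulated CpGs (cosmetic; model uses scaled x)
_REGION_GAP = 5000     # bp between simulated regions


@dataclass
class SimConfig:
    n_regions: int = 100
    n_cpg: int = 50
    n_subjects: int = 20
    cluster_props: Sequence[float] = (0.1, 0.2, 0.3, 0.4)
    noise_sd: float = 0.2
    missing_rate: float = 0.2
    rbf_centers: int = 50
    rbf_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.cluster_props, dtype=float)
        if props.ndim != 1 or props.size < 1 or np.any(props < 0):
            raise ValueError("cluster_props must be a non-negative vector")
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("cluster_props must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.cluster_props = tuple(float(p) for p in props)


@dataclass
class SimTruth:
    """A simulated dataset plus everything the generator knows about it."""

    dataset: MethylationDataset
    full_values: Dict[str, np.ndarray]     # region_id -> (N, I) noise-free
    noisy_values: Dict[str, np.ndarray]    # region_id -> (N, I) pre-masking
    labels: Dict[str, np.ndarray]          # region_id -> (N,) true clusters
    cluster_curves: Dict[str, np.ndarray]  # region_id -> (K, I) mean curves
    config: Optional[SimConfig] = None

    def hidden_truth(self) -> Dict[str, np.ndarray]:
        """Per region, the pre-masking values at masked cells (NaN elsewhere)."""
        out = {}
        for region in self.dataset:
            t = np.full(region.values.shape, np.nan)
            hid = ~region.mask
            t[hid] = self.noisy_values[region.region_id][hid]
            out[region.region_id] = t
        return out


def _rescale_curve(curve: np.ndarray) -> np.ndarray:
    lo, hi = float(curve.min()), float(curve.max())
    if hi - lo < 1e-12:
        return np.full_like(curve, 0.5)
    return _CURVE_LO + (_CURVE_HI - _CURVE_LO) * (curve - lo) / (hi - lo)


def simulate(config: SimConfig) -> SimTruth:
    """Draw a complete :class:`SimTruth` from the mixture-of-RBF model."""
    rng = np.random.default_rng(config.seed)
    basis = RBFBasis.equally_spaced(config.rbf_centers, config.rbf_scale)
    x = np.linspace(-1.0, 1.0, config.n_cpg)
    h = design_matrix(x, basis)
    props = np.asarray(config.cluster_props)
    k = props.size
    n, i = config.n_subjects, config.n_cpg
    subject_ids = [f"S{j:03d}" for j in range(n)]
    n_mask = int(np.floor(config.missing_rate * i))

    regions, full, noisy, labels, curves = [], {}, {}, {}, {}
    n_clipped = 0
    for m in range(config.n_regions):
        rid = f"region_{m:04d}"
        w = rng.standard_normal((k, basis.J))
        region_curves = np.array([_rescale_curve(h @ wk) for wk in w])  # (K, I)
        lab = rng.choice(k, size=n, p=props)
        clean = region_curves[lab]                                      # (N, I)
        vals = clean + rng.normal(0.0, config.noise_sd, size=(n, i)) \
            if config.noise_sd > 0 else clean.copy()
        n_clipped += int(np.sum((vals < 0) | (vals > 1)))
        vals = np.clip(vals, 0.0, 1.0)
        mask = np.ones((n, i), dtype=bool)
        for s in range(n):
            if n_mask:
                mask[s, rng.choice(i, size=n_mask, replace=False)] = False
        start = 1 + m * (i * _CPG_SPACING + _REGION_GAP)
        positions = start + np.arange(i) * _CPG_SPACING
        masked_vals = np.where(mask, vals, np.nan)
        regions.append(RegionMatrix(
            region_id=rid, chrom="chr1", start=int(positions[0]),
            end=int(positions[-1]), positions=positions, values=masked_vals,
            mask=mask, subject_ids=subject_ids,
        ))
        full[rid], noisy[rid], labels[rid], curves[rid] = clean, vals, lab, region_curves
    if n_clipped:
        logger.info("simulate: clipped %d of %d values into [0, 1]",
                    n_clipped, config.n_regions * n * i)
    dataset = MethylationDataset(regions, provenance=f"mrm-sim seed={config.seed}")
    return SimTruth(dataset, full, noisy, labels, curves, config)


def inject_missing(dataset: MethylationDataset, rate: float, seed: int = 0
                   ) -> Tuple[MethylationDataset, Dict[str, np.ndarray]]:
    """Hide a fraction of the *observed* cells; return the hidden truth.

    Per subject per region, floor(rate * n_observed) cells are hidden without
    replacement (exact-count subsampling).  Hiding never leaves a subject
    with fewer than 2 observed points in a region; where it would, less is
    hidden and a warning is issued.  The hidden truth is returned as
    region_id -> (N, I) arrays, NaN except at the hidden cells.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    masked = dataset.copy()
    hidden: Dict[str, np.ndarray] = {}
    for region in masked:
        truth = np.full(region.values.shape, np.nan)
        for s in range(region.n_subjects):
            obs_idx = np.nonzero(region.mask[s])[0]
            n_hide = int(np.floor(rate * obs_idx.size))
            if obs_idx.size - n_hide < 2:
                reduced = max(0, obs_idx.size - 2)
                if reduced < n_hide:
                    warnings.warn(
                        f"region {region.region_id}, subject "
                        f"{region.subject_ids[s]!r}: hiding reduced "
                        f"{n_hide} -> {reduced} to keep 2 observed points")
                n_hide = reduced
            if n_hide == 0:
                continue
            hide = rng.choice(obs_idx, size=n_hide, replace=False)
            truth[s, hide] = region.values[s, hide]
            region.values[s, hide] = np.nan
            region.mask[s, hide] = False
        hidden[region.region_id] = truth
    return masked, hidden


def simulate_smooth_profile(n_regions: int = 10, n_cpg: int = 50,
                            n_subjects: int = 20, concentration: float = 30.0,
                            missing_rate: float = 0.2, n_knots: int = 6,
                            seed: int = 0) -> SimTruth:
    """Synthetic stand-in for profile-based bisulfite-sequencing simulators.

    Each region gets one random cubic-spline mean curve in [0.1, 0.9] shared
    by all subjects; subject values are Beta-distributed around the curve
    with the given concentration.  There is no cluster structure, so this
    deliberately violates the mixture model's assumptions — useful for
    misspecification tests only.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(-1.0, 1.0, n_cpg)
    subject_ids = [f"S{j:03d}" for j in range(n_subjects)]
    n_mask = int(np.floor(missing_rate * n_cpg))
    regions, full, noisy, labels, curves = [], {}, {}, {}, {}
    for m in range(n_regions):
        rid = f"region_{m:04d}"
        knots_x = np.linspace(-1.0, 1.0, n_knots)
        knots_y = rng.uniform(0.1, 0.9, size=n_knots)
        curve = np.clip(CubicSpline(knots_x, knots_y)(x), 0.01, 0.99)
        a = curve * concentration
        b = (1.0 - curve) * concentration
        vals = rng.beta(a, b, size=(n_subjects, n_cpg))
        mask = np.ones((n_subjects, n_cpg), dtype=bool)
        for s in range(n_subjects):
            if n_mask:
                mask[s, rng.choice(n_cpg, size=n_mask, replace=False)] = False
        start = 1 + m * (n_cpg * _CPG_SPACING + _REGION_GAP)
        positions = start + np.arange(n_cpg) * _CPG_SPACING
        regions.append(RegionMatrix(
            region_id=rid, chrom="chr1", start=int(positions[0]),
            end=int(positions[-1]), positions=positions,
            values=np.where(mask, vals, np.nan), mask=mask,
            subject_ids=subject_ids,
        ))
        full[rid] = np.tile(curve, (n_subjects, 1))
        noisy[rid] = vals
        labels[rid] = np.zeros(n_subjects, dtype=np.int64)
        curves[rid] = curve[None, :]
    dataset = MethylationDataset(regions, provenance=f"smooth-sim seed={seed}")
    return SimTruth(dataset, full, noisy, labels, curves, None)
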