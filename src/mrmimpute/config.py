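"""Run-time configuration shared by the imputation pipeline.

Defaults mirror the benchmark settings of the method: 50 equally spaced RBF
centers per region, scale delta = 10 on positions rescaled to [-1, 1], a
10-fold cross-validated lambda grid, ICL-based selection of the number of
clusters, and 100-bootstrap non-negative stacking.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml


@dataclass
class MRMConfig:
    # RBF basis
    rbf_centers: int = 50          # J, number of Gaussian bumps per region
    rbf_scale: float = 10.0        # delta, rate inside exp(-delta * r^2)
    ridge: float = 1e-8            # stabiliser for plain least-squares solves
    clip: bool = True              # clip predictions into [0, 1]

    # mixture fitting
    k_max: Optional[int] = None    # None -> max(2, N // 5), capped at 10
    k_fixed: Optional[int] = None  # bypass ICL selection with a fixed K
    lambda_grid: Optional[Sequence[float]] = None  # None -> 8 log-spaced * sd(y)
    lambda_fixed: Optional[float] = None           # bypass the CV grid search
    n_folds: int = 10
    em_tol: float = 1e-6
    em_max_iter: int = 200
    restarts: int = 5              # EM restarts for full-data fits
    cv_restarts: int = 1           # EM restarts inside CV folds (cheaper)
    cv_max_iter: int = 40          # EM iteration cap inside CV folds
    assignment: str = "hard"       # "hard" (argmax z) or "soft" (posterior mix)
    per_cluster_variance: bool = False
    icl_df: str = "active"         # "active": count nonzero w; "all": p = K*J + K

    # stacking
    n_boot: int = 100
    artificial_frac: float = 0.1
    stack_intercept: bool = False
    per_region_stacking: bool = False

    # baselines
    knn_k: int = 10
    knn_scaled_distance: bool = False

    # misc
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.rbf_centers < 1:
            raise ValueError("rbf_centers must be >= 1")
        if self.rbf_scale <= 0:
            raise ValueError("rbf_scale must be > 0")
        if self.assignment not in ("hard", "soft"):
            raise ValueError("assignment must be 'hard' or 'soft'")
        if self.icl_df not in ("all", "active"):
            raise ValueError("icl_df must be 'all' or 'active'")

    @classmethod
    def from_yaml(cls, path) -> "MRMConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "MRMConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["lambda_grid"] is not None:
            d["lambda_grid"] = [float(v) for v in d["lambda_grid"]]
        return d

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


DEFAULT_CONFIG = MRMConfig()
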