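"""Radial-basis-function design matrices and single-profile linear fits.

A methylation profile over a region is modelled as y = H w, where H is the
I x J design matrix with entries h_ij = exp(-delta * (x_i - mu_j)^2), the
centers mu_j are equally spaced over the rescaled region [-1, 1], and delta
is the (positive) rate of the Gaussian bump.  The literature sometimes
quotes the scale as gamma = -10 inside exp(gamma * r^2); here delta = 10 is
stored as a positive rate, the same kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import InputDomainError


class RankDeficiencyError(np.linalg.LinAlgError):
    """Normal equations singular at ridge = 0; retry with ridge > 0."""


@dataclass
class RBFBasis:
    centers: np.ndarray  # (J,) scaled positions in [-1, 1]
    scale: float         # delta > 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 1 or self.centers.size < 1:
            raise ValueError("centers must be a non-empty 1-d vector")
        if np.any(self.centers < -1.0) or np.any(self.centers > 1.0):
            raise ValueError("centers must lie in [-1, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def J(self) -> int:
        return self.centers.size

    @classmethod
    def equally_spaced(cls, n_centers: int = 50, scale: float = 10.0) -> "RBFBasis":
        """The default basis: J centers equally distributed over [-1, 1]."""
        if n_centers == 1:
            centers = np.array([0.0])
        else:
            centers = np.linspace(-1.0, 1.0, n_centers)
        return cls(centers=centers, scale=scale)


@dataclass
class LinearFit:
    weights: np.ndarray
    basis: RBFBasis
    residual_sse: float


def scale_positions(positions, start: float, end: float) -> np.ndarray:
    """Affine map of genomic coordinates onto [-1, 1] (start -> -1, end -> 1)."""
    if start >= end:
        raise InputDomainError(f"degenerate region: start {start} >= end {end}")
    positions = np.asarray(positions, dtype=float)
    if positions.size and (positions.min() < start or positions.max() > end):
        raise InputDomainError("positions outside region bounds")
    return 2.0 * (positions - start) / (end - start) - 1.0


def design_matrix(x, basis: RBFBasis) -> np.ndarray:
    """I x J matrix with h_ij = exp(-delta * (x_i - mu_j)^2)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    diff = x[:, None] - basis.centers[None, :]
    return np.exp(-basis.scale * diff * diff)


def fit_least_squares(x, y, basis: RBFBasis, ridge: float = 1e-8) -> LinearFit:
    """Solve the (optionally ridge-stabilised) normal equations (H'H)w = H'y."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.size != y.size or x.size < 1:
        raise ValueError("x and y must be equal-length, non-empty")
    h = design_matrix(x, basis)
    gram = h.T @ h
    if ridge > 0:
        gram = gram + ridge * np.eye(basis.J)
    try:
        w = scipy.linalg.solve(gram, h.T @ y, assume_a="pos")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        raise RankDeficiencyError(
            "normal equations are rank deficient; retry with ridge > 0"
        ) from None
    if not np.all(np.isfinite(w)):
        raise RankDeficiencyError(
            "normal equations are rank deficient; retry with ridge > 0"
        )
    resid = y - h @ w
    return LinearFit(weights=w, basis=basis, residual_sse=float(resid @ resid))


def predict(fit: LinearFit, x_new, clip: bool = True) -> np.ndarray:
    """Evaluate H(x_new) w, clipped into [0, 1] by default."""
    pred = design_matrix(x_new, fit.basis) @ fit.weights
    return np.clip(pred, 0.0, 1.0) if clip else pred
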