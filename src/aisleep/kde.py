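"""Weighted Gaussian kernel density estimation on the 2-D embedding.

The estimator is

    p(x) = 1 / (n * bx * by) * sum_i w_i * K2((x - x_i) / b)

with K2 the radially symmetric bivariate standard Gaussian and the bandwidth
factor b = n^(-1/(4+dx)) (Scott). By default each embedding axis is
standardized by its sample standard deviation before the factor is applied
(bx = b * std_x), the common implementation convention; ``raw_bandwidth=True``
uses the literal unscaled factor on both axes. All staging decisions compare
densities that share one normalization, so the constant is immaterial to the
resulting labels but is kept consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

SIGMA_FLOOR = 1e-6


@dataclass
class WeightedDensityModel:
    support: np.ndarray  # (n, 2)
    weights: np.ndarray  # (n,)
    bandwidth: float  # Scott factor n^(-1/(4+dx))
    scales: np.ndarray  # (2,) per-axis bandwidth multipliers

    @property
    def n_points(self) -> int:
        return int(self.support.shape[0])


@dataclass
class GaussianParams:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def scott_bandwidth(n: int, dx: int) -> float:
    """Scott bandwidth factor n^(-1/(4+dx))."""
    if n < 1:
        raise ValueError("need at least one sample for bandwidth selection")
    if dx < 1:
        raise ValueError("dimension must be >= 1")
    return float(n) ** (-1.0 / (4 + dx))


def fit_density(
    support: np.ndarray,
    weights: np.ndarray,
    raw_bandwidth: bool = False,
) -> WeightedDensityModel:
    """Build a weighted KDE model over 2-D support points."""
    support = np.asarray(support, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if support.ndim != 2 or support.shape[1] != 2:
        raise ValueError("support must have shape (n, 2)")
    if support.shape[0] == 0:
        raise ValueError("empty support")
    if weights.shape != (support.shape[0],):
        raise ValueError("weights must be one per support point")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    b = scott_bandwidth(support.shape[0], 2)
    if raw_bandwidth:
        scales = np.ones(2)
    else:
        scales = support.std(axis=0, ddof=1) if support.shape[0] > 1 else np.ones(2)
        scales = np.where(scales > 0, scales, 1.0)
    return WeightedDensityModel(support, weights, b, scales)


def evaluate_density(model: WeightedDensityModel, queries: np.ndarray) -> np.ndarray:
    """Evaluate the weighted density at query points, shape (m, 2) -> (m,)."""
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if queries.shape[1] != 2:
        raise ValueError("queries must have shape (m, 2)")
    if model.n_points == 0:
        raise ValueError("empty support")
    bx, by = model.bandwidth * model.scales
    dx = (queries[:, None, 0] - model.support[None, :, 0]) / bx
    dy = (queries[:, None, 1] - model.support[None, :, 1]) / by
    kern = np.exp(-0.5 * (dx * dx + dy * dy)) / (2.0 * np.pi)
    return kern @ model.weights / (model.n_points * bx * by)


def gaussian_fit(values: np.ndarray) -> GaussianParams:
    """Moment estimates (sample mean, sample std with ddof=0).

    Constant input floors sigma at 1e-6 with a warning rather than failing,
    so degenerate feature splits still produce usable CDF weights.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values for a Gaussian fit")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma < SIGMA_FLOOR:
        warnings.warn(
            "near-constant input to gaussian_fit; flooring sigma at 1e-6",
            stacklevel=2,
        )
        sigma = SIGMA_FLOOR
    return GaussianParams(mu, sigma)


def gaussian_cdf(x: np.ndarray | float, params: GaussianParams) -> np.ndarray | float:
    """Gaussian CDF via the error-function closed form."""
    z = (np.asarray(x, dtype=np.float64) - params.mu) / (params.sigma * np.sqrt(2.0))
    out = 0.5 * (1.0 + erf(z))
    return float(out) if np.isscalar(x) else out
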