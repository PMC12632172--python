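"""Convergence monitoring via KL divergence between successive posteriors.

At every monitoring-grid point the GP posterior is summarized by a
univariate Gaussian (mu, sigma). Between two campaign iterations the
pointwise change is the closed-form KL divergence between those Gaussians,

    D_KL(P || Q) = log(sigma2/sigma1)
                   + (sigma1^2 + (mu1 - mu2)^2) / (2 sigma2^2) - 1/2,

with P the *current* posterior and Q the *previous* one (measuring the
information added by the newest batch; the direction is a package
convention — KL is asymmetric). The scalar monitor is the root sum of
squares (RSS) of these divergences over the grid, deliberately without
normalization so steep local transitions stay visible. A campaign is
declared converged once the RSS stays below a user threshold for
``patience`` consecutive iterations.

Per-dimension traces take the 1D transect through the grid midpoint along
each axis and report the RSS of KL over that transect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design_space import DesignSpace
from .errors import NonGridField, NonPositiveSigma, PointSetMismatch
from .surrogate import KernelState, PosteriorField

#: predictive standard deviations are floored here before KL evaluation,
#: preventing division blow-ups at near-interpolated grid points
SIGMA_FLOOR = 1e-6


def kl_normal(mu1, sigma1, mu2, sigma2):
    """Closed-form KL divergence D(N(mu1, sigma1) || N(mu2, sigma2)).

    Vectorized; nonnegative, and zero iff the two distributions coincide.
    """
    sigma1 = np.asarray(sigma1, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma1 <= 0) or np.any(sigma2 <= 0):
        raise NonPositiveSigma("standard deviations must be positive")
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    return (
        np.log(sigma2 / sigma1)
        + (sigma1**2 + (mu1 - mu2) ** 2) / (2.0 * sigma2**2)
        - 0.5
    )


def _kl_field(current: PosteriorField, previous: PosteriorField) -> np.ndarray:
    if current.points.shape != previous.points.shape or not np.allclose(
        current.points, previous.points
    ):
        raise PointSetMismatch("posterior fields evaluated on different point sets")
    s1 = np.maximum(current.sigma, SIGMA_FLOOR)
    s2 = np.maximum(previous.sigma, SIGMA_FLOOR)
    return np.asarray(kl_normal(current.mu, s1, previous.mu, s2))


def rss_kl(current: PosteriorField, previous: PosteriorField) -> float:
    """Root sum of squares of pointwise KL over the monitoring grid."""
    kl = _kl_field(current, previous)
    return float(np.sqrt(np.sum(kl**2)))


def _grid_resolution(field: PosteriorField, space: DesignSpace) -> int:
    n = round(len(field.points) ** (1.0 / space.n_dims))
    if n**space.n_dims != len(field.points):
        raise NonGridField(
            f"{len(field.points)} points is not a full {space.n_dims}-D grid"
        )
    return int(n)


def per_dimension_rss(
    current: PosteriorField, previous: PosteriorField, space: DesignSpace
) -> np.ndarray:
    """RSS of KL along the midpoint transect of each grid dimension.

    Requires both fields on a full Cartesian grid in ``make_grid`` order.
    """
    n = _grid_resolution(current, space)
    kl = _kl_field(current, previous).reshape((n,) * space.n_dims)
    mid = n // 2
    out = np.empty(space.n_dims)
    for d in range(space.n_dims):
        index = [mid] * space.n_dims
        index[d] = slice(None)
        out[d] = np.sqrt(np.sum(kl[tuple(index)] ** 2))
    return out


def check_converged(rss_values, threshold: float, patience: int) -> bool:
    """True iff the last ``patience`` RSS values are all strictly below threshold."""
    if patience < 1:
        raise ValueError("patience must be >= 1")
    rss_values = list(rss_values)
    if len(rss_values) < patience:
        return False
    return all(v < threshold for v in rss_values[-patience:])


@dataclass
class ConvergenceTrace:
    """Per-iteration convergence record of a campaign."""

    rss: list[float] = field(default_factory=list)
    per_dimension: list[np.ndarray] = field(default_factory=list)
    length_scales: list[KernelState] = field(default_factory=list)

    def append(self, rss_value: float, per_dim: np.ndarray, kernel: KernelState):
        self.rss.append(float(rss_value))
        self.per_dimension.append(np.asarray(per_dim, dtype=float))
        self.length_scales.append(kernel)

    def __len__(self) -> int:
        return len(self.rss)

    def to_dataframe(self, space: DesignSpace):
        import pandas as pd

        rows = []
        for i, (r, pd_rss, ks) in enumerate(
            zip(self.rss, self.per_dimension, self.length_scales)
        ):
            row = {"iteration": i + 2, "rss_kl": r}  # first KL needs two posteriors
            for name, v in zip(space.names, pd_rss):
                row[f"rss_kl_{name}"] = v
            for name, v in zip(space.names, ks.length_scales):
                row[f"length_scale_{name}"] = v
            row["amplitude"] = ks.amplitude
            rows.append(row)
        return pd.DataFrame(rows)
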