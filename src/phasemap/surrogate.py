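"""Gaussian-process surrogate of the phase-separation fraction.

The loop's observable is the PS fraction of droplet replicates at one
composition, a value in [0, 1]. A Gaussian process regression with a
constant (signal-amplitude) kernel times a Matérn 5/2 correlation kernel
models this fraction over the flow-rate design space, giving a predictive
mean mu(x) and standard deviation sigma(x) that downstream acquisition
and convergence monitoring consume.

Inputs are standardized to the unit cube internally (optimizer
conditioning); kernel length scales are constrained to [range/100, range]
per dimension and reported back in flow units. PS fractions are regressed
untransformed; mu may therefore leave [0, 1] slightly, and
:func:`clip_probability` provides the clipped reporting view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .design_space import DesignSpace
from .errors import DegenerateTrainingWarning, DimensionMismatch

#: diagonal jitter added to the kernel matrix for numerical stability
JITTER = 1e-6

#: length-scale box on standardized inputs: [1% of range, full range]
LENGTH_SCALE_BOUNDS = (0.01, 1.0)

AMPLITUDE_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class KernelState:
    """Fitted kernel hyperparameters, length scales in flow units (µL/h)."""

    amplitude: float
    length_scales: np.ndarray


@dataclass(frozen=True)
class PosteriorField:
    """GP posterior mean/std evaluated on a point set (flow coordinates)."""

    points: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.points) == len(self.mu) == len(self.sigma)):
            raise ValueError("points, mu and sigma must have equal length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")


class SurrogateState:
    """A fitted surrogate: the GP, its training data and the design space."""

    def __init__(
        self,
        gp: GaussianProcessRegressor,
        space: DesignSpace,
        X: np.ndarray,
        y: np.ndarray,
    ):
        self.gp = gp
        self.space = space
        self.X = X
        self.y = y
        self._fast = None

    @property
    def kernel_state(self) -> KernelState:
        k = self.gp.kernel_
        amplitude = float(k.k1.constant_value)
        ls = np.atleast_1d(np.asarray(k.k2.length_scale, dtype=float))
        if ls.size == 1:
            ls = np.repeat(ls, self.space.n_dims)
        return KernelState(amplitude=amplitude, length_scales=ls * self.space.ranges)

    def to_dict(self) -> dict:
        ks = self.kernel_state
        return {
            "amplitude": ks.amplitude,
            "length_scales": ks.length_scales.tolist(),
            "n_train": int(len(self.y)),
        }

    # -- fast posterior path ---------------------------------------------

    def _fast_predict(self, X_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean/std from the cached Cholesky factor.

        Equivalent to ``gp.predict(..., return_std=True)`` but without the
        per-call validation overhead; used in the acquisition inner loop.
        """
        gp = self.gp
        if self._fast is None:
            y_mean = np.ravel(np.atleast_1d(gp._y_train_mean))[0]
            y_std = np.ravel(np.atleast_1d(gp._y_train_std))[0]
            self._fast = (gp.kernel_, gp.X_train_, np.ravel(gp.alpha_), gp.L_,
                          y_mean, y_std)
        kernel, X_train, alpha, L, y_mean, y_std = self._fast
        K_star = kernel(X_std, X_train)
        mu = K_star @ alpha * y_std + y_mean
        V = solve_triangular(L, K_star.T, lower=True, check_finite=False)
        var = kernel.diag(X_std) - np.einsum("ij,ij->j", V, V)
        np.maximum(var, 0.0, out=var)
        return mu, np.sqrt(var) * y_std


def _build_kernel(n_dims: int, length_scale=None, amplitude: float = 1.0,
                  fixed: bool = False):
    ls = np.full(n_dims, 0.3) if length_scale is None else np.asarray(length_scale)
    ls_bounds = "fixed" if fixed else LENGTH_SCALE_BOUNDS
    amp_bounds = "fixed" if fixed else AMPLITUDE_BOUNDS
    return ConstantKernel(amplitude, amp_bounds) * Matern(
        length_scale=ls, length_scale_bounds=ls_bounds, nu=2.5
    )


def fit_surrogate(
    X: np.ndarray,
    y: np.ndarray,
    space: DesignSpace,
    n_restarts: int = 25,
    seed=None,
    noise_level: float | np.ndarray = 0.0,
    normalize_y: bool = True,
    kernel_state: KernelState | None = None,
    initial_kernel_state: KernelState | None = None,
    optimize: bool = True,
) -> SurrogateState:
    """Fit (or refit) the GP on all collected (flows, PS fraction) data.

    Parameters
    ----------
    n_restarts : int
        Number of random restarts of the marginal-likelihood optimizer.
    noise_level : float or array
        Optional observation-noise variance added to the diagonal jitter;
        a scalar is homoscedastic, an array gives per-sample values
        (e.g. binomial variance of a droplet-count fraction). Default 0
        (no white-noise kernel).
    kernel_state : KernelState, optional
        Fix the kernel at these hyperparameters (length scales in flow
        units) instead of optimizing — used for controlled evaluations.
    initial_kernel_state : KernelState, optional
        Warm-start the marginal-likelihood optimization from these
        hyperparameters (the random restarts still run); campaign refits
        pass the previous iteration's kernel here so the fitted
        hyperparameters evolve smoothly instead of hopping between local
        optima, which would otherwise dominate the KL convergence trace.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] != space.n_dims:
        raise DimensionMismatch(
            f"training inputs have {X.shape[1]} dims, space has {space.n_dims}"
        )
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(y) == 0:
        raise ValueError("need at least one observation")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("PS fractions must lie in [0, 1]")
    if not space.contains(X.min(axis=0)) or not space.contains(X.max(axis=0)):
        raise ValueError("training inputs outside design-space bounds")

    if len(y) < 2:
        warnings.warn(
            "single observation: hyperparameters cannot be optimized; "
            "falling back to a prior-mean model",
            DegenerateTrainingWarning,
        )
        optimize = False

    if kernel_state is not None:
        kernel = _build_kernel(
            space.n_dims,
            length_scale=kernel_state.length_scales / space.ranges,
            amplitude=kernel_state.amplitude,
            fixed=True,
        )
        optimize = False
    elif initial_kernel_state is not None:
        ls0 = np.clip(
            initial_kernel_state.length_scales / space.ranges,
            LENGTH_SCALE_BOUNDS[0], LENGTH_SCALE_BOUNDS[1],
        )
        amp0 = float(np.clip(initial_kernel_state.amplitude, *AMPLITUDE_BOUNDS))
        kernel = _build_kernel(space.n_dims, length_scale=ls0, amplitude=amp0)
    else:
        kernel = _build_kernel(space.n_dims)

    rs = None
    if seed is not None:
        rs = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    noise = np.asarray(noise_level, dtype=float)
    if noise.ndim not in (0, 1) or (noise.ndim == 1 and len(noise) != len(y)):
        raise ValueError("noise_level must be a scalar or one value per sample")
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=JITTER + noise,
        optimizer="fmin_l_bfgs_b" if optimize else None,
        n_restarts_optimizer=n_restarts if optimize else 0,
        normalize_y=normalize_y,
        random_state=rs,
    )
    with warnings.catch_warnings():
        # length scales pinned at their box edge are expected behaviour here
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(space.standardize(X), y)
    return SurrogateState(gp=gp, space=space, X=X, y=y)


def predict(state: SurrogateState, points: np.ndarray,
            chunk: int = 20_000) -> PosteriorField:
    """Evaluate the posterior mean and standard deviation at ``points``."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != state.space.n_dims:
        raise DimensionMismatch(
            f"points have {points.shape[1]} dims, space has {state.space.n_dims}"
        )
    X_std = state.space.standardize(points)
    mus, sigmas = [], []
    for i in range(0, len(X_std), chunk):
        mu, sigma = state._fast_predict(X_std[i : i + chunk])
        mus.append(mu)
        sigmas.append(sigma)
    return PosteriorField(
        points=points, mu=np.concatenate(mus), sigma=np.concatenate(sigmas)
    )


def clip_probability(field: PosteriorField) -> PosteriorField:
    """Reporting view with mu clipped to [0, 1]; sigma untouched.

    Acquisition and KL monitoring always use the unclipped field.
    """
    return PosteriorField(
        points=field.points, mu=np.clip(field.mu, 0.0, 1.0), sigma=field.sigma
    )


def field_to_dataframe(field: PosteriorField, space: DesignSpace):
    """PosteriorField as a DataFrame: one row per point, flows + mu + sigma."""
    import pandas as pd

    df = pd.DataFrame(field.points, columns=space.names)
    df["mu"] = field.mu
    df["sigma"] = field.sigma
    return df
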