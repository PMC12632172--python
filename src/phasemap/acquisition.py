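"""Acquisition functions, their minimization, and diverse batch assembly.

Four strategies score candidate compositions from the surrogate posterior
(mu, sigma); all are arranged so that *lower is better* and the next
sample sits at the minimizer:

- ``exploit``: ``|mu - target|`` — head straight for the predicted phase
  boundary (PS fraction = target, default 0.5).
- ``explore``: ``-sigma`` — head for the largest model uncertainty.
- ``hybrid``: ``-sigma**2 / (|mu - target| + epsilon)`` — trade off both,
  with epsilon (default 0.5) controlling the balance.
- ``random``: uniform in-bounds sampling, ignoring the posterior.

Minimization uses Nelder–Mead restarted from ``n_starts`` random probe
points (the probes are ranked by value and the best few polished); the
simplex search itself is unconstrained, so out-of-bounds proposals are
scored at their clipped projection plus a quadratic distance penalty and
the final point is clipped.

Batches are assembled sequentially: after each selection a Gaussian bump
is added on top of the acquisition landscape at the selected location
(width per dimension = a fraction of that dimension's range), forcing the
next minimizer elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .design_space import DesignSpace
from .errors import UnknownMode
from .surrogate import SurrogateState

MODES = ("random", "exploit", "explore", "hybrid")


@dataclass(frozen=True)
class AcquisitionConfig:
    mode: str = "hybrid"
    target: float = 0.5
    epsilon: float = 0.5
    n_starts: int = 100
    batch_size: int = 10
    penalty_amplitude: float | None = None  # None: adapt to the alpha range
    penalty_width_fraction: float = 0.1
    n_polish: int = 5  # probe points refined with Nelder-Mead

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise UnknownMode(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 <= self.target <= 1.0:
            raise ValueError("target must lie in [0, 1]")
        if self.batch_size < 1 or self.n_starts < 1:
            raise ValueError("batch_size and n_starts must be >= 1")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "target": self.target,
            "epsilon": self.epsilon,
            "n_starts": self.n_starts,
            "batch_size": self.batch_size,
            "penalty_amplitude": self.penalty_amplitude,
            "penalty_width_fraction": self.penalty_width_fraction,
        }


@dataclass(frozen=True)
class BatchSelection:
    """Selected batch in selection order, with pre-penalty alpha values."""

    points: np.ndarray
    acquisition_values: np.ndarray


def alpha(mode: str, mu, sigma, cfg: AcquisitionConfig, rng=None):
    """Acquisition value(s); vectorized over mu/sigma. Lower is better."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if mode == "exploit":
        return np.abs(mu - cfg.target)
    if mode == "explore":
        return -sigma
    if mode == "hybrid":
        return -(sigma**2) / (np.abs(mu - cfg.target) + cfg.epsilon)
    if mode == "random":
        if rng is None:
            raise ValueError("random mode needs an rng for the uniform draw")
        return rng.uniform(size=np.shape(mu))
    raise UnknownMode(f"unknown acquisition mode {mode!r}")


def penalty_value(points: np.ndarray, placed: np.ndarray, widths: np.ndarray,
                  amplitude: float) -> np.ndarray:
    """Sum of Gaussian bumps centred on already-selected batch points."""
    points = np.atleast_2d(points)
    if len(placed) == 0:
        return np.zeros(len(points))
    diff = (points[:, None, :] - placed[None, :, :]) / widths
    return amplitude * np.exp(-0.5 * np.sum(diff**2, axis=-1)).sum(axis=1)


def _penalized_landscape(state: SurrogateState, cfg: AcquisitionConfig,
                         space: DesignSpace, placed: np.ndarray,
                         amplitude: float):
    """Vectorized penalized-alpha evaluator on raw flow coordinates."""
    widths = cfg.penalty_width_fraction * space.ranges

    def f(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        mu, sigma = state._fast_predict(space.standardize(points))
        vals = alpha(cfg.mode, mu, sigma, cfg)
        if len(placed):
            vals = vals + penalty_value(points, placed, widths, amplitude)
        return vals

    return f


def _default_amplitude(cfg: AcquisitionConfig, probe_values: np.ndarray) -> float:
    """Bump amplitude adapted to the acquisition landscape.

    The bump must dominate the landscape *locally* to force diversity,
    so it is set to the dynamic range of alpha over the probe points; a
    fallback of 1 covers degenerate flat landscapes (range ~ 0), where
    any positive amplitude spreads the batch.
    """
    if cfg.penalty_amplitude is not None:
        return cfg.penalty_amplitude
    span = float(np.ptp(probe_values)) if len(probe_values) else 0.0
    return span if span > 1e-9 else 1.0


def minimize_acquisition(
    state: SurrogateState,
    cfg: AcquisitionConfig,
    space: DesignSpace,
    penalties: np.ndarray | None = None,
    seed=None,
    amplitude: float | None = None,
) -> np.ndarray:
    """Best in-bounds minimizer of the (optionally penalized) acquisition.

    ``penalties`` is the array of already-placed batch points (may be
    empty). Deterministic for a fixed seed. ``random`` mode returns a
    uniform in-bounds draw without any minimization.
    """
    rng = np.random.default_rng(seed)
    if cfg.mode == "random":
        return rng.uniform(space.lower, space.upper)
    placed = np.empty((0, space.n_dims)) if penalties is None else np.atleast_2d(penalties)

    starts = rng.uniform(space.lower, space.upper, size=(cfg.n_starts, space.n_dims))
    if amplitude is None:
        probe_alpha = _penalized_landscape(state, cfg, space,
                                           np.empty((0, space.n_dims)), 0.0)(starts)
        amplitude = _default_amplitude(cfg, probe_alpha)
    f = _penalized_landscape(state, cfg, space, placed, amplitude)
    start_vals = f(starts)
    order = np.argsort(start_vals, kind="stable")

    # polish the best probes, but spread the simplex starts over distinct
    # basins: greedily skip probes too close (scaled distance) to a start
    # already chosen, falling back to plain ranking if too few survive
    chosen: list[int] = []
    for idx in order:
        z = (starts[idx] - space.lower) / space.ranges
        if all(
            np.linalg.norm(z - (starts[j] - space.lower) / space.ranges) > 0.1
            for j in chosen
        ):
            chosen.append(int(idx))
        if len(chosen) == cfg.n_polish:
            break
    for idx in order:
        if len(chosen) == cfg.n_polish:
            break
        if int(idx) not in chosen:
            chosen.append(int(idx))

    lo, hi, ranges = space.lower, space.upper, space.ranges
    oob_scale = 10.0 * max(1.0, amplitude)

    def objective(x: np.ndarray) -> float:
        clipped = np.clip(x, lo, hi)
        excess = np.sum(((x - clipped) / ranges) ** 2)
        return float(f(clipped[None, :])[0]) + oob_scale * excess

    best_x = starts[order[0]]
    best_val = float(start_vals[order[0]])
    for idx in chosen:
        res = scipy_minimize(
            objective,
            starts[idx],
            method="Nelder-Mead",
            options={
                "maxiter": 200 * space.n_dims,
                "xatol": 1e-4 * float(ranges.min()),
                "fatol": 1e-9,
            },
        )
        x = np.clip(res.x, lo, hi)
        val = float(f(x[None, :])[0])
        # strict improvement only: exact ties keep the earliest start
        if val < best_val:
            best_x, best_val = x, val
    return best_x


def select_batch(
    state: SurrogateState,
    cfg: AcquisitionConfig,
    space: DesignSpace,
    seed=None,
) -> BatchSelection:
    """Assemble a spatially diverse batch of ``cfg.batch_size`` points.

    The first point is the unpenalized acquisition minimizer; each
    subsequent point minimizes the acquisition plus one Gaussian bump per
    already-selected point.
    """
    rng = np.random.default_rng(seed)
    if cfg.mode == "random":
        pts = rng.uniform(space.lower, space.upper, size=(cfg.batch_size, space.n_dims))
        return BatchSelection(points=pts, acquisition_values=np.full(cfg.batch_size, np.nan))

    # calibrate the bump amplitude on one shared probe of the raw landscape
    probe = rng.uniform(space.lower, space.upper, size=(cfg.n_starts, space.n_dims))
    raw_f = _penalized_landscape(state, cfg, space, np.empty((0, space.n_dims)), 0.0)
    amplitude = _default_amplitude(cfg, raw_f(probe))

    points: list[np.ndarray] = []
    values: list[float] = []
    min_sep = 1e-6
    for _ in range(cfg.batch_size):
        placed = np.array(points) if points else np.empty((0, space.n_dims))
        child = rng.integers(0, 2**31 - 1)
        x = minimize_acquisition(state, cfg, space, penalties=placed,
                                 seed=child, amplitude=amplitude)
        if points:
            sep = np.min(
                np.linalg.norm((np.array(points) - x) / space.ranges, axis=1)
            )
            if sep <= min_sep:  # degenerate landscape: fall back to a random point
                x = rng.uniform(space.lower, space.upper)
        points.append(x)
        values.append(float(raw_f(x[None, :])[0]))
    return BatchSelection(points=np.array(points), acquisition_values=np.array(values))
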