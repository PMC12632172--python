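"""Virtual laboratory: a seeded stand-in for the droplet/microscopy stage.

Each "experiment" at one composition draws a droplet count uniformly from
the analyzed-replicate range (default 50–250 droplets reach the imaging
field), lets every droplet phase-separate independently with a
probability given by a smooth ground-truth function of the final solute
concentrations, and reports the PS fraction. The ground truth operates on
*concentrations* (not flows) so its weights have physical units and a
chosen influence ordering of the solutes can be encoded directly.

Two observation routes exist: ``direct`` (binomial bookkeeping, above)
and ``imaged`` (the same droplet population rendered as two-channel
synthetic micrographs and re-analyzed by the classical detector in
:mod:`phasemap.imaging`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design_space import Composition, DesignSpace, flows_to_concentrations, grid_axes
from .errors import UnknownMode

PHASE_MODEL_KINDS = ("logistic_linear", "logistic_radial", "user_table")


@dataclass(frozen=True)
class PhaseModel:
    """Ground-truth PS probability as a function of concentrations.

    ``logistic_linear``: p(c) = 1 / (1 + exp(-k (w.c - offset))).
    ``logistic_radial``: p(c) = 1 / (1 + exp(-k (|c - w| - offset)))
    (``weights`` is the centre, ``offset`` the radius of the 0.5 shell).
    ``user_table``: multilinear interpolation of a user-supplied
    (concentration grid, probability) table.
    """

    kind: str = "logistic_linear"
    weights: tuple[float, ...] = ()
    offset: float = 0.0
    steepness: float = 1.0
    table: object | None = None  # RegularGridInterpolator for user_table

    def __post_init__(self) -> None:
        if self.kind not in PHASE_MODEL_KINDS:
            raise UnknownMode(f"unknown phase-model kind {self.kind!r}")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def to_dict(self) -> dict:
        if self.kind == "user_table":
            raise ValueError("user_table models are not serializable to config")
        return {
            "kind": self.kind,
            "weights": list(self.weights),
            "offset": self.offset,
            "steepness": self.steepness,
        }


@dataclass(frozen=True)
class ObservedSample:
    """One composition with its droplet counts and measured PS fraction."""

    composition: Composition
    n_droplets_analyzed: int
    n_ps: int

    def __post_init__(self) -> None:
        if self.n_droplets_analyzed < 1:
            raise ValueError("need at least one analyzed droplet")
        if not 0 <= self.n_ps <= self.n_droplets_analyzed:
            raise ValueError("n_ps must lie in [0, n_droplets_analyzed]")

    @property
    def ps_fraction(self) -> float:
        return self.n_ps / self.n_droplets_analyzed


def _logistic(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


def probability_at_concentrations(model: PhaseModel, conc: np.ndarray) -> np.ndarray:
    """Vectorized ground-truth probability for concentration row vectors."""
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    w = np.asarray(model.weights, dtype=float)
    if model.kind == "logistic_linear":
        if w.shape != (conc.shape[1],):
            raise ValueError("weights length must match number of variables")
        return _logistic(model.steepness * (conc @ w - model.offset))
    if model.kind == "logistic_radial":
        if w.shape != (conc.shape[1],):
            raise ValueError("centre length must match number of variables")
        r = np.linalg.norm(conc - w, axis=1)
        return _logistic(model.steepness * (r - model.offset))
    if model.kind == "user_table":
        if model.table is None:
            raise ValueError("user_table model has no interpolator attached")
        return np.clip(np.asarray(model.table(conc), dtype=float), 0.0, 1.0)
    raise UnknownMode(model.kind)


def true_ps_probability(
    model: PhaseModel, comp: Composition, space: DesignSpace
) -> float:
    """Ground-truth PS probability of one composition."""
    conc = flows_to_concentrations(comp, space)
    return float(probability_at_concentrations(model, conc[None, :])[0])


def probability_at_flows(
    model: PhaseModel, flows: np.ndarray, space: DesignSpace
) -> np.ndarray:
    """Vectorized ground truth for flow row vectors (derived concentration view)."""
    flows = np.atleast_2d(np.asarray(flows, dtype=float))
    conc = space.stocks * flows / space.total_flow
    return probability_at_concentrations(model, conc)


def user_table_model(grid_axes_conc: list[np.ndarray], probabilities: np.ndarray) -> PhaseModel:
    """Build a ``user_table`` model from a full concentration grid."""
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        grid_axes_conc, probabilities, bounds_error=False, fill_value=None
    )
    return PhaseModel(kind="user_table", table=interp)


def user_table_model_from_csv(path, space: DesignSpace) -> PhaseModel:
    """Read a (concentration..., probability) CSV laid out on a full grid."""
    import pandas as pd

    df = pd.read_csv(path)
    conc_cols = list(df.columns[:-1])
    axes = [np.sort(df[c].unique()) for c in conc_cols]
    shape = tuple(len(a) for a in axes)
    if int(np.prod(shape)) != len(df):
        raise ValueError("user table must cover a full Cartesian grid")
    df = df.sort_values(conc_cols, kind="stable")
    probs = df[df.columns[-1]].to_numpy().reshape(shape)
    return user_table_model(axes, probs)


def run_virtual_sample(
    model: PhaseModel,
    comp: Composition,
    space: DesignSpace,
    droplet_range: tuple[int, int] = (50, 250),
    seed=None,
) -> ObservedSample:
    """Observe one composition: uniform droplet count, binomial PS count."""
    if droplet_range[0] < 1 or droplet_range[1] < droplet_range[0]:
        raise ValueError("droplet_range must satisfy 1 <= min <= max")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(droplet_range[0], droplet_range[1] + 1))
    p = true_ps_probability(model, comp, space)
    n_ps = int(rng.binomial(n, p))
    return ObservedSample(composition=comp, n_droplets_analyzed=n, n_ps=n_ps)


def run_virtual_sample_imaged(
    model: PhaseModel,
    comp: Composition,
    space: DesignSpace,
    render_spec=None,
    droplet_range: tuple[int, int] = (50, 250),
    max_droplets_per_image: int = 40,
    seed=None,
) -> ObservedSample:
    """Observe via the imaging route: render droplet micrographs, detect, count.

    The droplet population (uniform count, Bernoulli PS flags at the
    ground-truth probability) is split across as many two-channel frames
    as needed, each frame is analyzed by the classical detector, and the
    detector's aggregated counts form the observation.
    """
    from . import imaging

    rng = np.random.default_rng(seed)
    spec = imaging.RenderSpec() if render_spec is None else render_spec
    n = int(rng.integers(droplet_range[0], droplet_range[1] + 1))
    p = true_ps_probability(model, comp, space)
    flags = rng.random(n) < p

    n_detected = 0
    n_ps_detected = 0
    for start in range(0, n, max_droplets_per_image):
        chunk_flags = flags[start : start + max_droplets_per_image]
        layout = imaging.sample_droplet_layout(len(chunk_flags), spec, rng)
        droplets = [
            (center, radius, bool(f))
            for (center, radius), f in zip(layout, chunk_flags)
        ]
        pair = imaging.render_images(droplets, spec, seed=rng)
        records = imaging.detect_droplets(pair)
        puncta = imaging.detect_condensates(pair)
        records = imaging.assign_ps(records, puncta)
        n_detected += len(records)
        n_ps_detected += sum(r.ps_flag for r in records)
    if n_detected == 0:
        from .errors import DegenerateSample

        raise DegenerateSample("detector found no droplets in any rendered frame")
    return ObservedSample(
        composition=comp, n_droplets_analyzed=n_detected, n_ps=n_ps_detected
    )


def true_boundary_points(
    model: PhaseModel, space: DesignSpace, n_per_dim: int = 21
) -> np.ndarray:
    """Flow-space points where the ground-truth probability crosses 0.5.

    Scans every axis-aligned transect of the ``n_per_dim`` grid for sign
    changes of (p - 0.5) and linearly interpolates each crossing. Used to
    score how well a fitted surrogate recovered the phase boundary.
    """
    axes = grid_axes(space, n_per_dim)
    d = space.n_dims
    shape = (n_per_dim,) * d
    from .design_space import make_grid

    grid = make_grid(space, n_per_dim)
    p = probability_at_flows(model, grid, space).reshape(shape) - 0.5

    crossings = []
    for dim in range(d):
        moved = np.moveaxis(p, dim, -1)  # (..., n) transects along `dim`
        sign_change = moved[..., :-1] * moved[..., 1:] < 0
        idx = np.argwhere(sign_change)
        for row in idx:
            base = row[:-1]
            j = row[-1]
            f0 = moved[tuple(base) + (j,)]
            f1 = moved[tuple(base) + (j + 1,)]
            t = f0 / (f0 - f1)
            point = np.empty(d)
            other_dims = [k for k in range(d) if k != dim]
            for b, k in zip(base, other_dims):
                point[k] = axes[k][b]
            x0, x1 = axes[dim][j], axes[dim][j + 1]
            point[dim] = x0 + t * (x1 - x0)
            crossings.append(point)
    return np.array(crossings) if crossings else np.empty((0, d))


def boundary_recovery_error(
    state, model: PhaseModel, space: DesignSpace, n_per_dim: int = 21
) -> float:
    """Median |mu - 0.5| of the surrogate over the true 0.5-level set."""
    from .surrogate import predict

    pts = true_boundary_points(model, space, n_per_dim)
    if len(pts) == 0:
        raise ValueError("ground-truth boundary does not cross the design space")
    field = predict(state, pts)
    return float(np.median(np.abs(field.mu - 0.5)))
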