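"""Experimental design space expressed as solution flow rates.

The search domain of a campaign is the vector of aqueous-solution flow
rates feeding the droplet maker. A plain-buffer *counter* solution tops
every composition up to a fixed total aqueous flow (default 100 µL/h), so
changing one solute's flow never perturbs the dilution of the others.
Final solute concentrations are a derived, linear view of the flows:
``c_i = stock_i * flow_i / total_flow``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridTooLarge, InfeasibleComposition

#: recognized stock concentration unit tags
UNITS = ("M", "g/L", "%w/w")

_REL_TOL = 1e-9


@dataclass(frozen=True)
class VariableSpec:
    """One searchable solution: its stock concentration and flow bounds."""

    name: str
    stock_concentration: float
    unit: str = "M"
    flow_min: float = 0.0
    flow_max: float = 100.0

    def __post_init__(self) -> None:
        if self.stock_concentration <= 0:
            raise ValueError(f"{self.name}: stock concentration must be positive")
        if self.unit not in UNITS:
            raise ValueError(f"{self.name}: unit must be one of {UNITS}")
        if self.flow_min < 0:
            raise ValueError(f"{self.name}: flow_min must be >= 0")
        if not self.flow_min < self.flow_max:
            raise ValueError(f"{self.name}: flow_min must be < flow_max")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "stock_concentration": self.stock_concentration,
            "unit": self.unit,
            "flow_min": self.flow_min,
            "flow_max": self.flow_max,
        }


@dataclass(frozen=True)
class DesignSpace:
    """Ordered set of searchable solutions plus the total aqueous flow.

    Invariants: unique variable names; every ``flow_max`` at most
    ``total_flow``; ``sum(flow_min) <= total_flow``. Note that in-bounds
    flow vectors can still be jointly infeasible when the per-variable
    maxima sum past the total flow — :func:`balance_counter` rejects
    those. Campaigns additionally require ``sum(flow_max) <= total_flow``
    so independent per-coordinate sampling always stays feasible.
    """

    variables: tuple[VariableSpec, ...]
    total_flow: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if not self.variables:
            raise ValueError("design space needs at least one variable")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if self.total_flow <= 0:
            raise ValueError("total_flow must be positive")
        for v in self.variables:
            if v.flow_max > self.total_flow + _REL_TOL * self.total_flow:
                raise ValueError(f"{v.name}: flow_max exceeds total_flow")
        if sum(v.flow_min for v in self.variables) > self.total_flow * (1 + _REL_TOL):
            raise ValueError("sum of flow_min over variables exceeds total_flow")

    @property
    def always_balanceable(self) -> bool:
        """True when every in-bounds flow vector can be counter-balanced."""
        return sum(v.flow_max for v in self.variables) <= self.total_flow * (1 + _REL_TOL)

    # -- geometry helpers -------------------------------------------------

    @property
    def n_dims(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def lower(self) -> np.ndarray:
        return np.array([v.flow_min for v in self.variables], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([v.flow_max for v in self.variables], dtype=float)

    @property
    def ranges(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def stocks(self) -> np.ndarray:
        return np.array([v.stock_concentration for v in self.variables], dtype=float)

    def contains(self, flows: np.ndarray, atol: float = 1e-9) -> bool:
        flows = np.asarray(flows, dtype=float)
        return bool(
            np.all(flows >= self.lower - atol) and np.all(flows <= self.upper + atol)
        )

    def standardize(self, flows: np.ndarray) -> np.ndarray:
        """Map raw flows onto the unit cube (per-dimension [0, 1])."""
        return (np.asarray(flows, dtype=float) - self.lower) / self.ranges

    def unstandardize(self, unit_coords: np.ndarray) -> np.ndarray:
        return np.asarray(unit_coords, dtype=float) * self.ranges + self.lower

    def to_dict(self) -> dict:
        return {
            "total_flow": self.total_flow,
            "variables": [v.to_dict() for v in self.variables],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpace":
        return cls(
            variables=tuple(VariableSpec(**v) for v in d["variables"]),
            total_flow=d.get("total_flow", 100.0),
        )


@dataclass(frozen=True)
class Composition:
    """One fully specified sample: variable flows plus the counter flow."""

    flows: np.ndarray
    counter_flow: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "flows", np.asarray(self.flows, dtype=float))


def balance_counter(flows: np.ndarray, space: DesignSpace) -> Composition:
    """Top a flow vector up to the total aqueous flow with the counter solution.

    Raises
    ------
    InfeasibleComposition
        If the solution flows already exceed the total flow budget.
    """
    flows = np.asarray(flows, dtype=float)
    if flows.shape != (space.n_dims,):
        raise ValueError(f"expected {space.n_dims} flows, got shape {flows.shape}")
    if not space.contains(flows):
        raise ValueError("flows outside the design-space bounds")
    total = float(np.sum(flows))
    if total > space.total_flow * (1 + _REL_TOL):
        raise InfeasibleComposition(
            f"solution flows sum to {total} µL/h > total {space.total_flow} µL/h"
        )
    return Composition(flows=flows, counter_flow=space.total_flow - total)


def flows_to_concentrations(comp: Composition, space: DesignSpace) -> np.ndarray:
    """Final solute concentrations under linear dilution at the total flow."""
    return space.stocks * comp.flows / space.total_flow


def concentrations_to_flows(conc: np.ndarray, space: DesignSpace) -> np.ndarray:
    """Inverse of :func:`flows_to_concentrations` (``f_i = c_i * total / stock_i``)."""
    return np.asarray(conc, dtype=float) * space.total_flow / space.stocks


def make_grid(
    space: DesignSpace, n_per_dim: int, max_points: int = 10_000_000
) -> np.ndarray:
    """Full Cartesian grid, ``n_per_dim`` evenly spaced values per dimension.

    Both bounds are included (a 21-point axis covers the closed interval).
    Returned array has shape ``(n_per_dim**d, d)`` with the first axis
    varying slowest (``numpy.meshgrid(..., indexing="ij")`` order).
    """
    if n_per_dim < 2:
        raise ValueError("n_per_dim must be >= 2")
    n_points = n_per_dim ** space.n_dims
    if n_points > max_points:
        raise GridTooLarge(f"{n_points} grid points exceeds cap {max_points}")
    axes = [
        np.linspace(v.flow_min, v.flow_max, n_per_dim) for v in space.variables
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def grid_axes(space: DesignSpace, n_per_dim: int) -> list[np.ndarray]:
    """The per-dimension coordinate axes of :func:`make_grid`."""
    return [np.linspace(v.flow_min, v.flow_max, n_per_dim) for v in space.variables]


def random_batch(space: DesignSpace, n: int, seed=None) -> np.ndarray:
    """``n`` flow vectors with per-coordinate uniform draws within bounds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(space.lower, space.upper, size=(n, space.n_dims))


def points_to_dataframe(points: np.ndarray, space: DesignSpace):
    """Flow vectors as a DataFrame: one column per variable + counter_flow.

    Rows whose flows exceed the total-flow budget get a NaN counter flow.
    """
    import pandas as pd

    points = np.atleast_2d(np.asarray(points, dtype=float))
    df = pd.DataFrame(points, columns=space.names)
    counter = space.total_flow - points.sum(axis=1)
    df["counter_flow"] = np.where(counter >= -_REL_TOL, counter, np.nan)
    return df
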