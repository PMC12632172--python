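"""Time and material cost comparison across phase-diagram workflows.

The traditional workflow pipettes microliter samples by hand on a grid:
10 samples for a 1D study (replicates included), a further factor of 10
per added dimension, 5 minutes and 100 µL of sample each, with the
researcher present throughout. The closed-loop droplet platform instead
runs a fixed iteration budget (11 iterations for 3D, 21 for 4D studies)
of ~7 minutes each, producing ~1000 droplet replicates of ~100 pL per
sample, and needs the researcher only for the first iteration. Both
workflows are charged the same precious-material concentration
(1 g/L final) so material scales with consumed sample volume.

Two single-innovation variants bracket the comparison: automated
analysis (traditional volumes, reduced researcher presence) and
droplet microfluidics alone (droplet volumes, grid sampling, with a 4D
study assembled from 10 separate 3D studies because spectral barcoding
runs out of channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import MissingIterationBudget


@dataclass(frozen=True)
class CostAssumptions:
    """All tunable quantities of the comparison, with workflow defaults."""

    trad_sample_volume_ul: float = 100.0
    trad_minutes_per_sample: float = 5.0
    trad_samples_1d: int = 10
    samples_per_added_dim_factor: float = 10.0
    precious_concentration_g_per_l: float = 1.0
    px_minutes_per_iteration: float = 7.0
    px_iterations: dict = field(default_factory=lambda: {3: 11, 4: 21})
    px_samples_per_iteration: int = 10
    px_droplets_per_sample: int = 1000
    px_droplet_volume_pl: float = 100.0
    microfluidics_4d_multiplier: int = 10
    auto_prep_minutes_per_sample: float = 1.0

    def __post_init__(self) -> None:
        numeric = [
            self.trad_sample_volume_ul,
            self.trad_minutes_per_sample,
            self.trad_samples_1d,
            self.samples_per_added_dim_factor,
            self.precious_concentration_g_per_l,
            self.px_minutes_per_iteration,
            self.px_samples_per_iteration,
            self.px_droplets_per_sample,
            self.px_droplet_volume_pl,
            self.microfluidics_4d_multiplier,
        ]
        if any(v <= 0 for v in numeric):
            raise ValueError("all cost assumptions must be positive")


@dataclass(frozen=True)
class CostReport:
    """One workflow's bill for a study of a given dimensionality."""

    method: str
    dims: int
    n_samples: float
    total_time_min: float
    researcher_time_min: float
    material_mg: float

    def __post_init__(self) -> None:
        if self.researcher_time_min > self.total_time_min * (1 + 1e-12):
            raise ValueError("researcher time cannot exceed total time")


def _mass_mg(volume_ul: float, concentration_g_per_l: float) -> float:
    # g/L == mg/mL == 1e-3 mg/µL
    return volume_ul * concentration_g_per_l * 1e-3


def _trad_n_samples(dims: int, a: CostAssumptions) -> float:
    return a.trad_samples_1d * a.samples_per_added_dim_factor ** (dims - 1)


def traditional_cost(dims: int, a: CostAssumptions | None = None) -> CostReport:
    """Grid-based manual pipetting: researcher present the whole time."""
    a = a or CostAssumptions()
    if not 1 <= dims <= 6:
        raise ValueError("dims must be in [1, 6]")
    n = _trad_n_samples(dims, a)
    time = n * a.trad_minutes_per_sample
    material = _mass_mg(n * a.trad_sample_volume_ul, a.precious_concentration_g_per_l)
    return CostReport(
        method="traditional",
        dims=dims,
        n_samples=n,
        total_time_min=time,
        researcher_time_min=time,
        material_mg=material,
    )


def closed_loop_cost(dims: int, a: CostAssumptions | None = None) -> CostReport:
    """Closed-loop droplet platform: full iteration budget, researcher
    present for the first iteration only. Material counts all produced
    droplets, not just the imaged subset (the conservative accounting)."""
    a = a or CostAssumptions()
    if dims not in a.px_iterations:
        raise MissingIterationBudget(
            f"no iteration budget configured for {dims}D studies"
        )
    iterations = a.px_iterations[dims]
    n = iterations * a.px_samples_per_iteration
    time = iterations * a.px_minutes_per_iteration
    volume_ul = n * a.px_droplets_per_sample * a.px_droplet_volume_pl * 1e-6
    material = _mass_mg(volume_ul, a.precious_concentration_g_per_l)
    return CostReport(
        method="closed_loop",
        dims=dims,
        n_samples=n,
        total_time_min=time,
        researcher_time_min=a.px_minutes_per_iteration,
        material_mg=material,
    )


def automated_analysis_cost(dims: int, a: CostAssumptions | None = None) -> CostReport:
    """Single innovation: automated imaging/analysis on manual samples.

    Material and total time match the traditional workflow; the
    researcher is only needed for sample preparation. Bracketing preset —
    no quantitative claims are attached to it.
    """
    a = a or CostAssumptions()
    base = traditional_cost(dims, a)
    return replace(
        base,
        method="automated_analysis",
        researcher_time_min=base.n_samples * a.auto_prep_minutes_per_sample,
    )


def microfluidics_only_cost(dims: int, a: CostAssumptions | None = None) -> CostReport:
    """Single innovation: droplet volumes with grid sampling.

    A 4D study is assembled from ``microfluidics_4d_multiplier`` separate
    3D studies (spectral barcoding limits simultaneous dimensions).
    Bracketing preset — no quantitative claims are attached to it.
    """
    a = a or CostAssumptions()
    if not 1 <= dims <= 4:
        raise ValueError("dims must be in [1, 4]")
    eff_dims, repeats = (3, a.microfluidics_4d_multiplier) if dims == 4 else (dims, 1)
    n = _trad_n_samples(eff_dims, a) * repeats
    time = n * a.trad_minutes_per_sample
    volume_ul = n * a.px_droplets_per_sample * a.px_droplet_volume_pl * 1e-6
    return CostReport(
        method="microfluidics_only",
        dims=dims,
        n_samples=n,
        total_time_min=time,
        researcher_time_min=time,
        material_mg=_mass_mg(volume_ul, a.precious_concentration_g_per_l),
    )


def fold_improvements(dims: int, a: CostAssumptions | None = None) -> dict:
    """Traditional-over-closed-loop ratios of total time and material."""
    a = a or CostAssumptions()
    trad = traditional_cost(dims, a)
    px = closed_loop_cost(dims, a)
    return {
        "time_fold": trad.total_time_min / px.total_time_min,
        "material_fold": trad.material_mg / px.material_mg,
    }


def cost_table(dims_list=(1, 2, 3, 4), a: CostAssumptions | None = None):
    """DataFrame of all computable workflows over the requested dims."""
    import pandas as pd

    a = a or CostAssumptions()
    rows = []
    for dims in dims_list:
        for fn in (traditional_cost, automated_analysis_cost,
                   microfluidics_only_cost, closed_loop_cost):
            try:
                r = fn(dims, a)
            except (MissingIterationBudget, ValueError):
                continue
            rows.append(
                {
                    "method": r.method,
                    "dims": r.dims,
                    "n_samples": r.n_samples,
                    "total_min": r.total_time_min,
                    "researcher_min": r.researcher_time_min,
                    "material_mg": r.material_mg,
                }
            )
    return pd.DataFrame(rows)
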