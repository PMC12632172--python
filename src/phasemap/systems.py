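"""Shipped virtual model systems (synthetic ground truths).

These emulate an RNA-homopolymer / salt / crowder solution set: a
polyadenylic-acid stock that condenses with potassium chloride, sodium
chloride and PEG, all diluted from stocks against a plain-buffer counter
flow at 100 µL/h total. The logistic ground truths are synthetic — they
mimic a monotone salt/polymer boundary crossing the sampled flow window
and, in 4D, an influence ordering KCl > NaCl > PEG > poly rA, but make
no quantitative claim about any real condensate system.
"""

from __future__ import annotations

from .design_space import DesignSpace, VariableSpec
from .virtual_lab import PhaseModel


def demo_system_2d() -> tuple[DesignSpace, PhaseModel]:
    """poly rA / KCl flows, one boundary crossing the window diagonally."""
    space = DesignSpace(
        (
            VariableSpec("polyrA", 20.0, "g/L", 0.0, 50.0),
            VariableSpec("KCl", 4.0, "M", 0.0, 50.0),
        )
    )
    # weights per concentration unit: boundary near 0.05*c_rA + c_KCl = 1
    model = PhaseModel(
        kind="logistic_linear", weights=(0.05, 1.0), offset=1.0, steepness=8.0
    )
    return space, model


def demo_system_3d() -> tuple[DesignSpace, PhaseModel]:
    """poly rA / KCl / buffer flows; buffer has a weak indirect effect."""
    space = DesignSpace(
        (
            VariableSpec("polyrA", 20.0, "g/L", 0.0, 30.0),
            VariableSpec("KCl", 4.0, "M", 0.0, 30.0),
            VariableSpec("buffer", 1.0, "M", 0.0, 30.0),
        )
    )
    model = PhaseModel(
        kind="logistic_linear", weights=(0.08, 1.0, 0.15), offset=0.7, steepness=8.0
    )
    return space, model


def demo_system_4d() -> tuple[DesignSpace, PhaseModel]:
    """poly rA / KCl / NaCl / PEG with influence ordering KCl > NaCl > PEG > poly rA.

    Effect sizes over each variable's concentration range are 0.3, 2.4,
    1.2 and 0.6: each adjacent pair in the ordering is separated by a
    factor 2 and every normalized effect stays above 0.1, so discriminant
    summaries have an unambiguous, recoverable ground-truth ordering.
    """
    space = DesignSpace(
        (
            VariableSpec("polyrA", 10.0, "g/L", 0.0, 25.0),
            VariableSpec("KCl", 4.0, "M", 0.0, 25.0),
            VariableSpec("NaCl", 4.0, "M", 0.0, 25.0),
            VariableSpec("PEG", 5.0, "%w/w", 0.0, 25.0),
        )
    )
    # conc ranges: rA 2.5 g/L, KCl 1 M, NaCl 1 M, PEG 1.25 %w/w
    model = PhaseModel(
        kind="logistic_linear",
        weights=(0.12, 2.4, 1.2, 0.48),
        offset=1.8,
        steepness=4.0,
    )
    return space, model
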