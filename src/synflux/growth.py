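"""Growth-regime setup and cross-condition comparison.

A cyanobacterium can grow autotrophically (CO₂/HCO₃⁻ + photons),
heterotrophically on glucose in the dark, heterotrophically with light
("light-activated"), or mixotrophically on both carbon sources at once.
To make conditions comparable, carbon sources are matched per carbon
atom: a total carbon budget of 3.4 mmol C·gDW⁻¹·h⁻¹ corresponds to
3.4 mmol CO₂ but only 3.4/6 ≈ 0.567 mmol of six-carbon glucose.
Photon capture is capped either by the two-phase physiological estimate
(0.8 mE·gDW⁻¹·h⁻¹ per photosystem) or by the geometric maximum a
spherical cell can intercept.  A maintenance ATP drain of 1.67 mol ATP
per mol glucose-equivalent carbon consumed is imposed in every mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fba import (
    ConstraintSet,
    FluxDistribution,
    FluxRange,
    InfeasibleProblem,
    LinearBound,
    blocked_reactions,
    fba,
    fva,
)
from .model import MetabolicModel, ModelError

__all__ = [
    "AUTOTROPHY",
    "DARK_HETEROTROPHY",
    "LIGHT_HETEROTROPHY",
    "MIXOTROPHY",
    "MODES",
    "CellGeometry",
    "ExchangeMap",
    "GrowthCondition",
    "GrowthModeSuiteResult",
    "carbon_normalized_uptake",
    "max_photon_uptake",
    "make_condition",
    "standard_conditions",
    "run_growth_mode_suite",
    "GLUCOSE_UPTAKE_MAX",
    "CO2_UPTAKE_MAX",
    "MAINTENANCE_ATP_PER_GLUCOSE",
]

AUTOTROPHY = "autotrophy"
DARK_HETEROTROPHY = "dark_heterotrophy"
LIGHT_HETEROTROPHY = "light_heterotrophy"
MIXOTROPHY = "mixotrophy"
MODES = (AUTOTROPHY, DARK_HETEROTROPHY, LIGHT_HETEROTROPHY, MIXOTROPHY)

# literature caps (mmol gDW^-1 h^-1)
GLUCOSE_UPTAKE_MAX = 0.85
CO2_UPTAKE_MAX = 3.7
MAINTENANCE_ATP_PER_GLUCOSE = 1.67


@dataclass
class CellGeometry:
    """Spherical-cell photon-capture geometry."""

    radius_m: float = 1.75e-6
    dry_mass_g: float = 0.5e-12
    incident_flux_mE_m2_s: float = 0.15

    def __post_init__(self):
        if self.radius_m <= 0 or self.dry_mass_g <= 0:
            raise ModelError("cell radius and dry mass must be positive")
        if self.incident_flux_mE_m2_s < 0:
            raise ModelError("incident photon flux cannot be negative")


def carbon_normalized_uptake(
    total_carbon_flux: float, carbons_per_molecule: int
) -> float:
    """Uptake (mmol·gDW⁻¹·h⁻¹) delivering ``total_carbon_flux`` mmol C."""
    if carbons_per_molecule < 1:
        raise ModelError("carbons_per_molecule must be >= 1")
    return total_carbon_flux / carbons_per_molecule


def max_photon_uptake(geom: CellGeometry) -> float:
    """Theoretical maximum illumination, mE·gDW⁻¹·h⁻¹.

    Incident flux × sphere surface 4πr², per gram dry weight, per hour.
    """
    area = 4.0 * math.pi * geom.radius_m**2
    return geom.incident_flux_mE_m2_s * area / geom.dry_mass_g * 3600.0


@dataclass
class ExchangeMap:
    """Which reactions play which uptake roles in a given model."""

    glucose_uptake: str
    co2_uptake: str
    photon_uptakes: tuple[str, ...]
    maintenance: str
    hco3_uptake: str | None = None
    glucose_carbons: int = 6


@dataclass
class GrowthCondition:
    mode: str
    constraints: ConstraintSet
    total_carbon_flux: float
    photon_cap: float
    maintenance_flux: float


def make_condition(
    mode: str,
    exchange_map: ExchangeMap,
    total_carbon_flux: float = 3.4,
    photon_cap: float = 0.8,
    glucose_carbon_fraction: float | None = None,
    maintenance_atp: float | None = None,
) -> GrowthCondition:
    """Build the constraint overlay for one growth regime.

    ``photon_cap`` is the per-photosystem uptake cap (mE·gDW⁻¹·h⁻¹).
    ``glucose_carbon_fraction``: in mixotrophy, the share of the carbon
    budget reserved for glucose; None leaves both sources open under the
    joint net-carbon cap (glucose up to total/6 and CO₂/HCO₃⁻ up to the
    full budget simultaneously, matching how the published comparison
    opened both sources).  ``maintenance_atp`` defaults to 1.67 × the
    glucose-equivalent uptake and is imposed as a fixed flux.
    """

    if mode not in MODES:
        raise ModelError(f"unknown growth mode {mode!r}")
    if glucose_carbon_fraction is not None and not 0 <= glucose_carbon_fraction <= 1:
        raise ModelError("glucose_carbon_fraction must be in [0, 1]")
    em = exchange_map
    glc_full = carbon_normalized_uptake(total_carbon_flux, em.glucose_carbons)
    if glc_full > GLUCOSE_UPTAKE_MAX + 1e-12:
        raise ModelError(
            f"glucose uptake {glc_full:.4g} exceeds the literature maximum "
            f"{GLUCOSE_UPTAKE_MAX}"
        )
    if total_carbon_flux > CO2_UPTAKE_MAX + 1e-12:
        raise ModelError(
            f"CO2 uptake {total_carbon_flux:.4g} exceeds the literature "
            f"maximum {CO2_UPTAKE_MAX}"
        )
    if maintenance_atp is None:
        maintenance_atp = MAINTENANCE_ATP_PER_GLUCOSE * glc_full

    bounds: dict[str, tuple[float, float]] = {}
    photons_on = mode != DARK_HETEROTROPHY
    for ph in em.photon_uptakes:
        bounds[ph] = (0.0, photon_cap) if photons_on else (0.0, 0.0)
    carbon_coeffs: dict[str, float] = {
        em.glucose_uptake: float(em.glucose_carbons),
        em.co2_uptake: 1.0,
    }
    if em.hco3_uptake is not None:
        carbon_coeffs[em.hco3_uptake] = 1.0

    if mode == AUTOTROPHY:
        bounds[em.glucose_uptake] = (0.0, 0.0)
        bounds[em.co2_uptake] = (-math.inf, total_carbon_flux)
        if em.hco3_uptake is not None:
            bounds[em.hco3_uptake] = (0.0, total_carbon_flux)
    elif mode in (DARK_HETEROTROPHY, LIGHT_HETEROTROPHY):
        bounds[em.glucose_uptake] = (0.0, glc_full)
        bounds[em.co2_uptake] = (-math.inf, 0.0)  # release only
        if em.hco3_uptake is not None:
            bounds[em.hco3_uptake] = (0.0, 0.0)
    else:  # mixotrophy
        if glucose_carbon_fraction is None:
            glc_cap, co2_cap = glc_full, total_carbon_flux
        else:
            glc_cap = glucose_carbon_fraction * glc_full
            co2_cap = (1.0 - glucose_carbon_fraction) * total_carbon_flux
        bounds[em.glucose_uptake] = (0.0, glc_cap)
        bounds[em.co2_uptake] = (-math.inf, co2_cap)
        if em.hco3_uptake is not None:
            bounds[em.hco3_uptake] = (0.0, co2_cap)
    bounds[em.maintenance] = (maintenance_atp, maintenance_atp)
    constraints = ConstraintSet(
        bounds,
        [LinearBound(carbon_coeffs, upper=total_carbon_flux)],
    )
    return GrowthCondition(
        mode, constraints, total_carbon_flux, photon_cap, maintenance_atp
    )


def standard_conditions(
    exchange_map: ExchangeMap,
    total_carbon_flux: float = 3.4,
    photon_cap: float = 0.8,
    glucose_carbon_fraction: float | None = None,
    maintenance_atp: float | None = None,
) -> dict[str, GrowthCondition]:
    """All four regimes at a matched carbon budget and photon cap."""
    return {
        mode: make_condition(
            mode,
            exchange_map,
            total_carbon_flux=total_carbon_flux,
            photon_cap=photon_cap,
            glucose_carbon_fraction=glucose_carbon_fraction,
            maintenance_atp=maintenance_atp,
        )
        for mode in MODES
    }


@dataclass
class GrowthModeSuiteResult:
    solutions: dict[str, FluxDistribution]
    ranges: dict[str, FluxRange]
    blocked: frozenset[str]
    comparison: pd.DataFrame
    failures: dict[str, str] = field(default_factory=dict)


def run_growth_mode_suite(
    model: MetabolicModel,
    conditions: Mapping[str, GrowthCondition],
    fraction_of_optimum: float = 1.0,
    reactions_of_interest: Sequence[str] | None = None,
) -> GrowthModeSuiteResult:
    """FBA + FVA per condition, reactions blocked everywhere, and a
    Table-4-style flux/min/max comparison.  Per-condition infeasibility
    is recorded and the suite continues."""

    solutions: dict[str, FluxDistribution] = {}
    ranges: dict[str, FluxRange] = {}
    failures: dict[str, str] = {}
    for name, cond in conditions.items():
        try:
            solutions[name] = fba(model, cond.constraints)
            ranges[name] = fva(
                model, cond.constraints, fraction_of_optimum=fraction_of_optimum
            )
        except InfeasibleProblem as exc:
            failures[name] = str(exc)
    blocked = blocked_reactions(list(ranges.values())) if ranges else frozenset()
    rxn_ids = (
        list(reactions_of_interest)
        if reactions_of_interest is not None
        else list(model.reactions)
    )
    rows = []
    for rxn_id in rxn_ids:
        row: dict[str, object] = {"reaction_id": rxn_id}
        for name in solutions:
            lo, hi = ranges[name].ranges[rxn_id]
            row[f"{name}_flux"] = solutions[name].fluxes[rxn_id]
            row[f"{name}_min"] = lo
            row[f"{name}_max"] = hi
        rows.append(row)
    return GrowthModeSuiteResult(
        solutions, ranges, blocked, pd.DataFrame(rows), failures
    )
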