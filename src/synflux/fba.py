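"""Flux balance analysis by linear programming.

All solvers work on the steady-state polytope {v : S·v = 0, l ≤ v ≤ u}
where S spans the internal (balanced) metabolites.  Symbolically
unbounded reaction sides are mapped to a large finite magnitude
(``big``, default 1e6) before the LP is posed.  Beyond plain FBA this
module implements the two-phase photon-minimization procedure used for
phototrophic growth (fix growth at a target, then minimize summed photon
uptake), flux variability analysis, and blocked-reaction detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError, build_stoichiometric_matrix

__all__ = [
    "BIG_BOUND",
    "FEASIBILITY_TOL",
    "ZERO_TOL",
    "ConstraintSet",
    "LinearBound",
    "FluxDistribution",
    "FluxRange",
    "InfeasibleProblem",
    "UnboundedObjective",
    "fba",
    "two_phase_light_minimization",
    "fva",
    "blocked_reactions",
    "write_flux_report",
]

#: Finite magnitude substituted for symbolically unbounded fluxes.
BIG_BOUND = 1.0e6
#: LP feasibility tolerance.
FEASIBILITY_TOL = 1.0e-9
#: Threshold below which a reported flux counts as zero.
ZERO_TOL = 1.0e-6


class InfeasibleProblem(ModelError):
    """The constraint set admits no steady-state flux vector.

    Distinct from a feasible solution with zero growth.  May carry the
    maximum achievable objective when known (two-phase procedure).
    """

    def __init__(self, message: str, max_objective: float | None = None):
        super().__init__(message)
        self.max_objective = max_objective


class UnboundedObjective(ModelError):
    pass


@dataclass
class LinearBound:
    """Extra linear constraint  lo ≤ Σ coeff_r · v_r ≤ hi  (e.g. a joint
    net-carbon uptake cap across several exchange reactions)."""

    coefficients: dict[str, float]
    lower: float = -math.inf
    upper: float = math.inf


@dataclass
class ConstraintSet:
    """Per-reaction bound overlays plus optional extra linear constraints.

    ``bounds`` overrides the model's default (lower, upper) for the named
    reactions only; everything else keeps its model bounds.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    linear_constraints: list[LinearBound] = field(default_factory=list)

    def __post_init__(self):
        for rxn_id, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ModelError(f"constraint for {rxn_id}: lower {lo} > upper {hi}")

    def merged(self, extra: Mapping[str, tuple[float, float]]) -> "ConstraintSet":
        out = dict(self.bounds)
        out.update(extra)
        return ConstraintSet(out, list(self.linear_constraints))


@dataclass
class FluxDistribution:
    """One solved flux vector with its objective value."""

    fluxes: dict[str, float]
    objective_value: float
    objective_id: str

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in order])


@dataclass
class FluxRange:
    """Per-reaction feasible (min, max) flux at a fixed objective level."""

    ranges: dict[str, tuple[float, float]]
    objective_value: float

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]


# ---------------------------------------------------------------------------


def _effective_bounds(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    big: float,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    order = list(model.reactions)
    lo = np.empty(len(order))
    hi = np.empty(len(order))
    overlay = constraints.bounds if constraints is not None else {}
    for rxn_id in overlay:
        if rxn_id not in model.reactions:
            raise ModelError(f"constraint for unknown reaction {rxn_id!r}")
    for j, rxn_id in enumerate(order):
        l, h = model.reactions[rxn_id].bounds
        if rxn_id in overlay:
            l, h = overlay[rxn_id]
        lo[j] = max(l, -big)
        hi[j] = min(h, big)
        if lo[j] > hi[j]:
            raise ModelError(f"empty bound interval for reaction {rxn_id}")
    return order, lo, hi


def _extra_rows(
    constraints: ConstraintSet | None, order: list[str]
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Inequality rows A_ub v <= b_ub from the extra linear constraints."""
    if constraints is None or not constraints.linear_constraints:
        return None, None
    index = {r: j for j, r in enumerate(order)}
    rows, rhs = [], []
    for lc in constraints.linear_constraints:
        row = np.zeros(len(order))
        for rxn_id, coeff in lc.coefficients.items():
            if rxn_id not in index:
                raise ModelError(
                    f"linear constraint references unknown reaction {rxn_id!r}"
                )
            row[index[rxn_id]] = coeff
        if math.isfinite(lc.upper):
            rows.append(row)
            rhs.append(lc.upper)
        if math.isfinite(lc.lower):
            rows.append(-row)
            rhs.append(-lc.lower)
    if not rows:
        return None, None
    return np.vstack(rows), np.array(rhs)


def _solve_lp(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    objective_vector: Mapping[str, float],
    sense: str,
    big: float,
) -> tuple[dict[str, float], float, list[str]]:
    order, lo, hi = _effective_bounds(model, constraints, big)
    S = build_stoichiometric_matrix(model).matrix
    c = np.zeros(len(order))
    index = {r: j for j, r in enumerate(order)}
    for rxn_id, coeff in objective_vector.items():
        c[index[rxn_id]] = coeff
    sign = -1.0 if sense == "max" else 1.0
    A_ub, b_ub = _extra_rows(constraints, order)
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lo, hi]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 2:
        raise InfeasibleProblem("LP infeasible under the given constraints")
    if res.status == 3:
        raise UnboundedObjective(
            f"objective over {sorted(objective_vector)} is unbounded"
        )
    if res.status != 0:
        raise ModelError(f"LP solver failure: {res.message}")
    fluxes = {r: float(res.x[j]) for r, j in index.items()}
    value = float(c @ res.x)
    return fluxes, value, order


def fba(
    model: MetabolicModel,
    constraints: ConstraintSet | None = None,
    objective: str | None = None,
    sense: str = "max",
    big: float = BIG_BOUND,
) -> FluxDistribution:
    """Optimize one reaction's flux over the steady-state polytope.

    Raises :class:`InfeasibleProblem` when the polytope is empty and
    :class:`UnboundedObjective` when the optimum is unbounded; a feasible
    model with zero growth returns normally with objective 0.
    """

    if sense not in ("max", "min"):
        raise ModelError(f"sense must be 'max' or 'min', got {sense!r}")
    if objective is None:
        objective = model.objective_reaction_id
    if objective not in model.reactions:
        raise ModelError(f"objective reaction {objective!r} not in model")
    fluxes, value, _ = _solve_lp(model, constraints, {objective: 1.0}, sense, big)
    return FluxDistribution(fluxes, value, objective)


def two_phase_light_minimization(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    target_growth: float | None,
    photon_reactions: Iterable[str],
    growth_band: float = 1.0e-6,
    big: float = BIG_BOUND,
) -> FluxDistribution:
    """Minimize total photon uptake at a fixed growth rate.

    Phase 1 (implicit when ``target_growth`` is None): maximize growth
    with light unconstrained.  Phase 2: pin growth inside the band
    [target·(1−band), target·(1+band)] and minimize the summed flux of
    the photon uptake reactions.  The returned distribution's
    ``objective_value`` is that minimized photon sum.
    """

    photon_reactions = list(photon_reactions)
    if not photon_reactions:
        raise ModelError("no photon reactions given")
    biomass = model.objective_reaction_id
    wt = fba(model, constraints, big=big)
    if target_growth is None:
        target_growth = wt.objective_value
    if target_growth > wt.objective_value * (1 + growth_band) + FEASIBILITY_TOL:
        raise InfeasibleProblem(
            f"target growth {target_growth} exceeds maximum achievable "
            f"{wt.objective_value}",
            max_objective=wt.objective_value,
        )
    band = abs(target_growth) * growth_band
    pinned = (constraints or ConstraintSet()).merged(
        {biomass: (target_growth - band, target_growth + band)}
    )
    fluxes, value, _ = _solve_lp(
        model, pinned, {r: 1.0 for r in photon_reactions}, "min", big
    )
    return FluxDistribution(fluxes, value, biomass)


def fva(
    model: MetabolicModel,
    constraints: ConstraintSet | None = None,
    objective: str | None = None,
    fraction_of_optimum: float = 1.0,
    reactions: Iterable[str] | None = None,
    big: float = BIG_BOUND,
) -> FluxRange:
    """Per-reaction (min, max) flux with the objective held at a fraction
    of its optimum — two LPs per reaction."""

    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ModelError("fraction_of_optimum must be in [0, 1]")
    if objective is None:
        objective = model.objective_reaction_id
    opt = fba(model, constraints, objective, big=big)
    floor = fraction_of_optimum * opt.objective_value
    # small slack keeps the pinned problem feasible against round-off
    floor -= max(abs(floor), 1.0) * 1.0e-9
    pinned = (constraints or ConstraintSet()).merged(
        {objective: (floor, model.reactions[objective].upper_bound)}
    )
    if reactions is None:
        reactions = list(model.reactions)
    ranges: dict[str, tuple[float, float]] = {}
    for rxn_id in reactions:
        lo_f, lo_v, _ = _solve_lp(model, pinned, {rxn_id: 1.0}, "min", big)
        hi_f, hi_v, _ = _solve_lp(model, pinned, {rxn_id: 1.0}, "max", big)
        ranges[rxn_id] = (lo_v, hi_v)
    return FluxRange(ranges, opt.objective_value)


def blocked_reactions(
    ranges: Sequence[FluxRange], tol: float = ZERO_TOL
) -> frozenset[str]:
    """Reactions whose flux interval is {0} in every supplied condition."""
    if not ranges:
        return frozenset()
    keys = set(ranges[0].ranges)
    for fr in ranges[1:]:
        if set(fr.ranges) != keys:
            raise ModelError("FluxRange objects cover different reaction sets")
    out = set()
    for rxn_id in keys:
        if all(
            abs(fr.ranges[rxn_id][0]) < tol and abs(fr.ranges[rxn_id][1]) < tol
            for fr in ranges
        ):
            out.add(rxn_id)
    return frozenset(out)


def write_flux_report(
    path,
    conditions: Mapping[str, tuple[FluxDistribution, FluxRange | None]],
) -> None:
    """TSV with reaction_id then flux / min_flux / max_flux per condition."""
    import pandas as pd

    first = next(iter(conditions.values()))[0]
    rows = []
    for rxn_id in first.fluxes:
        row: dict[str, object] = {"reaction_id": rxn_id}
        for cond, (dist, rng) in conditions.items():
            row[f"{cond}_flux"] = float(f"{dist.fluxes[rxn_id]:.6g}")
            if rng is not None:
                lo, hi = rng.ranges[rxn_id]
                row[f"{cond}_min_flux"] = float(f"{lo:.6g}")
                row[f"{cond}_max_flux"] = float(f"{hi:.6g}")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
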