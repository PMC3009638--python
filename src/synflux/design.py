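"""Knockout strain design for overproduction of a target metabolite.

The outer problem searches over sets of reaction deletions; the inner
problem fixes the mutant's flux state with a *biological* objective —
either FBA (growth re-optimization) or MOMA (minimal adjustment from the
wild type) — and the *design* objective (flux of the target exchange
reaction, e.g. succinate export or H₂ evolution) is read off that state.
Both an exhaustive enumeration (single/double/triple knockouts) and an
OptGene-style genetic algorithm over binary deletion vectors are
provided.  Deletions are reaction-centered; the gene sets that would
realize each deletion are reported post hoc by GPR inversion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fba import ConstraintSet, FluxDistribution, InfeasibleProblem, fba
from .model import MetabolicModel, ModelError, reactions_disabled_by
from .moma import moma

__all__ = [
    "DesignResult",
    "GAParameters",
    "default_candidates",
    "genes_implying",
    "evaluate_design",
    "exhaustive_knockout_search",
    "evolutionary_knockout_search",
    "write_design_report_tsv",
]

EXHAUSTIVE_GUARD = 200_000  # max deletion sets to enumerate


@dataclass
class DesignResult:
    knocked_out: frozenset[str]
    implied_genes: dict[str, frozenset[str]]
    production: float
    growth: float
    inner_method: str
    feasible: bool = True
    fluxes: FluxDistribution | None = None


@dataclass
class GAParameters:
    population: int = 40
    generations: int = 200
    mutation_rate: float = 0.02
    tournament_size: int = 2
    elitism: int = 1


def default_candidates(model: MetabolicModel) -> list[str]:
    """Deletion candidates: gene-associated, non-exchange reactions.

    Exchange/transport reactions and spontaneous (GPR-less) reactions are
    excluded — deleting an uptake trivially reroutes carbon and is not a
    realizable enzyme knockout.  The biomass and design objectives are
    never candidates.
    """

    exchange = set(model.exchange_reactions())
    skip = {model.objective_reaction_id}
    if model.design_objective_id:
        skip.add(model.design_objective_id)
    return [
        r.id
        for r in model.reactions.values()
        if r.gpr is not None and r.id not in exchange and r.id not in skip
    ]


def genes_implying(model: MetabolicModel, reaction_id: str) -> frozenset[str]:
    """Smallest gene set whose deletion disables the reaction, by inversion
    of its GPR: for an isozyme family every branch must lose a member, for
    a complex one subunit suffices.  Returns a minimal hitting set found
    greedily over the rule's gene universe (exact for the small rules used
    here)."""

    rxn = model.reactions[reaction_id]
    if rxn.gpr is None:
        return frozenset()
    universe = sorted(rxn.gpr.genes())
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            if not rxn.gpr.evaluate(frozenset(combo)):
                return frozenset(combo)
    return frozenset(universe)


def evaluate_design(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    deletions: Iterable[str],
    design_reaction: str,
    inner: str = "moma",
    wild_type: FluxDistribution | None = None,
) -> DesignResult:
    """Score one deletion set: inner flux state, then read off production.

    inner='fba'  → the mutant re-optimizes growth; production is the
    design flux of that optimum.  inner='moma' → the mutant state is the
    MOMA solution against ``wild_type``; production and growth are both
    read from it.  Infeasible mutants score production 0, growth 0 and
    are flagged.
    """

    inner = inner.lower()
    if inner not in ("fba", "moma"):
        raise ModelError(f"inner method must be 'fba' or 'moma', got {inner!r}")
    if design_reaction not in model.reactions:
        raise ModelError(f"unknown design reaction {design_reaction!r}")
    deletions = frozenset(deletions)
    implied = {r: genes_implying(model, r) for r in sorted(deletions)}
    closed = {r: (0.0, 0.0) for r in deletions}
    mutant_constraints = (constraints or ConstraintSet()).merged(closed)
    try:
        if inner == "fba":
            state = fba(model, mutant_constraints)
            growth = state.objective_value
        else:
            if wild_type is None:
                wild_type = fba(model, constraints)
            sol = moma(model, constraints, deletions, wild_type)
            state = sol.fluxes
            growth = sol.growth
    except InfeasibleProblem:
        return DesignResult(deletions, implied, 0.0, 0.0, inner, feasible=False)
    return DesignResult(
        deletions,
        implied,
        production=state.fluxes[design_reaction],
        growth=growth,
        inner_method=inner,
        fluxes=state,
    )


def _passes_filter(result: DesignResult, min_growth: float) -> bool:
    return result.feasible and result.growth >= min_growth


def exhaustive_knockout_search(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    k: int,
    design_reaction: str,
    min_growth_fraction: float = 0.1,
    inner: str = "moma",
    wild_type: FluxDistribution | None = None,
    candidates: Sequence[str] | None = None,
) -> list[DesignResult]:
    """Evaluate every deletion set of size ≤ k; rank by production.

    Deterministic: results sorted by production (descending), then by the
    sorted deletion ids.  Sets failing the growth filter are dropped.
    A combinatorial guard refuses enumerations beyond
    ``EXHAUSTIVE_GUARD`` evaluations.
    """

    if candidates is None:
        candidates = default_candidates(model)
    total = sum(math.comb(len(candidates), s) for s in range(k + 1))
    if total > EXHAUSTIVE_GUARD:
        raise ModelError(
            f"{total} deletion sets exceed the exhaustive guard "
            f"({EXHAUSTIVE_GUARD}); use evolutionary_knockout_search"
        )
    if wild_type is None:
        wild_type = fba(model, constraints)
    min_growth = min_growth_fraction * wild_type.objective_value
    results: list[DesignResult] = []
    for size in range(k + 1):
        for combo in itertools.combinations(sorted(candidates), size):
            res = evaluate_design(
                model, constraints, combo, design_reaction, inner, wild_type
            )
            if size == 0 or _passes_filter(res, min_growth):
                results.append(res)
    results.sort(key=lambda r: (-r.production, sorted(r.knocked_out)))
    return results


def evolutionary_knockout_search(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    k: int,
    design_reaction: str,
    seed: int,
    population: int | None = None,
    generations: int | None = None,
    mutation_rate: float | None = None,
    min_growth_fraction: float = 0.1,
    inner: str = "moma",
    wild_type: FluxDistribution | None = None,
    candidates: Sequence[str] | None = None,
    params: GAParameters | None = None,
) -> DesignResult:
    """Genetic algorithm over binary deletion vectors capped at k set bits.

    Fitness is the production of :func:`evaluate_design`, zero when the
    growth filter fails.  Tournament selection, uniform crossover,
    per-bit mutation, elitism; a mandatory seed makes runs reproducible.
    """

    p = params or GAParameters()
    if population is not None:
        p.population = population
    if generations is not None:
        p.generations = generations
    if mutation_rate is not None:
        p.mutation_rate = mutation_rate
    if candidates is None:
        candidates = default_candidates(model)
    candidates = sorted(candidates)
    n = len(candidates)
    rng = np.random.default_rng(seed)
    if wild_type is None:
        wild_type = fba(model, constraints)
    min_growth = min_growth_fraction * wild_type.objective_value

    cache: dict[frozenset[str], DesignResult] = {}

    def score(bits: np.ndarray) -> tuple[float, DesignResult]:
        dele = frozenset(candidates[i] for i in np.flatnonzero(bits))
        if dele not in cache:
            cache[dele] = evaluate_design(
                model, constraints, dele, design_reaction, inner, wild_type
            )
        res = cache[dele]
        fit = res.production if (not dele or _passes_filter(res, min_growth)) else 0.0
        return fit, res

    def repair(bits: np.ndarray) -> np.ndarray:
        on = np.flatnonzero(bits)
        if len(on) > k:
            drop = rng.choice(on, size=len(on) - k, replace=False)
            bits = bits.copy()
            bits[drop] = False
        return bits

    # initial population: wild type plus random individuals of size <= k
    pop = [np.zeros(n, dtype=bool)]
    while len(pop) < p.population:
        bits = np.zeros(n, dtype=bool)
        size = int(rng.integers(0, k + 1)) if n else 0
        if size and n:
            bits[rng.choice(n, size=min(size, n), replace=False)] = True
        pop.append(bits)
    fits = [score(b)[0] for b in pop]

    best_bits = pop[int(np.argmax(fits))].copy()
    best_fit = max(fits)

    for _ in range(p.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: p.elitism]]
        while len(new_pop) < p.population:
            picks = []
            for _ in range(2):
                contestants = rng.integers(0, p.population, size=p.tournament_size)
                winner = max(contestants, key=lambda i: fits[i])
                picks.append(pop[winner])
            mask = rng.random(n) < 0.5
            child = np.where(mask, picks[0], picks[1])
            flips = rng.random(n) < p.mutation_rate
            child = child ^ flips
            new_pop.append(repair(child))
        pop = new_pop
        fits = [score(b)[0] for b in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_bits = pop[gen_best].copy()

    return score(best_bits)[1]


def write_design_report_tsv(results: Sequence[DesignResult], path) -> None:
    import pandas as pd

    rows = []
    for rank, r in enumerate(results, start=1):
        rows.append(
            {
                "rank": rank,
                "deletions": ";".join(sorted(r.knocked_out)) or "(wild type)",
                "implied_genes": ";".join(
                    ",".join(sorted(g)) for _, g in sorted(r.implied_genes.items())
                ),
                "production": float(f"{r.production:.6g}"),
                "growth": float(f"{r.growth:.6g}"),
                "inner_method": r.inner_method,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
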