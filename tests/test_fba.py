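"""LP flux balance analysis, photon minimization, FVA, blocked reactions."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import linprog

import synflux as sf
from synflux.fba import ConstraintSet, LinearBound


def chain_model(double_b=False):
    mets = [sf.Metabolite("A_ext", external=True), sf.Metabolite("A"),
            sf.Metabolite("B")]
    rxns = [
        sf.Reaction("EX_A", {"A_ext": -1, "A": 1}, upper_bound=1.0),
        sf.Reaction("R", {"A": -1, "B": 2.0 if double_b else 1.0}),
        sf.Reaction("BM", {"B": -1}),
    ]
    return sf.MetabolicModel(mets, rxns, objective_reaction_id="BM")


def branched_model():
    """Bounded 8-reaction branched network for the vertex oracle."""
    mets = [sf.Metabolite("S", external=True), sf.Metabolite("A"),
            sf.Metabolite("B"), sf.Metabolite("C")]
    rxns = [
        sf.Reaction("EX", {"S": -1, "A": 1}, upper_bound=2.0),
        sf.Reaction("R1", {"A": -1, "B": 1}, upper_bound=3.0),
        sf.Reaction("R2", {"A": -1, "C": 1}, upper_bound=1.2),
        sf.Reaction("R3", {"B": -1, "C": 1}, reversible=True,
                    lower_bound=-3.0, upper_bound=3.0),
        sf.Reaction("R4", {"B": -2, "C": 1}, upper_bound=3.0),
        sf.Reaction("EX_B", {"B": -1}, upper_bound=0.5),
        sf.Reaction("R5", {"C": -1, "B": 0.5}, upper_bound=3.0),
        sf.Reaction("BM", {"C": -1}, upper_bound=5.0),
    ]
    return sf.MetabolicModel(mets, rxns, objective_reaction_id="BM")


def enumerate_vertices_max(model, objective):
    """Brute-force LP oracle: enumerate basic solutions of the bounded
    polytope {Sv=0, l<=v<=u} and maximize the objective over them."""
    S = sf.build_stoichiometric_matrix(model).matrix
    order = list(model.reactions)
    lo = np.array([model.reactions[r].lower_bound for r in order])
    hi = np.array([model.reactions[r].upper_bound for r in order])
    n = len(order)
    rank = np.linalg.matrix_rank(S)
    n_fix = n - rank
    j_obj = order.index(objective)
    best = -np.inf
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for pattern in itertools.product([0, 1], repeat=n_fix):
            v = np.zeros(n)
            for j, p in zip(fixed, pattern):
                v[j] = lo[j] if p == 0 else hi[j]
            rhs = -S[:, list(fixed)] @ v[list(fixed)]
            sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v[free] = sol
            if np.abs(S @ v).max() > 1e-8:
                continue
            if (v < lo - 1e-8).any() or (v > hi + 1e-8).any():
                continue
            best = max(best, v[j_obj])
    return best


class TestFba:
    def test_linear_chain_optimum(self):
        assert sf.fba(chain_model()).objective_value == pytest.approx(1.0)

    def test_stoichiometric_gain(self):
        assert sf.fba(chain_model(double_b=True)).objective_value == pytest.approx(2.0)

    def test_branched_optimum_matches_vertex_enumeration(self):
        model = branched_model()
        expected = enumerate_vertices_max(model, "BM")
        assert sf.fba(model).objective_value == pytest.approx(expected, abs=1e-8)

    def test_mass_balance_on_solutions(self, toy, conditions, stoich):
        order = list(toy.reactions)
        for cond in conditions.values():
            sol = sf.fba(toy, cond.constraints)
            residual = np.abs(stoich.matrix @ sol.as_array(order)).max()
            assert residual < 1e-6

    def test_fluxes_respect_bounds(self, toy, mixo):
        sol = sf.fba(toy, mixo)
        from synflux.fba import _effective_bounds

        order, lo, hi = _effective_bounds(toy, mixo, 1e6)
        v = sol.as_array(order)
        assert (v >= lo - 1e-6).all() and (v <= hi + 1e-6).all()

    def test_infeasible_distinct_from_zero_growth(self, toy, mixo):
        # contradictory requirement: growth forced on while carbon is off
        stuck = mixo.merged(
            {"EX_glc": (0, 0), "EX_co2": (0, 0), "EX_hco3": (0, 0),
             "BIOMASS": (0.1, 1.0)}
        )
        with pytest.raises(sf.InfeasibleProblem):
            sf.fba(toy, stuck)
        zero = mixo.merged(
            {"EX_glc": (0, 0), "EX_co2": (-1e6, 0), "EX_hco3": (0, 0),
             "EX_photon1": (0, 0), "EX_photon2": (0, 0), "NGAM": (0, 0)}
        )
        assert sf.fba(toy, zero).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unbounded_objective_detected(self):
        mets = [sf.Metabolite("X")]
        rxns = [
            sf.Reaction("a", {"X": 1}, reversible=True),
            sf.Reaction("b", {"X": -1}, reversible=True),
        ]
        model = sf.MetabolicModel(mets, rxns, objective_reaction_id="a")
        with pytest.raises(sf.UnboundedObjective):
            sf.fba(model, big=math.inf)

    def test_optimum_invariant_to_reaction_order(self, toy, mixo, mixo_wt):
        reordered = sf.MetabolicModel(
            list(toy.metabolites.values()),
            list(reversed(list(toy.copy().reactions.values()))),
            objective_reaction_id="BIOMASS",
            design_objective_id="EX_succ",
        )
        assert sf.fba(reordered, mixo).objective_value == pytest.approx(
            mixo_wt.objective_value, rel=1e-9
        )

    def test_optimum_invariant_to_reversible_split(self, toy, mixo, mixo_wt):
        split = toy.copy()
        fum = split.reactions.pop("FUM")
        split.reactions["FUM_f"] = sf.Reaction("FUM_f", dict(fum.stoichiometry))
        split.reactions["FUM_b"] = sf.Reaction(
            "FUM_b", {m: -c for m, c in fum.stoichiometry.items()}
        )
        assert sf.fba(split, mixo).objective_value == pytest.approx(
            mixo_wt.objective_value, rel=1e-9
        )

    def test_added_constraint_never_increases_optimum(self, toy, mixo, mixo_wt):
        for cap in (0.4, 0.2, 0.05):
            tightened = mixo.merged({"EX_glc": (0.0, cap)})
            assert (
                sf.fba(toy, tightened).objective_value
                <= mixo_wt.objective_value + 1e-9
            )

    def test_agrees_with_independent_cobra_solver(self, toy):
        cobra = pytest.importorskip("cobra")
        overlay = {
            "EX_glc": (0.0, 0.567), "EX_photon1": (0.0, 0.0),
            "EX_photon2": (0.0, 0.0), "EX_co2": (-1000.0, 0.0),
            "EX_hco3": (0.0, 0.0), "NGAM": (0.946, 0.946),
        }
        mine = sf.fba(toy, ConstraintSet(dict(overlay)))
        cm = cobra.Model("toy")
        cmets = {m.id: cobra.Metabolite(m.id) for m in toy.metabolites.values()
                 if not m.external}
        for rxn in toy.reactions.values():
            cr = cobra.Reaction(rxn.id)
            cr.add_metabolites(
                {cmets[m]: c for m, c in rxn.stoichiometry.items() if m in cmets}
            )
            lo, hi = overlay.get(rxn.id, rxn.bounds)
            cr.bounds = (max(lo, -1e6), min(hi, 1e6))
            cm.add_reactions([cr])
        cm.objective = "BIOMASS"
        assert mine.objective_value == pytest.approx(
            cm.slim_optimize(), abs=1e-6
        )


class TestTwoPhaseLightMinimization:
    def test_zero_growth_with_sugar_needs_no_photons(self, toy, conditions):
        light_het = conditions["light_heterotrophy"].constraints
        sol = sf.two_phase_light_minimization(
            toy, light_het, 0.0, ["EX_photon1", "EX_photon2"]
        )
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_matches_direct_lp_rederivation(self, toy, conditions):
        auto = conditions["autotrophy"].constraints
        target = sf.fba(toy, auto).objective_value
        sol = sf.two_phase_light_minimization(
            toy, auto, target, ["EX_photon1", "EX_photon2"]
        )
        # independent LP: same polytope, growth pinned, photon sum objective
        from synflux.fba import _effective_bounds, _extra_rows

        order, lo, hi = _effective_bounds(toy, auto, 1e6)
        j_bm = order.index("BIOMASS")
        lo[j_bm] = target * (1 - 1e-6)
        hi[j_bm] = target * (1 + 1e-6)
        c = np.zeros(len(order))
        c[order.index("EX_photon1")] = 1
        c[order.index("EX_photon2")] = 1
        S = sf.build_stoichiometric_matrix(toy).matrix
        A_ub, b_ub = _extra_rows(auto, order)
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub,
                      bounds=np.column_stack([lo, hi]), method="highs")
        assert res.status == 0
        assert sol.objective_value == pytest.approx(res.fun, abs=1e-6)

    def test_infeasible_target_reports_maximum(self, toy, conditions):
        auto = conditions["autotrophy"].constraints
        max_growth = sf.fba(toy, auto).objective_value
        with pytest.raises(sf.InfeasibleProblem) as err:
            sf.two_phase_light_minimization(
                toy, auto, max_growth * 2, ["EX_photon1", "EX_photon2"]
            )
        assert err.value.max_objective == pytest.approx(max_growth)


class TestFva:
    def test_linear_chain_collapses_to_points(self):
        model = chain_model()
        ranges = sf.fva(model)
        sol = sf.fba(model)
        for rid, (lo, hi) in ranges.ranges.items():
            assert lo == pytest.approx(hi, abs=1e-8)
            assert lo == pytest.approx(sol.fluxes[rid], abs=1e-8)

    def test_parallel_routes_share_total_flux(self):
        mets = [sf.Metabolite("S", external=True), sf.Metabolite("A"),
                sf.Metabolite("B")]
        rxns = [
            sf.Reaction("EX", {"S": -1, "A": 1}, lower_bound=1.0, upper_bound=1.0),
            sf.Reaction("P1", {"A": -1, "B": 1}),
            sf.Reaction("P2", {"A": -1, "B": 1}),
            sf.Reaction("BM", {"B": -1}),
        ]
        model = sf.MetabolicModel(mets, rxns, objective_reaction_id="BM")
        ranges = sf.fva(model)
        assert ranges["P1"] == pytest.approx((0.0, 1.0), abs=1e-8)
        assert ranges["P2"] == pytest.approx((0.0, 1.0), abs=1e-8)

    def test_contains_fba_solution(self, toy, mixo, mixo_wt):
        ranges = sf.fva(toy, mixo)
        for rid, flux in mixo_wt.fluxes.items():
            lo, hi = ranges[rid]
            assert lo - 1e-6 <= flux <= hi + 1e-6

    def test_agrees_with_independent_cobra_fva(self, toy):
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import flux_variability_analysis

        overlay = {
            "EX_glc": (0.0, 0.567), "EX_photon1": (0.0, 0.0),
            "EX_photon2": (0.0, 0.0), "EX_co2": (-1000.0, 0.0),
            "EX_hco3": (0.0, 0.0), "NGAM": (0.946, 0.946),
        }
        subset = ["EX_glc", "EX_succ", "SDH", "ICL", "BIOMASS", "PGI"]
        mine = sf.fva(toy, ConstraintSet(dict(overlay)), reactions=subset)
        cm = cobra.Model("toy")
        cmets = {m.id: cobra.Metabolite(m.id) for m in toy.metabolites.values()
                 if not m.external}
        for rxn in toy.reactions.values():
            cr = cobra.Reaction(rxn.id)
            cr.add_metabolites(
                {cmets[m]: c for m, c in rxn.stoichiometry.items() if m in cmets}
            )
            lo, hi = overlay.get(rxn.id, rxn.bounds)
            cr.bounds = (max(lo, -1e6), min(hi, 1e6))
            cm.add_reactions([cr])
        cm.objective = "BIOMASS"
        ref = flux_variability_analysis(
            cm, reaction_list=subset, fraction_of_optimum=1.0
        )
        for rid in subset:
            assert mine[rid][0] == pytest.approx(ref.loc[rid, "minimum"], abs=1e-4)
            assert mine[rid][1] == pytest.approx(ref.loc[rid, "maximum"], abs=1e-4)


class TestBlockedReactions:
    def test_blocked_everywhere_included_partial_excluded(self):
        a = sf.FluxRange({"r1": (0.0, 0.0), "r2": (0.0, 0.0)}, 1.0)
        b = sf.FluxRange({"r1": (0.0, 0.0), "r2": (0.0, 0.7)}, 1.0)
        assert sf.blocked_reactions([a, b]) == frozenset({"r1"})

    def test_mismatched_reaction_sets_rejected(self):
        a = sf.FluxRange({"r1": (0.0, 0.0)}, 1.0)
        b = sf.FluxRange({"r2": (0.0, 0.0)}, 1.0)
        with pytest.raises(sf.ModelError):
            sf.blocked_reactions([a, b])

    def test_dead_end_pathway_matches_reachability_oracle(self):
        import networkx as nx

        mets = [sf.Metabolite("S", external=True), sf.Metabolite("A"),
                sf.Metabolite("B"), sf.Metabolite("X"), sf.Metabolite("Y")]
        rxns = [
            sf.Reaction("EX", {"S": -1, "A": 1}, upper_bound=1.0),
            sf.Reaction("R1", {"A": -1, "B": 1}),
            sf.Reaction("BM", {"B": -1}),
            sf.Reaction("D1", {"B": -1, "X": 1}),
            sf.Reaction("D2", {"X": -1, "Y": 1}),
        ]
        model = sf.MetabolicModel(mets, rxns, objective_reaction_id="BM")
        blocked = sf.blocked_reactions([sf.fva(model, fraction_of_optimum=0.0)])

        # oracle: a reaction is blocked iff some product cannot reach a sink
        g = nx.DiGraph()
        for r in rxns:
            for met, coeff in r.stoichiometry.items():
                if coeff < 0:
                    g.add_edge(met, r.id)
                else:
                    g.add_edge(r.id, met)
        sinks = {"BM"} | {m.id for m in mets if m.external}
        expected = {
            r.id
            for r in rxns
            if not any(
                nx.has_path(g, r.id, s) for s in sinks if g.has_node(s)
            )
        }
        assert blocked == expected == {"D1", "D2"}

    def test_toy_decoy_reactions_blocked_in_all_conditions(self, toy, conditions):
        ranges = [sf.fva(toy, c.constraints) for c in conditions.values()]
        blocked = sf.blocked_reactions(ranges)
        decoys = {r for r in toy.reactions if r.startswith("DEC")}
        assert decoys <= blocked
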