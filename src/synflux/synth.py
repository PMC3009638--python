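"""Synthetic phototroph model and planted-signal expression generators.

The toy network condenses the documented architecture of a cyanobacterial
genome-scale model into ~45 reactions: two photosystems sharing a
plastoquinone pool with the respiratory chain, water splitting with O₂
evolution, ATP synthase driven by a proton-motive pseudo-metabolite,
RuBisCO plus a condensed Calvin cycle, a glucose transporter and
glycolysis with both ATP- and GTP-dependent pyruvate-kinase variants,
PEP carboxylase anaplerosis, a TCA cycle that lacks 2-oxoglutarate
dehydrogenase and is completed by the glyoxylate shunt, succinate
dehydrogenase feeding the electron chain, an optional bidirectional
hydrogenase, and a biomass drain over precursor proxies whose
coefficients keep the proportions of the published biomass composition.
Acetyl-CoA can only be fully oxidized through the glyoxylate shunt, so
the succinate branch carries real flux in growing cells — the property
the knockout-design analyses rely on.

Decoy genes gate dead-end side reactions: they are never essential,
give flux-variability analysis genuinely blocked reactions, and widen
the gene pool for the reporter statistics.

The expression generator plants differential-expression signal around
chosen metabolites: genes neighboring a planted metabolite draw
p ~ Beta(α, 1) (stochastically small for α < 1), everything else is
Uniform(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .growth import ExchangeMap
from .model import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    parse_gpr,
)
from .reporter import ExpressionDataset, metabolite_gene_neighborhoods

__all__ = [
    "ToySpec",
    "PHOTON_PACKET",
    "generate_toy_phototroph",
    "toy_exchange_map",
    "generate_expression_dataset",
    "dead_end_decoy_genes",
    "published_biomass_composition",
]

#: Photon excitations delivered per unit flux of a photon-uptake reaction.
#: One flux unit stands for one milli-einstein of captured light driving
#: this many photochemical events, so physiological mE-scale uptake caps
#: support mmol-scale carbon fixation (≈10 photons per CO₂).
PHOTON_PACKET = 10.0

#: Growth-associated ATP cost (mmol ATP per unit biomass flux).
BIOMASS_ATP = 30.0
#: Growth-associated NADPH cost.
BIOMASS_NADPH = 10.0


@dataclass
class ToySpec:
    """Knobs of the toy generator; defaults define the study conditions."""

    seed: int = 0
    include_hydrogenase: bool = True
    include_glyoxylate_shunt: bool = True
    include_photosystems: bool = True
    include_glucose_transport: bool = True
    n_decoy_genes: int = 24
    biomass_precursor_subset: tuple[str, ...] = (
        "pyr", "pg3", "akg", "oaa", "r5p", "g6p", "accoa",
    )


# Published biomass composition (mmol per g dry cell weight).
_BIOMASS_COMPOSITION = {
    "Alanine": 0.499149,
    "Arginine": 0.28742,
    "Aspartate": 0.234232,
    "Asparagine": 0.234232,
    "Cysteine": 0.088988,
    "Glutamine": 0.255712,
    "Glutamate": 0.255712,
    "Glycine": 0.595297,
    "Histidine": 0.092056,
    "Isoleucine": 0.282306,
    "Leucine": 0.437778,
    "Lysine": 0.333448,
    "Methionine": 0.149336,
    "Phenylalanine": 0.180021,
    "Proline": 0.214798,
    "Serine": 0.209684,
    "Threonine": 0.246506,
    "Tryptophan": 0.055234,
    "Tyrosine": 0.133993,
    "Valine": 0.411184,
    "Glycogen": 0.01450617,
    "dATP": 0.0241506,
    "dTTP": 0.0241506,
    "dGTP": 0.02172983,
    "dCTP": 0.02172983,
    "AMP": 0.14038929,
    "UMP": 0.14038929,
    "GMP": 0.12374585,
    "CMP": 0.12374585,
    "16C-lipid": 0.20683718,
    "(9Z)16C-lipid": 0.01573412,
    "18C-lipid": 0.00351776,
    "(9Z)18C-lipid": 0.03188596,
    "(9Z,12Z)18C-lipid": 0.03568367,
    "(9Z,12Z,15Z)18C-lipid": 0.01797109,
    "(6Z,9Z,12Z)18C-lipid": 0.05031906,
    "(6Z,9Z,12Z,15Z)18C-lipid": 0.01448179,
    "Chlorophyll a": 0.02728183,
    "Carotenoids": 0.00820225,
}


def published_biomass_composition() -> dict[str, float]:
    """The published biomass composition, mmol·gDCW⁻¹ per precursor."""
    return dict(_BIOMASS_COMPOSITION)


# toy precursor proxy -> the biomass-composition entry whose coefficient it
# inherits (keeps relative proportions without ~80 biosynthesis routes)
_PRECURSOR_PROXY = {
    "pyr": "Alanine",
    "pg3": "Glycine",
    "akg": "Glutamate",
    "oaa": "Aspartate",
    "r5p": "AMP",
    "g6p": "Glycogen",
    "accoa": "16C-lipid",
}

# id -> (name, carbon_count, cofactor)
_METABOLITES: dict[str, tuple[str, int, bool]] = {
    "photon1": ("photon (PSI)", 0, True),
    "photon2": ("photon (PSII)", 0, True),
    "pq": ("plastoquinone", 0, True),
    "pqh2": ("plastoquinol", 0, True),
    "pmf": ("proton-motive force", 0, True),
    "h2o": ("H2O", 0, True),
    "o2": ("oxygen O2", 0, True),
    "co2": ("CO2", 1, True),
    "hco3": ("bicarbonate", 1, False),
    "pi": ("phosphate", 0, True),
    "atp": ("ATP", 0, True),
    "adp": ("ADP", 0, True),
    "amp": ("AMP", 0, True),
    "gtp": ("GTP", 0, True),
    "gdp": ("GDP", 0, True),
    "nad": ("NAD+", 0, True),
    "nadh": ("NADH", 0, True),
    "nadp": ("NADP+", 0, True),
    "nadph": ("NADPH", 0, True),
    "coa": ("coenzyme A", 0, True),
    "h2": ("hydrogen H2", 0, False),
    "glc": ("beta-D-glucose", 6, False),
    "g6p": ("glucose-6-phosphate", 6, False),
    "f6p": ("fructose-6-phosphate", 6, False),
    "g3p": ("glyceraldehyde-3-phosphate", 3, False),
    "pg3": ("3-phosphoglycerate", 3, False),
    "pep": ("phosphoenolpyruvate", 3, False),
    "pyr": ("pyruvate", 3, False),
    "accoa": ("acetyl-CoA", 2, False),
    "cit": ("citrate", 6, False),
    "akg": ("2-oxoglutarate", 5, False),
    "succ": ("succinate", 4, False),
    "fum": ("fumarate", 4, False),
    "mal": ("malate", 4, False),
    "oaa": ("oxaloacetate", 4, False),
    "glx": ("glyoxylate", 2, False),
    "rubp": ("ribulose-1,5-bisphosphate", 5, False),
    "ru5p": ("ribulose-5-phosphate", 5, False),
    "r5p": ("ribose-5-phosphate", 5, False),
}

_EXTERNALS = {
    "photon1_ext": ("photon source (PSI)", 0),
    "photon2_ext": ("photon source (PSII)", 0),
    "co2_ext": ("external CO2", 1),
    "hco3_ext": ("external bicarbonate", 1),
    "glc_ext": ("external glucose", 6),
    "o2_ext": ("external oxygen", 0),
    "h2o_ext": ("external water", 0),
    "pi_ext": ("external phosphate", 0),
    "succ_ext": ("external succinate", 4),
    "h2_ext": ("external hydrogen", 0),
}

# (id, equation-ish stoichiometry, reversible, gpr rule or None, ec)
_P = PHOTON_PACKET


def _core_reactions(spec: ToySpec) -> list[tuple]:
    rxns: list[tuple] = [
        # exchanges / transport
        ("EX_co2", {"co2_ext": -1, "co2": 1}, True, None, None),
        ("EX_hco3", {"hco3_ext": -1, "hco3": 1}, False, None, None),
        ("EX_o2", {"o2": -1, "o2_ext": 1}, True, None, None),
        ("EX_h2o", {"h2o_ext": -1, "h2o": 1}, True, None, None),
        ("EX_pi", {"pi_ext": -1, "pi": 1}, True, None, None),
        ("EX_succ", {"succ": -1, "succ_ext": 1}, False, None, None),
        ("CA", {"hco3": -1, "co2": 1}, True, "cynT", "4.2.1.1"),
        ("NGAM", {"atp": -1, "h2o": -1, "adp": 1, "pi": 1}, False, None, None),
        ("THD", {"nadh": -1, "nadp": -1, "nad": 1, "nadph": 1}, True, "pntA", None),
        ("NDH1", {"nadh": -1, "pq": -1, "nad": 1, "pqh2": 1, "pmf": 1},
         False, "ndhA", "1.6.5.3"),
        ("COX", {"pqh2": -1, "o2": -0.5, "pq": 1, "pmf": 2, "h2o": 1},
         False, "coxA", "1.9.3.1"),
        ("ATPSYN", {"pmf": -3, "adp": -1, "pi": -1, "atp": 1, "h2o": 1},
         False, "atpA", "3.6.3.14"),
        # central carbon
        ("HK", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}, False, "glk", "2.7.1.2"),
        ("PGI", {"g6p": -1, "f6p": 1}, True, "pgi1 or pgi2", "5.3.1.9"),
        ("PFK", {"f6p": -1, "atp": -1, "g3p": 2, "adp": 1}, False, "pfkA", None),
        ("FBP", {"g3p": -2, "f6p": 1, "pi": 1}, False, "fbaB", "4.1.2.13"),
        ("GAPC", {"g3p": -1, "nad": -1, "adp": -1, "pi": -1,
                  "pg3": 1, "nadh": 1, "atp": 1}, False, "gapC", "1.2.1.12"),
        ("GAPN", {"pg3": -1, "atp": -1, "nadph": -1,
                  "g3p": 1, "adp": 1, "nadp": 1, "pi": 1},
         False, "gapN", "1.2.1.13"),
        ("ENO", {"pg3": -1, "pep": 1}, True, "eno", "4.2.1.11"),
        ("PYK_ATP", {"pep": -1, "adp": -1, "pyr": 1, "atp": 1},
         False, "pykA", "2.7.1.40"),
        ("PYK_GTP", {"pep": -1, "gdp": -1, "pyr": 1, "gtp": 1},
         False, "pykG1 and pykG2", "2.7.1.40"),
        ("PPS", {"pyr": -1, "atp": -1, "h2o": -1, "pep": 1, "amp": 1, "pi": 1},
         False, "ppsA", "2.7.9.2"),
        ("NDK", {"atp": -1, "gdp": -1, "adp": 1, "gtp": 1}, True, "ndk", "2.7.4.6"),
        ("ADK", {"atp": -1, "amp": -1, "adp": 2}, True, "adk", "2.7.4.3"),
        ("PPOX", {"g6p": -1, "nadp": -2, "h2o": -1,
                  "ru5p": 1, "co2": 1, "nadph": 2}, False, "zwf", "1.1.1.49"),
        ("RPI", {"ru5p": -1, "r5p": 1}, True, "rpiA", "5.3.1.6"),
        # pyruvate / TCA (no 2-oxoglutarate dehydrogenase)
        ("PDH", {"pyr": -1, "coa": -1, "nad": -1,
                 "accoa": 1, "co2": 1, "nadh": 1}, False, "pdhA", "1.2.4.1"),
        ("PEPC", {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1},
         False, "ppc", "4.1.1.31"),
        ("CS", {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1},
         False, "gltA", "2.3.3.1"),
        ("IDH", {"cit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1},
         False, "icd", "1.1.1.42"),
        ("SDH", {"succ": -1, "pq": -1, "fum": 1, "pqh2": 1},
         False, "sdhA and sdhB", "1.3.99.1"),
        ("FUM", {"fum": -1, "h2o": -1, "mal": 1}, True, "fumC", "4.2.1.2"),
        ("MDH", {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1}, True, "mdh", "1.1.1.37"),
    ]
    if spec.include_photosystems:
        rxns += [
            ("EX_photon1", {"photon1_ext": -1, "photon1": _P}, False, None, None),
            ("EX_photon2", {"photon2_ext": -1, "photon2": _P}, False, None, None),
            ("PSII", {"photon2": -1, "h2o": -1, "pq": -1,
                      "o2": 0.5, "pqh2": 1, "pmf": 2},
             False, "psbA and psbD", None),
            ("PSI", {"photon1": -1, "pqh2": -1, "nadp": -1,
                     "pq": 1, "nadph": 1, "pmf": 2}, False, "psaA", None),
            ("RBC", {"rubp": -1, "co2": -1, "h2o": -1, "pg3": 2},
             False, "rbcL", "4.1.1.39"),
            ("PRK", {"ru5p": -1, "atp": -1, "rubp": 1, "adp": 1},
             False, "prkB", "2.7.1.19"),
            ("CBB", {"g3p": -5, "ru5p": 3, "pi": 2}, False, "tktA", None),
        ]
    if spec.include_glucose_transport:
        rxns.append(("EX_glc", {"glc_ext": -1, "glc": 1}, False, "glcP", None))
    if spec.include_glyoxylate_shunt:
        rxns += [
            ("ICL", {"cit": -1, "succ": 1, "glx": 1}, False, "aceA", "4.1.3.1"),
            ("MS", {"glx": -1, "accoa": -1, "h2o": -1, "mal": 1, "coa": 1},
             False, "aceB", "2.3.3.9"),
        ]
    if spec.include_hydrogenase:
        rxns += [
            ("HOX", {"nadh": -1, "nad": 1, "h2": 1}, True, "hoxH", "1.12.1.2"),
            ("EX_h2", {"h2": -1, "h2_ext": 1}, False, None, None),
        ]
    return rxns


def generate_toy_phototroph(
    spec: ToySpec | None = None,
) -> tuple[MetabolicModel, dict[str, str]]:
    """Build the toy model; returns (model, GPR rule table).

    Deterministic for a fixed seed.  Raises when the configuration removes both the
    photosystems and the glucose transporter (no energy or carbon source
    could ever reach biomass).
    """

    spec = spec or ToySpec()
    if not spec.include_photosystems and not spec.include_glucose_transport:
        raise ModelError(
            "a toy without photosystems and without glucose transport "
            "cannot grow"
        )
    rng = np.random.default_rng(spec.seed)

    reactions = _core_reactions(spec)
    rxn_ids = {r[0] for r in reactions}

    # biomass drain over the precursor subset with published proportions
    composition: dict[str, float] = {}
    for met_id in spec.biomass_precursor_subset:
        if met_id not in _PRECURSOR_PROXY:
            raise ModelError(f"no biomass proxy defined for {met_id!r}")
        composition[met_id] = _BIOMASS_COMPOSITION[_PRECURSOR_PROXY[met_id]]
    biomass_stoich: dict[str, float] = {m: -c for m, c in composition.items()}
    biomass_stoich.update(
        {
            "atp": -BIOMASS_ATP,
            "h2o": -BIOMASS_ATP,
            "nadph": -BIOMASS_NADPH,
            "adp": BIOMASS_ATP,
            "pi": BIOMASS_ATP,
            "nadp": BIOMASS_NADPH,
        }
    )
    if "accoa" in composition:
        biomass_stoich["coa"] = composition["accoa"]
    reactions.append(("BIOMASS", biomass_stoich, False, None, None))

    # decoy genes gate dead-end reactions hanging off real intermediates
    hosts = sorted(
        m for m, (_, c, cof) in _METABOLITES.items()
        if not cof and c > 0 and m not in ("glc", "hco3")
    )
    metabolites = [
        Metabolite(m, name, external=False, carbon_count=c, cofactor=cof)
        for m, (name, c, cof) in _METABOLITES.items()
    ]
    metabolites += [
        Metabolite(m, name, external=True, carbon_count=c)
        for m, (name, c) in _EXTERNALS.items()
    ]
    used_mets = set(_METABOLITES) | set(_EXTERNALS)
    for i in range(spec.n_decoy_genes):
        host = hosts[int(rng.integers(0, len(hosts)))]
        dead = f"dead{i:02d}"
        metabolites.append(
            Metabolite(
                dead,
                name=f"dead-end metabolite {i}",
                carbon_count=_METABOLITES[host][1],
            )
        )
        used_mets.add(dead)
        reactions.append(
            (f"DEC{i:02d}", {host: -1, dead: 1}, False, f"dg{i:02d}", None)
        )

    built = []
    gpr_table: dict[str, str] = {}
    for rxn_id, stoich, reversible, rule, ec in reactions:
        gpr = parse_gpr(rule) if rule else None
        if rule:
            gpr_table[rxn_id] = rule
        built.append(
            Reaction(
                id=rxn_id,
                stoichiometry=dict(stoich),
                reversible=reversible,
                gpr=gpr,
                ec_number=ec,
            )
        )
    model = MetabolicModel(
        metabolites=[m for m in metabolites if m.id in used_mets or m.external],
        reactions=built,
        objective_reaction_id="BIOMASS",
        biomass_composition=composition,
        design_objective_id="EX_succ",
        name="toy_phototroph",
    )
    return model, gpr_table


def toy_exchange_map() -> ExchangeMap:
    """Growth-condition roles of the toy's uptake reactions."""
    return ExchangeMap(
        glucose_uptake="EX_glc",
        co2_uptake="EX_co2",
        hco3_uptake="EX_hco3",
        photon_uptakes=("EX_photon1", "EX_photon2"),
        maintenance="NGAM",
        glucose_carbons=6,
    )


def dead_end_decoy_genes(model: MetabolicModel) -> frozenset[str]:
    """Genes whose every reaction touches a dead-end internal metabolite.

    Such genes are network annotations with no flux-bearing context — the
    toy's decoy genes by construction.  They emulate genes linked to the
    network whose transcription is independent of the perturbation, so
    the expression generator never plants signal on them.
    """

    appearances: dict[str, int] = {}
    for rxn in model.reactions.values():
        for met in rxn.stoichiometry:
            appearances[met] = appearances.get(met, 0) + 1
    decoys: set[str] = set()
    for gene in model.genes:
        rxns = [
            r for r in model.reactions.values()
            if r.gpr is not None and gene in r.gpr.genes()
        ]
        if rxns and all(
            any(
                appearances[met] == 1 and not model.metabolites[met].external
                for met in r.stoichiometry
            )
            for r in rxns
        ):
            decoys.add(gene)
    return frozenset(decoys)


def generate_expression_dataset(
    model: MetabolicModel,
    planted_metabolites: Iterable[str] = (),
    effect_alpha: float = 0.1,
    n_contrasts: int = 1,
    seed: int = 0,
    contrast_prefix: str = "contrast",
    decoy_genes: Iterable[str] = (),
) -> ExpressionDataset:
    """Seeded per-gene p-values with signal planted around metabolites.

    Genes neighboring a planted metabolite draw p ~ Beta(α, 1); all other
    genes are Uniform(0, 1).  α = 1 yields a pure null dataset.  Genes
    listed in ``decoy_genes`` (e.g. :func:`dead_end_decoy_genes`) are
    never planted — they model gene-reaction links whose transcription
    ignores the perturbation.
    """

    if not 0 < effect_alpha <= 1:
        raise ModelError("effect_alpha must be in (0, 1]")
    planted = list(planted_metabolites)
    hoods = metabolite_gene_neighborhoods(model)
    affected: set[str] = set()
    for met in planted:
        if met not in model.metabolites:
            raise ModelError(f"planted metabolite {met!r} not in model")
        genes = hoods.get(met, frozenset())
        if not genes:
            raise ModelError(f"planted metabolite {met!r} has no gene neighbors")
        affected |= genes
    affected -= set(decoy_genes)
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    data: dict[str, dict[str, float]] = {}
    for c in range(n_contrasts):
        col: dict[str, float] = {}
        for g in genes:
            if g in affected and effect_alpha < 1:
                col[g] = float(rng.beta(effect_alpha, 1.0))
            else:
                col[g] = float(rng.uniform())
        data[f"{contrast_prefix}_{c + 1}"] = col
    return ExpressionDataset(pd.DataFrame(data))
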