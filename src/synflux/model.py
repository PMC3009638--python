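"""Domain types for genome-scale metabolic models.

A model is a set of metabolites, a set of reactions with signed
stoichiometries and flux bounds, optional gene-protein-reaction (GPR)
rules, and one biomass objective reaction whose flux is the specific
growth rate.  External metabolites are boundary species that are not
mass-balanced; internal metabolites each contribute one row to the
stoichiometric matrix S used by the steady-state condition S·v = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "GeneAssociation",
    "Gene",
    "AllOf",
    "AnyOf",
    "MetabolicModel",
    "StoichiometricMatrix",
    "ConnectivityRecord",
    "ModelError",
    "StructuralError",
    "DEFAULT_COFACTORS",
    "parse_gpr",
    "build_stoichiometric_matrix",
    "evaluate_gpr",
    "reactions_disabled_by",
    "metabolite_connectivity",
    "mark_cofactors",
    "write_connectivity_tsv",
]


class ModelError(ValueError):
    """Invalid model content or usage."""


class StructuralError(ModelError):
    """A reaction references an unknown metabolite or gene."""


#: Currency/cofactor species excluded from connectivity rankings and from
#: reporter-metabolite neighborhoods when filtering is on.  Matching is by
#: metabolite id or name, case-insensitive.
DEFAULT_COFACTORS = frozenset(
    {
        "h2o", "water", "atp", "adp", "amp", "phosphate", "pi",
        "diphosphate", "ppi", "h+", "h", "proton", "nad+", "nad", "nadh",
        "nadp+", "nadp", "nadph", "co2", "o2", "oxygen", "nh3", "ammonia",
        "coa", "coenzyme a", "gtp", "gdp",
    }
)


@dataclass
class Metabolite:
    """A chemical species.

    ``external=True`` marks an unbalanced boundary species (no row in S).
    ``carbon_count`` is the number of traced backbone carbon atoms, or
    ``None`` when unknown; cofactor carbon is conventionally not traced.
    """

    id: str
    name: str = ""
    external: bool = False
    carbon_count: int | None = None
    cofactor: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ModelError(f"invalid metabolite id {self.id!r}")
        if self.carbon_count is not None and self.carbon_count < 0:
            raise ModelError(f"negative carbon count for {self.id}")
        if not self.name:
            self.name = self.id


# ---------------------------------------------------------------------------
# GPR boolean trees


class GeneAssociation:
    """Boolean expression over gene ids.

    ``AllOf`` models an enzyme complex: loss of any subunit disables the
    reaction.  ``AnyOf`` models isozymes: any remaining member suffices.
    """

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Gene(GeneAssociation):
    gene: str

    def evaluate(self, deleted):
        return self.gene not in deleted

    def genes(self):
        return frozenset({self.gene})

    def to_text(self):
        return self.gene


@dataclass(frozen=True)
class AllOf(GeneAssociation):
    children: tuple[GeneAssociation, ...]

    def __post_init__(self):
        if not self.children:
            raise ModelError("empty ALL-OF association")

    def evaluate(self, deleted):
        return all(c.evaluate(deleted) for c in self.children)

    def genes(self):
        return frozenset().union(*(c.genes() for c in self.children))

    def to_text(self):
        return "(" + " and ".join(c.to_text() for c in self.children) + ")"


@dataclass(frozen=True)
class AnyOf(GeneAssociation):
    children: tuple[GeneAssociation, ...]

    def __post_init__(self):
        if not self.children:
            raise ModelError("empty ANY-OF association")

    def evaluate(self, deleted):
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self):
        return frozenset().union(*(c.genes() for c in self.children))

    def to_text(self):
        return "(" + " or ".join(c.to_text() for c in self.children) + ")"


def parse_gpr(text: str) -> GeneAssociation:
    """Parse a boolean rule like ``"gA and (gB or gC)"``.

    Grammar: OR has lowest precedence, then AND; parentheses group.
    Keywords ``and``/``or`` are case-insensitive.
    """

    tokens: list[str] = []
    buf = ""
    for ch in text:
        if ch in "()":
            if buf:
                tokens.append(buf)
                buf = ""
            tokens.append(ch)
        elif ch.isspace():
            if buf:
                tokens.append(buf)
                buf = ""
        else:
            buf += ch
    if buf:
        tokens.append(buf)
    if not tokens:
        raise ModelError("empty GPR rule")

    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> GeneAssociation:
        nonlocal pos
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else AnyOf(tuple(parts))

    def parse_and() -> GeneAssociation:
        nonlocal pos
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else AllOf(tuple(parts))

    def parse_atom() -> GeneAssociation:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ModelError(f"truncated GPR rule: {text!r}")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise ModelError(f"unbalanced parentheses in GPR rule: {text!r}")
            pos += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelError(f"unexpected token {tok!r} in GPR rule: {text!r}")
        pos += 1
        return Gene(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise ModelError(f"trailing tokens in GPR rule: {text!r}")
    return expr


# ---------------------------------------------------------------------------
# Reactions and models


@dataclass
class Reaction:
    """One biochemical conversion.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = substrate, positive = product).  Bounds are fluxes in
    mmol·gDW⁻¹·h⁻¹; ``math.inf`` marks a symbolically unbounded side.
    Irreversible reactions must have a non-negative lower bound —
    reversibility is input data, never inferred.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    gpr: GeneAssociation | None = None
    ec_number: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ModelError(f"invalid reaction id {self.id!r}")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id} has empty stoichiometry")
        if self.lower_bound is None:
            self.lower_bound = -math.inf if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = math.inf
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ModelError(
                f"irreversible reaction {self.id} has negative lower bound"
            )

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.stoichiometry)


class MetabolicModel:
    """A genome-scale metabolic model."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_reaction_id: str,
        biomass_composition: Mapping[str, float] | None = None,
        design_objective_id: str | None = None,
        name: str = "model",
    ) -> None:
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {met.id}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelError(f"duplicate reaction id {rxn.id}")
            self.reactions[rxn.id] = rxn
        self.objective_reaction_id = objective_reaction_id
        self.design_objective_id = design_objective_id
        if biomass_composition is None:
            biomass_composition = self._composition_from_objective()
        self.biomass_composition = dict(biomass_composition)
        self.validate()

    def _composition_from_objective(self) -> dict[str, float]:
        rxn = self.reactions.get(self.objective_reaction_id)
        if rxn is None:
            return {}
        return {m: -c for m, c in rxn.stoichiometry.items() if c < 0}

    # -- derived sets -----------------------------------------------------

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr is not None:
                out |= rxn.gpr.genes()
        return frozenset(out)

    def internal_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.external]

    def external_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.external]

    def exchange_reactions(self) -> list[str]:
        """Reactions touching at least one external metabolite."""
        return [
            r.id
            for r in self.reactions.values()
            if any(self.metabolites[m].external for m in r.stoichiometry)
        ]

    # -- integrity --------------------------------------------------------

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise StructuralError(
                        f"reaction {rxn.id} references unknown metabolite "
                        f"{met_id!r}"
                    )
        if self.objective_reaction_id not in self.reactions:
            raise StructuralError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        if (
            self.design_objective_id is not None
            and self.design_objective_id not in self.reactions
        ):
            raise StructuralError(
                f"design objective {self.design_objective_id!r} not in model"
            )

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.name}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>"
        )


@dataclass
class StoichiometricMatrix:
    """Dense S with row/column index maps (internal metabolites × reactions)."""

    matrix: np.ndarray
    metabolite_index: dict[str, int]
    reaction_index: dict[str, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S: one row per internal metabolite, one column per reaction.

    Entry (i, j) is the signed coefficient of metabolite i in reaction j,
    zero if absent.  External metabolites contribute no row.
    """

    internal = model.internal_metabolites()
    met_index = {m: i for i, m in enumerate(internal)}
    rxn_index = {r: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(internal), len(rxn_index)))
    for rxn_id, rxn in model.reactions.items():
        j = rxn_index[rxn_id]
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in model.metabolites:
                raise StructuralError(
                    f"reaction {rxn_id} references unknown metabolite {met_id!r}"
                )
            i = met_index.get(met_id)
            if i is not None:
                S[i, j] = coeff
    return StoichiometricMatrix(S, met_index, rxn_index)


def evaluate_gpr(gpr: GeneAssociation, deleted: Iterable[str]) -> bool:
    """True when the reaction remains enzymatically feasible after deletions."""
    return gpr.evaluate(frozenset(deleted))


def reactions_disabled_by(
    model: MetabolicModel, deleted: Iterable[str]
) -> frozenset[str]:
    """Reaction ids whose GPR evaluates false under the given gene deletions.

    Reactions without a GPR (spontaneous or passive transport) are never
    disabled.
    """

    deleted = frozenset(deleted)
    unknown = deleted - model.genes
    if unknown:
        raise StructuralError(f"unknown gene id(s): {sorted(unknown)}")
    return frozenset(
        rxn.id
        for rxn in model.reactions.values()
        if rxn.gpr is not None and not rxn.gpr.evaluate(deleted)
    )


@dataclass
class ConnectivityRecord:
    metabolite_id: str
    name: str
    neighbor_count: int


def mark_cofactors(
    model: MetabolicModel, cofactors: Iterable[str] = DEFAULT_COFACTORS
) -> None:
    """Flag metabolites whose id or name is in the cofactor list (in place)."""
    lowered = {c.lower() for c in cofactors}
    for met in model.metabolites.values():
        if met.id.lower() in lowered or met.name.lower() in lowered:
            met.cofactor = True


def metabolite_connectivity(
    model: MetabolicModel, filter_cofactors: bool = False
) -> list[ConnectivityRecord]:
    """Rank metabolites by the number of distinct reactions they appear in.

    Sorted descending by neighbor count; ties broken lexicographically by
    metabolite id for reproducibility.
    """

    counts: dict[str, int] = {}
    for rxn in model.reactions.values():
        for met_id in rxn.metabolite_ids():
            counts[met_id] = counts.get(met_id, 0) + 1
    records = [
        ConnectivityRecord(m, model.metabolites[m].name, n)
        for m, n in counts.items()
        if not (filter_cofactors and model.metabolites[m].cofactor)
    ]
    records.sort(key=lambda r: (-r.neighbor_count, r.metabolite_id))
    return records


def write_connectivity_tsv(records: Sequence[ConnectivityRecord], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [(r.metabolite_id, r.name, r.neighbor_count) for r in records],
        columns=["metabolite_id", "name", "neighbor_count"],
    )
    df.to_csv(path, sep="\t", index=False)
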