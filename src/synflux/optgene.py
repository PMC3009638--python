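"""Reader/writer for the OptGene/BioOpt flat-text model dialect.

The document is section-oriented.  Section headers are case-insensitive,
with or without a leading dash:

    -REACTIONS              one equation per line, ``Rid : A + 2 B -> C``
    -CONSTRAINTS            per-reaction bound overrides, ``Rid [lo, hi]``
    -EXTERNAL METABOLITES   one metabolite id per line
    -OBJ                    objective (biomass) reaction id
    -DESIGNOBJ              optional design-objective reaction id

``->`` declares an irreversible reaction (default bounds [0, inf)),
``<->`` a reversible one ((-inf, inf)).  Coefficients default to 1 and use
a decimal point; metabolite tokens may contain dashes and underscores but
no spaces.  Blank lines are ignored; lines starting with '%' or '#' are
comments.  Unbounded constraint sides are written ``inf`` / ``-inf``.

GPR rules are not part of the flat format; they travel in a separate
two-column TSV (reaction_id, boolean rule with and/or/parentheses), see
:func:`read_gpr_table`.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import TextIO

from .model import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    parse_gpr,
)

__all__ = [
    "ParseError",
    "read_model",
    "write_model",
    "load_model",
    "read_gpr_table",
    "write_gpr_table",
    "attach_gprs",
]


class ParseError(ModelError):
    """Malformed OptGene document; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


_SECTION_ALIASES = {
    "reactions": "reactions",
    "constraints": "constraints",
    "external metabolites": "external",
    "externalmetabolites": "external",
    "obj": "objective",
    "objective": "objective",
    "designobj": "designobj",
}


def _canonical_header(line: str) -> str | None:
    text = line.strip().lstrip("-").strip().lower()
    return _SECTION_ALIASES.get(text)


def _parse_number(token: str, lineno: int) -> float:
    t = token.strip().lower()
    if t in ("inf", "+inf", "infinity"):
        return math.inf
    if t == "-inf":
        return -math.inf
    try:
        return float(t)
    except ValueError:
        raise ParseError(f"cannot parse number {token!r}", lineno) from None


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _parse_side(text: str, lineno: int) -> list[tuple[float, str]]:
    terms = []
    text = text.strip()
    if not text:
        return terms
    for chunk in text.split("+"):
        tokens = chunk.split()
        if not tokens:
            raise ParseError("empty term in equation", lineno)
        if len(tokens) == 1:
            terms.append((1.0, tokens[0]))
        elif len(tokens) == 2 and _is_number(tokens[0]):
            terms.append((float(tokens[0]), tokens[1]))
        else:
            raise ParseError(f"cannot parse term {chunk.strip()!r}", lineno)
    return terms


def _parse_equation(text: str, lineno: int) -> tuple[dict[str, float], bool]:
    if "<->" in text:
        lhs, rhs = text.split("<->", 1)
        reversible = True
    elif "->" in text:
        lhs, rhs = text.split("->", 1)
        reversible = False
    else:
        raise ParseError("equation has no '->' or '<->' arrow", lineno)
    stoich: dict[str, float] = {}
    for coeff, met in _parse_side(lhs, lineno):
        stoich[met] = stoich.get(met, 0.0) - coeff
    for coeff, met in _parse_side(rhs, lineno):
        stoich[met] = stoich.get(met, 0.0) + coeff
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ParseError("equation has no net stoichiometry", lineno)
    return stoich, reversible


def read_model(source: str | Path | TextIO, name: str = "model") -> MetabolicModel:
    """Parse an OptGene document from a path, string, or text stream."""

    if isinstance(source, Path):
        stream: TextIO = source.open()
    elif isinstance(source, str):
        if "\n" not in source and Path(source).exists():
            stream = open(source)
        else:
            stream = io.StringIO(source)
    else:
        stream = source

    section: str | None = None
    reactions: list[Reaction] = []
    seen: dict[str, int] = {}
    constraints: list[tuple[str, float, float, int]] = []
    external: list[str] = []
    objective: str | None = None
    designobj: str | None = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("%") or line.startswith("#"):
            continue
        header = _canonical_header(line)
        if header is not None:
            section = header
            continue
        if section is None:
            raise ParseError(f"content before any section header: {line!r}", lineno)
        if section == "reactions":
            if ":" not in line:
                raise ParseError("reaction line lacks 'id :' prefix", lineno)
            rxn_id, equation = line.split(":", 1)
            rxn_id = rxn_id.strip()
            if not rxn_id or " " in rxn_id:
                raise ParseError(f"invalid reaction id {rxn_id!r}", lineno)
            if rxn_id in seen:
                raise ParseError(
                    f"duplicate reaction id {rxn_id!r} (first at line "
                    f"{seen[rxn_id]})",
                    lineno,
                )
            seen[rxn_id] = lineno
            stoich, reversible = _parse_equation(equation, lineno)
            reactions.append(
                Reaction(id=rxn_id, stoichiometry=stoich, reversible=reversible)
            )
        elif section == "constraints":
            if "[" not in line or "]" not in line:
                raise ParseError("constraint line lacks '[lo, hi]'", lineno)
            rxn_id, rest = line.split("[", 1)
            rxn_id = rxn_id.strip()
            bounds_text = rest.split("]", 1)[0]
            parts = bounds_text.split(",")
            if len(parts) != 2:
                raise ParseError("constraint needs exactly two bounds", lineno)
            lo = _parse_number(parts[0], lineno)
            hi = _parse_number(parts[1], lineno)
            constraints.append((rxn_id, lo, hi, lineno))
        elif section == "external":
            if " " in line:
                raise ParseError(f"invalid external metabolite {line!r}", lineno)
            external.append(line)
        elif section == "objective":
            objective = line.split()[0]
        elif section == "designobj":
            designobj = line.split()[0]

    by_id = {r.id: r for r in reactions}
    for rxn_id, lo, hi, lineno in constraints:
        if rxn_id not in by_id:
            raise ParseError(f"constraint for unknown reaction {rxn_id!r}", lineno)
        rxn = by_id[rxn_id]
        if lo > hi:
            raise ParseError(f"constraint for {rxn_id}: lo > hi", lineno)
        rxn.lower_bound = lo
        rxn.upper_bound = hi
        if lo < 0:
            rxn.reversible = True
    if objective is None:
        raise ParseError("document has no -OBJ section", 0)
    if objective not in by_id:
        raise ParseError(f"objective references unknown reaction {objective!r}", 0)
    if designobj is not None and designobj not in by_id:
        raise ParseError(
            f"design objective references unknown reaction {designobj!r}", 0
        )

    external_set = set(external)
    met_ids: list[str] = []
    seen_mets: set[str] = set()
    for rxn in reactions:
        for m in rxn.stoichiometry:
            if m not in seen_mets:
                seen_mets.add(m)
                met_ids.append(m)
    for m in external:
        if m not in seen_mets:
            seen_mets.add(m)
            met_ids.append(m)
    metabolites = [Metabolite(id=m, external=m in external_set) for m in met_ids]
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=objective,
        design_objective_id=designobj,
        name=name,
    )


def _format_number(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def _format_side(terms: list[tuple[str, float]]) -> str:
    parts = []
    for met, coeff in terms:
        if coeff == 1.0:
            parts.append(met)
        else:
            parts.append(f"{_format_number(coeff)} {met}")
    return " + ".join(parts)


def write_model(model: MetabolicModel, stream: TextIO | None = None) -> str:
    """Serialize a model to the OptGene dialect.

    Output is deterministic: reactions in model order, metabolite terms in
    reaction-declaration order, so two writes of the same model are
    byte-identical and ``read_model(write_model(m))`` is structurally
    equal to ``m``.
    """

    out = io.StringIO()
    out.write("-REACTIONS\n")
    for rxn in model.reactions.values():
        subs = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
        prods = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
        arrow = "<->" if rxn.reversible else "->"
        out.write(
            f"{rxn.id} : {_format_side(subs)} {arrow} {_format_side(prods)}\n"
        )
    out.write("\n-CONSTRAINTS\n")
    for rxn in model.reactions.values():
        default_lo = -math.inf if rxn.reversible else 0.0
        if rxn.lower_bound != default_lo or rxn.upper_bound != math.inf:
            out.write(
                f"{rxn.id} [{_format_number(rxn.lower_bound)}, "
                f"{_format_number(rxn.upper_bound)}]\n"
            )
    out.write("\n-EXTERNAL METABOLITES\n")
    for met_id in sorted(m.id for m in model.metabolites.values() if m.external):
        out.write(met_id + "\n")
    out.write("\n-OBJ\n")
    out.write(f"{model.objective_reaction_id} 1 1\n")
    if model.design_objective_id is not None:
        out.write("\n-DESIGNOBJ\n")
        out.write(f"{model.design_objective_id} 1 1\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# GPR tables


def read_gpr_table(source: str | Path | TextIO) -> dict[str, str]:
    """Read a two-column TSV mapping reaction id to a boolean gene rule."""
    if isinstance(source, (str, Path)):
        stream: TextIO = open(source)
    else:
        stream = source
    table: dict[str, str] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError("GPR line needs reaction_id<TAB>rule", lineno)
        rxn_id, rule = parts[0].strip(), parts[1].strip()
        if rxn_id.lower() == "reaction_id":  # header row
            continue
        if rxn_id in table:
            raise ParseError(f"duplicate GPR for reaction {rxn_id!r}", lineno)
        table[rxn_id] = rule
    return table


def write_gpr_table(model: MetabolicModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\trule\n")
        for rxn in model.reactions.values():
            if rxn.gpr is not None:
                fh.write(f"{rxn.id}\t{rxn.gpr.to_text()}\n")


def attach_gprs(model: MetabolicModel, table: dict[str, str]) -> None:
    """Attach parsed GPR rules to the model's reactions (in place)."""
    for rxn_id, rule in table.items():
        if rxn_id not in model.reactions:
            raise ModelError(f"GPR table references unknown reaction {rxn_id!r}")
        model.reactions[rxn_id].gpr = parse_gpr(rule)


def load_model(
    model_path: str | Path,
    gpr_path: str | Path | None = None,
    name: str = "model",
) -> MetabolicModel:
    """Read an OptGene model file and, optionally, its companion GPR TSV."""
    model = read_model(Path(model_path), name=name)
    if gpr_path is not None:
        attach_gprs(model, read_gpr_table(gpr_path))
    return model
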