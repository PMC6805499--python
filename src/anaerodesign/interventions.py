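"""Heterologous intervention library and the design-evaluation grid.

An :class:`InterventionSet` is a named bundle of reactions (with any species
the host may be missing) representing one published or proposed strain
design: fermentative ATP generation via acetate kinase, nitrate/nitrite
respiration, an electrode electron sink, and the anaerobic alternatives to
the O2-dependent biosynthesis steps (class I dihydroorotate dehydrogenase,
class III ribonucleotide-triphosphate reductase, fumarate-coupled
L-aspartate oxidase, quinone-dependent protoporphyrinogen oxidase).

:func:`evaluate_designs` expands a host model with combinations of sets,
applies each growth condition and classifies the FBA outcome into
no-growth / poor-growth / growth relative to the wild-type oxic rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model_core import (
    GROWTH_EPSILON,
    ConfigurationError,
    MediumSpec,
    Metabolite,
    MetabolicModel,
    ReactionDef,
    ValidationError,
    add_reactions,
    apply_medium,
    reaction_balance,
)
from .fba_engine import FBAResult, fba

log = logging.getLogger("anaerodesign")

#: growth is classified "poor" below this fraction of the wild-type oxic rate
POOR_GROWTH_FRACTION = 0.10

#: the consolidated fermentative design: anaerobic orotate + dNTP synthesis
#: plus substrate-level ATP generation
CONSOLIDATED_DESIGN = ("DHODH_I", "RNR_III", "ACK")


@dataclass
class InterventionSet:
    name: str
    reactions: Tuple[ReactionDef, ...]
    provenance: str

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"design {self.name!r}: duplicate reaction ids")


@dataclass
class GridCell:
    status: str
    mu: float
    growth_class: str  # none | poor | growth


@dataclass
class DesignGrid:
    rows: List[str]
    columns: List[str]
    cells: Dict[Tuple[str, str], GridCell]
    mu_ref: float
    epsilon: float
    poor_fraction: float

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            for col in self.columns:
                cell = self.cells[(row, col)]
                records.append(
                    {
                        "design": row,
                        "condition": col,
                        "status": cell.status,
                        "mu": cell.mu,
                        "growth_class": cell.growth_class,
                    }
                )
        return pd.DataFrame(records, columns=["design", "condition", "status", "mu", "growth_class"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# -- library loading ---------------------------------------------------------


def _parse_library(payload: dict, origin: str) -> Dict[str, InterventionSet]:
    met_table = {
        mid: Metabolite(
            id=mid,
            name=spec.get("name", mid),
            compartment=spec.get("compartment", "c"),
            formula=spec.get("formula"),
        )
        for mid, spec in payload.get("metabolites", {}).items()
    }
    library: Dict[str, InterventionSet] = {}
    for entry in payload["designs"]:
        defs = []
        for r in entry["reactions"]:
            declared = tuple(met_table[m] for m in r["stoich"] if m in met_table)
            defs.append(
                ReactionDef(
                    id=r["id"],
                    name=r.get("name", r["id"]),
                    stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                    lower_bound=float(r["lb"]),
                    upper_bound=float(r["ub"]),
                    provenance=entry.get("provenance", ""),
                    metabolites=declared,
                )
            )
        provenance = entry.get("provenance", "")
        if not provenance:
            raise ValidationError(f"{origin}: design {entry['name']!r} has empty provenance")
        library[entry["name"]] = InterventionSet(
            name=entry["name"], reactions=tuple(defs), provenance=provenance
        )
    return library


def load_design_library(path) -> Dict[str, InterventionSet]:
    """Load a design library from a JSON file in the shipped schema."""
    payload = json.loads(Path(path).read_text())
    return _parse_library(payload, str(path))


def builtin_designs() -> Dict[str, InterventionSet]:
    """The shipped library of nine named designs, each with provenance."""
    payload = json.loads(resources.files("anaerodesign.data").joinpath("designs.json").read_text())
    return _parse_library(payload, "builtin designs")


def builtin_design_formulas() -> Dict[str, str]:
    """Metabolite id -> formula table backing the shipped library."""
    payload = json.loads(resources.files("anaerodesign.data").joinpath("designs.json").read_text())
    return {mid: spec["formula"] for mid, spec in payload["metabolites"].items()}


def design_library_to_json(library: Mapping[str, InterventionSet], path) -> None:
    """Serialize a library back to the shipped JSON schema (so generated
    toy libraries are loadable through the same reader)."""
    metabolites: Dict[str, dict] = {}
    designs = []
    for iset in library.values():
        reactions = []
        for rdef in iset.reactions:
            for met in rdef.metabolites:
                metabolites[met.id] = {
                    "name": met.name,
                    "compartment": met.compartment,
                    "formula": met.formula,
                }
            reactions.append(
                {
                    "id": rdef.id,
                    "name": rdef.name,
                    "stoich": dict(rdef.stoichiometry),
                    "lb": rdef.lower_bound,
                    "ub": rdef.upper_bound,
                }
            )
        designs.append({"name": iset.name, "provenance": iset.provenance, "reactions": reactions})
    Path(path).write_text(
        json.dumps({"metabolites": metabolites, "designs": designs}, indent=1) + "\n"
    )


def check_design_balance(
    iset: InterventionSet,
    formulas: Mapping[str, str],
    elements: Sequence[str] = ("C", "N", "O", "P", "S"),
) -> List[str]:
    """Return human-readable imbalance messages (empty list = all balanced)."""
    problems = []
    for rdef in iset.reactions:
        net = reaction_balance(formulas, rdef.to_reaction(), elements)
        if net:
            problems.append(f"{iset.name}/{rdef.id}: net {net}")
    return problems


# -- model expansion and the evaluation grid ---------------------------------


def apply_design(model: MetabolicModel, iset: InterventionSet) -> MetabolicModel:
    """Expand the host with one design set, declaring missing species."""
    return add_reactions(model, iset.reactions)


def _expand(model: MetabolicModel, combo: Sequence[str], library: Mapping[str, InterventionSet]) -> MetabolicModel:
    expanded = model
    seen_rids = set(model.reactions)
    for name in combo:
        iset = library[name]
        # sets may share coupling reactions (e.g. ACK inside NIKEL): add once
        fresh = [r for r in iset.reactions if r.id not in seen_rids]
        expanded = add_reactions(expanded, fresh)
        seen_rids.update(r.id for r in fresh)
    return expanded


def classify_growth(mu: float, mu_ref: float, epsilon: float, poor_fraction: float) -> str:
    """Half-open classification: none = [0, eps), poor = [eps, f*mu_ref),
    growth = [f*mu_ref, inf)."""
    if mu < epsilon:
        return "none"
    if mu < poor_fraction * mu_ref:
        return "poor"
    return "growth"


def evaluate_designs(
    model: MetabolicModel,
    combos: Sequence[Sequence[str]],
    conditions: Sequence[MediumSpec],
    library: Optional[Mapping[str, InterventionSet]] = None,
    reference_medium: Optional[MediumSpec] = None,
    epsilon: float = GROWTH_EPSILON,
    poor_fraction: float = POOR_GROWTH_FRACTION,
) -> DesignGrid:
    """Growth class per (design combo x condition).

    ``reference_medium`` (default: the first condition) provides the
    wild-type reference rate mu_ref used for the poor/growth boundary.
    Unknown design names raise before any LP is solved.
    """
    library = library if library is not None else builtin_designs()
    for combo in combos:
        for name in combo:
            if name not in library:
                raise ConfigurationError(f"unknown design name {name!r}")
    if not conditions:
        raise ConfigurationError("evaluate_designs needs at least one condition")
    ref_medium = reference_medium if reference_medium is not None else conditions[0]
    mu_ref = fba(apply_medium(model, ref_medium)).mu

    rows, cells = [], {}
    columns = [c.name for c in conditions]
    for combo in combos:
        label = " + ".join(combo) if combo else "wild-type"
        rows.append(label)
        expanded = _expand(model, combo, library)
        for condition in conditions:
            result: FBAResult = fba(apply_medium(expanded, condition))
            cells[(label, condition.name)] = GridCell(
                status=result.status,
                mu=result.mu,
                growth_class=classify_growth(result.mu, mu_ref, epsilon, poor_fraction),
            )
    return DesignGrid(
        rows=rows,
        columns=columns,
        cells=cells,
        mu_ref=mu_ref,
        epsilon=epsilon,
        poor_fraction=poor_fraction,
    )
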