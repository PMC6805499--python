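"""Stoichiometric model containers, readers/writers and editing primitives.

The containers follow the conventions of genome-scale metabolic (GSM)
modelling: a :class:`MetabolicModel` is a set of metabolites and bounded
reactions with a designated biomass objective, media are encoded purely as
uptake bounds on exchange reactions, and molecular oxygen is tracked as an
explicit set of metabolite ids so downstream essentiality scans can locate
every O2-involving reaction.

Sign convention: for an exchange reaction written as ``A ->`` (coefficient
-1 on its single metabolite), negative flux is uptake and positive flux is
secretion.  All uptake limits are therefore applied as ``lower_bound =
-limit`` while the secretion direction is left untouched.

Two dialects are supported on disk: SBML Level 3 with the FBC package
(Level 2 with COBRA-style notes/kinetic-law bounds is read-only) and a
small JSON dialect documented in :func:`write_model_json`.
"""

from __future__ import annotations

import copy
import json
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

log = logging.getLogger("anaerodesign")

# -- shared constants -------------------------------------------------------

#: growth threshold in 1/h below which an FBA optimum counts as "no growth"
GROWTH_EPSILON = 1e-6
#: "unlimited" uptake rate in mmol/(gdw h) used for open exchanges
UNLIMITED_UPTAKE = 1000.0
#: experimentally measured maximal glucose uptake rate, mmol/(gdw h)
GLUCOSE_UPTAKE_LIMIT = 6.14
#: maximal O2 uptake rate under oxic conditions, mmol/(gdw h)
O2_UPTAKE_LIMIT = 18.5

EXTRACELLULAR_TOKENS = {"e", "e0", "ext", "extracellular", "external", "c_e", "out"}

#: metabolite-id patterns treated as molecular oxygen when no formula is given
O2_ID_PATTERNS = (r"^o2$", r"^o2_[a-z0-9]+$", r"^m_o2(_[a-z0-9]+)?$", r"^oxygen(_[a-z0-9]+)?$")


class ModelError(Exception):
    """Base class for model-layer failures."""


class FormatError(ModelError):
    """A file does not parse under the requested dialect."""


class ValidationError(ModelError):
    """A structurally invalid model (dangling references, bad bounds...)."""


class ConfigurationError(ModelError):
    """Missing objective, missing O2 configuration, unknown preset..."""


class UnknownReactionError(ModelError, KeyError):
    """A reaction id that does not exist in the model."""


# -- domain types -----------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A bounded reaction; ``stoichiometry`` maps metabolite id -> signed
    coefficient (negative = consumed).  Bounds are in mmol/(gdw h)."""

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = UNLIMITED_UPTAKE
    gene_association: Optional[str] = None
    is_exchange: bool = False
    is_transport: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: stoichiometry must be non-empty")


@dataclass
class ReactionDef:
    """A reaction to be grafted onto a host model, with provenance.

    ``metabolites`` optionally declares species the host may lack; they are
    created on addition if (and only if) missing.
    """

    id: str
    name: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    provenance: str = ""
    gene_association: Optional[str] = None
    metabolites: Sequence[Metabolite] = ()

    def to_reaction(self) -> Reaction:
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gene_association=self.gene_association,
        )


@dataclass
class MediumSpec:
    """A named medium: exchange-reaction id -> maximal uptake rate.

    ``default_uptake`` applies to every exchange not listed: ``0.0`` closes
    it for uptake, a positive value opens it, and ``None`` leaves it
    untouched (overlay semantics, used for the oxic/anoxic O2 overlays).
    """

    name: str
    uptake_limits: Dict[str, float] = field(default_factory=dict)
    default_uptake: Optional[float] = 0.0

    def __post_init__(self) -> None:
        for rid, rate in self.uptake_limits.items():
            if rate < 0:
                raise ValidationError(f"medium {self.name!r}: uptake limit for {rid} is negative")
        if self.default_uptake is not None and self.default_uptake < 0:
            raise ValidationError(f"medium {self.name!r}: default_uptake is negative")


@dataclass
class MetabolicModel:
    id: str
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objective_id: str = ""
    o2_metabolite_ids: set = field(default_factory=set)

    # -- access helpers ----------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[rid]
        except KeyError:
            raise UnknownReactionError(f"model {self.id!r} has no reaction {rid!r}") from None

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[mid]

    @property
    def exchange_reactions(self) -> list:
        return [r for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- validation --------------------------------------------------------
    def validate(self) -> "MetabolicModel":
        if self.objective_id not in self.reactions:
            raise ConfigurationError(
                f"model {self.id!r}: objective reaction {self.objective_id!r} does not exist"
            )
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
        missing_o2 = self.o2_metabolite_ids - set(self.metabolites)
        if missing_o2:
            raise ValidationError(f"o2_metabolite_ids not in model: {sorted(missing_o2)}")
        return self


# -- structural annotation ---------------------------------------------------


def _is_extracellular(compartment: str) -> bool:
    return compartment.lower() in EXTRACELLULAR_TOKENS


def _base_metabolite_id(mid: str) -> str:
    return re.sub(r"_[A-Za-z0-9]{1,4}$", "", mid)


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse an elemental composition string like ``C6H12O6`` into counts."""
    counts: Dict[str, float] = defaultdict(float)
    for element, num in re.findall(r"([A-Z][a-z]?)(\d*\.?\d*)", formula or ""):
        counts[element] += float(num) if num else 1.0
    return dict(counts)


def looks_like_o2(met: Metabolite) -> bool:
    if met.formula and met.formula.strip().upper() in {"O2"}:
        return True
    mid = met.id.lower()
    return any(re.match(p, mid) for p in O2_ID_PATTERNS) or met.name.strip().lower() in {
        "o2",
        "oxygen",
        "molecular oxygen",
    }


def annotate_structure(model: MetabolicModel) -> MetabolicModel:
    """Auto-flag exchange/transport reactions and detect O2 metabolites.

    Exchange: a reaction touching exactly one metabolite that lives in an
    extracellular compartment (or, if the model has no extracellular
    compartment at all, any single-metabolite boundary reaction).
    Transport: a reaction moving the same base species between two
    compartments without net chemistry on anything else.
    """
    has_extracellular = any(_is_extracellular(m.compartment) for m in model.metabolites.values())
    for rxn in model.reactions.values():
        mets = [model.metabolites[m] for m in rxn.stoichiometry]
        if len(mets) == 1:
            rxn.is_exchange = _is_extracellular(mets[0].compartment) or not has_extracellular
        else:
            bases = defaultdict(set)
            for m in mets:
                bases[_base_metabolite_id(m.id)].add(m.compartment)
            rxn.is_transport = any(len(comps) > 1 for comps in bases.values())
    if not model.o2_metabolite_ids:
        model.o2_metabolite_ids = {m.id for m in model.metabolites.values() if looks_like_o2(m)}
    return model


# -- editing primitives ------------------------------------------------------


def apply_medium(model: MetabolicModel, medium: MediumSpec, strict: bool = False) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set from ``medium``.

    Only the uptake direction is touched; secretion bounds are preserved.
    Unknown exchange ids in the medium are skipped with a warning (lenient
    default, since compound naming differs between reconstructions) or raise
    in strict mode.
    """
    edited = model.copy()
    exchange_ids = {r.id for r in edited.exchange_reactions}
    for rid in medium.uptake_limits:
        if rid not in exchange_ids:
            msg = f"medium {medium.name!r} names absent exchange {rid!r}"
            if strict:
                raise ConfigurationError(msg)
            log.warning("%s -- skipped", msg)
    for rxn in edited.reactions.values():
        if not rxn.is_exchange:
            continue
        if rxn.id in medium.uptake_limits:
            limit: Optional[float] = medium.uptake_limits[rxn.id]
        else:
            limit = medium.default_uptake
        if limit is None:
            continue
        coeff = next(iter(rxn.stoichiometry.values()))
        if coeff < 0:  # written as "A ->": uptake is negative flux
            rxn.lower_bound = -limit
            rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)
        else:  # written as "-> A": uptake is positive flux
            rxn.upper_bound = limit
            rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
        log.debug("medium %s: %s uptake bound set to %s", medium.name, rxn.id, limit)
    return edited


def delete_reaction(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Knock a reaction out by zeroing both bounds (kept in the index so scan
    reports stay aligned with the original reaction order)."""
    edited = model.copy()
    rxn = edited.reaction(reaction_id)
    rxn.lower_bound = 0.0
    rxn.upper_bound = 0.0
    log.debug("deleted reaction %s (bounds zeroed)", reaction_id)
    return edited


def add_reactions(model: MetabolicModel, defs: Sequence[ReactionDef]) -> MetabolicModel:
    """Return an expanded copy of the model; every addition is logged with
    its provenance.  New metabolites must be declared on the ReactionDef."""
    edited = model.copy()
    for rdef in defs:
        if rdef.id in edited.reactions:
            raise ValidationError(f"reaction id collision on add: {rdef.id!r}")
        declared = {m.id: m for m in rdef.metabolites}
        for mid in rdef.stoichiometry:
            if mid not in edited.metabolites:
                if mid in declared:
                    edited.metabolites[mid] = copy.deepcopy(declared[mid])
                    log.debug("declared new metabolite %s for %s", mid, rdef.id)
                else:
                    raise ValidationError(
                        f"reaction {rdef.id!r} references undeclared metabolite {mid!r}"
                    )
        edited.reactions[rdef.id] = rdef.to_reaction()
        log.info("added reaction %s (%s) [%s]", rdef.id, rdef.name, rdef.provenance or "no provenance")
    annotate_structure(edited)
    return edited


# -- media presets -----------------------------------------------------------

# name/id/formula patterns for the compounds whose uptake the minimal glucose
# medium opens; identifiers differ between reconstructions, so resolution is
# lenient and user-overridable.
_COMPOUND_PATTERNS: Dict[str, Dict[str, Sequence[str]]] = {
    "glucose": {"name": (r"glucose",), "id": (r"^glc(__d)?(_[a-z0-9]+)?$",), "formula": ("C6H12O6",)},
    "copper": {"name": (r"copper", r"\bcu\b"), "id": (r"^cu2?(_[a-z0-9]+)?$",), "formula": ("Cu",)},
    "cobalt": {"name": (r"cobalt",), "id": (r"^cobalt2?(_[a-z0-9]+)?$", r"^co2(_[a-z0-9]+)?$"), "formula": ("Co",)},
    "iron": {"name": (r"\biron\b", r"fe2\+", r"fe3\+"), "id": (r"^fe[23]?(_[a-z0-9]+)?$",), "formula": ("Fe",)},
    "proton": {"name": (r"proton", r"^h\+$"), "id": (r"^h(_[a-z0-9]+)?$",), "formula": ("H",)},
    "water": {"name": (r"water",), "id": (r"^h2o(_[a-z0-9]+)?$",), "formula": ("H2O",)},
    "sodium": {"name": (r"sodium",), "id": (r"^na1?(_[a-z0-9]+)?$",), "formula": ("Na",)},
    "nickel": {"name": (r"nickel",), "id": (r"^ni2?(_[a-z0-9]+)?$",), "formula": ("Ni",)},
    "ammonia": {"name": (r"ammoni", r"nh4", r"nh3"), "id": (r"^nh[34](_[a-z0-9]+)?$",), "formula": ("NH4", "NH3", "H4N", "H3N")},
    "phosphate": {"name": (r"phosphate",), "id": (r"^pi(_[a-z0-9]+)?$",), "formula": ("HPO4", "HO4P", "P")},
    "sulphate": {"name": (r"sulphate", r"sulfate"), "id": (r"^so4(_[a-z0-9]+)?$",), "formula": ("SO4", "O4S")},
    "nitrate": {"name": (r"nitrate",), "id": (r"^no3(_[a-z0-9]+)?$",), "formula": ("NO3",)},
}

#: the compounds opened (at 1000) by the minimal glucose medium besides glucose
MINIMAL_MEDIUM_COMPOUNDS = tuple(c for c in _COMPOUND_PATTERNS if c != "glucose")

PRESET_NAMES = ("minimal_glucose", "rich", "oxic", "anoxic")


def _exchange_metabolite(model: MetabolicModel, rxn: Reaction) -> Metabolite:
    return model.metabolites[next(iter(rxn.stoichiometry))]


def _matches_compound(met: Metabolite, compound: str) -> bool:
    pats = _COMPOUND_PATTERNS[compound]
    if met.formula and met.formula.strip() in pats.get("formula", ()):
        return True
    name = (met.name or "").lower()
    if any(re.search(p, name) for p in pats["name"]):
        return True
    mid = met.id.lower()
    return any(re.match(p, mid) for p in pats["id"])


def o2_exchange_ids(model: MetabolicModel) -> list:
    ids = [
        r.id
        for r in model.exchange_reactions
        if next(iter(r.stoichiometry)) in model.o2_metabolite_ids
    ]
    return sorted(ids)


def preset_medium(
    name: str,
    model: MetabolicModel,
    overrides: Optional[Mapping[str, float]] = None,
) -> MediumSpec:
    """Resolve one of the shipped medium presets against a concrete model.

    * ``minimal_glucose`` — glucose uptake <= 6.14; copper, cobalt, iron,
      protons, water, sodium, nickel, ammonia, phosphate, sulphate and
      nitrate uptake <= 1000; every other exchange closed for uptake.
    * ``rich`` — every exchange except O2 open for uptake at <= 1000.
    * ``oxic`` / ``anoxic`` — overlays touching only the O2 exchange(s):
      uptake <= 18.5 and = 0 respectively.

    ``overrides`` (exchange id -> limit) wins over pattern resolution.
    """
    if name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown medium preset {name!r}; choose from {PRESET_NAMES}")
    o2_ex = set(o2_exchange_ids(model))
    limits: Dict[str, float] = {}
    default: Optional[float] = 0.0
    if name == "minimal_glucose":
        for rxn in model.exchange_reactions:
            if rxn.id in o2_ex:
                continue
            met = _exchange_metabolite(model, rxn)
            if _matches_compound(met, "glucose"):
                limits[rxn.id] = GLUCOSE_UPTAKE_LIMIT
            elif any(_matches_compound(met, c) for c in MINIMAL_MEDIUM_COMPOUNDS):
                limits[rxn.id] = UNLIMITED_UPTAKE
    elif name == "rich":
        for rxn in model.exchange_reactions:
            if rxn.id not in o2_ex:
                limits[rxn.id] = UNLIMITED_UPTAKE
    elif name == "oxic":
        if not o2_ex:
            raise ConfigurationError("oxic preset: model has no O2 exchange reaction")
        limits = {rid: O2_UPTAKE_LIMIT for rid in o2_ex}
        default = None
    elif name == "anoxic":
        if not o2_ex:
            raise ConfigurationError("anoxic preset: model has no O2 exchange reaction")
        limits = {rid: 0.0 for rid in o2_ex}
        default = None
    if overrides:
        limits.update(overrides)
    return MediumSpec(name=name, uptake_limits=limits, default_uptake=default)


# -- JSON dialect ------------------------------------------------------------
# {id, metabolites:[{id,name,compartment,formula}],
#  reactions:[{id,name,stoich:{met:coef},lb,ub,gene_association}],
#  objective, o2_metabolites}


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment, "formula": m.formula}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gene_association": r.gene_association,
            }
            for r in model.reactions.values()
        ],
        "objective": model.objective_id,
        "o2_metabolites": sorted(model.o2_metabolite_ids),
    }


def model_from_dict(payload: dict) -> MetabolicModel:
    try:
        model = MetabolicModel(id=payload["id"], objective_id=payload["objective"])
        for m in payload["metabolites"]:
            model.metabolites[m["id"]] = Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
            )
        for r in payload["reactions"]:
            model.reactions[r["id"]] = Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=float(r["lb"]),
                upper_bound=float(r["ub"]),
                gene_association=r.get("gene_association"),
            )
        model.o2_metabolite_ids = set(payload.get("o2_metabolites", []))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"JSON model dialect violation: {exc!r}") from exc
    annotate_structure(model)
    return model.validate()


def write_model_json(model: MetabolicModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def load_model_json(path) -> MetabolicModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return model_from_dict(payload)


# -- SBML dialect (Level 3 + FBC v2; legacy Level 2 read-only) ---------------


def _sbml_sid(prefix: str, raw: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not re.match(r"^[A-Za-z_]", sid):
        sid = "_" + sid
    return prefix + sid


def _strip_sbml_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def write_model_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_sid("", model.id or "model"))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(_sbml_sid("", comp))
        c.setConstant(True)

    for met in model.metabolites.values():
        s = sbml_model.createSpecies()
        s.setId(_sbml_sid("M_", met.id))
        s.setName(met.name or met.id)
        s.setCompartment(_sbml_sid("", met.compartment))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        if met.formula:
            s.getPlugin("fbc").setChemicalFormula(met.formula)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        r = sbml_model.createReaction()
        r.setId(_sbml_sid("R_", rxn.id))
        r.setName(rxn.name or rxn.id)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        for mid, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(_sbml_sid("M_", mid))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gene_association:
            r.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'><p>GENE_ASSOCIATION: {rxn.gene_association}</p></body>")

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(_sbml_sid("R_", model.objective_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _notes_field(notes_text: str, key: str) -> Optional[str]:
    match = re.search(rf"{key}\s*:\s*([^<\n]+)", notes_text or "")
    return match.group(1).strip() if match else None


def load_model_sbml(path, objective_override: Optional[str] = None) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: SBML document contains no <model> element")

    model = MetabolicModel(id=sbml_model.getId() or Path(str(path)).stem)
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        if s.getBoundaryCondition():
            continue
        formula = None
        splug = s.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        mid = _strip_sbml_prefix(s.getId(), "M_")
        model.metabolites[mid] = Metabolite(
            id=mid, name=s.getName() or mid, compartment=s.getCompartment() or "c", formula=formula
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    objective_id = None
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = _strip_sbml_prefix(active.getFluxObjective(0).getReaction(), "R_")

    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rid = _strip_sbml_prefix(r.getId(), "R_")
        stoich: Dict[str, float] = defaultdict(float)
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            mid = _strip_sbml_prefix(ref.getSpecies(), "M_")
            if mid in model.metabolites:
                stoich[mid] -= ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            mid = _strip_sbml_prefix(ref.getSpecies(), "M_")
            if mid in model.metabolites:
                stoich[mid] += ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}
        if not stoich:
            continue

        lb, ub = None, None
        rplug = r.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = params.get(rplug.getLowerFluxBound())
            ub = params.get(rplug.getUpperFluxBound())
        gene_assoc = None
        notes = r.getNotesString() if r.isSetNotes() else ""
        if lb is None:
            # legacy Level 2: bounds in kinetic-law parameters or COBRA notes
            kl = r.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    p = kl.getParameter(j)
                    if p.getId() == "LOWER_BOUND":
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND":
                        ub = p.getValue()
                    elif p.getId() == "OBJECTIVE_COEFFICIENT" and p.getValue() == 1 and objective_id is None:
                        objective_id = rid
            if lb is None:
                lb_txt = _notes_field(notes, "LOWER_BOUND")
                ub_txt = _notes_field(notes, "UPPER_BOUND")
                lb = float(lb_txt) if lb_txt is not None else None
                ub = float(ub_txt) if ub_txt is not None else None
        if lb is None:
            lb = -UNLIMITED_UPTAKE if r.getReversible() else 0.0
        if ub is None:
            ub = UNLIMITED_UPTAKE
        gene_assoc = _notes_field(notes, "GENE_ASSOCIATION")
        model.reactions[rid] = Reaction(
            id=rid,
            name=r.getName() or rid,
            stoichiometry=dict(stoich),
            lower_bound=float(lb),
            upper_bound=float(ub),
            gene_association=gene_assoc,
        )

    if objective_override:
        objective_id = objective_override
    if objective_id is None:
        # last resort: a reaction whose id/name says biomass
        candidates = [rid for rid in model.reactions if "biomass" in rid.lower()]
        if candidates:
            objective_id = candidates[0]
    if objective_id is None:
        raise ConfigurationError(
            f"{path}: no FBC objective and no biomass-named reaction; pass objective_override"
        )
    model.objective_id = objective_id
    annotate_structure(model)
    return model.validate()


# -- dispatching loader/writer ----------------------------------------------


def _infer_format(path) -> str:
    suffix = Path(str(path)).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in {".xml", ".sbml"}:
        return "sbml_fbc"
    raise ConfigurationError(f"cannot infer model dialect from suffix {suffix!r}; pass format=")


def load_model(path, format: Optional[str] = None, objective_override: Optional[str] = None) -> MetabolicModel:
    """Load a model from SBML(+FBC) or the JSON dialect; flags and O2
    metabolites are auto-detected, and the result is validated."""
    fmt = format or _infer_format(path)
    if fmt == "json":
        return load_model_json(path)
    if fmt == "sbml_fbc":
        return load_model_sbml(path, objective_override=objective_override)
    raise ConfigurationError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "json":
        write_model_json(model, path)
    elif fmt == "sbml_fbc":
        write_model_sbml(model, path)
    else:
        raise ConfigurationError(f"unknown model format {fmt!r}")


# -- elemental balance -------------------------------------------------------


def reaction_balance(
    model_or_formulas, rxn: Reaction, elements: Sequence[str] = ("C", "N", "O", "P", "S")
) -> Dict[str, float]:
    """Net elemental imbalance of a reaction for the given elements.

    ``model_or_formulas`` is either a MetabolicModel or a mapping metabolite
    id -> formula string.  Metabolites without a formula make the reaction
    uncheckable and raise ValueError.
    """
    if isinstance(model_or_formulas, MetabolicModel):
        formulas = {m.id: m.formula for m in model_or_formulas.metabolites.values()}
    else:
        formulas = dict(model_or_formulas)
    net: Dict[str, float] = {e: 0.0 for e in elements}
    for mid, coeff in rxn.stoichiometry.items():
        formula = formulas.get(mid)
        if not formula:
            raise ValueError(f"metabolite {mid!r} has no formula; cannot balance-check {rxn.id!r}")
        counts = parse_formula(formula)
        for e in elements:
            net[e] += coeff * counts.get(e, 0.0)
    return {e: v for e, v in net.items() if abs(v) > 1e-9}
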