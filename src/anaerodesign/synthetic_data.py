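"""Desk-scale synthetic inputs with planted ground truth.

Two generators:

* :func:`make_toy_model` — a deterministic ~18-reaction metabolic network
  that reproduces, in miniature, the energetics of an obligate aerobe:
  lumped glycolysis yields a little substrate-level ATP, NADH and an
  acetyl-phosphate pool; an electron-transfer-chain (ETC) reaction burns
  NADH with O2 for most of the ATP; four biosynthesis reactions
  (heme-like, NAD-precursor-like, orotate-like and a class-I-RNR-like dNTP
  step) each require O2 and are the sole producers of a biomass precursor.
  Under anoxia the wild type cannot grow (the four precursors are
  unmakeable); with O2-independent alternative reactions growth returns but
  is ATP-starved; adding acetate kinase (substrate-level ATP from the
  acetyl-phosphate pool) exactly doubles that anoxic growth rate — the
  biomass ATP/precursor split is solved in closed form so the doubling is a
  property of the construction, not a numerical accident.

* :func:`make_domain_tables` — per-genome protein-domain tables in the
  simple_tsv dialect with a planted group-exclusive core, a shared core and
  per-genome noise domains.  Noise is constructed so it can never mimic a
  target-exclusive domain, making the planted exclusive core exactly
  identifiable for every seed.

Every dataset ships its :class:`PlantedTruth` so downstream recovery tests
read expectations from the generator, not from hard-coded numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model_core import (
    GLUCOSE_UPTAKE_LIMIT,
    O2_UPTAKE_LIMIT,
    UNLIMITED_UPTAKE,
    MediumSpec,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
    ReactionDef,
    annotate_structure,
)
from .interventions import InterventionSet

log = logging.getLogger("anaerodesign")


class GeneratorError(ModelError):
    """Parameter combination violating a generator budget."""


@dataclass
class PlantedTruth:
    """Ground truth serialized alongside every generated dataset."""

    essential_o2_reactions: Set[str] = field(default_factory=set)
    anaerobic_mu_expected: Dict[str, float] = field(default_factory=dict)
    exclusive_core_domains: Set[str] = field(default_factory=set)
    parameters: Dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "essential_o2_reactions": sorted(self.essential_o2_reactions),
            "anaerobic_mu_expected": self.anaerobic_mu_expected,
            "exclusive_core_domains": sorted(self.exclusive_core_domains),
            "parameters": self.parameters,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            essential_o2_reactions=set(payload["essential_o2_reactions"]),
            anaerobic_mu_expected=dict(payload["anaerobic_mu_expected"]),
            exclusive_core_domains=set(payload["exclusive_core_domains"]),
            parameters=payload["parameters"],
        )


# -- toy metabolic model -----------------------------------------------------


@dataclass(frozen=True)
class ToyParams:
    """Energetic parameters of the toy network.

    atp_per_o2          ATP formed per NADH oxidized at the ETC (with 1/2 O2)
    biomass_atp_demand  ATP consumed per unit biomass flux
    maintenance_atp     fixed non-growth ATP drain, mmol/(gdw h)
    substrate_level_atp ATP per glucose from lumped glycolysis
    glucose_limit       maximal glucose uptake, mmol/(gdw h)
    """

    atp_per_o2: float = 2.0
    biomass_atp_demand: float = 10.0
    maintenance_atp: float = 1.0
    substrate_level_atp: float = 0.5
    glucose_limit: float = GLUCOSE_UPTAKE_LIMIT


PLANTED_ESSENTIALS = ("HEME_SYNTH_O2", "NAD_SYNTH_O2", "ORO_SYNTH_O2", "RNR_I_O2")


def solve_toy_budget(params: ToyParams) -> Dict[str, float]:
    """Closed-form ATP budget of the toy network.

    With s = substrate-level ATP/glucose, D = biomass ATP, M = maintenance,
    G = glucose cap, the anoxic growth rate with the four anaerobic
    alternatives is ATP-limited at mu_alt = (sG - M)/D.  Adding acetate
    kinase lets surplus acetyl-phosphate pay 1 extra ATP per glucose-half,
    giving mu_ack = ((s+1)G - M)/(D + c) where c is the total
    acetyl-phosphate drawn per unit biomass (directly plus via the
    alternatives and their fermentative redox disposal).  Solving
    mu_ack = 2 mu_alt for c:

        c = D * ((1 - s) G + M) / (2 (s G - M))

    which requires sG > M (anaerobic substrate-level ATP must cover
    maintenance with surplus) and (1 - s) G + M > 0.
    """
    s, D, M, G = (
        params.substrate_level_atp,
        params.biomass_atp_demand,
        params.maintenance_atp,
        params.glucose_limit,
    )
    for name in ("atp_per_o2", "biomass_atp_demand", "maintenance_atp",
                 "substrate_level_atp", "glucose_limit"):
        if getattr(params, name) <= 0:
            raise GeneratorError(f"toy parameter {name} must be > 0")
    if s * G <= M:
        raise GeneratorError(
            f"anaerobic ATP budget violated: substrate-level yield s*G = {s * G:.3f} "
            f"must exceed maintenance M = {M:.3f} for the alternatives to enable growth"
        )
    if (1 - s) * G + M <= 0:
        raise GeneratorError(
            f"acetate-kinase doubling budget violated: need (1-s)*G + M > 0, "
            f"got {(1 - s) * G + M:.3f} (substrate-level yield too high)"
        )
    c = D * ((1 - s) * G + M) / (2 * (s * G - M))
    mu_alt = (s * G - M) / D
    # biomass composition: split c between direct acetyl-phosphate (b_p) and
    # the four O2-requiring precursors (b_h each); alternatives also cost
    # 2*b_h extra acetyl-phosphate via fermentative NADH disposal, hence
    # c = b_p + 6*b_h with the fixed split b_h = c/12, b_p = c/2.
    b_h = c / 12.0
    b_p = c / 2.0
    return {
        "precursor_demand_total": c,
        "b_h": b_h,
        "b_p": b_p,
        "mu_anoxic_alternatives": mu_alt,
        "mu_anoxic_alternatives_ack": 2.0 * mu_alt,
    }


def make_toy_model(params: Optional[ToyParams] = None) -> Tuple[MetabolicModel, PlantedTruth]:
    """Deterministic toy network with planted O2-essential reactions.

    Pseudo-formulas use a consistent internal scheme (A = adenosine-like
    moiety, N = NAD scaffold, X unused here) so a balance checker passes on
    every non-exchange, non-biomass reaction.
    """
    params = params or ToyParams()
    budget = solve_toy_budget(params)
    s = params.substrate_level_atp
    P = params.atp_per_o2
    D = params.biomass_atp_demand
    M = params.maintenance_atp
    b_h, b_p = budget["b_h"], budget["b_p"]

    mets = [
        Metabolite("glc_e", "D-glucose", "e", "C6H12O6"),
        Metabolite("o2_e", "oxygen", "e", "O2"),
        Metabolite("o2_c", "oxygen", "c", "O2"),
        Metabolite("ac_e", "acetate (lumped C3)", "e", "C3H4O3"),
        Metabolite("eth_e", "fermentation product (ethanol-like)", "e", "C3H8O3"),
        Metabolite("h2o_e", "water", "e", "H2O"),
        Metabolite("pi_e", "phosphate", "e", "P"),
        Metabolite("atp", "ATP", "c", "AP"),
        Metabolite("adp", "ADP", "c", "A"),
        Metabolite("nad", "NAD+", "c", "N"),
        Metabolite("nadh", "NADH", "c", "NH2"),
        Metabolite("acp", "acetyl phosphate (lumped C3)", "c", "C3H4O3P"),
        Metabolite("heme", "heme-like precursor", "c", "C3H4O4"),
        Metabolite("nadx", "NAD-precursor (iminoaspartate-like)", "c", "C3H4O4"),
        Metabolite("oro", "orotate-like precursor", "c", "C3H4O4"),
        Metabolite("dntp", "dNTP-like precursor", "c", "C3H4O4"),
    ]

    rxns = [
        Reaction("EX_glc", "D-glucose exchange", {"glc_e": -1}, -UNLIMITED_UPTAKE, UNLIMITED_UPTAKE),
        Reaction("EX_o2", "oxygen exchange", {"o2_e": -1}, -UNLIMITED_UPTAKE, UNLIMITED_UPTAKE),
        Reaction("EX_ac", "acetate exchange", {"ac_e": -1}, 0.0, UNLIMITED_UPTAKE),
        Reaction("EX_eth", "fermentation product exchange", {"eth_e": -1}, 0.0, UNLIMITED_UPTAKE),
        Reaction("EX_h2o", "water exchange", {"h2o_e": -1}, -UNLIMITED_UPTAKE, UNLIMITED_UPTAKE),
        Reaction("EX_pi", "phosphate exchange", {"pi_e": -1}, -UNLIMITED_UPTAKE, UNLIMITED_UPTAKE),
        Reaction("O2t", "oxygen transport", {"o2_e": -1, "o2_c": 1}, 0.0, UNLIMITED_UPTAKE),
        Reaction(
            "GLYC",
            "lumped glucose uptake + glycolysis to acetyl phosphate",
            {"glc_e": -1, "pi_e": -(s + 2), "adp": -s, "nad": -2,
             "acp": 2, "atp": s, "nadh": 2},
            0.0, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "ETC_O2",
            "electron transfer chain (NADH oxidase, ATP-coupled)",
            {"nadh": -1, "o2_c": -0.5, "adp": -P, "pi_e": -P,
             "nad": 1, "atp": P, "h2o_e": 1},
            0.0, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "FERM",
            "fermentative NADH disposal (acetyl phosphate to ethanol-like)",
            {"acp": -1, "nadh": -2, "eth_e": 1, "pi_e": 1, "nad": 2},
            0.0, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "HEME_SYNTH_O2",
            "protoporphyrinogen-oxidase-like heme synthesis (O2-dependent)",
            {"acp": -1, "o2_c": -0.5, "heme": 1, "pi_e": 1},
            0.0, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "NAD_SYNTH_O2",
            "L-aspartate-oxidase-like NAD-precursor synthesis (O2-dependent)",
            {"acp": -1, "o2_c": -0.5, "nadx": 1, "pi_e": 1},
            0.0, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "ORO_SYNTH_O2",
            "dihydroorotate-dehydrogenase-like orotate synthesis (O2-dependent)",
            {"acp": -1, "o2_c": -0.5, "oro": 1, "pi_e": 1},
            0.0, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "RNR_I_O2",
            "class-I-ribonucleotide-reductase-like dNTP synthesis (O2-dependent)",
            {"acp": -1, "o2_c": -0.5, "dntp": 1, "pi_e": 1},
            0.0, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "ACP_HYDR",
            "acetyl phosphate hydrolysis (overflow acetate secretion)",
            {"acp": -1, "ac_e": 1, "pi_e": 1},
            0.0, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "ATPM",
            "non-growth ATP maintenance",
            {"atp": -1, "adp": 1, "pi_e": 1},
            M, UNLIMITED_UPTAKE,
        ),
        Reaction(
            "BIOMASS",
            "biomass pseudo-reaction",
            {"acp": -b_p, "heme": -b_h, "nadx": -b_h, "oro": -b_h, "dntp": -b_h,
             "atp": -D, "adp": D, "pi_e": D},
            0.0, UNLIMITED_UPTAKE,
        ),
    ]

    model = MetabolicModel(
        id="toy_aerobe",
        metabolites={m.id: m for m in mets},
        reactions={r.id: r for r in rxns},
        objective_id="BIOMASS",
        o2_metabolite_ids={"o2_e", "o2_c"},
    )
    annotate_structure(model)
    model.validate()

    truth = PlantedTruth(
        essential_o2_reactions=set(PLANTED_ESSENTIALS),
        anaerobic_mu_expected={
            "wild_type": 0.0,
            "anaerobic_alternatives": budget["mu_anoxic_alternatives"],
            "anaerobic_alternatives+ack": budget["mu_anoxic_alternatives_ack"],
        },
        parameters={**dataclasses.asdict(params), **budget},
    )
    return model, truth


def toy_intervention_library(params: Optional[ToyParams] = None) -> Dict[str, InterventionSet]:
    """Intervention sets phrased in the toy model's namespace.

    ``anaerobic_alternatives`` bypasses all four planted O2-dependent
    biosyntheses with NAD-coupled, water-as-oxygen-donor versions (the toy
    analogue of the fumarate/NAD-coupled class I dihydroorotate
    dehydrogenase, class III RNR, fumarate-coupled aspartate oxidase and
    quinone-dependent protoporphyrinogen oxidase); ``ack`` is acetate
    kinase.
    """
    alt_targets = {
        "HEME_SYNTH_ALT": ("heme", "heme synthesis, anaerobic alternative (HemG/HemJ-like)"),
        "NAD_SYNTH_ALT": ("nadx", "NAD-precursor synthesis, anaerobic alternative (NadB-fumarate-like)"),
        "ORO_SYNTH_ALT": ("oro", "orotate synthesis, anaerobic alternative (class I DHODH-like)"),
        "RNR_III_ALT": ("dntp", "dNTP synthesis, anaerobic alternative (class III RNR-like)"),
    }
    alternatives = tuple(
        ReactionDef(
            id=rid,
            name=name,
            stoichiometry={"acp": -1, "h2o_e": -1, "nad": -1, product: 1, "pi_e": 1, "nadh": 1},
            lower_bound=0.0,
            upper_bound=UNLIMITED_UPTAKE,
            provenance="toy analogue of the anaerobic-alternative design set",
        )
        for rid, (product, name) in alt_targets.items()
    )
    ack = ReactionDef(
        id="ACK",
        name="acetate kinase (substrate-level ATP from acetyl phosphate)",
        stoichiometry={"acp": -1, "adp": -1, "ac_e": 1, "atp": 1},
        lower_bound=0.0,
        upper_bound=UNLIMITED_UPTAKE,
        provenance="toy analogue of the acetate kinase design",
    )
    return {
        "anaerobic_alternatives": InterventionSet(
            name="anaerobic_alternatives",
            reactions=alternatives,
            provenance="toy analogue of the anaerobic-alternative design set",
        ),
        "ack": InterventionSet(
            name="ack", reactions=(ack,), provenance="toy analogue of the acetate kinase design"
        ),
    }


def toy_media(params: Optional[ToyParams] = None) -> Dict[str, MediumSpec]:
    """Minimal-glucose base medium plus oxic/anoxic overlays for the toy."""
    params = params or ToyParams()
    return {
        "minimal_glucose": MediumSpec(
            name="minimal_glucose",
            uptake_limits={
                "EX_glc": params.glucose_limit,
                "EX_pi": UNLIMITED_UPTAKE,
                "EX_h2o": UNLIMITED_UPTAKE,
            },
            default_uptake=0.0,
        ),
        "oxic": MediumSpec(name="oxic", uptake_limits={"EX_o2": O2_UPTAKE_LIMIT}, default_uptake=None),
        "anoxic": MediumSpec(name="anoxic", uptake_limits={"EX_o2": 0.0}, default_uptake=None),
    }


# -- random small networks (for oracle-equivalence testing) ------------------


def make_random_model(rng: np.random.Generator, n_metabolites: int = 5, n_reactions: int = 9) -> MetabolicModel:
    """A random sparse bounded network for LP-oracle comparisons.

    Coefficients are small integers, bounds are finite, and with small
    probability a reaction is forced on (lb > 0), which can make the
    program infeasible — statuses are part of the comparison.
    """
    mets = {f"m{i}": Metabolite(f"m{i}", compartment="c") for i in range(n_metabolites)}
    rxns: Dict[str, Reaction] = {}
    for j in range(n_reactions):
        k = int(rng.integers(1, min(3, n_metabolites) + 1))
        touched = rng.choice(n_metabolites, size=k, replace=False)
        coeffs = rng.choice([-2, -1, 1, 2], size=k)
        stoich = {f"m{i}": float(c) for i, c in zip(touched, coeffs)}
        lb = float(rng.choice([-10.0, 0.0]))
        ub = float(rng.choice([0.0, 10.0]))
        if lb > ub:
            lb, ub = ub, lb
        if rng.random() < 0.15:
            lb, ub = 1.0, 10.0  # forced flux: may create infeasibility
        rxns[f"r{j}"] = Reaction(f"r{j}", stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
    objective = f"r{int(rng.integers(0, n_reactions))}"
    model = MetabolicModel(id="random_net", metabolites=mets, reactions=rxns, objective_id=objective)
    return model.validate()


# -- synthetic domain tables -------------------------------------------------


def _accessions(prefix_number: int, count: int) -> List[str]:
    return [f"IPR{prefix_number + i:06d}" for i in range(count)]


def make_domain_tables(
    out_dir,
    seed: int,
    n_target: int = 6,
    n_background: int = 6,
    n_exclusive: int = 47,
    n_shared_core: int = 800,
    n_noise: int = 1200,
    dropout: float = 0.3,
) -> Tuple[Dict[str, Path], PlantedTruth]:
    """Write one simple_tsv per genome plus a PlantedTruth sidecar.

    Planted exclusive domains appear in every target (anaerobe) genome and
    in no background (aerobe) genome; the shared core appears everywhere;
    each noise domain enters each genome independently with probability
    ``1 - dropout``.  Any noise domain that would mimic target-exclusivity
    is forced into one background genome, so the exclusive core is exactly
    the planted set by construction.  Output is byte-reproducible from the
    seed.
    """
    if n_target < 1 or n_background < 1:
        raise GeneratorError("need at least one genome per group")
    if not (0 <= dropout < 1):
        raise GeneratorError("dropout must be in [0, 1)")
    if n_exclusive == 0:
        log.warning("n_exclusive = 0: recovery tests will have an empty planted truth")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    exclusive = _accessions(900001, n_exclusive)
    shared = _accessions(100001, n_shared_core)
    noise = _accessions(500001, n_noise)
    genome_ids = [f"anae_{i + 1:02d}" for i in range(n_target)] + [
        f"aero_{i + 1:02d}" for i in range(n_background)
    ]
    is_target = [True] * n_target + [False] * n_background

    include = rng.random((n_noise, len(genome_ids))) < (1.0 - dropout)
    # noise must never mimic a target-exclusive domain
    forced = 0
    for d in range(n_noise):
        in_targets = include[d, :n_target].all()
        in_background = include[d, n_target:].any()
        if in_targets and not in_background:
            include[d, n_target + int(rng.integers(0, n_background))] = True
            forced += 1
    if forced:
        log.debug("make_domain_tables: de-mimicked %d noise domains", forced)

    paths: Dict[str, Path] = {}
    for g, genome_id in enumerate(genome_ids):
        domains = list(shared)
        if is_target[g]:
            domains += exclusive
        domains += [noise[d] for d in range(n_noise) if include[d, g]]
        lines = ["genome_id\tgene_id\tdomain_id"]
        for i, domain in enumerate(domains):
            gene = f"{genome_id}_g{i + 1:05d}"
            lines.append(f"{genome_id}\t{gene}\t{domain}")
            # occasionally a second gene carries the same domain: presence
            # is boolean, so duplicates must not change any downstream set
            if rng.random() < 0.05:
                lines.append(f"{genome_id}\t{genome_id}_g{i + 1:05d}b\t{domain}")
        path = out_dir / f"{genome_id}.tsv"
        path.write_text("\n".join(lines) + "\n")
        paths[genome_id] = path

    # planted exclusive domains never leak into background sets
    for g in range(n_target, len(genome_ids)):
        written = paths[genome_ids[g]].read_text()
        assert not any(acc in written for acc in exclusive)

    truth = PlantedTruth(
        exclusive_core_domains=set(exclusive),
        parameters={
            "seed": seed,
            "n_target": n_target,
            "n_background": n_background,
            "n_exclusive": n_exclusive,
            "n_shared_core": n_shared_core,
            "n_noise": n_noise,
            "dropout": dropout,
            "target_genomes": genome_ids[:n_target],
            "background_genomes": genome_ids[n_target:],
        },
    )
    truth.to_json(out_dir / "planted_truth.json")
    return paths, truth
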