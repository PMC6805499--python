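import json

import numpy as np
import pytest

from anaerodesign import (
    ConfigurationError,
    MediumSpec,
    Metabolite,
    ReactionDef,
    UnknownReactionError,
    ValidationError,
    add_reactions,
    apply_medium,
    delete_reaction,
    load_model,
    preset_medium,
    write_model,
)
from anaerodesign.fba_engine import fba
from anaerodesign.model_core import (
    GLUCOSE_UPTAKE_LIMIT,
    O2_UPTAKE_LIMIT,
    UNLIMITED_UPTAKE,
    model_to_dict,
    parse_formula,
    reaction_balance,
)
from anaerodesign.synthetic_data import ToyParams, solve_toy_budget

CHAIN_MODEL = {
    "id": "chain",
    "metabolites": [
        {"id": "a_e", "name": "A", "compartment": "e", "formula": "C"},
        {"id": "a_c", "name": "A", "compartment": "c", "formula": "C"},
        {"id": "b_c", "name": "B", "compartment": "c", "formula": "C"},
        {"id": "o2_e", "name": "oxygen", "compartment": "e", "formula": "O2"},
    ],
    "reactions": [
        {"id": "EX_a", "name": "A exchange", "stoich": {"a_e": -1}, "lb": -10, "ub": 1000},
        {"id": "EX_o2", "name": "O2 exchange", "stoich": {"o2_e": -1}, "lb": -1000, "ub": 1000},
        {"id": "At", "name": "A transport", "stoich": {"a_e": -1, "a_c": 1}, "lb": 0, "ub": 1000},
        {"id": "AB", "name": "A to B", "stoich": {"a_c": -1, "b_c": 1}, "lb": 0, "ub": 1000},
        {"id": "BIOMASS", "name": "biomass", "stoich": {"b_c": -1}, "lb": 0, "ub": 1000},
        {"id": "DRAIN1", "name": "drain", "stoich": {"b_c": -1}, "lb": 0, "ub": 0},
        {"id": "LOOP1", "name": "loop fwd", "stoich": {"a_c": -1, "b_c": 1}, "lb": 0, "ub": 0},
        {"id": "LOOP2", "name": "loop back", "stoich": {"b_c": -1, "a_c": 1}, "lb": 0, "ub": 0},
    ],
    "objective": "BIOMASS",
    "o2_metabolites": [],
}


@pytest.fixture()
def chain_model(tmp_path):
    path = tmp_path / "chain.json"
    path.write_text(json.dumps(CHAIN_MODEL))
    return load_model(path)


def test_json_fixture_loads_with_expected_structure(chain_model):
    assert len(chain_model.reactions) == 8
    assert chain_model.objective_id == "BIOMASS"
    # exchange/transport auto-flagging and O2 auto-detection
    assert {r.id for r in chain_model.exchange_reactions} == {"EX_a", "EX_o2"}
    assert chain_model.reactions["At"].is_transport
    assert chain_model.o2_metabolite_ids == {"o2_e"}


@pytest.mark.parametrize("fmt,suffix", [("json", ".json"), ("sbml_fbc", ".xml")])
def test_round_trip_preserves_network(toy_model, tmp_path, fmt, suffix):
    """Write-then-load is the identity on topology, bounds and objective.

    JSON is bit-exact; SBML serializes IEEE doubles as decimal text with 15
    significant digits, so numeric equality there is up to 1e-12 relative.
    """
    path = tmp_path / f"toy{suffix}"
    write_model(toy_model, path, format=fmt)
    reloaded = load_model(path, format=fmt)
    assert list(reloaded.reactions) == list(toy_model.reactions)
    assert list(reloaded.metabolites) == list(toy_model.metabolites)
    assert reloaded.objective_id == toy_model.objective_id
    assert reloaded.o2_metabolite_ids == toy_model.o2_metabolite_ids
    for rid, rxn in toy_model.reactions.items():
        other = reloaded.reactions[rid]
        assert set(other.stoichiometry) == set(rxn.stoichiometry)
        for mid, coeff in rxn.stoichiometry.items():
            assert other.stoichiometry[mid] == pytest.approx(coeff, rel=1e-12)
        assert other.lower_bound == pytest.approx(rxn.lower_bound, rel=1e-12)
        assert other.upper_bound == pytest.approx(rxn.upper_bound, rel=1e-12)
    if fmt == "json":
        assert model_to_dict(reloaded) == model_to_dict(toy_model)


def test_apply_medium_sets_uptake_bounds_only(toy_model, media):
    before = model_to_dict(toy_model)
    conditioned = apply_medium(toy_model, media["minimal_glucose"])
    assert model_to_dict(toy_model) == before, "input model must not be mutated"
    assert conditioned.reactions["EX_glc"].lower_bound == -GLUCOSE_UPTAKE_LIMIT
    assert conditioned.reactions["EX_pi"].lower_bound == -UNLIMITED_UPTAKE
    assert conditioned.reactions["EX_o2"].lower_bound == 0.0  # closed by default_uptake
    for rid, rxn in conditioned.reactions.items():
        assert rxn.stoichiometry == toy_model.reactions[rid].stoichiometry
        if not rxn.is_exchange:
            assert rxn.lower_bound == toy_model.reactions[rid].lower_bound
        else:
            assert rxn.upper_bound == toy_model.reactions[rid].upper_bound


def test_presets_resolve_by_compound_identity(toy_model):
    minimal = preset_medium("minimal_glucose", toy_model)
    assert minimal.uptake_limits["EX_glc"] == GLUCOSE_UPTAKE_LIMIT
    assert minimal.uptake_limits["EX_pi"] == UNLIMITED_UPTAKE
    assert minimal.uptake_limits["EX_h2o"] == UNLIMITED_UPTAKE
    assert "EX_o2" not in minimal.uptake_limits
    rich = preset_medium("rich", toy_model)
    assert rich.uptake_limits["EX_ac"] == UNLIMITED_UPTAKE
    assert "EX_o2" not in rich.uptake_limits
    oxic = preset_medium("oxic", toy_model)
    assert oxic.uptake_limits == {"EX_o2": O2_UPTAKE_LIMIT}
    assert oxic.default_uptake is None
    anoxic = preset_medium("anoxic", toy_model)
    assert anoxic.uptake_limits == {"EX_o2": 0.0}
    with pytest.raises(ConfigurationError):
        preset_medium("broth", toy_model)


def test_medium_with_absent_exchange_lenient_vs_strict(toy_model):
    medium = MediumSpec(name="odd", uptake_limits={"EX_missing": 5.0}, default_uptake=None)
    apply_medium(toy_model, medium)  # lenient: warn + skip
    with pytest.raises(ConfigurationError):
        apply_medium(toy_model, medium, strict=True)


def test_delete_objective_forces_zero_growth(oxic_model):
    assert fba(delete_reaction(oxic_model, "BIOMASS")).mu == 0.0


def test_delete_is_idempotent_and_checks_ids(oxic_model):
    once = delete_reaction(oxic_model, "ETC_O2")
    twice = delete_reaction(once, "ETC_O2")
    assert fba(once).mu == pytest.approx(fba(twice).mu, abs=1e-12)
    with pytest.raises(UnknownReactionError):
        delete_reaction(oxic_model, "NOPE")


def test_deleting_etc_leaves_substrate_level_growth(oxic_model):
    """Without the ETC the model survives on substrate-level ATP alone:
    mu = (s*G - M)/D from the hand ATP-budget algebra."""
    params = ToyParams()
    expected = (
        params.substrate_level_atp * params.glucose_limit - params.maintenance_atp
    ) / params.biomass_atp_demand
    result = fba(delete_reaction(oxic_model, "ETC_O2"))
    assert result.mu == pytest.approx(expected, abs=1e-9)
    assert 0 < result.mu < fba(oxic_model).mu


def test_add_reactions_identity_collision_and_undeclared(toy_model):
    assert model_to_dict(add_reactions(toy_model, [])) == model_to_dict(toy_model)
    dup = ReactionDef("GLYC", "dup", {"glc_e": -1}, 0, 1, provenance="x")
    with pytest.raises(ValidationError):
        add_reactions(toy_model, [dup])
    dangling = ReactionDef("NEW", "new", {"ghost_c": -1}, 0, 1, provenance="x")
    with pytest.raises(ValidationError):
        add_reactions(toy_model, [dangling])
    declared = ReactionDef(
        "NEW", "new", {"ghost_c": -1, "acp": 1}, 0, 1, provenance="x",
        metabolites=[Metabolite("ghost_c", "ghost", "c")],
    )
    expanded = add_reactions(toy_model, [declared])
    assert "ghost_c" in expanded.metabolites and "NEW" in expanded.reactions


def test_add_is_monotone_delete_is_antimonotone(oxic_model, toy_library):
    base = fba(oxic_model).mu
    for iset in toy_library.values():
        assert fba(add_reactions(oxic_model, iset.reactions)).mu >= base - 1e-9
    for rid in oxic_model.reactions:
        assert fba(delete_reaction(oxic_model, rid)).mu <= base + 1e-9


def test_parse_formula():
    assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
    assert parse_formula("AP") == {"A": 1, "P": 1}
    assert parse_formula("C49H74O4") == {"C": 49, "H": 74, "O": 4}


def test_toy_internal_reactions_are_elementally_balanced(toy_model):
    """Every non-exchange reaction except the biomass pseudo-reaction is
    balanced under the toy's pseudo-formula scheme."""
    for rxn in toy_model.reactions.values():
        if rxn.is_exchange or rxn.id == toy_model.objective_id:
            continue
        assert reaction_balance(toy_model, rxn, elements=("C", "H", "O", "P", "N", "A")) == {}, rxn.id
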