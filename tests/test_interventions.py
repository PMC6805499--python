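import itertools

import pytest

from anaerodesign import (
    CONSOLIDATED_DESIGN,
    ConfigurationError,
    apply_design,
    builtin_designs,
    check_design_balance,
    evaluate_designs,
    fba,
)
from anaerodesign.interventions import (
    builtin_design_formulas,
    classify_growth,
    design_library_to_json,
    load_design_library,
)
from anaerodesign.model_core import apply_medium


def test_builtin_library_completeness():
    library = builtin_designs()
    assert len(library) >= 9
    expected = {"ACK", "NIKEL", "NAR", "NIR_NOR", "ELECTRODE",
                "DHODH_I", "RNR_III", "NADB_FUM", "HEMG_Q"}
    assert expected <= set(library)
    for iset in library.values():
        assert iset.provenance.strip()
        assert iset.reactions


def test_consolidated_design_names():
    """The consolidated fermentative design: class I DHODH + class III RNR
    + acetate kinase."""
    assert set(CONSOLIDATED_DESIGN) == {"DHODH_I", "RNR_III", "ACK"}
    library = builtin_designs()
    reaction_names = " ".join(
        r.name.lower() for name in CONSOLIDATED_DESIGN for r in library[name].reactions
    )
    assert "dihydroorotate" in reaction_names
    assert "ribonucleotide" in reaction_names
    assert "acetate kinase" in reaction_names


def test_builtin_designs_are_elementally_balanced():
    formulas = builtin_design_formulas()
    for iset in builtin_designs().values():
        assert check_design_balance(iset, formulas) == []


def test_library_json_round_trip(tmp_path, toy_library):
    path = tmp_path / "lib.json"
    design_library_to_json(toy_library, path)
    reloaded = load_design_library(path)
    assert set(reloaded) == set(toy_library)
    for name, iset in toy_library.items():
        other = reloaded[name]
        assert [r.id for r in other.reactions] == [r.id for r in iset.reactions]
        assert all(
            a.stoichiometry == b.stoichiometry and (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
            for a, b in zip(other.reactions, iset.reactions)
        )


def test_grid_reproduces_planted_anaerobic_ladder(toy_model, toy_truth, toy_library, media):
    conditions = [media["minimal_glucose"]]
    anoxic = media["anoxic"]
    merged = media["minimal_glucose"].uptake_limits | anoxic.uptake_limits
    from anaerodesign.model_core import MediumSpec

    anoxic_minimal = MediumSpec("anoxic_minimal", dict(merged), 0.0)
    oxic_minimal = MediumSpec(
        "oxic_minimal", media["minimal_glucose"].uptake_limits | media["oxic"].uptake_limits, 0.0
    )
    combos = [[], ["anaerobic_alternatives"], ["anaerobic_alternatives", "ack"]]
    grid = evaluate_designs(
        toy_model, combos, [oxic_minimal, anoxic_minimal],
        library=toy_library, reference_medium=oxic_minimal,
    )
    expected = toy_truth.anaerobic_mu_expected
    assert grid.cells[("wild-type", "anoxic_minimal")].mu == pytest.approx(0.0, abs=1e-9)
    assert grid.cells[("wild-type", "anoxic_minimal")].growth_class == "none"
    assert grid.cells[("anaerobic_alternatives", "anoxic_minimal")].mu == pytest.approx(
        expected["anaerobic_alternatives"], abs=1e-9
    )
    assert grid.cells[("anaerobic_alternatives + ack", "anoxic_minimal")].mu == pytest.approx(
        expected["anaerobic_alternatives+ack"], abs=1e-9
    )
    assert grid.cells[("wild-type", "oxic_minimal")].growth_class == "growth"
    frame = grid.to_frame()
    assert len(frame) == len(combos) * 2

    # grid cells are reproducible by manual expand -> medium -> fba
    manual = toy_model
    for name in ["anaerobic_alternatives", "ack"]:
        manual = apply_design(manual, toy_library[name])
    mu_manual = fba(apply_medium(manual, anoxic_minimal)).mu
    assert mu_manual == grid.cells[("anaerobic_alternatives + ack", "anoxic_minimal")].mu


def test_design_addition_is_monotone_across_combos(toy_model, toy_library, media):
    from anaerodesign.model_core import MediumSpec

    anoxic_minimal = MediumSpec(
        "anoxic_minimal",
        media["minimal_glucose"].uptake_limits | media["anoxic"].uptake_limits,
        0.0,
    )
    names = list(toy_library)
    mus = {}
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            expanded = toy_model
            for name in combo:
                expanded = apply_design(expanded, toy_library[name])
            mus[frozenset(combo)] = fba(apply_medium(expanded, anoxic_minimal)).mu
    for small, large in itertools.permutations(mus, 2):
        if small < large:
            assert mus[small] <= mus[large] + 1e-9


def test_unknown_design_fails_before_solving(toy_model, toy_library, media):
    with pytest.raises(ConfigurationError, match="unknown design"):
        evaluate_designs(toy_model, [["nonesuch"]], [media["minimal_glucose"]], library=toy_library)


def test_classification_boundaries_are_half_open():
    eps, mu_ref, fraction = 1e-6, 0.5, 0.10
    assert classify_growth(0.0, mu_ref, eps, fraction) == "none"
    assert classify_growth(eps, mu_ref, eps, fraction) == "poor"
    assert classify_growth(fraction * mu_ref - 1e-12, mu_ref, eps, fraction) == "poor"
    assert classify_growth(fraction * mu_ref, mu_ref, eps, fraction) == "growth"
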