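from fractions import Fraction

import numpy as np
import pytest

from galuferm.pathways import (
    PathwayError,
    Reaction,
    build_pathway,
    check_reaction_balance,
    stoichiometric_matrix,
)


def test_unknown_variant_lists_valid_names():
    with pytest.raises(PathwayError, match="hybrid_isomerase_pk"):
        build_pathway("foo")


def test_canonical_variant_structure(all_variants):
    p = all_variants["canonical_isomerase"]
    assert len(p.reactions) == 12
    for m in ("taga", "frua", "manna", "kdg", "kdpg", "gap"):
        assert m in p.internal_species


def test_hybrid_contains_the_novel_enzymes(all_variants):
    names = {r.enzyme_name for r in all_variants["hybrid_isomerase_pk"].reactions}
    assert "mannonate kinase" in names
    assert "6-phosphomannonate 2-epimerase" in names


def test_pdh_branch_only_in_plus_pdh_variant(all_variants):
    assert "PDH" not in [r.id for r in all_variants["canonical_isomerase"].reactions]
    assert "PDH" in [r.id for r in all_variants["canonical_isomerase_plus_pdh"].reactions]


def test_phosphoketolase_starts_from_6_phosphogluconate(all_variants):
    assert all_variants["phosphoketolase"].substrate == "pg6"


def test_every_shipped_reaction_balances(all_variants, registry):
    for p in all_variants.values():
        for r in p.reactions:
            rep = check_reaction_balance(r, registry)
            assert rep.closed, f"{p.name}/{r.id}: {rep.residuals}"
            assert rep.gamma_residual == pytest.approx(0, abs=1e-9)


def test_isomerization_balances_trivially(all_variants, registry):
    rep = check_reaction_balance(
        all_variants["canonical_isomerase"].reaction("UxaC"), registry)
    assert all(v == pytest.approx(0) for v in rep.residuals.values())


def test_corrupted_decarboxylation_leaves_carbon_residual(registry):
    # 6PGD with the CO2 product dropped must show one stray carbon
    bad = Reaction(
        id="PGD_bad", enzyme_name="broken", ec_number=None,
        stoichiometry={"pg6": Fraction(-1), "ru5p": Fraction(1)},
        reversible=False, cofactor_deltas={"NADPH": Fraction(1)})
    rep = check_reaction_balance(bad, registry)
    assert abs(rep.residuals["C"]) == pytest.approx(1.0)
    assert not rep.closed


def test_unregistered_compound_is_named(registry):
    r = Reaction("X", "x", None, {"nosuch": Fraction(-1), "co2": Fraction(1)},
                 False, {})
    p = build_pathway("canonical_isomerase")
    p.reactions.append(r)
    with pytest.raises(PathwayError, match="nosuch"):
        p.validate()


def test_uxub_cofactor_toggle_changes_only_the_redox_split():
    a = build_pathway("hybrid_isomerase_pk", uxub_cofactor="NADPH")
    b = build_pathway("hybrid_isomerase_pk", uxub_cofactor="NADH")
    ra, rb = a.reaction("UxuB"), b.reaction("UxuB")
    assert ra.stoichiometry == rb.stoichiometry
    assert ra.cofactor_deltas.get("NADPH") == Fraction(-1)
    assert rb.cofactor_deltas.get("NADH") == Fraction(-1)
    assert ra.nad_p_h_delta == rb.nad_p_h_delta


def test_stoichiometric_matrix_shape_and_internal_rows(all_variants):
    p = all_variants["canonical_isomerase"]
    sm = stoichiometric_matrix(p)
    assert sm.matrix.shape == (len(p.species), 12)
    for s in p.internal_species:
        row = sm.row(s)
        assert (row > 0).any() and (row < 0).any()


def test_matrix_times_ones_gives_net_stoichiometry_on_toy_chain(registry):
    # two-step chain galua -> taga -> frua; unit flux everywhere sums to
    # the overall conversion galua -> frua
    from galuferm.pathways import PathwayModel
    r1 = Reaction("S1", "iso", None,
                  {"galua": Fraction(-1), "taga": Fraction(1)}, True, {})
    r2 = Reaction("S2", "epi", None,
                  {"taga": Fraction(-1), "frua": Fraction(1)}, True, {})
    p = PathwayModel("toy", [r1, r2], "galua",
                     frozenset({"galua", "frua"}), registry)
    p.validate()
    sm = stoichiometric_matrix(p)
    net = sm.matrix @ np.ones(2)
    expect = {"galua": -1, "taga": 0, "frua": 1}
    for cid, val in expect.items():
        assert net[sm.species.index(cid)] == pytest.approx(val)


def test_truncation_presets_and_unknown_truncation():
    p = build_pathway("canonical_isomerase", truncate="pyruvate_gap")
    assert [r.id for r in p.reactions] == ["UxaC", "UxuE", "UxuB", "UxuA",
                                           "KdgK", "KdgA"]
    assert p.external_species == {"galua", "pyr", "gap"}
    with pytest.raises(PathwayError, match="pyruvate"):
        build_pathway("canonical_isomerase", truncate="nope")


def test_pathway_file_round_trip(tmp_path):
    from galuferm.pathways import load_pathway_file
    text = (
        "# pathway: mini\n# substrate: galua\n# externals: galua frua\n"
        "S1 | uronate isomerase | 5.3.1.12 | galua -> taga | rev | uxaC\n"
        "S2 | tagaturonate 3-epimerase | 5.1.2.7 | taga -> frua | rev | uxaE\n")
    f = tmp_path / "mini.txt"
    f.write_text(text)
    p = load_pathway_file(f)
    assert p.name == "mini" and len(p.reactions) == 2
    assert p.internal_species == ["taga"]
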