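from fractions import Fraction

import pytest

from galuferm.flux import (
    UnderdeterminedError,
    atp_yield,
    cofactor_summary,
    net_conversion,
    product_profile_feasible,
)
from galuferm.pathways import ELECTRONS_PER_NADH, build_pathway


def net_by_hand(p, fluxes):
    """Independent oracle: symbolic summation of reaction equations under a
    hand-assigned flux vector (no linear algebra)."""
    net, atp, nadh, nadph = {}, Fraction(0), Fraction(0), Fraction(0)
    for r in p.reactions:
        f = Fraction(fluxes[r.id])
        for cid, coef in r.stoichiometry.items():
            net[cid] = net.get(cid, Fraction(0)) + coef * f
        atp += r.cofactor_deltas.get("ATP", Fraction(0)) * f
        nadh += r.cofactor_deltas.get("NADH", Fraction(0)) * f
        nadph += r.cofactor_deltas.get("NADPH", Fraction(0)) * f
    return {k: v for k, v in net.items() if v != 0}, atp, nadh, nadph


# unit fluxes traced along each route by hand: every reaction runs once,
# except the canonical triose split where both KDPG halves reach pyruvate
# (glycolysis once) and LDH turns over twice
HAND_FLUXES = {
    "canonical_isomerase": dict.fromkeys(
        ["UxaC", "UxuE", "UxuB", "UxuA", "KdgK", "KdgA", "GAPDH", "PGK",
         "PGM", "ENO", "PYK"], 1) | {"nLDH": 2},
    "hybrid_isomerase_pk": dict.fromkeys(
        ["UxaC", "UxuE", "UxuB", "MAK", "MPE", "PGD", "RPE", "XpkA",
         "GAPDH", "PGK", "PGM", "ENO", "PYK", "nLDH", "AckA"], 1),
    "phosphoketolase": dict.fromkeys(
        ["PGD", "RPE", "XpkA", "GAPDH", "PGK", "PGM", "ENO", "PYK",
         "nLDH", "AckA"], 1),
}


@pytest.mark.parametrize("variant", sorted(HAND_FLUXES))
def test_net_conversion_matches_symbolic_summation_oracle(variant):
    p = build_pathway(variant)
    nc = net_conversion(p)
    net, atp, nadh, nadph = net_by_hand(p, HAND_FLUXES[variant])
    external_net = {k: v for k, v in net.items() if k in p.external_species}
    assert nc.net_stoichiometry == external_net
    assert (nc.atp_delta, nc.nadh_delta, nc.nadph_delta) == (atp, nadh, nadph)
    # every internal species cancels in the hand summation
    assert all(k in p.external_species for k in net)


def test_upper_pathway_requires_one_atp_and_one_nadph_equivalent():
    p = build_pathway("canonical_isomerase", truncate="pyruvate_gap")
    nc = net_conversion(p)
    assert nc.net_stoichiometry == {"galua": -1, "pyr": 1, "gap": 1}
    assert nc.atp_delta == -1
    assert nc.nad_p_h_combined == -1


def test_full_canonical_route_to_two_pyruvate_is_redox_neutral():
    p = build_pathway("canonical_isomerase", truncate="pyruvate")
    nc = net_conversion(p)
    assert nc.net_stoichiometry == {"galua": -1, "pyr": 2}
    assert nc.atp_delta == 1
    assert nc.nad_p_h_combined == 0


def test_hybrid_upper_route_is_redox_neutral_to_ru5p():
    nc = net_conversion(build_pathway("hybrid_isomerase_pk", truncate="ru5p"))
    assert nc.net_stoichiometry == {"galua": -1, "ru5p": 1, "co2": 1}
    assert nc.nad_p_h_combined == 0


def test_full_hybrid_yields_equimolar_lactate_acetate_co2_with_two_atp():
    nc = net_conversion(build_pathway("hybrid_isomerase_pk"))
    assert nc.net_stoichiometry == {"galua": -1, "lactate": 1, "acetate": 1,
                                    "co2": 1}
    assert nc.atp_delta == 2
    assert nc.nadh_delta == 0 and nc.nadph_delta == 0


@pytest.mark.parametrize("variant, truncate", [
    ("canonical_isomerase", None),
    ("canonical_isomerase", "pyruvate"),
    ("canonical_isomerase", "pyruvate_gap"),
    ("hybrid_isomerase_pk", None),
    ("hybrid_isomerase_pk", "ru5p"),
    ("phosphoketolase", None),
])
def test_carbon_and_electron_conservation(variant, truncate, registry):
    p = build_pathway(variant, truncate=truncate)
    nc = net_conversion(p)
    carbon = sum(float(c) * registry[cid].carbon_count
                 for cid, c in nc.net_stoichiometry.items())
    assert carbon == pytest.approx(0, abs=1e-12)
    gamma = sum(float(c) * registry[cid].gamma
                for cid, c in nc.net_stoichiometry.items())
    assert gamma + ELECTRONS_PER_NADH * float(nc.nad_p_h_combined) == \
        pytest.approx(0, abs=1e-12)


def test_net_conversion_scales_linearly_with_uptake():
    p = build_pathway("hybrid_isomerase_pk")
    one, two = net_conversion(p, 1), net_conversion(p, 2)
    assert two.atp_delta == 2 * one.atp_delta
    for cid, c in one.net_stoichiometry.items():
        assert two.net_stoichiometry[cid] == 2 * c
    zero = net_conversion(p, 0)
    assert zero.atp_delta == 0 and all(v == 0 for v in zero.flux_vector.values())


def test_branched_variant_is_underdetermined_and_names_free_reactions():
    with pytest.raises(UnderdeterminedError) as exc:
        net_conversion(build_pathway("canonical_isomerase_plus_pdh"))
    assert {"PDH", "nLDH"} <= set(exc.value.free_reactions)


def test_cofactor_summary_matched_and_mismatched_hybrid():
    matched = net_conversion(build_pathway("hybrid_isomerase_pk",
                                           uxub_cofactor="NADPH"))
    s = cofactor_summary(matched, transhydrogenase=False)
    assert s.values["NADH"] == 0 and s.values["NADPH"] == 0
    assert not s.imbalance

    mism = net_conversion(build_pathway("hybrid_isomerase_pk",
                                        uxub_cofactor="NADH"))
    s2 = cofactor_summary(mism, transhydrogenase=False)
    assert s2.values["NAD(P)H"] == 0
    assert s2.values["NADPH"] == 1 and s2.values["NADH"] == -1
    assert s2.imbalance

    pooled = cofactor_summary(mism, transhydrogenase=True)
    assert pooled.values["NAD(P)H"] == 0 and not pooled.imbalance


def test_equimolar_profile_feasibility_discriminates_variants():
    hybrid = product_profile_feasible(
        build_pathway("hybrid_isomerase_pk"), {"lactate": 1, "acetate": 1}, 0.01)
    assert hybrid.feasible and hybrid.residual <= 0.01

    canonical = product_profile_feasible(
        build_pathway("canonical_isomerase"), {"lactate": 1, "acetate": 1}, 0.01)
    assert not canonical.feasible
    assert canonical.certificate["unreachable_targets"] == ["acetate"]

    plus_pdh = product_profile_feasible(
        build_pathway("canonical_isomerase_plus_pdh"),
        {"lactate": 1, "acetate": 1}, 0.01, require_redox_neutral=True)
    assert plus_pdh.feasible
    # the 1:1 split runs PDH and LDH at equal net rates
    assert plus_pdh.flux_vector["PDH"] == pytest.approx(1.0, abs=1e-6)


def test_feasibility_rejects_negative_tolerance():
    with pytest.raises(ValueError):
        product_profile_feasible(build_pathway("hybrid_isomerase_pk"),
                                 {"lactate": 1}, -0.1)


def test_atp_yields():
    assert atp_yield(build_pathway("canonical_isomerase",
                                   truncate="pyruvate")) == 1
    assert atp_yield(build_pathway("hybrid_isomerase_pk")) == 2
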