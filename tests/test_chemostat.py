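import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from galuferm.chemostat import (
    BatchTimeCourse,
    ChemostatRecord,
    biomass_yield,
    carbon_balance,
    electron_balance,
    estimate_mu_batch,
    reconcile,
    yields_from_rates,
)


def test_published_rate_table_yields(table2_record):
    y = yields_from_rates(table2_record)
    assert y == {"acetate": 0.87, "lactate": 0.75, "co2": 1.04}


def test_zero_product_rate_gives_zero_yield(table2_record, registry):
    rec = ChemostatRecord(0.13, {"galua": -6.9, "lactate": 0.0},
                          registry=registry)
    assert yields_from_rates(rec)["lactate"] == 0.0


def test_biomass_yield_from_rates(table2_record):
    # D/(|q_s| * M_s): 0.13/(0.0069*194.14) = 0.097 g/g — the rate-based
    # recomputation, slightly above the conventionally printed 0.09
    assert biomass_yield(table2_record) == pytest.approx(0.0970, abs=5e-4)


def test_biomass_yield_constructed_identity(registry):
    m = registry["galua"].molar_mass
    rec = ChemostatRecord(0.13, {"galua": -0.13 / m * 1e3}, registry=registry)
    assert biomass_yield(rec) == pytest.approx(1.0)


def test_balance_closures_on_published_record(table2_record):
    # hand oracle: (6.0*2 + 5.2*3 + 7.2*1 + 5.28)/41.4 and
    # (6.0*8 + 5.2*12 + 5.28*4.2)/138
    assert carbon_balance(table2_record) == pytest.approx(0.968, abs=0.001)
    assert electron_balance(table2_record) == pytest.approx(0.961, abs=0.001)


def test_dropping_the_biomass_term_lowers_both_recoveries(table2_record):
    rec = ChemostatRecord(table2_record.dilution_rate, table2_record.rates,
                          registry=table2_record.registry, biomass_rate=0.0)
    assert carbon_balance(rec) < carbon_balance(table2_record)
    assert electron_balance(rec) < electron_balance(table2_record)


def test_all_products_zeroed_leaves_biomass_term_only(table2_record, registry):
    rec = ChemostatRecord(0.13, {"galua": -6.9, "acetate": 0, "lactate": 0,
                                 "co2": 0}, registry=registry)
    assert carbon_balance(rec) == pytest.approx(rec.q_biomass / (6.9 * 6))


@settings(deadline=None, derandomize=True)
@given(st.floats(0.1, 50))
def test_recoveries_invariant_to_common_rate_scaling(scale):
    from galuferm import load_default_registry
    registry = load_default_registry()
    base = {"galua": -6.9, "acetate": 6.0, "lactate": 5.2, "co2": 7.2}
    a = ChemostatRecord(0.13, base, registry=registry)
    b = ChemostatRecord(0.13, {k: v * scale for k, v in base.items()},
                        registry=registry,
                        biomass_rate=a.q_biomass * scale)
    assert carbon_balance(b) == pytest.approx(carbon_balance(a), rel=1e-9)
    assert electron_balance(b) == pytest.approx(electron_balance(a), rel=1e-9)


def test_yield_rate_round_trip(table2_record):
    y = yields_from_rates(table2_record, round_to=None)
    qs = abs(table2_record.q_substrate)
    rates = {"galua": -qs} | {cid: v * qs for cid, v in y.items()}
    rec2 = ChemostatRecord(0.13, rates, registry=table2_record.registry)
    assert yields_from_rates(rec2, round_to=None) == pytest.approx(y)


def test_record_validation(registry):
    with pytest.raises(ValueError):
        ChemostatRecord(0.13, {"galua": 6.9}, registry=registry)  # sign
    with pytest.raises(ValueError):
        ChemostatRecord(-1, {"galua": -6.9}, registry=registry)   # D > 0
    with pytest.raises(KeyError):
        ChemostatRecord(0.13, {"galua": -6.9, "bogus": 1}, registry=registry)


def test_reconcile_report_round_trips_to_dict(table2_record):
    rep = reconcile(table2_record)
    d = rep.as_dict()
    assert d["yields"]["acetate"] == 0.87
    assert 0 < d["carbon_recovery"] <= 1.2


def test_mu_from_exact_exponential_series():
    t = np.linspace(0, 10, 11)
    tc = BatchTimeCourse(time=t, biomass=0.1 * np.exp(0.20 * t))
    mu, se = estimate_mu_batch(tc, (0, 10))
    assert mu == pytest.approx(0.20, abs=1e-12)
    assert se == pytest.approx(0.0, abs=1e-8)


def test_mu_of_constant_series_is_zero():
    tc = BatchTimeCourse(time=np.arange(5.0), biomass=np.full(5, 0.3))
    mu, _ = estimate_mu_batch(tc, (0, 4))
    assert mu == pytest.approx(0.0, abs=1e-12)


def test_mu_estimation_guards():
    tc = BatchTimeCourse(time=np.arange(5.0), biomass=np.ones(5))
    with pytest.raises(ValueError):
        estimate_mu_batch(tc, (0, 1))          # < 3 points
    tc2 = BatchTimeCourse(time=np.arange(5.0),
                          biomass=np.array([1, 1, 0, 1, 1.0]))
    with pytest.raises(ValueError):
        estimate_mu_batch(tc2, (0, 4))         # non-positive biomass


def test_time_course_validation():
    with pytest.raises(ValueError):
        BatchTimeCourse(time=np.array([0.0, 0.0, 1.0]), biomass=np.ones(3))
    with pytest.raises(ValueError):
        BatchTimeCourse(time=np.arange(3.0), biomass=np.array([1, -1, 1.0]))
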