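import pytest

from galuferm import (
    ChemostatRecord,
    build_pathway,
    load_default_registry,
    load_lcv1_evidence_map,
    load_table3_fixture,
)


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def table2_record(registry):
    """The published chemostat rates (D = 0.13 1/h) as a record."""
    return ChemostatRecord(
        dilution_rate=0.13,
        rates={"galua": -6.9, "acetate": 6.0, "lactate": 5.2, "co2": 7.2},
        substrate_id="galua",
        registry=registry,
    )


@pytest.fixture(scope="session")
def lcv1_proteome():
    return load_table3_fixture()


@pytest.fixture(scope="session")
def lcv1_map():
    return load_lcv1_evidence_map()


@pytest.fixture(scope="session")
def all_variants():
    return {name: build_pathway(name)
            for name in ("canonical_isomerase", "canonical_isomerase_plus_pdh",
                         "phosphoketolase", "hybrid_isomerase_pk")}
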