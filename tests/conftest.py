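"""Shared fixtures: terminology store, MDR, forged registry, contexts.

Everything is generated programmatically from the shipped data files;
module-scoped where construction is not trivially cheap.
"""

from __future__ import annotations

import pytest

from fhirqc import (ClassificationContext, SiteConfig, forge_package,
                    generate_site, load_bfarm_units, load_mdr,
                    load_terminology, mdr_by_loinc, run_pipeline)
from fhirqc.fixtures import INHOUSE_FLAGS_CS


@pytest.fixture(scope="session")
def store():
    return load_terminology()


@pytest.fixture(scope="session")
def mdr():
    return load_mdr()


@pytest.fixture(scope="session")
def bfarm():
    return load_bfarm_units()


@pytest.fixture(scope="session")
def forged(store, mdr):
    """(registry, substitution map) with the general ValueSet reduced."""
    return forge_package(mdr, store=store)


@pytest.fixture(scope="session")
def registry(forged):
    return forged[0]


@pytest.fixture(scope="session")
def substitution(forged):
    return forged[1]


@pytest.fixture()
def ctx(store, mdr, bfarm):
    return ClassificationContext(
        mdr=mdr_by_loinc(mdr),
        bfarm_list=bfarm,
        store=store,
        invalid_concepts=frozenset({(INHOUSE_FLAGS_CS, "invalid"),
                                    (INHOUSE_FLAGS_CS, "not-measurable")}),
        site_id="test-site",
    )


@pytest.fixture(scope="session")
def clean_site(store, mdr, registry):
    cfg = SiteConfig(site_id="clean", seed=11)
    return generate_site(cfg, mdr, registry, store)


def make_observation(loinc="718-7", value=13.4, unit="g/dL"):
    """A conformant quantitative lab observation claiming the CDS profile."""
    from fhirqc import CDS_PROFILE_BY_TYPE, systems

    return {
        "resourceType": "Observation",
        "id": "obs-fixture-1",
        "meta": {"profile": [CDS_PROFILE_BY_TYPE["Observation"]]},
        "status": "final",
        "category": [{"coding": [{"system": systems.OBSERVATION_CATEGORY,
                                  "code": "laboratory"}]}],
        "code": {"coding": [{"system": systems.LOINC, "code": loinc}]},
        "subject": {"reference": "Patient/p1"},
        "effectiveDateTime": "2022-05-01",
        "valueQuantity": {"value": value, "unit": unit,
                          "system": systems.UCUM, "code": unit},
    }


@pytest.fixture()
def observation():
    return make_observation()


def run_site_pipeline(resources, registry, substitution, store, ctx,
                      seed=1, cap=500):
    return run_pipeline(resources, registry, substitution, store, ctx,
                        cap=cap, seed=seed)
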