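"""Discrepancy classification: taxonomy mapping, consent closure, forms."""

import pytest

from fhirqc import baseline, systems
from fhirqc.classifier import (DiscrepancyCategory, classify_issues,
                               classify_resource, consent_closure_check,
                               medication_form, record_from_dict,
                               record_to_dict)
from fhirqc.fixtures import INHOUSE_FLAGS_CS
from fhirqc.profiles import resolve_chain
from fhirqc.validator import validate_resource

from tests.conftest import make_observation

D = DiscrepancyCategory


def classify_observation(observation, registry, substitution, store, ctx):
    url = substitution.resolve(baseline.CDS_LAB_OBSERVATION, observation)
    issues = validate_resource(observation, resolve_chain(url, registry),
                               store)
    return classify_issues(observation, issues, ctx)


class TestIssueMapping:
    def test_zero_issues_zero_records(self, observation, ctx):
        assert classify_issues(observation, [], ctx) == []

    def test_missing_status_is_missing_mandatory(self, registry,
                                                 substitution, store, ctx):
        observation = make_observation()
        del observation["status"]
        records = classify_observation(observation, registry, substitution,
                                       store, ctx)
        assert [r.category for r in records] == [D.MISSING_MANDATORY]

    def test_case_variant_unit(self, registry, substitution, store, ctx):
        observation = make_observation(unit="g/dL")
        observation["valueQuantity"]["code"] = "g/dl"
        records = classify_observation(observation, registry, substitution,
                                       store, ctx)
        assert len(records) == 1
        record = records[0]
        assert record.category is D.UNIT_DISCREPANCY
        assert record.unit_class.category.value == "CASE_VARIANT"
        assert record.loinc == "718-7"

    def test_invalid_measurement_coding_on_quantitative_code(
            self, registry, substitution, store, ctx):
        observation = make_observation()
        del observation["valueQuantity"]
        observation["valueCodeableConcept"] = {"coding": [{
            "system": INHOUSE_FLAGS_CS, "code": "invalid"}]}
        records = classify_observation(observation, registry, substitution,
                                       store, ctx)
        assert [r.category for r in records] == [D.SCALE_QUAL_FOR_QUANT]
        assert records[0].invalid_measurement_flag

    def test_loinc_missing_from_mdr_is_reported_not_dropped(
            self, registry, substitution, store, ctx):
        observation = make_observation(loinc="99999-9")
        del observation["valueQuantity"]
        observation["valueCodeableConcept"] = {"coding": [{
            "system": INHOUSE_FLAGS_CS, "code": "invalid"}]}
        # no per-LOINC FDPG profile exists; validate against CDS directly
        issues = validate_resource(
            observation, resolve_chain(baseline.CDS_LAB_OBSERVATION,
                                       registry), store)
        records = classify_issues(observation, issues, ctx)
        # CDS requires valueQuantity.code/system only under valueQuantity;
        # with a concept value the CDS chain itself is satisfied
        assert all(r.category is not D.SCALE_QUAL_FOR_QUANT
                   for r in records)

    def test_procedure_category_special_case(self, registry, substitution,
                                             store, ctx):
        resource = {
            "resourceType": "Procedure", "id": "pr1", "status": "completed",
            "code": {"coding": [{"system": systems.OPS, "code": "5-470"}]},
            "subject": {"reference": "Patient/p"},
            "performedDateTime": "2022-01-01",
        }
        url = substitution.static[baseline.CDS_PROCEDURE]
        issues = validate_resource(resource, resolve_chain(url, registry),
                                   store)
        records = classify_issues(resource, issues, ctx)
        assert {r.category for r in records} == {D.MISSING_PROCEDURE_CATEGORY}

    def test_lexical_system_variant_is_wrong_system_url(
            self, registry, substitution, store, ctx):
        resource = {
            "resourceType": "Condition", "id": "c1",
            "code": {"coding": [{
                "system": "https://fhir.de/CodeSystem/bfarm/icd-10-gm",
                "code": "E11.9"}]},
            "subject": {"reference": "Patient/p"},
        }
        url = substitution.static[baseline.CDS_CONDITION]
        issues = validate_resource(resource, resolve_chain(url, registry),
                                   store)
        records = classify_issues(resource, issues, ctx)
        assert [r.category for r in records] == [D.WRONG_SYSTEM_URL]

    def test_genuinely_missing_coding_is_missing_mandatory(
            self, registry, substitution, store, ctx):
        resource = {
            "resourceType": "Condition", "id": "c2",
            "code": {"coding": [{"system": systems.SNOMED,
                                 "code": "73211009"}]},
            "subject": {"reference": "Patient/p"},
        }
        url = substitution.static[baseline.CDS_CONDITION]
        issues = validate_resource(resource, resolve_chain(url, registry),
                                   store)
        records = classify_issues(resource, issues, ctx)
        assert [r.category for r in records] == [D.MISSING_MANDATORY]

    def test_totality_one_record_per_error_issue(self, registry,
                                                 substitution, store, ctx):
        observation = make_observation(unit="g/dL")
        del observation["status"]
        observation["valueQuantity"]["code"] = "mmol/L"
        url = substitution.resolve(baseline.CDS_LAB_OBSERVATION, observation)
        issues = validate_resource(observation,
                                   resolve_chain(url, registry), store)
        errors = [i for i in issues if i.severity == "error"]
        records = classify_issues(observation, issues, ctx)
        assert len(records) == len(errors) == 2

    def test_classification_is_pure(self, registry, substitution, store,
                                    ctx):
        observation = make_observation(unit="g/dL")
        observation["valueQuantity"]["code"] = "g/l"
        first = classify_observation(observation, registry, substitution,
                                     store, ctx)
        second = classify_observation(observation, registry, substitution,
                                      store, ctx)
        assert first == second


def consent_resource(codes, foreign=()):
    provisions = [{"code": [{"coding": [{
        "system": systems.MII_CONSENT_POLICY, "code": code}]}]}
        for code in codes]
    provisions += [{"code": [{"coding": [{
        "system": systems.GICS_POLICY, "code": code}]}]}
        for code in foreign]
    return {
        "resourceType": "Consent", "id": "consent-1", "status": "active",
        "scope": {"coding": [{"code": "research"}]},
        "category": [{"coding": [{"code": "59284-0"}]}],
        "patient": {"reference": "Patient/p"},
        "provision": {"type": "permit", "provision": provisions},
    }


PARENT = "PATDAT_erheben_speichern_nutzen"
CHILDREN = ("IDAT_erheben", "IDAT_speichern_verarbeiten", "MDAT_erheben",
            "MDAT_speichern_verarbeiten", "MDAT_wissenschaftlich_nutzen")


class TestConsentClosure:
    def policy(self, store):
        return store.systems[systems.MII_CONSENT_POLICY]

    def test_full_closure_is_clean(self, store):
        resource = consent_resource((PARENT, *CHILDREN))
        assert consent_closure_check(resource, self.policy(store),
                                     store) == []

    def test_only_encompassing_code_is_a_gap(self, store):
        resource = consent_resource((PARENT,))
        records = consent_closure_check(resource, self.policy(store), store)
        assert [r.category for r in records] == [D.CONSENT_HIERARCHY_GAP]
        assert set(records[0].expected.split(",")) == set(CHILDREN)

    def test_partial_closure_lists_only_missing(self, store):
        resource = consent_resource((PARENT, *CHILDREN[:2]))
        records = consent_closure_check(resource, self.policy(store), store)
        assert set(records[0].expected.split(",")) == set(CHILDREN[2:])

    def test_foreign_provisions_are_informational(self, store):
        resource = consent_resource((PARENT, *CHILDREN),
                                    foreign=("gics-policy-x",))
        records = consent_closure_check(resource, self.policy(store), store)
        assert [r.category for r in records] == [D.FOREIGN_PROVISION_CODES]
        assert records[0].severity == "information"

    def test_required_code_restriction(self, store):
        resource = consent_resource((PARENT,))
        records = consent_closure_check(
            resource, self.policy(store), store,
            required_codes=frozenset({"MDAT_erheben"}))
        assert records[0].expected == "MDAT_erheben"


class TestMedicationForm:
    @pytest.mark.parametrize("resource_type, key, supported", [
        ("MedicationAdministration", "medicationReference", True),
        ("MedicationAdministration", "medicationCodeableConcept", False),
        ("MedicationRequest", "medicationReference", False),
        ("MedicationRequest", "medicationCodeableConcept", False),
        ("MedicationStatement", "medicationReference", False),
        ("MedicationStatement", "medicationCodeableConcept", False),
    ])
    def test_six_forms_one_supported(self, resource_type, key, supported):
        resource = {"resourceType": resource_type, "id": "m",
                    key: {"reference": "Medication/x"}
                    if key == "medicationReference"
                    else {"coding": [{"system": systems.ATC,
                                      "code": "B01AC06"}]}}
        form = medication_form(resource)
        assert form.supported is supported

    def test_non_medication_resource_raises(self):
        with pytest.raises(TypeError):
            medication_form({"resourceType": "Observation"})

    def test_unsupported_form_yields_record_downstream(self, ctx):
        resource = {"resourceType": "MedicationStatement", "id": "m",
                    "medicationCodeableConcept": {"coding": []}}
        records = classify_resource(resource, [], ctx)
        assert [r.category for r in records] == [D.MEDICATION_FORM_UNSUPPORTED]


class TestRecordSerialization:
    def test_round_trip(self, registry, substitution, store, ctx):
        observation = make_observation(unit="g/dL")
        observation["valueQuantity"]["code"] = "mg/dL"
        records = classify_observation(observation, registry, substitution,
                                       store, ctx)
        for record in records:
            assert record_from_dict(record_to_dict(record)) == record
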