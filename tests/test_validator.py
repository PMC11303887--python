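"""Validator: layer-attributed issues, sampling, substitution."""

import copy

import pytest

from fhirqc import baseline, systems
from fhirqc.profiles import Layer, resolve_chain
from fhirqc.validator import (ConstraintKind, EmptyStoreWarning,
                              TypeMismatchError, sample_instances,
                              substitute_profiles, validate_resource)



def issue_tuples(issues):
    return [(i.path, i.constraint_kind.value, i.origin_layer.name)
            for i in issues]


@pytest.fixture()
def lab_chain(registry, substitution):
    return resolve_chain(substitution.lab_by_loinc["718-7"], registry)


class TestValidateResource:
    def test_conforming_observation_has_no_issues(self, observation,
                                                  lab_chain, store):
        assert validate_resource(observation, lab_chain, store) == []

    def test_missing_status_is_base_layer_cardinality(self, observation,
                                                      lab_chain, store):
        del observation["status"]
        issues = validate_resource(observation, lab_chain, store)
        assert issue_tuples(issues) == \
            [("status", "CARDINALITY", "FHIR_BASE")]

    def test_missing_medication_administration_status(self, registry,
                                                      substitution, store):
        resource = {
            "resourceType": "MedicationAdministration", "id": "m1",
            "medicationReference": {"reference": "Medication/x"},
            "subject": {"reference": "Patient/p"},
            "effectiveDateTime": "2022-01-01",
            "dosage": {"dose": {"value": 1, "unit": "mg",
                                "system": systems.UCUM, "code": "mg"}},
        }
        url = substitution.static[baseline.CDS_MEDICATION_ADMINISTRATION]
        issues = validate_resource(resource, resolve_chain(url, registry),
                                   store)
        assert ("status", "CARDINALITY", "FHIR_BASE") in issue_tuples(issues)

    def test_procedure_without_snomed_category(self, registry, substitution,
                                               store):
        resource = {
            "resourceType": "Procedure", "id": "pr1", "status": "completed",
            "code": {"coding": [{"system": systems.OPS, "code": "5-470"}]},
            "subject": {"reference": "Patient/p"},
            "performedDateTime": "2022-01-01",
        }
        url = substitution.static[baseline.CDS_PROCEDURE]
        issues = validate_resource(resource, resolve_chain(url, registry),
                                   store)
        kinds = {(i.path, i.constraint_kind) for i in issues}
        assert ("category", ConstraintKind.CARDINALITY) in kinds

    def test_misspelled_system_url_fails_the_slice(self, registry,
                                                   substitution, store):
        resource = {
            "resourceType": "Condition", "id": "c1",
            "code": {"coding": [{
                "system": "http://fhir.de/CodeSystem/dimdi/icd-10-gm",
                "code": "E11.9"}]},
            "subject": {"reference": "Patient/p"},
        }
        url = substitution.static[baseline.CDS_CONDITION]
        issues = validate_resource(resource, resolve_chain(url, registry),
                                   store)
        assert ("code.coding:icd10-gm", "SLICE", "FDPG") in \
            issue_tuples(issues)

    def test_non_ucum_dose_system_contradicts_fixed_uri(self, registry,
                                                        substitution, store):
        resource = {
            "resourceType": "MedicationAdministration", "id": "m2",
            "status": "completed",
            "medicationReference": {"reference": "Medication/x"},
            "subject": {"reference": "Patient/p"},
            "effectiveDateTime": "2022-01-01",
            "dosage": {"dose": {"value": 1, "unit": "tablet",
                                "system": systems.SNOMED,
                                "code": "428673006"}},
        }
        url = substitution.static[baseline.CDS_MEDICATION_ADMINISTRATION]
        issues = validate_resource(resource, resolve_chain(url, registry),
                                   store)
        fixed = [i for i in issues
                 if i.constraint_kind is ConstraintKind.FIXED]
        assert fixed and fixed[0].path == "dosage.dose.system"
        assert fixed[0].origin_layer is Layer.CDS

    def test_case_only_binding_carries_machine_readable_flag(
            self, registry, substitution, store):
        resource = {
            "resourceType": "Procedure", "id": "pr2", "status": "completed",
            "category": {"coding": [{"system": systems.SNOMED,
                                     "code": "387713003"}]},
            "code": {"coding": [{"system": systems.OPS, "code": "5-470A"}]},
            "subject": {"reference": "Patient/p"},
            "performedDateTime": "2022-01-01",
        }
        url = substitution.static[baseline.CDS_PROCEDURE]
        issues = validate_resource(resource, resolve_chain(url, registry),
                                   store)
        binding = [i for i in issues
                   if i.constraint_kind is ConstraintKind.BINDING]
        assert len(binding) == 1
        assert binding[0].case_only
        assert binding[0].severity == "error"

    def test_wrong_value_type_attributed_to_the_restricting_layer(
            self, observation, lab_chain, store):
        del observation["valueQuantity"]
        observation["valueCodeableConcept"] = {
            "coding": [{"system": systems.SNOMED, "code": "2667000"}]}
        issues = validate_resource(observation, lab_chain, store)
        assert issue_tuples(issues) == [("value[x]", "TYPE", "FDPG")]

    def test_resource_type_mismatch(self, lab_chain, store):
        with pytest.raises(TypeMismatchError):
            validate_resource({"resourceType": "Condition"}, lab_chain,
                              store)

    def test_issue_lists_are_order_stable(self, observation, lab_chain,
                                          store):
        del observation["status"]
        observation["valueQuantity"]["code"] = "g/l"
        first = validate_resource(observation, lab_chain, store)
        second = validate_resource(observation, lab_chain, store)
        assert first == second
        assert [i.path for i in first] == sorted(i.path for i in first)

    def test_display_checking_is_off_by_default_and_warns_when_on(
            self, registry, substitution, store):
        resource = {
            "resourceType": "Procedure", "id": "pr3", "status": "completed",
            "category": {"coding": [{"system": systems.SNOMED,
                                     "code": "387713003"}]},
            "code": {"coding": [{"system": systems.OPS, "code": "5-470",
                                 "display": "A home-grown display"}]},
            "subject": {"reference": "Patient/p"},
            "performedDateTime": "2022-01-01",
        }
        url = substitution.static[baseline.CDS_PROCEDURE]
        chain = resolve_chain(url, registry)
        assert validate_resource(resource, chain, store) == []
        with_display = validate_resource(resource, chain, store,
                                         check_display=True)
        assert [i.severity for i in with_display] == ["warning"]


class TestLayerConsistency:
    def test_cds_subset_equals_cds_alone(self, mdr, registry, substitution,
                                         store):
        """Issues attributed at or below CDS by the full chain equal the
        issues of validating the CDS profile alone (clean + defective)."""
        from fhirqc import SiteConfig, generate_site

        cfg = SiteConfig.uniform("layercheck", 0.5, seed=3)
        resources, _ = generate_site(cfg, mdr, registry, store)
        cds_chains = {}
        checked = 0
        for resource in resources:
            claimed = resource["meta"]["profile"][0]
            target = substitution.resolve(claimed, resource)
            if target not in registry or resource["resourceType"] == \
                    "Patient":
                continue
            full = validate_resource(resource,
                                     resolve_chain(target, registry), store)
            if claimed not in cds_chains:
                cds_chains[claimed] = resolve_chain(claimed, registry)
            cds_only = validate_resource(resource, cds_chains[claimed],
                                         store)
            assert [i for i in full if i.origin_layer <= Layer.CDS] == \
                cds_only
            checked += 1
        assert checked >= 100


class TestSampler:
    def make_store(self, n, url="profile-url"):
        return [{"resourceType": "Observation", "id": f"r{i:05d}",
                 "meta": {"profile": [url]}} for i in range(n)]

    def test_cap_is_enforced(self):
        sample = sample_instances(self.make_store(1200), "profile-url",
                                  cap=500, seed=9)
        assert len(sample.instances) == 500
        assert sample.total_available == 1200

    def test_under_cap_takes_all(self):
        sample = sample_instances(self.make_store(3), "profile-url",
                                  cap=500, seed=9)
        assert len(sample.instances) == 3

    def test_same_seed_same_ids(self):
        store = self.make_store(2000)
        first = sample_instances(store, "profile-url", cap=100, seed=5)
        second = sample_instances(store, "profile-url", cap=100, seed=5)
        assert first.ids == second.ids
        third = sample_instances(store, "profile-url", cap=100, seed=6)
        assert first.ids != third.ids

    def test_empty_store_warns_not_raises(self):
        with pytest.warns(EmptyStoreWarning):
            sample = sample_instances([], "profile-url", cap=10, seed=0)
        assert sample.instances == []


class TestSubstituteProfiles:
    def test_mapped_claim_is_swapped(self):
        resource = {"id": "x", "meta": {"profile": ["a", "b"]}}
        out = substitute_profiles(resource, {"a": "A"})
        assert out["meta"]["profile"] == ["A", "b"]

    def test_original_is_untouched(self):
        resource = {"id": "x", "meta": {"profile": ["a"]}}
        copy_before = copy.deepcopy(resource)
        substitute_profiles(resource, {"a": "A"})
        assert resource == copy_before

    def test_resource_without_meta_profile_is_unchanged(self):
        assert substitute_profiles({"id": "x"}, {"a": "A"}) == {"id": "x"}
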