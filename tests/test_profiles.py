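"""Profile model: StructureDefinition import/export, chains, narrowing."""

import pytest

from fhirqc import baseline, systems
from fhirqc.profiles import (Binding, CycleError, DuplicateUrlError,
                             ElementConstraint, Layer, MissingBaseError,
                             ProfileDefinition, ProfileError,
                             ProfileRegistry, check_narrowing,
                             load_structure_definition, resolve_chain,
                             write_structure_definition)


def minimal_sd(url="https://example.org/fhir/cds/StructureDefinition/p1",
               base="http://hl7.org/fhir/StructureDefinition/Observation",
               elements=()):
    return {
        "resourceType": "StructureDefinition",
        "url": url,
        "name": "P1",
        "type": "Observation",
        "baseDefinition": base,
        "differential": {"element": [{"id": "Observation",
                                      "path": "Observation"}, *elements]},
    }


class TestLoad:
    def test_single_element_import(self):
        profile = load_structure_definition(minimal_sd(elements=[
            {"id": "Observation.status", "path": "Observation.status",
             "min": 1}]), layer=Layer.CDS)
        assert len(profile.constraints) == 1
        constraint = profile.constraints[0]
        assert constraint.path == "status"
        assert constraint.min == 1

    def test_code_value_interdependency_profile(self):
        """A per-code lab profile: coding slice plus fixed quantity unit."""
        document = minimal_sd(elements=[
            {"id": "Observation.code.coding", "path":
             "Observation.code.coding",
             "slicing": {"discriminator": [{"type": "pattern",
                                            "path": "$this"}]}, "min": 1},
            {"id": "Observation.code.coding:loinc",
             "path": "Observation.code.coding", "sliceName": "loinc",
             "min": 1, "max": "1",
             "patternCoding": {"system": systems.LOINC, "code": "4548-4"}},
            {"id": "Observation.valueQuantity.system",
             "path": "Observation.valueQuantity.system",
             "fixedUri": systems.UCUM},
            {"id": "Observation.valueQuantity.code",
             "path": "Observation.valueQuantity.code",
             "fixedCode": "mmol/mol"},
        ], url="https://example.org/fhir/fdpg/StructureDefinition/lab")
        profile = load_structure_definition(document)
        assert profile.layer is Layer.FDPG  # inferred from the URL
        slice_constraint = profile.constraint("code.coding:loinc")
        assert slice_constraint.pattern == {"system": systems.LOINC,
                                            "code": "4548-4"}
        assert profile.constraint("valueQuantity.code").fixed == "mmol/mol"

    def test_fhirpath_invariants_go_to_import_report(self):
        document = minimal_sd(elements=[
            {"id": "Observation.value[x]", "path": "Observation.value[x]",
             "constraint": [{"key": "obs-7",
                             "expression": "value.exists()"}]}])
        profile = load_structure_definition(document, layer=Layer.CDS)
        assert any("obs-7" in line for line in profile.import_report)

    def test_missing_url_or_type_is_an_import_error(self):
        document = minimal_sd()
        del document["url"]
        with pytest.raises(ProfileError):
            load_structure_definition(document)

    def test_fixed_and_pattern_are_mutually_exclusive(self):
        with pytest.raises(ProfileError):
            ElementConstraint(path="x", fixed="a", pattern={"b": 1})


class TestRoundTrip:
    def test_writer_loader_preserve_effective_constraints(self, registry):
        for url in registry.urls():
            original = registry.get(url)
            reloaded = load_structure_definition(
                write_structure_definition(original), layer=original.layer)
            fresh = ProfileRegistry()
            for other in registry.profiles.values():
                fresh.register(other if other.url != url else reloaded)
            before = resolve_chain(url, registry).effective
            after = resolve_chain(url, fresh).effective
            assert set(before) == set(after)
            for path, element in before.items():
                got = after[path]
                for facet, value in element.facets.items():
                    assert got.facets[facet].value == value.value, \
                        f"{url} {path} {facet}"


class TestResolveChain:
    def test_core_only_chain(self, registry):
        chain = resolve_chain(f"{baseline.HL7_BASE}/Observation", registry)
        assert [p.layer for p in chain.profiles] == [Layer.FHIR_BASE]

    def test_three_level_lab_chain(self, registry, substitution):
        url = substitution.lab_by_loinc["718-7"]
        chain = resolve_chain(url, registry)
        assert [p.layer for p in chain.profiles] == \
            [Layer.FHIR_BASE, Layer.CDS, Layer.FDPG]

    def test_facet_origin_is_the_introducing_layer(self, registry,
                                                   substitution):
        chain = resolve_chain(substitution.lab_by_loinc["718-7"], registry)
        # status min=1 comes from the FHIR base resource, restated nowhere
        assert chain.effective["status"].facets["min"].origin_layer \
            is Layer.FHIR_BASE
        # the fixed quantity code is introduced by the leaf profile
        assert chain.effective["valueQuantity.code"].facets["fixed"] \
            .origin_layer is Layer.FDPG

    def test_missing_base(self):
        registry = ProfileRegistry()
        registry.register(ProfileDefinition(
            url="u", name="u", resource_type="Observation", layer=Layer.CDS,
            base_url="missing"))
        with pytest.raises(MissingBaseError):
            resolve_chain("u", registry)

    def test_cycle(self):
        registry = ProfileRegistry()
        registry.register(ProfileDefinition(
            url="a", name="a", resource_type="Observation", layer=Layer.CDS,
            base_url="b"))
        registry.register(ProfileDefinition(
            url="b", name="b", resource_type="Observation", layer=Layer.CDS,
            base_url="a"))
        with pytest.raises(CycleError):
            resolve_chain("a", registry)

    def test_duplicate_registration(self, registry):
        with pytest.raises(DuplicateUrlError):
            registry.register(registry.get(f"{baseline.HL7_BASE}/Patient"))


def two_layer(base_constraints, derived_constraints):
    registry = ProfileRegistry()
    registry.register(ProfileDefinition(
        url="base", name="base", resource_type="Observation",
        layer=Layer.CDS, base_url=None, constraints=base_constraints))
    registry.register(ProfileDefinition(
        url="leaf", name="leaf", resource_type="Observation",
        layer=Layer.FDPG, base_url="base",
        constraints=derived_constraints))
    return resolve_chain("leaf", registry)


class TestCheckNarrowing:
    def test_well_formed_chain_is_clean(self, registry, substitution):
        for url in substitution.lab_by_loinc.values():
            assert check_narrowing(resolve_chain(url, registry)) == []

    def test_lowered_min_is_a_widening(self):
        chain = two_layer(
            [ElementConstraint(path="status", min=1)],
            [ElementConstraint(path="status", min=0)])
        violations = check_narrowing(chain)
        assert [v["facet"] for v in violations] == ["min"]

    def test_added_choice_type_is_a_widening(self):
        chain = two_layer(
            [ElementConstraint(path="value[x]", types=("Quantity",))],
            [ElementConstraint(path="value[x]",
                               types=("Quantity", "string"))])
        assert [v["facet"] for v in check_narrowing(chain)] == ["types"]

    def test_weakened_binding_is_a_widening(self):
        chain = two_layer(
            [ElementConstraint(path="valueCodeableConcept",
                               binding=Binding("vs", "required"))],
            [ElementConstraint(path="valueCodeableConcept",
                               binding=Binding("vs", "extensible"))])
        assert [v["facet"] for v in check_narrowing(chain)] == ["binding"]

    def test_effective_merge_keeps_most_constrained(self):
        chain = two_layer(
            [ElementConstraint(path="category", min=1, max=5,
                               max_stated=True)],
            [ElementConstraint(path="category", min=2, max=3,
                               max_stated=True)])
        element = chain.effective["category"]
        assert element.facet_value("min") == 2
        assert element.facet_value("max") == 3
        assert element.facets["min"].origin_url == "leaf"
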