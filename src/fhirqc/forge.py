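"""Forge of use-case-constrained (FDPG-layer) profiles.

Two families are produced on top of the CDS layer:

* one laboratory profile per LOINC code, encoding the code–value
  interdependency from the MDR table: the LOINC coding slice is pinned
  to the specific code, and the value is restricted to a Quantity with
  the one expected UCUM unit (quantitative) or to a CodeableConcept
  bound to the answer list / reduced general ValueSet (qualitative);
* one coded-module profile per resource type, mandating a coding from
  the respective national code system plus a technical patient
  reference.

Profile URLs are deterministic functions of the inputs (base URI plus
LOINC code or module name), which makes the CDS→FDPG substitution map
trivial to audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import baseline, systems
from .fixtures import (GENERAL_QUALITATIVE_VS, MdrEntry, SPECIMEN_TOP50_VS,
                       load_equivalence_map)
from .profiles import (Binding, DuplicateUrlError, ElementConstraint, Layer,
                       ProfileDefinition, ProfileRegistry, Slicing)
from .terminology import TerminologyStore, reduce_equivalents
from .ucum import ParseError, parse_unit

FDPG_BASE = "https://www.medizininformatik-initiative.de/fhir/fdpg"


class ForgeError(ValueError):
    pass


@dataclass(frozen=True)
class ModuleSpec:
    """Blueprint for one coded-module profile.

    ``required_system`` is the national code system a coding must come
    from (absent for modules whose coding lives on a referenced
    resource, e.g. MedicationAdministration pointing at a Medication);
    ``code_path`` is the CodeableConcept element carrying it.
    ``code_subset`` optionally restricts codes to a ValueSet (e.g. the
    top-50 specimen codes).
    """

    resource_type: str
    cds_base: str
    required_system: str | None = None
    code_path: str = "code"
    slice_name: str = "module"
    code_subset: str | None = None
    require_patient_reference: bool = True
    patient_path: str = "subject"


def lab_profile_url(loinc: str) -> str:
    return f"{FDPG_BASE}/StructureDefinition/ObservationLab-{loinc}"


def module_profile_url(resource_type: str) -> str:
    return f"{FDPG_BASE}/StructureDefinition/{resource_type}"


def forge_lab_profile(entry: MdrEntry,
                      cds_base: str = baseline.CDS_LAB_OBSERVATION,
                      general_vs: str = GENERAL_QUALITATIVE_VS
                      ) -> ProfileDefinition:
    """Per-LOINC laboratory profile with code–value interdependency."""
    if entry.scale == "QUANTITATIVE":
        try:
            parse_unit(entry.ucum_unit)
        except ParseError as exc:
            raise ForgeError(
                f"MDR unit {entry.ucum_unit!r} for {entry.loinc} does not "
                f"parse: {exc}") from exc
    constraints = [
        ElementConstraint(
            path="code.coding:loinc", min=1, max=1, max_stated=True,
            pattern={"system": systems.LOINC, "code": entry.loinc},
            pattern_type="Coding"),
        ElementConstraint(path="subject", min=1, types=("Reference",),
                          ref_targets=("Patient",)),
    ]
    if entry.scale == "QUANTITATIVE":
        constraints += [
            ElementConstraint(path="value[x]", types=("Quantity",)),
            ElementConstraint(path="valueQuantity.system", min=1,
                              fixed=systems.UCUM, fixed_type="Uri"),
            ElementConstraint(path="valueQuantity.code", min=1,
                              fixed=entry.ucum_unit, fixed_type="Code"),
        ]
    else:
        valueset = entry.answer_vs or general_vs
        constraints += [
            ElementConstraint(path="value[x]", types=("CodeableConcept",)),
            ElementConstraint(path="valueCodeableConcept",
                              binding=Binding(valueset=valueset,
                                              strength="required")),
        ]
    return ProfileDefinition(
        url=lab_profile_url(entry.loinc),
        name=f"ObservationLab{entry.loinc.replace('-', '')}",
        resource_type="Observation",
        layer=Layer.FDPG,
        base_url=cds_base,
        constraints=constraints,
    )


def forge_coded_profile(spec: ModuleSpec) -> ProfileDefinition:
    """Coded-module profile: required system coding + patient reference."""
    constraints: list[ElementConstraint] = []
    if spec.required_system is not None:
        slice_path = f"{spec.code_path}.coding:{spec.slice_name}"
        binding = None
        if spec.code_subset is not None:
            binding = Binding(valueset=spec.code_subset, strength="required")
        constraints += [
            ElementConstraint(
                path=f"{spec.code_path}.coding", min=1,
                slicing=Slicing(discriminator_path="$this",
                                discriminator_type="pattern")),
            ElementConstraint(
                path=slice_path, min=1,
                pattern={"system": spec.required_system},
                pattern_type="Coding", binding=binding),
        ]
    if spec.require_patient_reference:
        constraints.append(ElementConstraint(
            path=spec.patient_path, min=1, types=("Reference",),
            ref_targets=("Patient",)))
    return ProfileDefinition(
        url=module_profile_url(spec.resource_type),
        name=f"Fdpg{spec.resource_type}",
        resource_type=spec.resource_type,
        layer=Layer.FDPG,
        base_url=spec.cds_base,
        constraints=constraints,
    )


def default_module_specs() -> list[ModuleSpec]:
    """The module blueprints matching the feasibility portal's coverage."""
    return [
        ModuleSpec(resource_type="Condition", cds_base=baseline.CDS_CONDITION,
                   required_system=systems.ICD10GM, slice_name="icd10-gm"),
        ModuleSpec(resource_type="Procedure", cds_base=baseline.CDS_PROCEDURE,
                   required_system=systems.OPS, slice_name="ops",
                   code_subset="https://fhirqc.example.org/fhir/ValueSet/ops-all"),
        ModuleSpec(resource_type="Medication",
                   cds_base=baseline.CDS_MEDICATION,
                   required_system=systems.ATC, slice_name="atc",
                   require_patient_reference=False),
        ModuleSpec(resource_type="MedicationAdministration",
                   cds_base=baseline.CDS_MEDICATION_ADMINISTRATION),
        ModuleSpec(resource_type="Consent", cds_base=baseline.CDS_CONSENT,
                   patient_path="patient"),
        ModuleSpec(resource_type="Specimen", cds_base=baseline.CDS_SPECIMEN,
                   required_system=systems.SNOMED, code_path="type",
                   slice_name="sct", code_subset=SPECIMEN_TOP50_VS),
    ]


@dataclass
class SubstitutionMap:
    """CDS→FDPG profile-identifier substitution.

    Module substitutions are a plain URL map.  The laboratory module is
    code-dependent: every lab observation claims the same CDS profile,
    but the FDPG target is the per-LOINC profile, selected from the
    instance's LOINC coding.
    """

    static: dict[str, str] = field(default_factory=dict)
    cds_lab_url: str | None = None
    lab_by_loinc: dict[str, str] = field(default_factory=dict)

    def resolve(self, url: str, resource: Mapping | None = None) -> str:
        if url == self.cds_lab_url and resource is not None:
            for coding in (resource.get("code", {}) or {}).get("coding", ()):
                if coding.get("system") == systems.LOINC:
                    target = self.lab_by_loinc.get(coding.get("code", ""))
                    if target:
                        return target
            return url
        return self.static.get(url, url)

    def items(self):
        return self.static.items()

    def as_rows(self) -> list[tuple[str, str]]:
        rows = sorted(self.static.items())
        rows += sorted((self.cds_lab_url, url)
                       for url in self.lab_by_loinc.values())
        return rows


def forge_package(mdr: Iterable[MdrEntry],
                  specs: Iterable[ModuleSpec] | None = None,
                  store: TerminologyStore | None = None,
                  equivalence_map: Mapping[str, str] | None = None
                  ) -> tuple[ProfileRegistry, SubstitutionMap]:
    """Forge the full FDPG package over the baseline layers.

    Returns a registry holding core + CDS + forged FDPG profiles, and
    the substitution map covering every CDS base used.  When a
    terminology store is given, the general-purpose qualitative ValueSet
    is reduced in place via the equivalence map before any qualitative
    fallback profile binds to it.
    """
    specs = default_module_specs() if specs is None else list(specs)
    registry = baseline.baseline_registry()
    substitution = SubstitutionMap(cds_lab_url=baseline.CDS_LAB_OBSERVATION)

    if store is not None and GENERAL_QUALITATIVE_VS in store.valuesets:
        mapping = (load_equivalence_map() if equivalence_map is None
                   else equivalence_map)
        store.add_valueset(reduce_equivalents(
            store.valuesets[GENERAL_QUALITATIVE_VS], mapping))

    for entry in mdr:
        profile = forge_lab_profile(entry)
        try:
            registry.register(profile)
        except DuplicateUrlError:
            raise DuplicateUrlError(
                f"duplicate MDR entry for LOINC {entry.loinc}") from None
        substitution.lab_by_loinc[entry.loinc] = profile.url
    for spec in specs:
        profile = forge_coded_profile(spec)
        registry.register(profile)
        substitution.static[spec.cds_base] = profile.url
    return registry, substitution
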