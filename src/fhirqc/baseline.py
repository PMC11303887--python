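"""Baseline profile layers: FHIR core resources and the CDS layer.

The core definitions are a pragmatic subset of the R4 base resources —
just the cardinalities, choice types and reference targets the pipeline
evaluates.  The CDS layer models the nationally agreed core-data-set
profiles this package analyses against: laboratory observations with a
LOINC coding slice and UCUM-coded quantities, diagnosis/procedure/
medication resources with national code-system slices, consent with a
mandatory patient reference, and specimen bound to the SNOMED specimen
subtree.  They are constructed programmatically (not read from the
published packages) and are therefore stand-ins with the same shape,
not the published artifacts.
"""

from __future__ import annotations

from . import systems
from .fixtures import SPECIMEN_ALL_VS
from .profiles import (Binding, ElementConstraint, Layer, ProfileDefinition,
                       ProfileRegistry, Slicing)

HL7_BASE = "http://hl7.org/fhir/StructureDefinition"
CDS_BASE = "https://www.medizininformatik-initiative.de/fhir/core"

CDS_LAB_OBSERVATION = f"{CDS_BASE}/modul-labor/StructureDefinition/ObservationLab"
CDS_CONDITION = f"{CDS_BASE}/modul-diagnose/StructureDefinition/Diagnose"
CDS_PROCEDURE = f"{CDS_BASE}/modul-prozedur/StructureDefinition/Procedure"
CDS_MEDICATION_ADMINISTRATION = (
    f"{CDS_BASE}/modul-medikation/StructureDefinition/MedicationAdministration")
CDS_MEDICATION_REQUEST = (
    f"{CDS_BASE}/modul-medikation/StructureDefinition/MedicationRequest")
CDS_MEDICATION_STATEMENT = (
    f"{CDS_BASE}/modul-medikation/StructureDefinition/MedicationStatement")
CDS_MEDICATION = f"{CDS_BASE}/modul-medikation/StructureDefinition/Medication"
CDS_CONSENT = f"{CDS_BASE}/modul-consent/StructureDefinition/Consent"
CDS_SPECIMEN = f"{CDS_BASE}/modul-biobank/StructureDefinition/Specimen"
CDS_PATIENT = f"{CDS_BASE}/modul-person/StructureDefinition/Patient"


def _ec(path: str, **kwargs) -> ElementConstraint:
    return ElementConstraint(path=path, **kwargs)


def _core(resource_type: str,
          constraints: list[ElementConstraint]) -> ProfileDefinition:
    return ProfileDefinition(
        url=f"{HL7_BASE}/{resource_type}",
        name=resource_type,
        resource_type=resource_type,
        layer=Layer.FHIR_BASE,
        base_url=None,
        constraints=constraints,
    )


def core_profiles() -> list[ProfileDefinition]:
    subject_patient_group = ("Patient", "Group")
    return [
        _core("Patient", []),
        _core("Observation", [
            _ec("status", min=1, max=1, max_stated=True, types=("code",)),
            _ec("category", types=("CodeableConcept",)),
            _ec("code", min=1, max=1, max_stated=True,
                types=("CodeableConcept",)),
            _ec("subject", max=1, max_stated=True, types=("Reference",),
                ref_targets=("Patient", "Group", "Device", "Location")),
            _ec("effective[x]", max=1, max_stated=True,
                types=("dateTime", "Period", "Timing", "instant")),
            _ec("value[x]", max=1, max_stated=True,
                types=("Quantity", "CodeableConcept", "string", "boolean",
                       "integer", "Range", "Ratio", "SampledData", "time",
                       "dateTime", "Period")),
        ]),
        _core("Condition", [
            _ec("code", max=1, max_stated=True, types=("CodeableConcept",)),
            _ec("subject", min=1, max=1, max_stated=True,
                types=("Reference",), ref_targets=subject_patient_group),
            _ec("recordedDate", max=1, max_stated=True, types=("dateTime",)),
        ]),
        _core("Procedure", [
            _ec("status", min=1, max=1, max_stated=True, types=("code",)),
            _ec("category", max=1, max_stated=True,
                types=("CodeableConcept",)),
            _ec("code", max=1, max_stated=True, types=("CodeableConcept",)),
            _ec("subject", min=1, max=1, max_stated=True,
                types=("Reference",), ref_targets=subject_patient_group),
            _ec("performed[x]", max=1, max_stated=True,
                types=("dateTime", "Period", "string", "Age", "Range")),
        ]),
        _core("MedicationAdministration", [
            _ec("status", min=1, max=1, max_stated=True, types=("code",)),
            _ec("medication[x]", min=1, max=1, max_stated=True,
                types=("CodeableConcept", "Reference"),
                ref_targets=("Medication",)),
            _ec("subject", min=1, max=1, max_stated=True,
                types=("Reference",), ref_targets=subject_patient_group),
            _ec("effective[x]", min=1, max=1, max_stated=True,
                types=("dateTime", "Period")),
            _ec("dosage", max=1, max_stated=True),
            _ec("dosage.dose", max=1, max_stated=True, types=("Quantity",)),
        ]),
        _core("MedicationRequest", [
            _ec("status", min=1, max=1, max_stated=True, types=("code",)),
            _ec("intent", min=1, max=1, max_stated=True, types=("code",)),
            _ec("medication[x]", min=1, max=1, max_stated=True,
                types=("CodeableConcept", "Reference"),
                ref_targets=("Medication",)),
            _ec("subject", min=1, max=1, max_stated=True,
                types=("Reference",), ref_targets=subject_patient_group),
        ]),
        _core("MedicationStatement", [
            _ec("status", min=1, max=1, max_stated=True, types=("code",)),
            _ec("medication[x]", min=1, max=1, max_stated=True,
                types=("CodeableConcept", "Reference"),
                ref_targets=("Medication",)),
            _ec("subject", min=1, max=1, max_stated=True,
                types=("Reference",), ref_targets=subject_patient_group),
        ]),
        _core("Medication", [
            _ec("code", max=1, max_stated=True, types=("CodeableConcept",)),
        ]),
        _core("Consent", [
            _ec("status", min=1, max=1, max_stated=True, types=("code",)),
            _ec("scope", min=1, max=1, max_stated=True,
                types=("CodeableConcept",)),
            _ec("category", min=1, types=("CodeableConcept",)),
            _ec("patient", max=1, max_stated=True, types=("Reference",),
                ref_targets=("Patient",)),
            _ec("provision", max=1, max_stated=True),
        ]),
        _core("Specimen", [
            _ec("type", max=1, max_stated=True, types=("CodeableConcept",)),
            _ec("subject", max=1, max_stated=True, types=("Reference",),
                ref_targets=("Patient", "Group", "Device", "Substance",
                             "Location")),
        ]),
    ]


def _cds(url: str, resource_type: str,
         constraints: list[ElementConstraint]) -> ProfileDefinition:
    return ProfileDefinition(
        url=url,
        name=url.rsplit("/", 1)[-1],
        resource_type=resource_type,
        layer=Layer.CDS,
        base_url=f"{HL7_BASE}/{resource_type}",
        constraints=constraints,
    )


def _system_slice(path: str, slice_name: str, system: str,
                  minimum: int = 0) -> list[ElementConstraint]:
    """A pattern-discriminated coding slice pinning a code system."""
    return [
        _ec(path, min=1, slicing=Slicing(discriminator_path="$this",
                                         discriminator_type="pattern")),
        _ec(f"{path}:{slice_name}", min=minimum,
            pattern={"system": system}, pattern_type="Coding"),
    ]


def cds_profiles() -> list[ProfileDefinition]:
    return [
        ProfileDefinition(
            url=CDS_PATIENT, name="Patient", resource_type="Patient",
            layer=Layer.CDS, base_url=f"{HL7_BASE}/Patient", constraints=[]),
        _cds(CDS_LAB_OBSERVATION, "Observation", [
            _ec("category", min=1),
            *_system_slice("code.coding", "loinc", systems.LOINC, minimum=1),
            _ec("subject", min=1, types=("Reference",),
                ref_targets=("Patient",)),
            _ec("effective[x]", min=1),
            _ec("value[x]", types=("Quantity", "CodeableConcept")),
            _ec("valueQuantity.value", min=1),
            _ec("valueQuantity.code", min=1),
            _ec("valueQuantity.system", min=1, fixed=systems.UCUM,
                fixed_type="Uri"),
        ]),
        _cds(CDS_CONDITION, "Condition", [
            _ec("code", min=1),
            *_system_slice("code.coding", "icd10-gm", systems.ICD10GM),
            _ec("subject", min=1, types=("Reference",),
                ref_targets=("Patient",)),
        ]),
        _cds(CDS_PROCEDURE, "Procedure", [
            _ec("category", min=1),
            *_system_slice("category.coding", "sct", systems.SNOMED,
                           minimum=1),
            _ec("code", min=1),
            *_system_slice("code.coding", "ops", systems.OPS),
            _ec("subject", min=1, types=("Reference",),
                ref_targets=("Patient",)),
            _ec("performed[x]", min=1),
        ]),
        _cds(CDS_MEDICATION_ADMINISTRATION, "MedicationAdministration", [
            _ec("status", min=1),
            _ec("subject", min=1, types=("Reference",),
                ref_targets=("Patient",)),
            _ec("dosage.dose.code", min=1),
            _ec("dosage.dose.system", min=1, fixed=systems.UCUM,
                fixed_type="Uri"),
        ]),
        _cds(CDS_MEDICATION_REQUEST, "MedicationRequest", [
            _ec("subject", min=1, types=("Reference",),
                ref_targets=("Patient",)),
        ]),
        _cds(CDS_MEDICATION_STATEMENT, "MedicationStatement", [
            _ec("subject", min=1, types=("Reference",),
                ref_targets=("Patient",)),
        ]),
        _cds(CDS_MEDICATION, "Medication", [
            _ec("code", min=1),
            *_system_slice("code.coding", "atc", systems.ATC),
        ]),
        _cds(CDS_CONSENT, "Consent", [
            _ec("patient", min=1, types=("Reference",),
                ref_targets=("Patient",)),
            _ec("provision", min=1),
        ]),
        _cds(CDS_SPECIMEN, "Specimen", [
            _ec("type", min=1),
            _ec("type.coding", min=1,
                slicing=Slicing(discriminator_path="$this",
                                discriminator_type="pattern")),
            # the CDS layer limits specimen codings to the SNOMED
            # specimen subtree
            _ec("type.coding:sct", min=1,
                pattern={"system": systems.SNOMED}, pattern_type="Coding",
                binding=Binding(valueset=SPECIMEN_ALL_VS,
                                strength="required")),
            _ec("subject", min=1, types=("Reference",),
                ref_targets=("Patient",)),
        ]),
    ]


def baseline_registry() -> ProfileRegistry:
    """Registry with the FHIR core layer and the CDS layer preloaded."""
    registry = ProfileRegistry()
    for profile in core_profiles():
        registry.register(profile)
    for profile in cds_profiles():
        registry.register(profile)
    return registry


#: CDS profile URL per resource type, used for claims and substitution.
CDS_PROFILE_BY_TYPE = {
    "Patient": CDS_PATIENT,
    "Observation": CDS_LAB_OBSERVATION,
    "Condition": CDS_CONDITION,
    "Procedure": CDS_PROCEDURE,
    "MedicationAdministration": CDS_MEDICATION_ADMINISTRATION,
    "MedicationRequest": CDS_MEDICATION_REQUEST,
    "MedicationStatement": CDS_MEDICATION_STATEMENT,
    "Medication": CDS_MEDICATION,
    "Consent": CDS_CONSENT,
    "Specimen": CDS_SPECIMEN,
}
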