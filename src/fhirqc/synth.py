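"""Synthetic multi-site FHIR instance generator with ground-truth injection.

Each site emits Patients plus resources that claim the CDS profile URLs
in ``meta.profile``, exactly as instance data at a data integration
center would.  With a configurable per-category probability, one defect
is injected per resource (categories are tried in random order, first
Bernoulli success wins, at most one injection per resource so that
ground-truth counting stays unambiguous):

* drop the mandatory MedicationAdministration status,
* corrupt a Condition coding's system URL into a lexical variant,
* uppercase the letters of a Procedure's OPS code,
* drop the SNOMED-coded Procedure category,
* swap a quantitative value for a qualitative (invalid-measurement)
  concept and vice versa,
* swap the expected UCUM unit for a table variant with a known intended
  taxonomy class,
* keep only the encompassing consent provision code (hierarchy gap),
* add foreign provision codings from a consent-management system,
* switch the medication representation to an unsupported form,
* use a qualitative result coding outside the bound answer list.

A zero-rate configuration emits fully conformant data; the emitted
ground truth records every injection.  Generation is deterministic in
the configured seed: identical configurations yield byte-identical
bundles.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import systems
from .baseline import CDS_PROFILE_BY_TYPE
from .classifier import DiscrepancyCategory
from .fixtures import (GENERAL_QUALITATIVE_VS, INHOUSE_FLAGS_CS, MdrEntry,
                       SPECIMEN_TOP50_VS)
from .profiles import ProfileRegistry
from .terminology import TerminologyStore
from .ucum import UnitCategory


class ConfigError(ValueError):
    pass


class DuplicateSiteError(ConfigError):
    pass


#: expected unit → (variant code, intended taxonomy class) choices.
DEFAULT_UNIT_VARIANTS: dict[str, tuple[tuple[str, UnitCategory], ...]] = {
    "g/dL": (("g/dl", UnitCategory.CASE_VARIANT),
             ("g/L", UnitCategory.POWER_OF_TEN),
             ("mmol/L", UnitCategory.MOLAR_MASS_REQUIRED)),
    "mg/dL": (("mg/dl", UnitCategory.CASE_VARIANT),
              ("g/L", UnitCategory.POWER_OF_TEN),
              ("umol/L", UnitCategory.MOLAR_MASS_REQUIRED)),
    "mmol/L": (("mmol/l", UnitCategory.CASE_VARIANT),
               ("umol/L", UnitCategory.POWER_OF_TEN),
               ("mg/dL", UnitCategory.MOLAR_MASS_REQUIRED)),
    "U/L": (("U/l", UnitCategory.CASE_VARIANT),
            ("U/mL", UnitCategory.POWER_OF_TEN)),
    "%": (("g/dL", UnitCategory.DIMENSION_MISMATCH),),
    "10*3/uL": (("Gpt/L", UnitCategory.INVALID_UCUM),
                ("10*9/L", UnitCategory.EQUIVALENT_REPRESENTATION),
                ("10*3/μL", UnitCategory.GREEK_VARIANT)),
    "10*6/uL": (("10*12/L", UnitCategory.EQUIVALENT_REPRESENTATION),
                ("10*6/μL", UnitCategory.GREEK_VARIANT)),
    "g/L": (("g/l", UnitCategory.CASE_VARIANT),
            ("mg/dL", UnitCategory.POWER_OF_TEN),
            ("mmol/L", UnitCategory.MOLAR_MASS_REQUIRED)),
    "mg/L": (("ug/dl", UnitCategory.POWER_OF_TEN),
             ("mg/l", UnitCategory.CASE_VARIANT)),
    "ng/mL": (("ug/L", UnitCategory.EQUIVALENT_REPRESENTATION),
              ("ng/ml", UnitCategory.CASE_VARIANT)),
    "mm[Hg]": (("kPa", UnitCategory.COMPLEX_CONVERSION),),
}

_DEFAULT_N_PER_TYPE = {
    "Observation": 40,
    "Condition": 20,
    "Procedure": 20,
    "MedicationAdministration": 20,
    "Consent": 10,
    "Specimen": 10,
}

#: injection category → resource types it applies to.
_CATEGORY_TYPES = {
    DiscrepancyCategory.MISSING_MANDATORY: ("MedicationAdministration",),
    DiscrepancyCategory.WRONG_SYSTEM_URL: ("Condition",),
    DiscrepancyCategory.CODE_CASE_MISMATCH: ("Procedure",),
    DiscrepancyCategory.MISSING_PROCEDURE_CATEGORY: ("Procedure",),
    DiscrepancyCategory.SCALE_QUAL_FOR_QUANT: ("Observation",),
    DiscrepancyCategory.SCALE_QUANT_FOR_QUAL: ("Observation",),
    DiscrepancyCategory.UNIT_DISCREPANCY: ("Observation",),
    DiscrepancyCategory.CONSENT_HIERARCHY_GAP: ("Consent",),
    DiscrepancyCategory.FOREIGN_PROVISION_CODES: ("Consent",),
    DiscrepancyCategory.MEDICATION_FORM_UNSUPPORTED:
        ("MedicationAdministration",),
    DiscrepancyCategory.BINDING_VIOLATION: ("Observation",),
}

_ICD_SYSTEM_VARIANTS = (
    "https://fhir.de/CodeSystem/bfarm/icd-10-gm",
    "http://fhir.de/CodeSystem/bfarm/icd-10-gm/",
    "http://fhir.de/CodeSystem/dimdi/icd-10-gm",
)

#: the encompassing consent permission used by the generator.
CONSENT_PARENT = "PATDAT_erheben_speichern_nutzen"


@dataclass
class SiteConfig:
    site_id: str
    n_patients: int = 50
    n_per_type: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_PER_TYPE))
    injection_rates: Mapping[DiscrepancyCategory, float] = field(
        default_factory=dict)
    unit_variant_table: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_UNIT_VARIANTS))
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {}
        for category, rate in self.injection_rates.items():
            try:
                category = DiscrepancyCategory(category)
            except ValueError:
                raise ConfigError(
                    f"unknown injection category {category!r}") from None
            if category not in _CATEGORY_TYPES:
                raise ConfigError(f"unknown injection category {category}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate for {category} outside [0, 1]")
            rates[category] = float(rate)
        self.injection_rates = rates
        for resource_type, count in self.n_per_type.items():
            if count < 0:
                raise ConfigError(f"negative count for {resource_type}")
        for unit, variants in self.unit_variant_table.items():
            for _, intended in variants:
                UnitCategory(intended)

    @classmethod
    def uniform(cls, site_id: str, rate: float, seed: int = 0,
                **kwargs) -> "SiteConfig":
        """All injection categories at the same rate."""
        return cls(site_id=site_id, seed=seed,
                   injection_rates={c: rate for c in _CATEGORY_TYPES},
                   **kwargs)


@dataclass(frozen=True)
class GroundTruthEntry:
    resource_id: str
    category: DiscrepancyCategory
    path: str
    expected: str
    observed: str
    unit_class: UnitCategory | None = None  # UNIT_DISCREPANCY injections


@dataclass
class GroundTruth:
    entries: list[GroundTruthEntry] = field(default_factory=list)

    def counts(self) -> dict[DiscrepancyCategory, int]:
        out: dict[DiscrepancyCategory, int] = {}
        for entry in self.entries:
            out[entry.category] = out.get(entry.category, 0) + 1
        return out

    def to_csv_rows(self) -> list[list[str]]:
        rows = [["resource_id", "category", "path", "expected", "observed",
                 "unit_class"]]
        for entry in self.entries:
            rows.append([entry.resource_id, entry.category.value, entry.path,
                         entry.expected, entry.observed,
                         entry.unit_class.value if entry.unit_class else ""])
        return rows


class _SiteBuilder:
    def __init__(self, cfg: SiteConfig, mdr: list[MdrEntry],
                 store: TerminologyStore):
        self.cfg = cfg
        self.mdr = mdr
        self.store = store
        self.rng = random.Random(cfg.seed)
        self.resources: list[dict] = []
        self.truth = GroundTruth()
        self._counters: dict[str, int] = {}
        self._vs_cache: dict[str, list[tuple[str, str]]] = {}

    # -- helpers -----------------------------------------------------------

    def next_id(self, resource_type: str) -> str:
        index = self._counters.get(resource_type, 0)
        self._counters[resource_type] = index + 1
        return f"{self.cfg.site_id}-{resource_type.lower()}-{index:05d}"

    def vs_members(self, url: str) -> list[tuple[str, str]]:
        if url not in self._vs_cache:
            self._vs_cache[url] = sorted(self.store.expand(url))
        return self._vs_cache[url]

    def patient_ref(self, index: int) -> dict:
        patient = index % max(self.cfg.n_patients, 1)
        return {"reference":
                f"Patient/{self.cfg.site_id}-patient-{patient:05d}"}

    def claim(self, resource_type: str) -> dict:
        return {"profile": [CDS_PROFILE_BY_TYPE[resource_type]]}

    def _quantity_value(self, entry: MdrEntry) -> float:
        low = entry.low if entry.low is not None else 0.0
        high = entry.high if entry.high is not None else low + 100.0
        return round(self.rng.uniform(low, high), 2)

    # -- clean builders ----------------------------------------------------

    def build_patient(self, index: int) -> dict:
        return {
            "resourceType": "Patient",
            "id": f"{self.cfg.site_id}-patient-{index:05d}",
            "meta": self.claim("Patient"),
            "gender": "female" if index % 2 else "male",
            "birthDate": f"{1940 + (index * 7) % 70}-0{1 + index % 9}-15",
        }

    def build_observation(self, index: int) -> tuple[dict, MdrEntry]:
        entry = self.mdr[index % len(self.mdr)]
        resource = {
            "resourceType": "Observation",
            "id": self.next_id("Observation"),
            "meta": self.claim("Observation"),
            "status": "final",
            "category": [{"coding": [{
                "system": systems.OBSERVATION_CATEGORY,
                "code": "laboratory"}]}],
            "code": {"coding": [{"system": systems.LOINC,
                                 "code": entry.loinc,
                                 "display": entry.display}]},
            "subject": self.patient_ref(index),
            "effectiveDateTime":
                f"2022-{1 + index % 12:02d}-{1 + index % 28:02d}",
        }
        if entry.scale == "QUANTITATIVE":
            resource["valueQuantity"] = {
                "value": self._quantity_value(entry),
                "unit": entry.ucum_unit,
                "system": systems.UCUM,
                "code": entry.ucum_unit,
            }
        else:
            valueset = entry.answer_vs or GENERAL_QUALITATIVE_VS
            system, code = self.rng.choice(self.vs_members(valueset))
            resource["valueCodeableConcept"] = {
                "coding": [{"system": system, "code": code}]}
        return resource, entry

    def build_condition(self, index: int) -> dict:
        system, code = self.rng.choice(
            self.vs_members("https://fhirqc.example.org/fhir/ValueSet/icd10gm-all"))
        return {
            "resourceType": "Condition",
            "id": self.next_id("Condition"),
            "meta": self.claim("Condition"),
            "code": {"coding": [{"system": system, "code": code}]},
            "subject": self.patient_ref(index),
            "recordedDate": f"2022-{1 + index % 12:02d}-03",
        }

    def build_procedure(self, index: int) -> dict:
        system, code = self.rng.choice(
            self.vs_members("https://fhirqc.example.org/fhir/ValueSet/ops-all"))
        return {
            "resourceType": "Procedure",
            "id": self.next_id("Procedure"),
            "meta": self.claim("Procedure"),
            "status": "completed",
            "category": {"coding": [{"system": systems.SNOMED,
                                     "code": "387713003"}]},
            "code": {"coding": [{"system": system, "code": code}]},
            "subject": self.patient_ref(index),
            "performedDateTime": f"2022-{1 + index % 12:02d}-07",
        }

    def build_medication_pair(self, index: int) -> tuple[dict, dict]:
        system, code = self.rng.choice(
            self.vs_members("https://fhirqc.example.org/fhir/ValueSet/atc-all"))
        medication = {
            "resourceType": "Medication",
            "id": self.next_id("Medication"),
            "meta": self.claim("Medication"),
            "code": {"coding": [{"system": system, "code": code}]},
        }
        administration = {
            "resourceType": "MedicationAdministration",
            "id": self.next_id("MedicationAdministration"),
            "meta": self.claim("MedicationAdministration"),
            "status": "completed",
            "medicationReference": {
                "reference": f"Medication/{medication['id']}"},
            "subject": self.patient_ref(index),
            "effectiveDateTime": f"2022-{1 + index % 12:02d}-11",
            "dosage": {"dose": {"value": 100.0 + index % 400, "unit": "mg",
                                "system": systems.UCUM, "code": "mg"}},
        }
        return medication, administration

    def build_consent(self, index: int) -> dict:
        codes = [CONSENT_PARENT]
        codes += sorted(self.store.descendants(
            self.store.systems[systems.MII_CONSENT_POLICY], CONSENT_PARENT))
        return {
            "resourceType": "Consent",
            "id": self.next_id("Consent"),
            "meta": self.claim("Consent"),
            "status": "active",
            "scope": {"coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/consentscope",
                "code": "research"}]},
            "category": [{"coding": [{
                "system": "http://loinc.org", "code": "57016-8"}]}],
            "patient": self.patient_ref(index),
            "provision": {"type": "permit", "provision": [
                {"code": [{"coding": [{
                    "system": systems.MII_CONSENT_POLICY, "code": code}]}]}
                for code in codes]},
        }

    def build_specimen(self, index: int) -> dict:
        system, code = self.rng.choice(self.vs_members(SPECIMEN_TOP50_VS))
        return {
            "resourceType": "Specimen",
            "id": self.next_id("Specimen"),
            "meta": self.claim("Specimen"),
            "type": {"coding": [{"system": system, "code": code}]},
            "subject": self.patient_ref(index),
        }

    # -- injections --------------------------------------------------------

    def record(self, resource: dict, category: DiscrepancyCategory,
               path: str, expected: str, observed: str,
               unit_class: UnitCategory | None = None) -> None:
        self.truth.entries.append(GroundTruthEntry(
            resource_id=resource["id"], category=category, path=path,
            expected=expected, observed=observed, unit_class=unit_class))

    def inject(self, resource: dict, category: DiscrepancyCategory,
               entry: MdrEntry | None) -> bool:
        """Apply one defect; returns False when not applicable here."""
        cat = DiscrepancyCategory
        if category is cat.MISSING_MANDATORY:
            del resource["status"]
            self.record(resource, category, "status", "min 1", "absent")
        elif category is cat.WRONG_SYSTEM_URL:
            coding = resource["code"]["coding"][0]
            variant = self.rng.choice(_ICD_SYSTEM_VARIANTS)
            self.record(resource, category, "code.coding:icd10-gm",
                        coding["system"], variant)
            coding["system"] = variant
        elif category is cat.CODE_CASE_MISMATCH:
            coding = resource["code"]["coding"][0]
            upper = coding["code"].upper()
            if upper == coding["code"]:
                return False  # no letters to flip in this OPS code
            self.record(resource, category, "code.coding:ops",
                        coding["code"], upper)
            coding["code"] = upper
        elif category is cat.MISSING_PROCEDURE_CATEGORY:
            del resource["category"]
            self.record(resource, category, "category", "min 1", "absent")
        elif category is cat.SCALE_QUAL_FOR_QUANT:
            if entry is None or entry.scale != "QUANTITATIVE":
                return False
            del resource["valueQuantity"]
            resource["valueCodeableConcept"] = {"coding": [{
                "system": INHOUSE_FLAGS_CS, "code": "invalid"}]}
            self.record(resource, category, "value[x]", "Quantity",
                        "CodeableConcept")
        elif category is cat.SCALE_QUANT_FOR_QUAL:
            if entry is None or entry.scale != "QUALITATIVE":
                return False
            del resource["valueCodeableConcept"]
            resource["valueQuantity"] = {
                "value": round(self.rng.uniform(0.1, 10.0), 2),
                "unit": "mg/dL", "system": systems.UCUM, "code": "mg/dL"}
            self.record(resource, category, "value[x]", "CodeableConcept",
                        "Quantity")
        elif category is cat.UNIT_DISCREPANCY:
            if entry is None or entry.scale != "QUANTITATIVE":
                return False
            variants = self.cfg.unit_variant_table.get(entry.ucum_unit)
            if not variants:
                return False
            variant, intended = self.rng.choice(list(variants))
            resource["valueQuantity"]["code"] = variant
            self.record(resource, category, "valueQuantity.code",
                        entry.ucum_unit, variant,
                        unit_class=UnitCategory(intended))
        elif category is cat.CONSENT_HIERARCHY_GAP:
            provisions = resource["provision"]["provision"]
            dropped = sorted(
                p["code"][0]["coding"][0]["code"] for p in provisions
                if p["code"][0]["coding"][0]["code"] != CONSENT_PARENT)
            resource["provision"]["provision"] = [
                p for p in provisions
                if p["code"][0]["coding"][0]["code"] == CONSENT_PARENT]
            self.record(resource, category, "provision",
                        ",".join(dropped), CONSENT_PARENT)
        elif category is cat.FOREIGN_PROVISION_CODES:
            resource["provision"]["provision"].append({"code": [{"coding": [{
                "system": systems.GICS_POLICY,
                "code": "gics-study-consent"}]}]})
            self.record(resource, category, "provision", "",
                        f"{systems.GICS_POLICY}|gics-study-consent")
        elif category is cat.MEDICATION_FORM_UNSUPPORTED:
            reference = resource.pop("medicationReference")
            system, code = self.rng.choice(self.vs_members(
                "https://fhirqc.example.org/fhir/ValueSet/atc-all"))
            resource["medicationCodeableConcept"] = {
                "coding": [{"system": system, "code": code}]}
            self.record(resource, category, "medication[x]",
                        reference["reference"], "inline CodeableConcept")
        elif category is cat.BINDING_VIOLATION:
            if entry is None or entry.scale != "QUALITATIVE":
                return False
            resource["valueCodeableConcept"] = {"coding": [{
                "system": systems.SNOMED, "code": "999999004"}]}
            self.record(resource, category, "valueCodeableConcept",
                        entry.answer_vs or GENERAL_QUALITATIVE_VS,
                        f"{systems.SNOMED}|999999004")
        else:  # pragma: no cover - guarded by SiteConfig validation
            raise ConfigError(f"unknown injection category {category}")
        return True

    def maybe_inject(self, resource: dict,
                     entry: MdrEntry | None = None) -> None:
        applicable = [c for c, types in _CATEGORY_TYPES.items()
                      if resource["resourceType"] in types
                      and self.cfg.injection_rates.get(c, 0.0) > 0.0]
        applicable.sort(key=lambda c: c.value)
        self.rng.shuffle(applicable)
        for category in applicable:
            if self.rng.random() < self.cfg.injection_rates[category]:
                if self.inject(resource, category, entry):
                    return  # at most one injection per resource

    # -- assembly ----------------------------------------------------------

    def build(self) -> tuple[list[dict], GroundTruth]:
        for index in range(self.cfg.n_patients):
            self.resources.append(self.build_patient(index))
        counts = self.cfg.n_per_type
        for index in range(counts.get("Observation", 0)):
            resource, entry = self.build_observation(index)
            self.maybe_inject(resource, entry)
            self.resources.append(resource)
        for index in range(counts.get("Condition", 0)):
            resource = self.build_condition(index)
            self.maybe_inject(resource)
            self.resources.append(resource)
        for index in range(counts.get("Procedure", 0)):
            resource = self.build_procedure(index)
            self.maybe_inject(resource)
            self.resources.append(resource)
        for index in range(counts.get("MedicationAdministration", 0)):
            medication, administration = self.build_medication_pair(index)
            self.maybe_inject(administration)
            self.resources.append(medication)
            self.resources.append(administration)
        for index in range(counts.get("Consent", 0)):
            resource = self.build_consent(index)
            self.maybe_inject(resource)
            self.resources.append(resource)
        for index in range(counts.get("Specimen", 0)):
            resource = self.build_specimen(index)
            self.maybe_inject(resource)
            self.resources.append(resource)
        return self.resources, self.truth


def generate_site(cfg: SiteConfig, mdr: list[MdrEntry],
                  registry: ProfileRegistry | None,
                  terminology: TerminologyStore
                  ) -> tuple[list[dict], GroundTruth]:
    """Generate one site's resources plus the injected ground truth.

    ``registry`` is accepted for interface symmetry (the generator emits
    claims against the CDS URLs the registry resolves); generation
    itself only needs the MDR and the terminology store.
    """
    return _SiteBuilder(cfg, mdr, terminology).build()


def generate_multisite(cfgs: Iterable[SiteConfig], mdr: list[MdrEntry],
                       registry: ProfileRegistry | None,
                       terminology: TerminologyStore
                       ) -> dict[str, tuple[list[dict], GroundTruth]]:
    """Independent per-site bundles (streams seeded per site config)."""
    out: dict[str, tuple[list[dict], GroundTruth]] = {}
    for cfg in cfgs:
        if cfg.site_id in out:
            raise DuplicateSiteError(cfg.site_id)
        out[cfg.site_id] = generate_site(cfg, mdr, registry, terminology)
    return out


def to_ndjson(resources: Iterable[Mapping]) -> str:
    """Canonical NDJSON serialization (stable key order)."""
    return "\n".join(json.dumps(r, sort_keys=True, ensure_ascii=False)
                     for r in resources) + "\n"


def from_ndjson(text: str) -> list[dict]:
    return [json.loads(line) for line in text.splitlines() if line.strip()]
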