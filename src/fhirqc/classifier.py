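"""Discrepancy taxonomy: from raw validation issues to classified records.

The classifier is a pure, deterministic function of the resource, its
validation issues, and a classification context (MDR table, common-unit
list, consent policy hierarchy, invalid-measurement concept list,
system-URL alias table).  Each error-severity issue maps to exactly one
:class:`DiscrepancyRecord`; consent-hierarchy closure and medication
representation forms contribute additional records that no single
profile constraint can express.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

from . import systems
from .fixtures import MdrEntry
from .profiles import Layer
from .terminology import CodeSystemDef, TerminologyStore
from .ucum import ProfileUnitError, UnitPairClass, classify_unit_pair
from .validator import ConstraintKind, ValidationIssue, _as_list


class ContextError(ValueError):
    """A lab resource's LOINC is absent from the MDR context."""


class DiscrepancyCategory(str, Enum):
    MISSING_MANDATORY = "MISSING_MANDATORY"
    WRONG_SYSTEM_URL = "WRONG_SYSTEM_URL"
    CODE_CASE_MISMATCH = "CODE_CASE_MISMATCH"
    MISSING_PROCEDURE_CATEGORY = "MISSING_PROCEDURE_CATEGORY"
    SCALE_QUAL_FOR_QUANT = "SCALE_QUAL_FOR_QUANT"
    SCALE_QUANT_FOR_QUAL = "SCALE_QUANT_FOR_QUAL"
    UNIT_DISCREPANCY = "UNIT_DISCREPANCY"
    CONSENT_HIERARCHY_GAP = "CONSENT_HIERARCHY_GAP"
    FOREIGN_PROVISION_CODES = "FOREIGN_PROVISION_CODES"
    MEDICATION_FORM_UNSUPPORTED = "MEDICATION_FORM_UNSUPPORTED"
    BINDING_VIOLATION = "BINDING_VIOLATION"
    OTHER = "OTHER"


@dataclass(frozen=True)
class DiscrepancyRecord:
    site_id: str
    resource_id: str
    resource_type: str
    category: DiscrepancyCategory
    layer: Layer | None = None
    path: str = ""
    loinc: str | None = None
    unit_class: UnitPairClass | None = None
    invalid_measurement_flag: bool = False
    expected: str = ""
    observed: str = ""
    severity: str = "error"

    def __post_init__(self) -> None:
        has_class = self.unit_class is not None
        if has_class != (self.category is
                         DiscrepancyCategory.UNIT_DISCREPANCY):
            raise ValueError("unit_class present iff UNIT_DISCREPANCY")


#: slice name → the canonical system URI its pattern pins.
_SLICE_SYSTEMS = {
    "loinc": systems.LOINC,
    "icd10-gm": systems.ICD10GM,
    "ops": systems.OPS,
    "atc": systems.ATC,
    "sct": systems.SNOMED,
}

_MEDICATION_FAMILY = ("MedicationAdministration", "MedicationRequest",
                      "MedicationStatement")


@dataclass
class ClassificationContext:
    """Everything the taxonomy needs beyond the resource and its issues."""

    mdr: Mapping[str, MdrEntry] = field(default_factory=dict)
    bfarm_list: frozenset[str] = frozenset()
    store: TerminologyStore | None = None
    policy_system: str = systems.MII_CONSENT_POLICY
    invalid_concepts: frozenset[tuple[str, str]] = frozenset()
    required_consent_codes: frozenset[str] | None = None
    site_id: str = ""


def resource_loinc(resource: Mapping) -> str | None:
    for coding in _as_list((resource.get("code") or {}).get("coding")):
        if isinstance(coding, Mapping) \
                and coding.get("system") == systems.LOINC:
            return coding.get("code")
    return None


@dataclass(frozen=True)
class MedicationForm:
    """One of the six medication representation forms."""

    resource_type: str  # MedicationAdministration | Request | Statement
    linkage: str  # reference | inline
    supported: bool  # only Administration × reference is queryable


def medication_form(resource: Mapping) -> MedicationForm:
    resource_type = resource.get("resourceType")
    if resource_type not in _MEDICATION_FAMILY:
        raise TypeError(f"{resource_type!r} is not a medication-family "
                        "resource")
    linkage = ("reference" if "medicationReference" in resource
               else "inline")
    supported = (resource_type == "MedicationAdministration"
                 and linkage == "reference")
    return MedicationForm(resource_type=resource_type, linkage=linkage,
                          supported=supported)


def _classify_slice_min(resource: Mapping, issue: ValidationIssue
                        ) -> DiscrepancyCategory:
    """Missing coding slice: genuinely absent, or present under a
    lexically variant system URL?"""
    base_path, _, slice_name = issue.path.rpartition(":")
    expected_system = _SLICE_SYSTEMS.get(slice_name)
    if expected_system is None:
        return DiscrepancyCategory.MISSING_MANDATORY
    codings: list = [resource]
    for segment in base_path.split("."):
        codings = [item for value in codings if isinstance(value, Mapping)
                   for item in _as_list(value.get(segment))]
    for coding in codings:
        if not isinstance(coding, Mapping):
            continue
        observed_system = coding.get("system", "")
        if observed_system != expected_system \
                and systems.same_system(observed_system, expected_system):
            return DiscrepancyCategory.WRONG_SYSTEM_URL
    return DiscrepancyCategory.MISSING_MANDATORY


def _quantity_codings(resource: Mapping) -> list[tuple[str, str]]:
    out = []
    value = resource.get("valueCodeableConcept")
    if isinstance(value, Mapping):
        for coding in _as_list(value.get("coding")):
            if isinstance(coding, Mapping):
                out.append((coding.get("system", ""), coding.get("code", "")))
    return out


def _classify_issue(resource: Mapping, issue: ValidationIssue,
                    ctx: ClassificationContext,
                    context_notes: list[str]) -> DiscrepancyRecord:
    resource_type = resource.get("resourceType", "")
    loinc = resource_loinc(resource) if resource_type == "Observation" \
        else None
    base = dict(
        site_id=ctx.site_id,
        resource_id=str(resource.get("id", "")),
        resource_type=resource_type,
        layer=issue.origin_layer,
        path=issue.path,
        loinc=loinc,
        expected=issue.expected,
        observed=issue.observed,
        severity=issue.severity,
    )
    kind = issue.constraint_kind
    min_violation = issue.expected.startswith("min")

    if kind in (ConstraintKind.CARDINALITY, ConstraintKind.SLICE,
                ConstraintKind.REFERENCE) and min_violation:
        if resource_type == "Procedure" and issue.path.startswith("category"):
            return DiscrepancyRecord(
                category=DiscrepancyCategory.MISSING_PROCEDURE_CATEGORY,
                **base)
        if kind is ConstraintKind.SLICE:
            return DiscrepancyRecord(
                category=_classify_slice_min(resource, issue), **base)
        return DiscrepancyRecord(
            category=DiscrepancyCategory.MISSING_MANDATORY, **base)

    if kind is ConstraintKind.BINDING:
        if issue.case_only:
            return DiscrepancyRecord(
                category=DiscrepancyCategory.CODE_CASE_MISMATCH, **base)
        return DiscrepancyRecord(
            category=DiscrepancyCategory.BINDING_VIOLATION, **base)

    if kind is ConstraintKind.TYPE and issue.path.endswith("value[x]") \
            and resource_type == "Observation":
        if loinc is None or loinc not in ctx.mdr:
            context_notes.append(
                f"ContextError: LOINC {loinc!r} not in MDR for resource "
                f"{base['resource_id']}")
            return DiscrepancyRecord(category=DiscrepancyCategory.OTHER,
                                     **base)
        scale = ctx.mdr[loinc].scale
        if scale == "QUANTITATIVE" and issue.observed == "CodeableConcept":
            invalid = any(pair in ctx.invalid_concepts
                          for pair in _quantity_codings(resource))
            return DiscrepancyRecord(
                category=DiscrepancyCategory.SCALE_QUAL_FOR_QUANT,
                invalid_measurement_flag=invalid, **base)
        if scale == "QUALITATIVE" and issue.observed == "Quantity":
            return DiscrepancyRecord(
                category=DiscrepancyCategory.SCALE_QUANT_FOR_QUAL, **base)
        return DiscrepancyRecord(category=DiscrepancyCategory.OTHER, **base)

    if kind is ConstraintKind.FIXED and issue.path.endswith(".code"):
        # a fixed Quantity.code is a unit constraint
        try:
            unit_class = classify_unit_pair(issue.expected, issue.observed,
                                            ctx.bfarm_list)
        except ProfileUnitError:
            return DiscrepancyRecord(category=DiscrepancyCategory.OTHER,
                                     **base)
        return DiscrepancyRecord(
            category=DiscrepancyCategory.UNIT_DISCREPANCY,
            unit_class=unit_class, **base)

    if kind is ConstraintKind.FIXED and issue.path.endswith(".system"):
        if issue.observed != issue.expected \
                and systems.same_system(issue.observed, issue.expected):
            return DiscrepancyRecord(
                category=DiscrepancyCategory.WRONG_SYSTEM_URL, **base)
        return DiscrepancyRecord(category=DiscrepancyCategory.OTHER, **base)

    return DiscrepancyRecord(category=DiscrepancyCategory.OTHER, **base)


def classify_issues(resource: Mapping, issues: Iterable[ValidationIssue],
                    ctx: ClassificationContext) -> list[DiscrepancyRecord]:
    """Map every error-severity issue to exactly one record.

    A lab resource whose LOINC is missing from the MDR is reported (as
    an OTHER record with a context note), never dropped.
    """
    context_notes: list[str] = []
    records = []
    for issue in issues:
        if issue.severity != "error":
            continue
        record = _classify_issue(resource, issue, ctx, context_notes)
        if context_notes:
            record = replace(record,
                             observed=f"{record.observed} "
                                      f"[{context_notes.pop()}]")
        records.append(record)
    return records


def _provision_codes(resource: Mapping) -> list[tuple[str, str]]:
    """All (system, code) pairs in the provision tree, in document order."""
    out: list[tuple[str, str]] = []

    def walk(provision: Mapping) -> None:
        for concept in _as_list(provision.get("code")):
            if not isinstance(concept, Mapping):
                continue
            for coding in _as_list(concept.get("coding")):
                if isinstance(coding, Mapping):
                    out.append((coding.get("system", ""),
                                coding.get("code", "")))
        for child in _as_list(provision.get("provision")):
            if isinstance(child, Mapping):
                walk(child)

    provision = resource.get("provision")
    if isinstance(provision, Mapping):
        walk(provision)
    return out


def consent_closure_check(resource: Mapping, policy_cs: CodeSystemDef,
                          store: TerminologyStore,
                          required_codes: frozenset[str] | None = None,
                          site_id: str = "") -> list[DiscrepancyRecord]:
    """Hierarchy closure over consent provisions.

    An encompassing permission implies a set of specific permissions;
    the feasibility search needs every implied code listed explicitly,
    even when the parent code is present.  One gap record is produced
    per present non-leaf code with absent descendants.  Provisions from
    foreign code systems (e.g. consent-management software exports) are
    tolerated and reported once, informationally.
    """
    pairs = _provision_codes(resource)
    present = {code for system, code in pairs if system == policy_cs.url}
    foreign = sorted({(system, code) for system, code in pairs
                      if system != policy_cs.url and system})
    records = []
    resource_id = str(resource.get("id", ""))
    for code in sorted(present):
        if code not in policy_cs.concepts:
            continue  # unknown code: a binding concern, not a closure gap
        missing = store.descendants(policy_cs, code) - present
        if required_codes is not None:
            missing &= required_codes
        if missing:
            records.append(DiscrepancyRecord(
                site_id=site_id, resource_id=resource_id,
                resource_type="Consent",
                category=DiscrepancyCategory.CONSENT_HIERARCHY_GAP,
                path="provision", expected=",".join(sorted(missing)),
                observed=code))
    if foreign:
        records.append(DiscrepancyRecord(
            site_id=site_id, resource_id=resource_id,
            resource_type="Consent",
            category=DiscrepancyCategory.FOREIGN_PROVISION_CODES,
            path="provision", severity="information",
            observed=",".join(f"{system}|{code}"
                              for system, code in foreign)))
    return records


def record_to_dict(record: DiscrepancyRecord) -> dict:
    """JSON-able form of a record (used for the NDJSON record stream)."""
    unit_class = record.unit_class
    return {
        "site_id": record.site_id,
        "resource_id": record.resource_id,
        "resource_type": record.resource_type,
        "category": record.category.value,
        "layer": record.layer.name if record.layer is not None else None,
        "path": record.path,
        "loinc": record.loinc,
        "unit_class": None if unit_class is None else {
            "category": unit_class.category.value,
            "power_exponent": unit_class.power_exponent,
            "bfarm_listed": unit_class.bfarm_listed,
            "applied_normalizations":
                sorted(unit_class.applied_normalizations),
        },
        "invalid_measurement_flag": record.invalid_measurement_flag,
        "expected": record.expected,
        "observed": record.observed,
        "severity": record.severity,
    }


def record_from_dict(data: Mapping) -> DiscrepancyRecord:
    from .ucum import UnitCategory

    unit_class = None
    if data.get("unit_class") is not None:
        raw = data["unit_class"]
        unit_class = UnitPairClass(
            category=UnitCategory(raw["category"]),
            power_exponent=raw.get("power_exponent"),
            bfarm_listed=bool(raw.get("bfarm_listed")),
            applied_normalizations=frozenset(
                raw.get("applied_normalizations", ())),
        )
    return DiscrepancyRecord(
        site_id=data.get("site_id", ""),
        resource_id=data.get("resource_id", ""),
        resource_type=data.get("resource_type", ""),
        category=DiscrepancyCategory(data["category"]),
        layer=Layer[data["layer"]] if data.get("layer") else None,
        path=data.get("path", ""),
        loinc=data.get("loinc"),
        unit_class=unit_class,
        invalid_measurement_flag=bool(data.get("invalid_measurement_flag")),
        expected=data.get("expected", ""),
        observed=data.get("observed", ""),
        severity=data.get("severity", "error"),
    )


def classify_resource(resource: Mapping, issues: Iterable[ValidationIssue],
                      ctx: ClassificationContext) -> list[DiscrepancyRecord]:
    """Issue classification plus closure/representation findings."""
    records = classify_issues(resource, issues, ctx)
    resource_type = resource.get("resourceType")
    if resource_type == "Consent" and ctx.store is not None \
            and ctx.policy_system in ctx.store.systems:
        records.extend(consent_closure_check(
            resource, ctx.store.systems[ctx.policy_system], ctx.store,
            ctx.required_consent_codes, ctx.site_id))
    if resource_type in _MEDICATION_FAMILY:
        form = medication_form(resource)
        if not form.supported:
            records.append(DiscrepancyRecord(
                site_id=ctx.site_id,
                resource_id=str(resource.get("id", "")),
                resource_type=resource_type,
                category=DiscrepancyCategory.MEDICATION_FORM_UNSUPPORTED,
                path="medication[x]",
                expected="MedicationAdministration with Medication reference",
                observed=f"{form.resource_type} with {form.linkage} "
                         "medication"))
    return records
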