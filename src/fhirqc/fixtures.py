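"""Loaders for the shipped data files.

Everything here is a small, documented stand-in sufficient for testing
the pipeline: terminology fragments (CodeSystem/ValueSet JSON), the
lab metadata (MDR) table mapping LOINC codes to scale type and expected
UCUM unit, the common-UCUM-unit list, and the qualitative equivalence
map.  Real deployments point the loaders at full expansions and the
published lists instead.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable

from .terminology import TerminologyStore

#: Canonical URL of the shipped general-purpose qualitative ValueSet.
GENERAL_QUALITATIVE_VS = "https://fhirqc.example.org/fhir/ValueSet/qualitative-general"
SPECIMEN_ALL_VS = "https://fhirqc.example.org/fhir/ValueSet/specimen-snomed"
SPECIMEN_TOP50_VS = "https://fhirqc.example.org/fhir/ValueSet/specimen-top50"
OPS_ALL_VS = "https://fhirqc.example.org/fhir/ValueSet/ops-all"
ICD10GM_ALL_VS = "https://fhirqc.example.org/fhir/ValueSet/icd10gm-all"
ATC_ALL_VS = "https://fhirqc.example.org/fhir/ValueSet/atc-all"
INHOUSE_FLAGS_CS = "https://fhirqc.example.org/fhir/CodeSystem/inhouse-lab-flags"

_CODESYSTEM_FILES = (
    "codesystem-ops.json",
    "codesystem-icd10gm.json",
    "codesystem-atc.json",
    "codesystem-snomed-subset.json",
    "codesystem-consent-policy.json",
    "codesystem-inhouse-lab-flags.json",
)
_VALUESET_FILES = (
    "valueset-ops.json",
    "valueset-icd10gm.json",
    "valueset-atc.json",
    "valueset-specimen-all.json",
    "valueset-specimen-top50.json",
    "valueset-answers-presence.json",
    "valueset-answers-detection.json",
    "valueset-qualitative-general.json",
)


def _data_dir():
    return files("fhirqc.data")


def load_terminology(extra_dir: str | Path | None = None) -> TerminologyStore:
    """A store preloaded with the shipped CodeSystem/ValueSet fixtures."""
    store = TerminologyStore()
    data = _data_dir()
    for name in _CODESYSTEM_FILES:
        store.load_codesystem_json(json.loads((data / name).read_text("utf-8")))
    for name in _VALUESET_FILES:
        store.load_valueset_json(json.loads((data / name).read_text("utf-8")))
    if extra_dir is not None:
        for file in sorted(Path(extra_dir).glob("*.json")):
            document = json.loads(file.read_text("utf-8"))
            kind = document.get("resourceType")
            if kind == "CodeSystem":
                store.load_codesystem_json(document)
            elif kind == "ValueSet":
                store.load_valueset_json(document)
    return store


@dataclass(frozen=True)
class MdrEntry:
    """One row of the lab metadata table.

    Quantitative entries carry exactly one expected UCUM unit (the
    single-unit assumption is what surfaces the unit discrepancies under
    study); qualitative entries carry an answer ValueSet or fall back to
    the reduced general-purpose qualitative ValueSet.  ``low``/``high``
    give a plausible value range used by the synthetic generator.
    """

    loinc: str
    display: str
    scale: str  # QUANTITATIVE | QUALITATIVE
    ucum_unit: str | None = None
    answer_vs: str | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("QUANTITATIVE", "QUALITATIVE"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "QUANTITATIVE" and not self.ucum_unit:
            raise ValueError(f"quantitative entry {self.loinc} without unit")

    @property
    def fallback_to_general_vs(self) -> bool:
        return self.scale == "QUALITATIVE" and not self.answer_vs


def load_mdr(path: str | Path | None = None) -> list[MdrEntry]:
    """Read the MDR-style lab table (shipped table by default)."""
    if path is None:
        handle = (_data_dir() / "mdr_lab_table.csv").open(encoding="utf-8")
    else:
        handle = open(path, encoding="utf-8")
    entries = []
    with handle:
        for row in csv.DictReader(handle):
            entries.append(MdrEntry(
                loinc=row["loinc"],
                display=row["display"],
                scale=row["scale"],
                ucum_unit=row["ucum_unit"] or None,
                answer_vs=row["answer_vs"] or None,
                low=float(row["low"]) if row.get("low") else None,
                high=float(row["high"]) if row.get("high") else None,
            ))
    return entries


def mdr_by_loinc(entries: Iterable[MdrEntry]) -> dict[str, MdrEntry]:
    return {entry.loinc: entry for entry in entries}


def load_bfarm_units(path: str | Path | None = None) -> frozenset[str]:
    """The common-UCUM-unit list (shipped placeholder list by default).

    The shipped list is a documented placeholder with the units common in
    German laboratory reporting; replace it with the published list for
    production analyses.
    """
    if path is None:
        handle = (_data_dir() / "bfarm_common_units.csv").open(encoding="utf-8")
    else:
        handle = open(path, encoding="utf-8")
    with handle:
        return frozenset(row["unit"] for row in csv.DictReader(handle))


def load_equivalence_map(path: str | Path | None = None) -> dict[str, str]:
    """Code → canonical-code map reducing the general qualitative ValueSet."""
    if path is None:
        handle = (_data_dir()
                  / "qualitative_equivalence_map.csv").open(encoding="utf-8")
    else:
        handle = open(path, encoding="utf-8")
    with handle:
        return {row["member_code"]: row["canonical_code"]
                for row in csv.DictReader(handle)}
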