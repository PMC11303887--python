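"""Canonical code-system URIs and system-URL normalization.

The normalization table is deliberately conservative: only scheme
variation (http/https), a trailing slash, and documented historical
aliases (e.g. the pre-BfArM DIMDI URLs of the German national code
systems) are recognized.  Anything else is *not* treated as "the right
system spelled wrong".
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib.resources import files

LOINC = "http://loinc.org"
SNOMED = "http://snomed.info/sct"
UCUM = "http://unitsofmeasure.org"
ICD10GM = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
OPS = "http://fhir.de/CodeSystem/bfarm/ops"
ATC = "http://fhir.de/CodeSystem/bfarm/atc"
OBSERVATION_CATEGORY = "http://terminology.hl7.org/CodeSystem/observation-category"
MII_CONSENT_POLICY = "urn:oid:2.16.840.1.113883.3.1937.777.24.5.3"
GICS_POLICY = "https://ths-greifswald.de/fhir/CodeSystem/gics/Policy"


@lru_cache(maxsize=1)
def _alias_table() -> dict[str, str]:
    table: dict[str, str] = {}
    data = files("fhirqc.data")
    with (data / "system_url_aliases.csv").open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            table[row["alias"]] = row["canonical"]
    return table


def normalize_system_url(url: str) -> str:
    """Reduce a system URI to its canonical form where recognized.

    Applies, in order: exact alias lookup, https→http scheme folding,
    trailing-slash stripping, and alias lookup again on the folded form.
    Unrecognized URIs are returned scheme/slash-folded, which leaves a
    genuinely different system distinguishable from the expected one.
    """
    table = _alias_table()
    if url in table:
        return table[url]
    folded = url.rstrip("/")
    if folded.startswith("https://"):
        folded = "http://" + folded[len("https://"):]
    return table.get(folded, folded)


def same_system(observed: str, expected: str) -> bool:
    """True when the observed URI is a lexical variant of the expected."""
    return normalize_system_url(observed) == normalize_system_url(expected)
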