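"""Forge a per-LOINC lab profile and validate observations against it.

The lab metadata (MDR) table maps each LOINC code to its scale type and
— for quantitative codes — the one expected UCUM unit.  The forge turns
each row into a use-case profile layered on the core-data-set lab
profile; validation then attributes every violation to the layer that
introduced the constraint (FHIR base / CDS / use-case).
"""

import copy

from fhirqc import (forge_package, load_mdr, load_terminology,
                    resolve_chain, systems, validate_resource)

store = load_terminology()
mdr = load_mdr()  # shipped 20-entry table
registry, substitution = forge_package(mdr, store=store)

hemoglobin = next(e for e in mdr if e.loinc == "718-7")
url = substitution.lab_by_loinc[hemoglobin.loinc]
chain = resolve_chain(url, registry)
print("profile chain:",
      " -> ".join(f"{p.layer.name}" for p in chain.profiles))

observation = {
    "resourceType": "Observation", "id": "example-1",
    "status": "final",
    "category": [{"coding": [{"system": systems.OBSERVATION_CATEGORY,
                              "code": "laboratory"}]}],
    "code": {"coding": [{"system": systems.LOINC, "code": "718-7"}]},
    "subject": {"reference": "Patient/p1"},
    "effectiveDateTime": "2022-06-01",
    "valueQuantity": {"value": 13.4, "unit": "g/dL",
                      "system": systems.UCUM, "code": "g/dL"},
}

print("conformant observation:",
      len(validate_resource(observation, chain, store)), "issues")

broken = copy.deepcopy(observation)
del broken["status"]                       # violates the FHIR base
broken["valueQuantity"]["code"] = "g/l"    # violates the use-case layer
for issue in validate_resource(broken, chain, store):
    print(f"  {issue.origin_layer.name:9} {issue.constraint_kind.value:11}"
          f" {issue.path}: expected {issue.expected},"
          f" observed {issue.observed}")

# The layer column is the point: the missing status is an implementation
# error against the base standard, while the lowercase liter only breaks
# the stricter research-platform assumption.
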