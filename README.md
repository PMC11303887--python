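# fhirqc

Layered FHIR profile validation and discrepancy classification for
cross-institutional health-care data.

## What it is for

National FHIR profile layers (such as the German Core Data Set, CDS)
make hospital data interoperable, but downstream platforms — here, a
federated feasibility search over laboratory values, diagnoses,
procedures, medications, consent and specimens — need *stricter*
assumptions than the shared layer guarantees: a laboratory
observation's value must match its LOINC code's scale type and one
expected UCUM unit, codings must come from specific national code
systems with exact casing, consent permissions must be listed
explicitly even when an encompassing code implies them. `fhirqc` is
for data-integration engineers and interoperability researchers who
want to measure that gap: it derives the stricter profile layer from a
lab metadata (MDR) table, validates instance data against the layered
chain `FHIR base → CDS → use-case profile` with every violation
attributed to the layer that introduced the constraint, and classifies
the violations into an actionable discrepancy taxonomy.

## The core machinery

* **Layered profile model** — profiles as explicit constraint sets
  (cardinality, fixed/pattern values, choice types, required bindings,
  pattern-discriminated slices, reference targets) over a pragmatic
  StructureDefinition subset; chains resolve base→leaf, derived layers
  may only narrow, and each effective facet carries its origin layer.
* **UCUM engine** — a parser and canonicalizer over curated atom and
  prefix tables with exact rational arithmetic. Every unit reduces to
  an 8-slot dimension vector *d* and magnitude *m* ∈ ℚ; two units are
  commensurable iff their vectors (and arbitrary-unit signatures)
  match, with conversion factor r = m₁/m₂ exact. Amount of substance
  is its own dimension, so g ↔ mmol deliberately reports "molar mass
  required" instead of a number. Expected/observed pairs classify
  into: `EXACT_MATCH`, `CASE_VARIANT` (l vs L), `GREEK_VARIANT` (μ vs
  u), `EQUIVALENT_REPRESENTATION` (r = 1), `POWER_OF_TEN` (r = 10^k),
  `COMPLEX_CONVERSION` (e.g. mm[Hg] ↔ kPa), `MOLAR_MASS_REQUIRED`,
  `DIMENSION_MISMATCH`, `INVALID_UCUM` (e.g. `Gpt/L`).
* **Discrepancy classifier** — maps validation issues to a taxonomy of
  missing mandatory elements, lexical system-URL variants, code case
  mismatches, scale conflicts (with invalid-measurement flagging),
  unit discrepancies, consent-hierarchy gaps, foreign consent
  provisions, unsupported medication representation forms and binding
  violations.
* **Synthetic multi-site generator** — seeded, byte-reproducible
  bundles claiming CDS profiles, with per-category defect injection
  and exact ground truth, so the whole pipeline is testable without
  any real patient data.

## Worked example

```python
from fhirqc import (forge_package, load_mdr, load_terminology,
                    resolve_chain, validate_resource, classify_unit_pair)

store = load_terminology()                  # shipped terminology fragments
registry, submap = forge_package(load_mdr(), store=store)
chain = resolve_chain(submap.lab_by_loinc["718-7"], registry)

print(classify_unit_pair("mg/L", "ug/dl").category.value)
```

Running `python examples/forge_and_validate.py` builds the hemoglobin
(LOINC 718-7) profile chain, validates a conformant observation and a
broken copy, and prints:

```
profile chain: FHIR_BASE -> CDS -> FDPG
conformant observation: 0 issues
  FHIR_BASE CARDINALITY status: expected min 1, observed count 0
  FDPG      FIXED       valueQuantity.code: expected g/dL, observed g/l
```

The layer column is the analysis: the missing `status` violates the
base standard itself (an implementation error any consumer should
reject), while the lowercase liter only violates the stricter
use-case layer — valid CDS data that the feasibility platform still
cannot find, because FHIR search for codings is case-sensitive.

`python examples/simulate_study.py` runs three synthetic sites at a
10 % injection rate through the full sample → substitute → validate →
classify pipeline and ends with

```
exact recovery of injected categories: True
```

followed by the per-category injected/recovered table and the stepwise
unit-reduction analysis (case/Greek cleanup, common-unit-list filter,
power-of-ten vs complex partition).

## Command line

The same pipeline as five chainable commands:

```bash
fhirqc forge    --out package/ --substitution-map sub.csv
fhirqc simulate --config sites.json --out sim/
fhirqc validate --bundle sim/site-a.ndjson --out issues.json --seed 1
fhirqc classify --bundle sim/site-a.ndjson --issues issues.json \
                --out records.ndjson --records-csv records.csv
fhirqc report   --records records.ndjson --out report.json \
                --reduction-csv reduction.csv
```

All inputs and outputs are plain text (CSV, JSON, NDJSON).

## Layout

```
src/fhirqc/
  ucum/          UCUM parser, canonicalizer, pair taxonomy, naive oracle
  terminology.py CodeSystem/ValueSet store, case-aware membership
  profiles.py    layered profile model, StructureDefinition I/O
  baseline.py    FHIR-core and CDS stand-in layers
  forge.py       per-LOINC and coded-module profile forge
  validator.py   chain validation, sampling, claim substitution
  classifier.py  discrepancy taxonomy, consent closure, medication forms
  synth.py       seeded multi-site generator with ground truth
  pipeline.py    sample → substitute → validate → classify
  report.py      site summaries and the unit-reduction analysis
  cli.py         the five shell commands
  data/          atom/prefix tables, terminology fragments, MDR table
docs/methods.md  model, assumptions, design choices, limitations
examples/        one narrative script per capability
```
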