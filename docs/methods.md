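# Methods

## The problem

German university hospitals expose routine care data as FHIR R4
resources conforming to a nationally agreed profile layer, the Core
Data Set (CDS). A central feasibility platform for research (the FDPG)
makes stricter assumptions than the CDS — in particular, that a
laboratory observation's LOINC code and its value representation
(scale type and UCUM unit) match a curated metadata table. The gap
between what the CDS guarantees and what the platform assumes shows up
as *discrepancies* in real instance data: wrong or mis-cased codes,
lexical system-URL variants, missing mandatory elements, heterogeneous
units, incomplete consent hierarchies, unsupported medication
representations.

`fhirqc` reimplements that discrepancy analysis as an offline,
self-contained toolkit: a layered profile model with per-layer
violation attribution, a profile forge that derives the stricter layer
from the metadata table, a UCUM engine that classifies unit pairs, a
classifier that maps raw validation issues onto a discrepancy
taxonomy, and a synthetic multi-site generator that makes the whole
pipeline testable without access to any hospital's data.

## Layered profiles and violation attribution

Profiles are constraint sets over dotted element paths (with `:slice`
names), tagged with a conformance layer: `FHIR_BASE` (the core
resource), `CDS`, and `FDPG` (the use-case layer). A chain is resolved
base→leaf; the effective constraint per path is the most constrained
one, and every facet remembers the profile that *introduced* it.

Validation evaluates the profiles of a chain in base→leaf order and
lets the first layer whose stated constraint a value violates own the
issue (one issue per path × constraint kind). This gives the
attribution property the analysis relies on: the issues attributed at
or below CDS when validating the full chain are exactly the issues of
validating the CDS profile alone. Supported checks: cardinality,
fixed values (exact subtree equality), patterns (structural
containment: every pattern property must be present and equal,
recursively; pattern array elements must each match some instance
element), choice-type restriction, required bindings (through the
terminology store), pattern-discriminated slices (membership =
containment of the slice's discriminating pattern, then per-slice
cardinality), and reference presence plus declared target type.
References are never resolved into a server; the pipeline runs on
extracts. FHIRPath invariants in imported StructureDefinitions are
out of scope and surface in the import report instead of failing the
import.

Display strings are not validated by default: display generation for
the German national code systems is known to vary between sites and is
treated as noise. With `check_display=True` mismatches are emitted as
warnings.

Case handling is deliberate: FHIR search for codings is case-sensitive
unless a CodeSystem says otherwise, so a coding that matches a bound
ValueSet only case-insensitively is an *error* carrying a
machine-readable `case_only` flag; the classifier turns it into its
own category rather than a generic binding violation.

## The UCUM engine

The unit engine is built on exact rational arithmetic (`fractions`),
so the power-of-ten test needs no floating-point tolerance. A curated
atom table (~55 atoms: the SI base atoms, both liter casings, mol,
the common mechanical/electrical derived units, clinical workhorses
such as `mm[Hg]`, `U`, `[IU]`, `%`, `10*n`) and the standard prefix
table are shipped as versioned CSV files. Unknown atoms are parse
errors *by design* — that is precisely what makes a non-UCUM code like
`Gpt/L` detectable.

Canonicalization reduces an expression to an 8-slot dimension vector
(length, time, mass, plane angle, temperature, charge, luminosity,
amount of substance) plus an exact rational magnitude.
Amount-of-substance is kept as its own dimension rather than reduced
to a count via Avogadro's number, so mass↔substance pairs (g vs mmol)
are reported as *requiring a molar mass* instead of producing a
spurious numeric factor. Arbitrary units (`[IU]`, `[arb]`, `[CFU]`)
carry an opaque signature and convert only to units with the identical
signature; the enzyme unit `U` follows its standard definition
(µmol/min) and is therefore measurable. Special (nonlinear) units
such as `Cel` parse but refuse linear conversion; pairs involving them
classify as complex conversions.

Pair classification is a fixed-order decision tree: exact string
equality → Greek-mu normalization and case-insensitive comparison →
parseability of the observed code → commensurability (mass/substance
shift → molar-mass class, otherwise dimension mismatch) → exact factor
(1 → equivalent representation, 10^k → power of ten with exponent k,
otherwise complex). Because the lexical steps come first, a pair whose
strings differ only by case is a case variant *even when* the codes
also denote different magnitudes (milli `mg/L` vs mega `Mg/L`); this
mirrors how such data problems present in practice and keeps the
decision tree total and deterministic. Annotations in braces compare
as unity and are stripped before common-unit-list membership. The
`bfarm_listed` flag — membership of the (Greek-normalized,
annotation-stripped) observed code in the common-unit list — is
computed independently of the category.

A separately written, deliberately naive reference canonicalizer
(`fhirqc.ucum.bruteforce`: own tokenizer, recursive table
substitution, no caching) serves as an in-repo oracle; the test suite
and the acceptance script assert exact rational agreement on a shipped
60-pair fixture.

The shipped common-unit list is a documented placeholder containing
the units common in German laboratory reporting; production analyses
should point `load_bfarm_units()` at the published list.

## Profile forge

Per-LOINC laboratory profiles encode the code–value interdependency
from the MDR table: the LOINC coding slice is pinned to the specific
code; quantitative codes restrict `value[x]` to a Quantity with the
UCUM system fixed and the code fixed to the single expected unit
(exactly one unit per entry — the single-unit assumption is what
surfaces the discrepancies under study); qualitative codes restrict
the value to a CodeableConcept bound to the code's answer list, or to
the general-purpose qualitative ValueSet when no answer list exists.
That general ValueSet contains many representations of the same
concept; an equivalence map collapses them to canonical
representatives at forge time. Profile URLs are deterministic (base
URI + LOINC code), making the CDS→FDPG substitution map trivial to
audit.

Coded-module profiles mandate a coding from the respective national
code system (ICD-10-GM for diagnoses, OPS for procedures, ATC for
medications, a SNOMED specimen subset) plus a technical patient
reference. The substitution map is a plain URL map for these modules;
the laboratory module is code-dependent (one CDS profile, many
per-LOINC targets), so the map resolves lab claims through the
instance's LOINC coding.

## Discrepancy taxonomy

Each error-severity issue maps to exactly one record, deterministically:

* missing-cardinality → `MISSING_MANDATORY`, with `Procedure.category`
  special-cased to `MISSING_PROCEDURE_CATEGORY`;
* a failed coding slice whose instance codings carry a *lexical
  variant* of the required system URI (scheme, trailing slash,
  documented aliases such as the historical DIMDI URLs) →
  `WRONG_SYSTEM_URL`; the normalization is conservative — a genuinely
  different system never matches;
* case-only binding matches → `CODE_CASE_MISMATCH`;
* value-type vs MDR-scale conflicts → `SCALE_QUAL_FOR_QUANT` /
  `SCALE_QUANT_FOR_QUAL`, the former flagged as an invalid-measurement
  coding when the concept is in the configured invalid-concept list
  (site-local "invalid"/"not measurable" codings are configuration,
  since real deployments use heterogeneous in-house solutions);
* fixed-unit failures → `UNIT_DISCREPANCY` carrying the full unit-pair
  classification;
* residual binding failures → `BINDING_VIOLATION`; everything else →
  `OTHER`.

A lab resource whose LOINC is absent from the MDR is reported (an
`OTHER` record with a context note), never dropped. In principle one
element could trigger several mappings with precedence scale > unit >
binding; under this validator's semantics the triggering issues are
mutually exclusive per element (a wrong value type suppresses the unit
constraints structurally), so the 1:1 issue→record mapping and the
precedence rule coincide.

Two findings are not expressible as single profile constraints and are
produced by dedicated checks: consent hierarchy closure (an
encompassing permission whose implied specific permissions — the
transitive part-of descendants in the policy CodeSystem, optionally
intersected with a configured required-code set — are not all listed
yields one gap record; provisions from foreign code systems such as
consent-management exports are tolerated and reported once,
informationally) and the medication representation form (3 resource
types × reference/inline = 6 forms, of which only
MedicationAdministration-with-Medication-reference is queryable by the
platform; the other five yield an unsupported-form record).

## Synthetic multi-site data

The generator emulates the heterogeneity catalogued across real sites:
per-site unit variants with known intended classes, uppercase OPS
codes, missing mandatory elements, lexical system-URL variants, scale
mismatches (including invalid-measurement codings), consent-hierarchy
gaps, foreign provision codings, medication form switches, and
answer-list violations. It does *not* emulate clinically realistic
longitudinal records, value plausibility, or cross-resource
consistency — passing tests demonstrate that the pipeline measures
what was injected, not that real data would be clean.

Design choices: at most one injection per resource (categories are
tried in seeded random order, first Bernoulli success wins), which
keeps ground-truth counting unambiguous at the cost of a small
downward bias in per-category marginal rates when several categories
share a resource type (at the default rates the bias is far inside the
binomial noise the tests allow). Quantity values are drawn uniformly
from per-LOINC plausible ranges in the MDR fixture; plausibility is
not validated. Resource ids are deterministic functions of (site id,
type, index), and the stream is seeded per site config, so identical
configurations produce byte-identical bundles and the same
configuration under two site ids differs only in the ids.

The default per-site size (50 patients plus 120 clinical resources
across six types) keeps a 20-site simulation under a second; the
acceptance runs use 100 resources per type for the clean-closure check
and 1000 resources for injection recovery — sizes chosen so the whole
pipeline, including validation and classification, completes in
seconds while every category still occurs many times.

## Reporting

Site reports count records per layer and per category and tabulate the
lab discrepancies as (LOINC, expected unit, observed unit, class)
rows. The stepwise reduction analysis mirrors the published analysis
order — distinct discrepant codes, minus case/Greek variants, filtered
by common-unit-list membership of the observed unit, the remainder
partitioned into powers of ten versus everything else — and is
ambiguous between code-level and instance-level counting in the
original, so both views are emitted: distinct (LOINC, observed unit)
pairs as the primary view, with parallel instance counts. Aggregation
commutes with concatenation, so cross-site numbers are independent of
site partitioning. PDF rendering is replaced by JSON and CSV outputs;
the validation report JSON schema (version 1) is documented in
`fhirqc.pipeline.issues_report`.

## Numerical and degenerate-input choices

All unit arithmetic is exact; no tolerances exist anywhere in the
engine. Sampling sorts claimers by resource id and samples without
replacement with a caller-supplied seed, so equal stores and seeds
give identical samples; an empty store is a warning with an empty
sample, not an error. Issue lists are sorted (path, kind, layer) and
classification is a pure function of its inputs. Degenerate profile
registries (missing base, base cycles, duplicate URLs) raise dedicated
errors; an unparseable *expected* unit in a profile raises a
configuration error rather than producing a data-discrepancy record.

## Known limitations

* The StructureDefinition subset is pragmatic: no snapshot generation
  parity with the reference tooling, no FHIRPath evaluation, no
  extension authoring; re-slicing and non-pattern discriminators are
  not supported.
* The terminology store holds curated fragments; real deployments must
  load full ValueSet expansions (the store reads standard
  CodeSystem/ValueSet JSON).
* The baseline CDS/core profiles are programmatically built stand-ins
  with the same shape as the published packages, not the packages
  themselves; the shipped code-system fragments and the specimen
  top-50 subset are synthetic test fixtures.
* The UCUM atom table is curated, not the full catalogue; units
  defined via irrational constants (e.g. degree via π) are excluded to
  preserve exact arithmetic.
* Postcoordinated SNOMED expressions are treated as opaque codes.
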