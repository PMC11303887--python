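"""Classify expected-vs-observed UCUM unit pairs into the taxonomy.

A laboratory profile expects one specific UCUM unit per LOINC code; the
instance data at a site may use something else.  The classifier says how
far apart the two codes are: identical, a lexical (case/Greek) variant,
the same quantity written differently, a power of ten off, convertible
only with a molar mass or a more complex calculation, dimensionally
incompatible, or simply not valid UCUM.
"""

from fhirqc import classify_unit_pair, conversion_factor, load_bfarm_units

pairs = [
    ("mg/L", "mg/L"),     # identical
    ("mg/L", "mg/l"),     # lowercase liter
    ("umol/L", "μmol/L"),  # Greek mu instead of ASCII u
    ("ng/mL", "ug/L"),    # same quantity, different spelling
    ("mg/L", "ug/dl"),    # factor 100
    ("mm[Hg]", "kPa"),    # needs the mercury-column constant
    ("g/L", "mmol/L"),    # needs the analyte's molar mass
    ("%", "g/dL"),        # different dimensions entirely
    ("10*3/uL", "Gpt/L"),  # "giga particles" is not a UCUM code
]

common_units = load_bfarm_units()

print(f"{'expected':>10} {'observed':>10}  classification")
for expected, observed in pairs:
    result = classify_unit_pair(expected, observed, common_units)
    extra = ""
    if result.power_exponent is not None:
        extra = f" (10^{result.power_exponent})"
    elif result.category.value in ("EQUIVALENT_REPRESENTATION",):
        extra = f" (factor {conversion_factor(expected, observed)})"
    listed = "on common list" if result.bfarm_listed else "off list"
    print(f"{expected:>10} {observed:>10}  {result.category.value}"
          f"{extra} [{listed}]")

# The classification drives the discrepancy analysis: EXACT/CASE/GREEK/
# EQUIVALENT and POWER_OF_TEN pairs are "simply resolvable" by lexical
# cleanup or a scale factor; MOLAR/COMPLEX need real conversion logic,
# and INVALID/DIMENSION point at data errors.
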