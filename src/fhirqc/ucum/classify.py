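"""Classification of expected/observed unit pairs into the discrepancy taxonomy.

The classifier is a fixed-order decision tree over the pair of unit
strings: exact string equality, then lexical normalization (Greek mu,
case-insensitive comparison), then parseability of the observed code,
then commensurability, then the exact conversion factor (1, a power of
ten, or anything requiring a more complex calculation).  Mass-vs-amount
incommensurability is singled out because the conversion exists but
needs an analyte-specific molar mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Collection

from .canonical import canonicalize, power_of_ten_exponent
from .errors import ParseError, ProfileUnitError
from .parser import normalize_lexical, parse_unit, strip_annotations
from .tables import AMOUNT_SLOT, MASS_SLOT, UcumTables, load_tables


class UnitCategory(str, Enum):
    EXACT_MATCH = "EXACT_MATCH"
    CASE_VARIANT = "CASE_VARIANT"
    GREEK_VARIANT = "GREEK_VARIANT"
    EQUIVALENT_REPRESENTATION = "EQUIVALENT_REPRESENTATION"
    POWER_OF_TEN = "POWER_OF_TEN"
    COMPLEX_CONVERSION = "COMPLEX_CONVERSION"
    MOLAR_MASS_REQUIRED = "MOLAR_MASS_REQUIRED"
    DIMENSION_MISMATCH = "DIMENSION_MISMATCH"
    INVALID_UCUM = "INVALID_UCUM"


@dataclass(frozen=True)
class UnitPairClass:
    """Result of classifying one (expected, observed) unit pair."""

    category: UnitCategory
    power_exponent: int | None = None  # POWER_OF_TEN only, never 0
    bfarm_listed: bool = False  # observed unit on the common-unit list
    applied_normalizations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        has_exp = self.power_exponent is not None
        if has_exp != (self.category is UnitCategory.POWER_OF_TEN):
            raise ValueError("power_exponent present iff POWER_OF_TEN")
        if has_exp and self.power_exponent == 0:
            raise ValueError("a factor of 1 is EQUIVALENT_REPRESENTATION")


def _molar_mass_pair(dims_a: tuple[int, ...], dims_b: tuple[int, ...]) -> bool:
    """True when the vectors differ only in the mass and substance slots."""
    diff = [a - b for a, b in zip(dims_a, dims_b)]
    for slot, value in enumerate(diff):
        if value and slot not in (MASS_SLOT, AMOUNT_SLOT):
            return False
    return bool(diff[MASS_SLOT]) and bool(diff[AMOUNT_SLOT])


def classify_unit_pair(expected: str, observed: str,
                       bfarm_list: Collection[str] = (),
                       tables: UcumTables | None = None) -> UnitPairClass:
    """Classify an expected/observed UCUM pair.

    ``expected`` comes from a profile and must parse
    (:class:`ProfileUnitError` otherwise — a configuration fault, not a
    data discrepancy); ``observed`` is arbitrary instance data.  The
    ``bfarm_listed`` flag is set independently of the category by
    membership of the (Greek-normalized, annotation-stripped) observed
    code in ``bfarm_list``.
    """
    tables = tables or load_tables()
    norm_expected, greek_expected = normalize_lexical(expected)
    norm_observed, greek_observed = normalize_lexical(observed)
    bfarm_listed = strip_annotations(norm_observed) in set(bfarm_list)

    def result(category: UnitCategory, exponent: int | None = None,
               applied: frozenset[str] = frozenset()) -> UnitPairClass:
        return UnitPairClass(category, exponent, bfarm_listed, applied)

    # 1. exact string equality
    if expected == observed:
        return result(UnitCategory.EXACT_MATCH)

    # 2. lexical: greek mapping, then case-insensitive comparison
    greek_applied = greek_expected | greek_observed
    if norm_expected == norm_observed:
        return result(UnitCategory.GREEK_VARIANT, applied=greek_applied)
    if norm_expected.casefold() == norm_observed.casefold():
        applied = greek_applied | {"case"}
        category = (UnitCategory.GREEK_VARIANT if greek_applied
                    else UnitCategory.CASE_VARIANT)
        return result(category, applied=applied)

    # 3. observed must parse (after greek normalization)
    try:
        observed_expr = parse_unit(norm_observed, tables)
    except ParseError:
        return result(UnitCategory.INVALID_UCUM, applied=greek_applied)

    try:
        expected_expr = parse_unit(expected, tables)
    except ParseError as exc:
        raise ProfileUnitError(
            f"profile unit {expected!r} does not parse: {exc}") from exc

    # nonlinear units refuse a linear factor
    canon_expected = canonicalize(expected_expr, tables, allow_special=True)
    canon_observed = canonicalize(observed_expr, tables, allow_special=True)
    if canon_expected.is_special or canon_observed.is_special:
        return result(UnitCategory.COMPLEX_CONVERSION, applied=greek_applied)

    # 4. incommensurable pairs
    if not canon_expected.commensurable_with(canon_observed):
        if (canon_expected.arbitrary == canon_observed.arbitrary
                and _molar_mass_pair(canon_expected.dimensions,
                                     canon_observed.dimensions)):
            return result(UnitCategory.MOLAR_MASS_REQUIRED,
                          applied=greek_applied)
        return result(UnitCategory.DIMENSION_MISMATCH, applied=greek_applied)

    # 5./6./7. exact factor: unity, power of ten, or complex
    ratio = canon_expected.magnitude / canon_observed.magnitude
    if ratio == 1:
        return result(UnitCategory.EQUIVALENT_REPRESENTATION,
                      applied=greek_applied)
    exponent = power_of_ten_exponent(ratio)
    if exponent is not None:
        return result(UnitCategory.POWER_OF_TEN, exponent,
                      applied=greek_applied)
    return result(UnitCategory.COMPLEX_CONVERSION, applied=greek_applied)
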