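"""Canonicalization of unit expressions and exact conversion factors.

A :class:`CanonicalUnit` is an 8-slot signed dimension vector over
(length, time, mass, plane-angle, temperature, charge, luminosity,
amount-of-substance) plus an exact rational magnitude relative to the
base atoms (m, s, g, rad, K, C, cd, mol).  Amount-of-substance is kept
as its own dimension slot rather than being reduced to a count, so that
mass/substance pairs (mmol vs g) surface as requiring a molar mass
instead of yielding a spurious numeric factor.

Arbitrary atoms such as [IU] are carried as an opaque signature: they
are commensurable only with units carrying the identical signature.
Special (nonlinear) units such as Cel are parseable but refuse linear
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .errors import ArbitraryUnitError, IncommensurableError, SpecialUnitError
from .parser import UnitExpression, parse_unit
from .tables import DIMENSIONS, UcumTables, load_tables

_ZERO_DIMS = (0,) * len(DIMENSIONS)


@dataclass(frozen=True)
class CanonicalUnit:
    """Dimension vector + exact rational magnitude of a unit expression."""

    dimensions: tuple[int, ...]
    magnitude: Fraction
    arbitrary: tuple[tuple[str, int], ...] = ()  # sorted (atom, exponent)
    is_special: bool = False

    @property
    def is_arbitrary(self) -> bool:
        return bool(self.arbitrary)

    def __mul__(self, other: "CanonicalUnit") -> "CanonicalUnit":
        dims = tuple(a + b for a, b in zip(self.dimensions, other.dimensions))
        arb: dict[str, int] = dict(self.arbitrary)
        for atom, exp in other.arbitrary:
            arb[atom] = arb.get(atom, 0) + exp
        return CanonicalUnit(
            dimensions=dims,
            magnitude=self.magnitude * other.magnitude,
            arbitrary=tuple(sorted((a, e) for a, e in arb.items() if e)),
            is_special=self.is_special or other.is_special,
        )

    def __pow__(self, power: int) -> "CanonicalUnit":
        return CanonicalUnit(
            dimensions=tuple(d * power for d in self.dimensions),
            magnitude=self.magnitude ** power,
            arbitrary=tuple(sorted((a, e * power) for a, e in self.arbitrary)),
            is_special=self.is_special,
        )

    def commensurable_with(self, other: "CanonicalUnit") -> bool:
        return (self.dimensions == other.dimensions
                and self.arbitrary == other.arbitrary)


_ATOM_CACHE: dict[int, dict[str, CanonicalUnit]] = {}


def _canonical_atom(symbol: str, tables: UcumTables) -> CanonicalUnit:
    """Canonical form of one unprefixed atom, by recursive substitution."""
    cache = _ATOM_CACHE.setdefault(id(tables), {})
    if symbol in cache:
        return cache[symbol]
    atom = tables.atoms[symbol]
    if atom.kind == "base":
        dims = list(_ZERO_DIMS)
        dims[DIMENSIONS.index(atom.dimension)] = 1
        result = CanonicalUnit(tuple(dims), Fraction(1))
    elif atom.kind == "arbitrary":
        result = CanonicalUnit(_ZERO_DIMS, Fraction(1), ((symbol, 1),))
    else:  # derived or special: value * definition-unit
        definition = _canonicalize(parse_unit(atom.definition, tables), tables)
        result = CanonicalUnit(
            dimensions=definition.dimensions,
            magnitude=atom.value * definition.magnitude,
            arbitrary=definition.arbitrary,
            is_special=definition.is_special or atom.kind == "special",
        )
    cache[symbol] = result
    return result


def _canonicalize(expr: UnitExpression, tables: UcumTables) -> CanonicalUnit:
    result = CanonicalUnit(_ZERO_DIMS, expr.numeric_factor)
    for comp in expr.components:
        base = _canonical_atom(comp.atom, tables)
        scaled = CanonicalUnit(
            base.dimensions,
            base.magnitude * Fraction(10) ** comp.prefix_exponent,
            base.arbitrary,
            base.is_special,
        )
        result = result * scaled ** comp.exponent
    return result


def canonicalize(expr: UnitExpression | str,
                 tables: UcumTables | None = None,
                 allow_special: bool = False) -> CanonicalUnit:
    """Reduce an expression to base dimensions and an exact magnitude.

    Canonicalization is idempotent and multiplicative.  Nonlinear units
    raise :class:`SpecialUnitError` unless ``allow_special`` is set, in
    which case the returned unit carries ``is_special=True`` and refuses
    conversion downstream.
    """
    tables = tables or load_tables()
    if isinstance(expr, str):
        expr = parse_unit(expr, tables)
    result = _canonicalize(expr, tables)
    if result.is_special and not allow_special:
        raise SpecialUnitError(
            f"{expr.source!r} contains a nonlinear (special) unit")
    return result


def conversion_factor(a: UnitExpression | str, b: UnitExpression | str,
                      tables: UcumTables | None = None) -> Fraction:
    """Exact rational ``r`` such that ``1 * a == r * b``.

    Raises :class:`IncommensurableError` when the dimension vectors
    differ, :class:`ArbitraryUnitError` when the arbitrary-unit
    signatures differ, and :class:`SpecialUnitError` for nonlinear units.
    """
    tables = tables or load_tables()
    ca = canonicalize(a, tables)
    cb = canonicalize(b, tables)
    if ca.arbitrary != cb.arbitrary:
        raise ArbitraryUnitError(
            "arbitrary units are commensurable only with themselves: "
            f"{ca.arbitrary} vs {cb.arbitrary}")
    if ca.dimensions != cb.dimensions:
        raise IncommensurableError(
            f"dimension vectors differ: {ca.dimensions} vs {cb.dimensions}")
    return ca.magnitude / cb.magnitude


def power_of_ten_exponent(ratio: Fraction) -> int | None:
    """``k`` when ``ratio == 10**k`` with integer ``k != 0``, else ``None``."""
    num, den = ratio.numerator, ratio.denominator
    if num == 1 and den == 1:
        return None
    for value, sign in ((num, 1), (den, -1)):
        if value == 1:
            continue
        k = 0
        while value % 10 == 0:
            value //= 10
            k += 1
        if value != 1:
            return None
        if sign == 1 and den != 1:
            return None
        return sign * k
    return None
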