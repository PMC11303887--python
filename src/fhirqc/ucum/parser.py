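"""Parser and serializer for UCUM unit expressions.

The grammar covers the subset of UCUM used in laboratory data exchange:
``.`` and ``/`` operators (left to right, ``/`` inverting the following
component only), a leading ``/``, parenthesized terms, integer factors,
the ``10*n``/``10^n`` power atoms, signed integer exponents, and
``{annotation}`` terms which are semantically unity.  UCUM codes are
case-sensitive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction

from .errors import ParseError
from .tables import NUMBER_ATOMS, UcumTables, load_tables

_EXPONENT_RE = re.compile(r"[+-]?\d+$")
_INTEGER_RE = re.compile(r"\d+$")

#: Both Unicode micro signs map to the ASCII ``u`` UCUM uses.
GREEK_MICRO_SIGNS = ("μ", "µ")


@dataclass(frozen=True)
class Component:
    """One prefixed atom raised to a signed integer exponent."""

    prefix_exponent: int  # power of ten contributed by the prefix
    atom: str  # atom symbol from the shipped table
    exponent: int  # signed, never 0


@dataclass(frozen=True)
class UnitExpression:
    """A parsed UCUM expression.

    ``numeric_factor`` collects integer factors and ``10*n`` atoms as an
    exact rational; ``annotations`` are the brace-delimited comments, which
    are semantically unity.
    """

    source: str
    components: tuple[Component, ...]
    numeric_factor: Fraction = Fraction(1)
    annotations: tuple[str, ...] = ()

    def _key(self) -> tuple:
        # component multiset: UCUM multiplication commutes, and the
        # serializer groups positive and negative exponents
        components = tuple(sorted(
            self.components,
            key=lambda c: (c.atom, c.prefix_exponent, c.exponent)))
        return (components, self.numeric_factor,
                tuple(sorted(self.annotations)))

    def __eq__(self, other: object) -> bool:  # source string is not identity
        if not isinstance(other, UnitExpression):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())


@dataclass
class _State:
    components: list[Component] = field(default_factory=list)
    factor: Fraction = Fraction(1)
    annotations: list[str] = field(default_factory=list)


class _Parser:
    def __init__(self, code: str, tables: UcumTables):
        self.code = code
        self.tables = tables
        self.pos = 0

    def error(self, reason: str, pos: int | None = None) -> ParseError:
        return ParseError(self.code, self.pos if pos is None else pos, reason)

    def peek(self) -> str:
        return self.code[self.pos] if self.pos < len(self.code) else ""

    # -- grammar -----------------------------------------------------------

    def parse(self) -> _State:
        state = _State()
        self.term(state, sign=1)
        if self.pos != len(self.code):
            raise self.error("unexpected trailing input")
        return state

    def term(self, state: _State, sign: int) -> None:
        if not self.peek():
            raise self.error("empty component")
        op_sign = sign
        if self.peek() == "/":  # leading division
            self.pos += 1
            op_sign = -sign
        self.component(state, op_sign)
        while self.peek() in (".", "/"):
            op = self.code[self.pos]
            self.pos += 1
            self.component(state, sign if op == "." else -sign)

    def component(self, state: _State, sign: int) -> None:
        ch = self.peek()
        if not ch:
            raise self.error("empty component")
        if ch == "(":
            self.pos += 1
            inner = _State()
            self.term(inner, sign=1)
            if self.peek() != ")":
                raise self.error("unbalanced parenthesis")
            self.pos += 1
            exponent = self.trailing_group_exponent()
            power = sign * exponent
            for comp in inner.components:
                state.components.append(
                    Component(comp.prefix_exponent, comp.atom,
                              comp.exponent * power))
            state.factor *= inner.factor ** power
            state.annotations.extend(inner.annotations)
            return
        if ch == "{":
            state.annotations.append(self.annotation())
            return
        token, start = self.symbol_token()
        self.simple_unit(state, token, start, sign)
        if self.peek() == "{":  # annotation attached to a unit is unity
            state.annotations.append(self.annotation())

    def annotation(self) -> str:
        end = self.code.find("}", self.pos)
        if end < 0:
            raise self.error("unterminated annotation")
        text = self.code[self.pos + 1:end]
        self.pos = end + 1
        return text

    def symbol_token(self) -> tuple[str, int]:
        start = self.pos
        while self.pos < len(self.code) and self.code[self.pos] not in "./(){}":
            if self.code[self.pos].isspace():
                raise self.error("whitespace in unit code")
            self.pos += 1
        token = self.code[start:self.pos]
        if not token:
            raise self.error("empty component", start)
        return token, start

    def trailing_group_exponent(self) -> int:
        """An integer exponent directly after a closing parenthesis."""
        match = re.match(r"[+-]?\d+", self.code[self.pos:])
        if not match:
            return 1
        self.pos += match.end()
        exponent = int(match.group())
        if exponent == 0:
            raise self.error("zero exponent")
        return exponent

    def simple_unit(self, state: _State, token: str, start: int,
                    sign: int) -> None:
        if _INTEGER_RE.fullmatch(token):  # pure integer factor
            state.factor *= Fraction(int(token)) ** sign
            return
        # split a trailing exponent, but never inside a bracketed atom part
        bracket = token.rfind("]")
        tail = token[bracket + 1:]
        match = _EXPONENT_RE.search(tail)
        if match:
            symbol = token[:bracket + 1 + match.start()]
            exponent = int(match.group())
            if exponent == 0:
                raise self.error("zero exponent", start)
            if not symbol:
                raise self.error("malformed exponent", start)
        else:
            symbol, exponent = token, 1
        resolved = self.tables.resolve_symbol(symbol)
        if resolved is None:
            raise self.error(f"unknown atom {symbol!r}", start)
        prefix_exponent, atom = resolved
        if atom.symbol in NUMBER_ATOMS:
            state.factor *= Fraction(10) ** (sign * exponent)
            return
        state.components.append(
            Component(prefix_exponent, atom.symbol, sign * exponent))


def parse_unit(code: str, tables: UcumTables | None = None) -> UnitExpression:
    """Parse a UCUM unit code into a :class:`UnitExpression`.

    Raises :class:`~fhirqc.ucum.errors.ParseError` (with position and
    reason) for anything outside the shipped atom/prefix tables or the
    supported grammar; such codes are exactly the ``INVALID_UCUM`` branch
    of the discrepancy taxonomy.
    """
    if not isinstance(code, str) or not code:
        raise ParseError(str(code), 0, "empty component")
    tables = tables or load_tables()
    state = _Parser(code, tables).parse()
    return UnitExpression(
        source=code,
        components=tuple(state.components),
        numeric_factor=state.factor,
        annotations=tuple(state.annotations),
    )


def serialize(expr: UnitExpression, tables: UcumTables | None = None) -> str:
    """Serialize an expression back to a UCUM string.

    Round-trip contract: ``parse_unit(serialize(e)) == e``.
    """
    tables = tables or load_tables()

    def piece(comp: Component, exponent: int) -> str:
        prefix = tables.prefix_symbol(comp.prefix_exponent)
        return f"{prefix}{comp.atom}" + (str(exponent) if exponent != 1 else "")

    positive: list[str] = []
    negative: list[str] = []
    num = expr.numeric_factor.numerator
    den = expr.numeric_factor.denominator
    if num != 1:
        positive.append(str(num))
    for comp in expr.components:
        if comp.exponent > 0:
            positive.append(piece(comp, comp.exponent))
        else:
            negative.append(piece(comp, -comp.exponent))
    positive.extend("{%s}" % a for a in expr.annotations)
    out = ".".join(positive) if positive else "1"
    if den != 1:
        out += f"/{den}"
    for item in negative:
        out += f"/{item}"
    return out


def normalize_lexical(code: str) -> tuple[str, frozenset[str]]:
    """Map Greek mu characters (U+03BC, U+00B5) to ASCII ``u``.

    Returns the normalized code and the set of applied normalizations
    (``{"greek"}`` or empty).  Case is deliberately *not* folded here:
    UCUM codes are case-sensitive and folding can change meaning, so case
    handling stays a lexical comparison inside the pair classifier.
    """
    normalized = code
    for sign in GREEK_MICRO_SIGNS:
        normalized = normalized.replace(sign, "u")
    applied = frozenset({"greek"}) if normalized != code else frozenset()
    return normalized, applied


_ANNOTATION_RE = re.compile(r"\{[^}]*\}")


def strip_annotations(code: str) -> str:
    """Remove ``{...}`` annotations, tidying the operators left behind."""
    out = _ANNOTATION_RE.sub("", code)
    out = re.sub(r"\.(?=[./])", "", out)  # ".." or "./" after removal
    out = out.strip(".")
    return out or "1"
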