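"""Naive reference canonicalizer for self-verification.

This module is a deliberately simple, separately written implementation
of UCUM canonicalization: it re-reads the shipped CSV tables on every
call, tokenizes with a single regular expression, and reduces derived
atoms by plain recursive substitution with no caching or shared code
with the main engine.  It exists purely as an independent cross-check
for :func:`fhirqc.ucum.conversion_factor`; it is not part of the public
validation pipeline.
"""

from __future__ import annotations

import csv
import re
from fractions import Fraction
from importlib.resources import files

_TOKEN = re.compile(r"\{[^}]*\}|[./()]|[^./(){}]+")
_BASE_DIMS = ("length", "time", "mass", "angle", "temperature", "charge",
              "luminosity", "amount")


def _read_tables():
    data = files("fhirqc.data")
    with (data / "ucum_prefixes.csv").open(encoding="utf-8") as handle:
        prefixes = {row["symbol"]: int(row["exponent"])
                    for row in csv.DictReader(handle)}
    with (data / "ucum_atoms.csv").open(encoding="utf-8") as handle:
        atoms = {row["symbol"]: row for row in csv.DictReader(handle)}
    return prefixes, atoms


def _rational(text: str) -> Fraction:
    if "/" in text:
        num, den = text.split("/")
        return Fraction(int(num), int(den))
    return Fraction(int(text))


class _Quantity:
    """A magnitude with per-dimension and per-arbitrary-atom exponents."""

    def __init__(self):
        self.magnitude = Fraction(1)
        self.dims: dict[str, int] = {}
        self.special = False

    def times(self, other: "_Quantity", power: int) -> None:
        self.magnitude *= other.magnitude ** power
        for key, exp in other.dims.items():
            new = self.dims.get(key, 0) + exp * power
            if new:
                self.dims[key] = new
            else:
                self.dims.pop(key, None)
        self.special = self.special or other.special


def _expand_symbol(symbol: str, prefixes, atoms) -> _Quantity:
    out = _Quantity()
    row = atoms.get(symbol)
    prefix_power = 0
    if row is None:
        for psym in sorted(prefixes, key=len, reverse=True):
            rest = symbol[len(psym):]
            if symbol.startswith(psym) and rest in atoms \
                    and atoms[rest]["metric"] == "1":
                prefix_power = prefixes[psym]
                row = atoms[rest]
                break
    if row is None:
        raise ValueError(f"unknown symbol {symbol!r}")
    out.magnitude = Fraction(10) ** prefix_power
    kind = row["kind"]
    if kind == "base":
        out.dims[row["dimension"]] = 1
    elif kind == "arbitrary":
        out.dims["arb:" + row["symbol"]] = 1
    else:
        definition = _evaluate(row["unit"], prefixes, atoms)
        out.magnitude *= _rational(row["value"]) * definition.magnitude
        for key, exp in definition.dims.items():
            out.dims[key] = out.dims.get(key, 0) + exp
        out.special = definition.special or kind == "special"
    return out


def _evaluate(code: str, prefixes, atoms) -> _Quantity:
    tokens = _TOKEN.findall(code)
    if "".join(tokens) != code:
        raise ValueError(f"cannot tokenize {code!r}")
    result = _Quantity()
    pos = 0

    def term(pos: int, depth: int) -> tuple[_Quantity, int]:
        out = _Quantity()
        sign = 1
        if pos < len(tokens) and tokens[pos] == "/":
            sign = -1
            pos += 1
        expect_operand = True
        while pos < len(tokens):
            tok = tokens[pos]
            if expect_operand:
                if tok == "(":
                    inner, pos = term(pos + 1, depth + 1)
                    if pos >= len(tokens) or tokens[pos] != ")":
                        raise ValueError("unbalanced parenthesis")
                    pos += 1
                    power = 1
                    if pos < len(tokens) and re.fullmatch(r"[+-]?\d+",
                                                          tokens[pos]):
                        power = int(tokens[pos])
                        pos += 1
                    out.times(inner, sign * power)
                elif tok.startswith("{"):
                    pos += 1  # annotation: unity
                else:
                    out.times(_atom_token(tok), sign)
                    pos += 1
                    if pos < len(tokens) and tokens[pos].startswith("{"):
                        pos += 1
                expect_operand = False
                sign = 1
            else:
                if tok == ".":
                    sign, pos, expect_operand = 1, pos + 1, True
                elif tok == "/":
                    sign, pos, expect_operand = -1, pos + 1, True
                elif tok == ")" and depth:
                    return out, pos
                else:
                    raise ValueError(f"unexpected token {tok!r}")
        if expect_operand:
            raise ValueError("dangling operator")
        return out, pos

    def _atom_token(tok: str) -> _Quantity:
        if re.fullmatch(r"\d+", tok):
            out = _Quantity()
            out.magnitude = Fraction(int(tok))
            return out
        bracket = tok.rfind("]")
        match = re.search(r"[+-]?\d+$", tok[bracket + 1:])
        if match:
            symbol = tok[:bracket + 1 + match.start()]
            power = int(match.group())
        else:
            symbol, power = tok, 1
        if symbol in ("10*", "10^"):
            out = _Quantity()
            out.magnitude = Fraction(10) ** power
            return out
        out = _Quantity()
        out.times(_expand_symbol(symbol, prefixes, atoms), power)
        return out

    result, pos = term(0, 0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in {code!r}")
    return result


def brute_canonicalize(code: str) -> tuple[dict[str, int], Fraction, bool]:
    """Dimension map, magnitude and special flag by naive substitution."""
    prefixes, atoms = _read_tables()
    quantity = _evaluate(code, prefixes, atoms)
    return dict(quantity.dims), quantity.magnitude, quantity.special


def brute_conversion_factor(unit_a: str, unit_b: str) -> Fraction:
    """Independent oracle for ``conversion_factor`` (commensurable pairs)."""
    dims_a, mag_a, special_a = brute_canonicalize(unit_a)
    dims_b, mag_b, special_b = brute_canonicalize(unit_b)
    if special_a or special_b:
        raise ValueError("special unit refuses conversion")
    if dims_a != dims_b:
        raise ValueError(f"incommensurable: {dims_a} vs {dims_b}")
    return mag_a / mag_b
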