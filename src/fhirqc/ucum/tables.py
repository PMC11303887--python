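"""Curated UCUM prefix and atom tables.

The tables are shipped as versioned CSV data files.  The atom table is a
deliberately small, curated subset of UCUM (SI base units, liter in both
casings, mol, the common derived mechanical/electrical units, clinical
workhorses such as mm[Hg], U, [IU], %, and the ``10*``/``10^`` power atoms).
Unknown atoms are parse errors by design: that is exactly what makes
non-UCUM codes such as ``Gpt/L`` detectable.

Columns of ``ucum_atoms.csv``:

symbol
    the case-sensitive UCUM atom code (may contain brackets, e.g. ``m[Hg]``)
kind
    ``base`` | ``derived`` | ``arbitrary`` | ``special``
metric
    1 if the atom accepts an SI prefix
value, unit
    for derived/special atoms, the definition ``value * unit`` as an exact
    rational and a UCUM expression over other table atoms; the definition
    graph is acyclic
dimension
    for base atoms, the name of the base dimension slot
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from importlib.resources import files

#: The eight base dimension slots, in vector order.
DIMENSIONS = (
    "length",
    "time",
    "mass",
    "angle",
    "temperature",
    "charge",
    "luminosity",
    "amount",
)

MASS_SLOT = DIMENSIONS.index("mass")
AMOUNT_SLOT = DIMENSIONS.index("amount")

#: Atoms that denote a pure power of ten; they fold into the numeric factor.
NUMBER_ATOMS = ("10*", "10^")


def parse_rational(text: str) -> Fraction:
    """Parse ``p`` or ``p/q`` into an exact :class:`Fraction`."""
    if "/" in text:
        num, den = text.split("/", 1)
        return Fraction(int(num), int(den))
    return Fraction(int(text))


@dataclass(frozen=True)
class Prefix:
    symbol: str
    exponent: int  # power of ten


@dataclass(frozen=True)
class Atom:
    symbol: str
    kind: str  # base | derived | arbitrary | special
    metric: bool
    value: Fraction
    definition: str | None  # UCUM expression, None for base/arbitrary atoms
    dimension: str | None  # base dimension name, base atoms only


class UcumTables:
    """In-memory prefix/atom tables with symbol lookup helpers."""

    def __init__(self, prefixes: dict[str, Prefix], atoms: dict[str, Atom]):
        self.prefixes = prefixes
        self.atoms = atoms
        # longest-first so that "da" is tried before "d"
        self._prefixes_by_length = sorted(
            prefixes.values(), key=lambda p: -len(p.symbol)
        )
        self._exp_to_prefix = {p.exponent: p.symbol for p in prefixes.values()}

    # -- symbol resolution -------------------------------------------------

    def resolve_symbol(self, symbol: str) -> tuple[int, Atom] | None:
        """Resolve a simple-unit symbol to ``(prefix exponent, atom)``.

        Whole-symbol atoms win over prefix+atom splits (``cd`` is candela,
        not centi-day).  Prefixes attach to metric atoms only.  Returns
        ``None`` when the symbol is not in the tables.
        """
        atom = self.atoms.get(symbol)
        if atom is not None:
            return 0, atom
        for prefix in self._prefixes_by_length:
            if symbol.startswith(prefix.symbol):
                rest = self.atoms.get(symbol[len(prefix.symbol):])
                if rest is not None and rest.metric:
                    return prefix.exponent, rest
        return None

    def prefix_symbol(self, exponent: int) -> str:
        """The prefix symbol for a power-of-ten exponent (0 -> '')."""
        if exponent == 0:
            return ""
        return self._exp_to_prefix[exponent]

    @property
    def prefix_exponents(self) -> frozenset[int]:
        return frozenset(self._exp_to_prefix)


@lru_cache(maxsize=1)
def load_tables() -> UcumTables:
    """Load the shipped prefix/atom tables (cached singleton)."""
    data = files("fhirqc.data")
    prefixes: dict[str, Prefix] = {}
    with (data / "ucum_prefixes.csv").open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            prefixes[row["symbol"]] = Prefix(row["symbol"], int(row["exponent"]))
    atoms: dict[str, Atom] = {}
    with (data / "ucum_atoms.csv").open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            atoms[row["symbol"]] = Atom(
                symbol=row["symbol"],
                kind=row["kind"],
                metric=row["metric"] == "1",
                value=parse_rational(row["value"]),
                definition=row["unit"] or None,
                dimension=row["dimension"] or None,
            )
    return UcumTables(prefixes, atoms)
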