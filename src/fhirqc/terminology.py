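"""In-process terminology store: CodeSystems, ValueSets, membership queries.

The store replaces a network terminology service with offline lookup
over FHIR R4 CodeSystem/ValueSet JSON (``expansion.contains`` or
``compose.include`` with enumerated concepts, whole systems, or
``is-a``/``descendent-of`` filters).  It supports the three queries the
validation pipeline needs:

* case-sensitivity-aware ValueSet membership (FHIR search for codings is
  case-sensitive unless the CodeSystem says otherwise, so a casing
  mismatch is a real finding, not noise),
* transitive *part-of* descendants within a CodeSystem (consent policy
  hierarchies, SNOMED specimen subtree), and
* equivalence reduction of general-purpose ValueSets (collapsing the
  many representations of the same qualitative concept to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class TerminologyError(ValueError):
    pass


class UnknownSystemError(TerminologyError):
    pass


class UnknownCodeError(TerminologyError):
    pass


@dataclass
class Concept:
    code: str
    display: str | None = None
    parents: tuple[str, ...] = ()  # part-of links within the same system


@dataclass
class CodeSystemDef:
    url: str
    version: str | None = None
    case_sensitive: bool = True
    concepts: dict[str, Concept] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for concept in self.concepts.values():
            for parent in concept.parents:
                if parent not in self.concepts:
                    raise TerminologyError(
                        f"parent {parent!r} of {concept.code!r} not in "
                        f"{self.url}")
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(code: str) -> None:
            state[code] = 1
            for parent in self.concepts[code].parents:
                if state.get(parent) == 1:
                    raise TerminologyError(f"part-of cycle at {code!r}")
                if parent not in state:
                    visit(parent)
            state[code] = 2

        for code in self.concepts:
            if code not in state:
                visit(code)


@dataclass
class ValueSetDef:
    """Either an enumerated member set or descendants-of an anchor concept."""

    url: str
    members: frozenset[tuple[str, str]] = frozenset()  # (system, code)
    anchor: tuple[str, str] | None = None  # descendants-of source
    include_anchor: bool = False  # is-a (True) vs descendent-of (False)


class MembershipStatus(str, Enum):
    EXACT = "EXACT"
    CASE_ONLY = "CASE_ONLY"
    ABSENT = "ABSENT"


@dataclass(frozen=True)
class MembershipResult:
    status: MembershipStatus
    matched_code: str | None = None  # set when status != ABSENT


class TerminologyStore:
    def __init__(self) -> None:
        self.systems: dict[str, CodeSystemDef] = {}
        self.valuesets: dict[str, ValueSetDef] = {}

    # -- loading -----------------------------------------------------------

    def add_system(self, system: CodeSystemDef) -> None:
        self.systems[system.url] = system

    def add_valueset(self, valueset: ValueSetDef) -> None:
        self.valuesets[valueset.url] = valueset

    def load_codesystem_json(self, document: Mapping) -> CodeSystemDef:
        """Import a FHIR R4 CodeSystem resource (nested concepts allowed).

        Child nesting and ``parent``/``part-of`` concept properties both
        map onto the part-of links.
        """
        if document.get("resourceType") != "CodeSystem" or "url" not in document:
            raise TerminologyError("not a CodeSystem with a url")
        concepts: dict[str, Concept] = {}

        def walk(entries: Iterable[Mapping], parent: str | None) -> None:
            for entry in entries:
                parents = [parent] if parent else []
                for prop in entry.get("property", ()):
                    if prop.get("code") in ("parent", "part-of"):
                        parents.append(prop.get("valueCode"))
                concepts[entry["code"]] = Concept(
                    code=entry["code"],
                    display=entry.get("display"),
                    parents=tuple(p for p in parents if p),
                )
                walk(entry.get("concept", ()), entry["code"])

        walk(document.get("concept", ()), None)
        system = CodeSystemDef(
            url=document["url"],
            version=document.get("version"),
            case_sensitive=document.get("caseSensitive", True),
            concepts=concepts,
        )
        self.add_system(system)
        return system

    def load_valueset_json(self, document: Mapping) -> ValueSetDef:
        """Import a FHIR R4 ValueSet (expansion or compose)."""
        if document.get("resourceType") != "ValueSet" or "url" not in document:
            raise TerminologyError("not a ValueSet with a url")
        members: set[tuple[str, str]] = set()
        anchor = None
        include_anchor = False
        expansion = document.get("expansion", {}).get("contains")
        if expansion:
            for entry in expansion:
                members.add((entry["system"], entry["code"]))
        else:
            for include in document.get("compose", {}).get("include", ()):
                system = include.get("system")
                filters = include.get("filter", ())
                if filters:
                    for flt in filters:
                        if flt.get("property") not in ("concept", "parent"):
                            raise TerminologyError(
                                f"unsupported filter {flt!r}")
                        anchor = (system, flt["value"])
                        include_anchor = flt.get("op") == "is-a"
                elif "concept" in include:
                    for concept in include["concept"]:
                        members.add((system, concept["code"]))
                else:  # whole code system
                    resolved = self.systems.get(system)
                    if resolved is None:
                        raise UnknownSystemError(system)
                    members.update((system, c) for c in resolved.concepts)
        valueset = ValueSetDef(
            url=document["url"],
            members=frozenset(members),
            anchor=anchor,
            include_anchor=include_anchor,
        )
        self.add_valueset(valueset)
        return valueset

    # -- queries -----------------------------------------------------------

    def expand(self, vs: ValueSetDef | str) -> frozenset[tuple[str, str]]:
        """The full (system, code) member set of a ValueSet."""
        if isinstance(vs, str):
            vs = self.valuesets[vs]
        members = set(vs.members)
        if vs.anchor is not None:
            system_url, code = vs.anchor
            system = self.systems.get(system_url)
            if system is None:
                raise UnknownSystemError(system_url)
            members.update((system_url, c)
                           for c in self.descendants(system, code))
            if vs.include_anchor:
                members.add((system_url, code))
        return frozenset(members)

    def vs_contains(self, vs: ValueSetDef | str, system: str,
                    code: str) -> MembershipResult:
        """Membership with case-sensitivity semantics.

        EXACT on an exact (system, code) match.  Otherwise CASE_ONLY when
        a case-insensitive match exists — whether because the code system
        is registered case-insensitive or because the instance data used
        the wrong casing in a case-sensitive system; the downstream
        classifier decides the severity.  ABSENT otherwise.
        """
        members = self.expand(vs)
        if (system, code) in members:
            return MembershipResult(MembershipStatus.EXACT, code)
        folded = code.casefold()
        for member_system, member_code in sorted(members):
            if member_system == system and member_code.casefold() == folded:
                return MembershipResult(MembershipStatus.CASE_ONLY,
                                        member_code)
        return MembershipResult(MembershipStatus.ABSENT)

    def descendants(self, cs: CodeSystemDef | str, code: str) -> set[str]:
        """Transitive part-of closure below ``code`` (exclusive)."""
        if isinstance(cs, str):
            if cs not in self.systems:
                raise UnknownSystemError(cs)
            cs = self.systems[cs]
        if code not in cs.concepts:
            raise UnknownCodeError(f"{code!r} not in {cs.url}")
        children: dict[str, list[str]] = {}
        for concept in cs.concepts.values():
            for parent in concept.parents:
                children.setdefault(parent, []).append(concept.code)
        out: set[str] = set()
        stack = list(children.get(code, ()))
        while stack:
            current = stack.pop()
            if current not in out:
                out.add(current)
                stack.extend(children.get(current, ()))
        return out

    def is_leaf(self, cs: CodeSystemDef | str, code: str) -> bool:
        return not self.descendants(cs, code)


def reduce_equivalents(vs: ValueSetDef,
                       equivalence_map: Mapping[str, str]) -> ValueSetDef:
    """Replace mapped member codes with their canonical code (idempotent).

    The member count never increases; applying the reduction twice equals
    applying it once provided the map's targets are not themselves mapped
    to something else (fixed points map to themselves).
    """
    members = frozenset(
        (system, equivalence_map.get(code, code)) for system, code in vs.members
    )
    return ValueSetDef(url=vs.url, members=members, anchor=vs.anchor,
                       include_anchor=vs.include_anchor)
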