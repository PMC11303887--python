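"""Layered FHIR profile model.

Profiles are represented as explicit constraint sets over dotted element
paths (with ``:slice`` names, e.g. ``code.coding:loinc``), each profile
tagged with the conformance layer it belongs to: the FHIR core resource
(``FHIR_BASE``), the nationally agreed Core Data Set layer (``CDS``),
and the stricter use-case layer of the research-portal profiles
(``FDPG``).  A pragmatic subset of StructureDefinition JSON is imported
and exported; unsupported features (FHIRPath invariants, unknown
extensions) are collected into an import report rather than silently
dropped.  Derived profiles may only narrow their base; widenings are
reported by :func:`check_narrowing`, never silently merged away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Any, Iterable, Mapping


class ProfileError(ValueError):
    pass


class ProfileImportError(ProfileError):
    pass


class MissingBaseError(ProfileError):
    pass


class CycleError(ProfileError):
    pass


class DuplicateUrlError(ProfileError):
    pass


class Layer(IntEnum):
    """Conformance levels, ordered from most permissive to most constrained."""

    FHIR_BASE = 0
    CDS = 1
    FDPG = 2


@dataclass(frozen=True)
class Binding:
    valueset: str
    strength: str  # required | extensible


@dataclass(frozen=True)
class Slicing:
    discriminator_path: str
    discriminator_type: str = "pattern"  # pattern | value


@dataclass(frozen=True)
class ElementConstraint:
    """Constraints one profile states on one element path.

    ``None`` means "not constrained at this layer".  ``max`` of ``None``
    with ``max_stated`` False is unstated; the unbounded ``*`` is stored
    as ``None`` with ``max_stated`` True.  ``fixed`` demands exact
    subtree equality, ``pattern`` structural containment; the two are
    mutually exclusive on one element.  ``fixed_type``/``pattern_type``
    carry the FHIR type suffix (``Uri``, ``Coding``, ...) used by the
    StructureDefinition writer.
    """

    path: str
    min: int | None = None
    max: int | None = None
    max_stated: bool = False
    types: tuple[str, ...] | None = None
    ref_targets: tuple[str, ...] | None = None
    fixed: Any = None
    fixed_type: str | None = None
    pattern: Any = None
    pattern_type: str | None = None
    binding: Binding | None = None
    slicing: Slicing | None = None

    def __post_init__(self) -> None:
        if self.fixed is not None and self.pattern is not None:
            raise ProfileError(
                f"fixed and pattern are mutually exclusive on {self.path}")
        if (self.min is not None and self.max is not None
                and self.min > self.max):
            raise ProfileError(f"min > max on {self.path}")

    @property
    def is_slice(self) -> bool:
        return ":" in self.path.rsplit(".", 1)[-1]


@dataclass
class ProfileDefinition:
    url: str
    name: str
    resource_type: str
    layer: Layer
    base_url: str | None = None
    constraints: list[ElementConstraint] = field(default_factory=list)
    import_report: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for constraint in self.constraints:
            if constraint.path in seen:
                raise ProfileError(
                    f"duplicate constraint path {constraint.path!r} in "
                    f"{self.url}")
            seen.add(constraint.path)

    def constraint(self, path: str) -> ElementConstraint | None:
        for item in self.constraints:
            if item.path == path:
                return item
        return None


@dataclass(frozen=True)
class Facet:
    """One effective constraint facet with the profile that introduced it."""

    value: Any
    origin_url: str
    origin_layer: Layer


@dataclass
class EffectiveElement:
    path: str
    facets: dict[str, Facet] = field(default_factory=dict)

    def facet_value(self, name: str, default: Any = None) -> Any:
        facet = self.facets.get(name)
        return default if facet is None else facet.value


@dataclass
class ProfileChain:
    """Ordered base-to-leaf chain with merged, origin-tagged constraints."""

    profiles: tuple[ProfileDefinition, ...]
    effective: dict[str, EffectiveElement]

    @property
    def resource_type(self) -> str:
        return self.profiles[-1].resource_type

    @property
    def leaf(self) -> ProfileDefinition:
        return self.profiles[-1]


class ProfileRegistry:
    """Canonical-URL keyed registry of profiles."""

    def __init__(self) -> None:
        self.profiles: dict[str, ProfileDefinition] = {}

    def register(self, profile: ProfileDefinition) -> None:
        if profile.url in self.profiles:
            raise DuplicateUrlError(profile.url)
        self.profiles[profile.url] = profile

    def get(self, url: str) -> ProfileDefinition:
        try:
            return self.profiles[url]
        except KeyError:
            raise MissingBaseError(f"profile {url!r} not registered") from None

    def __contains__(self, url: str) -> bool:
        return url in self.profiles

    def urls(self) -> list[str]:
        return sorted(self.profiles)


# -- facet merging ---------------------------------------------------------

_MORE_CONSTRAINED = "more"
_EQUAL = "equal"
_LESS_CONSTRAINED = "less"
_INCOMPARABLE = "incomparable"


def _compare_min(new: int, current: int | None) -> str:
    if current is None:
        return _MORE_CONSTRAINED if new > 0 else _EQUAL
    if new > current:
        return _MORE_CONSTRAINED
    return _EQUAL if new == current else _LESS_CONSTRAINED


def _compare_max(new: int | None, current: int | None) -> str:
    # None = unbounded
    if current is None:
        return _MORE_CONSTRAINED if new is not None else _EQUAL
    if new is None:
        return _LESS_CONSTRAINED
    if new < current:
        return _MORE_CONSTRAINED
    return _EQUAL if new == current else _LESS_CONSTRAINED


def _compare_types(new: tuple[str, ...],
                   current: tuple[str, ...] | None) -> str:
    if current is None:
        return _MORE_CONSTRAINED
    new_set, cur_set = set(new), set(current)
    if new_set == cur_set:
        return _EQUAL
    if new_set < cur_set:
        return _MORE_CONSTRAINED
    if new_set > cur_set:
        return _LESS_CONSTRAINED
    return _INCOMPARABLE


_STRENGTH_RANK = {"example": 0, "preferred": 1, "extensible": 2, "required": 3}


def _compare_binding(new: Binding, current: Binding | None) -> str:
    if current is None:
        return _MORE_CONSTRAINED
    if new == current:
        return _EQUAL
    new_rank = _STRENGTH_RANK.get(new.strength, 0)
    cur_rank = _STRENGTH_RANK.get(current.strength, 0)
    if new_rank < cur_rank:
        return _LESS_CONSTRAINED
    # same or higher strength with a different ValueSet: treated as a
    # narrowing (the derived layer owns the binding from here on)
    return _MORE_CONSTRAINED


def resolve_chain(url: str, registry: ProfileRegistry) -> ProfileChain:
    """Resolve ``url`` and its ancestry into an origin-tagged chain.

    The effective constraint per path is the most constrained across the
    chain; every facet carries the profile URL and layer that introduced
    it (a profile restating an inherited facet does not take it over).
    """
    chain: list[ProfileDefinition] = []
    seen: set[str] = set()
    current: str | None = url
    while current is not None:
        if current in seen:
            raise CycleError(f"profile base cycle at {current!r}")
        seen.add(current)
        profile = registry.get(current)
        chain.append(profile)
        current = profile.base_url
    chain.reverse()

    effective: dict[str, EffectiveElement] = {}
    for profile in chain:
        for constraint in profile.constraints:
            element = effective.setdefault(constraint.path,
                                           EffectiveElement(constraint.path))
            _merge(element, constraint, profile)
    return ProfileChain(profiles=tuple(chain), effective=effective)


def _merge(element: EffectiveElement, constraint: ElementConstraint,
           profile: ProfileDefinition) -> None:
    def adopt(name: str, value: Any) -> None:
        element.facets[name] = Facet(value, profile.url, profile.layer)

    facets = element.facets
    if constraint.min is not None:
        cmp = _compare_min(constraint.min,
                           facets["min"].value if "min" in facets else None)
        if cmp == _MORE_CONSTRAINED or "min" not in facets:
            adopt("min", constraint.min)
    if constraint.max_stated:
        current = facets.get("max")
        if current is None:
            adopt("max", constraint.max)
        elif _compare_max(constraint.max, current.value) == _MORE_CONSTRAINED:
            adopt("max", constraint.max)
    if constraint.types is not None:
        current = facets.get("types")
        if current is None:
            adopt("types", tuple(constraint.types))
        else:
            intersection = tuple(t for t in current.value
                                 if t in constraint.types)
            if set(intersection) != set(current.value):
                adopt("types", intersection)
    if constraint.ref_targets is not None:
        current = facets.get("ref_targets")
        if current is None or set(constraint.ref_targets) < set(current.value):
            adopt("ref_targets", tuple(constraint.ref_targets))
    if constraint.fixed is not None:
        adopt("fixed", constraint.fixed)
    if constraint.pattern is not None:
        if "fixed" not in facets:
            adopt("pattern", constraint.pattern)
    if constraint.binding is not None:
        current = facets.get("binding")
        if _compare_binding(constraint.binding,
                            current.value if current else None) \
                == _MORE_CONSTRAINED:
            adopt("binding", constraint.binding)
    if constraint.slicing is not None and "slicing" not in facets:
        adopt("slicing", constraint.slicing)


def check_narrowing(chain: ProfileChain) -> list[dict[str, Any]]:
    """Every place a derived profile widens its ancestry.

    A derived profile may raise ``min``, lower ``max``, shrink type
    lists, and tighten bindings — never the reverse.
    """
    violations: list[dict[str, Any]] = []
    state: dict[str, dict[str, Any]] = {}
    for profile in chain.profiles:
        for constraint in profile.constraints:
            facets = state.setdefault(constraint.path, {})

            def violation(facet: str, base: Any, derived: Any) -> None:
                violations.append({
                    "path": constraint.path,
                    "facet": facet,
                    "base_value": base,
                    "derived_value": derived,
                    "profile_url": profile.url,
                    "layer": profile.layer.name,
                })

            if constraint.min is not None:
                if _compare_min(constraint.min, facets.get("min")) \
                        == _LESS_CONSTRAINED:
                    violation("min", facets["min"], constraint.min)
                facets["min"] = max(constraint.min, facets.get("min") or 0)
            if constraint.max_stated:
                current = facets.get("max", ("unset",))
                if current != ("unset",):
                    if _compare_max(constraint.max, current) \
                            == _LESS_CONSTRAINED:
                        violation("max", current, constraint.max)
                    else:
                        facets["max"] = constraint.max
                else:
                    facets["max"] = constraint.max
            if constraint.types is not None:
                current = facets.get("types")
                cmp = _compare_types(tuple(constraint.types), current)
                if cmp in (_LESS_CONSTRAINED, _INCOMPARABLE):
                    violation("types", current, constraint.types)
                else:
                    facets["types"] = tuple(constraint.types)
            if constraint.binding is not None:
                current = facets.get("binding")
                if _compare_binding(constraint.binding, current) \
                        == _LESS_CONSTRAINED:
                    violation("binding", current, constraint.binding)
                else:
                    facets["binding"] = constraint.binding
    return violations


# -- StructureDefinition JSON import/export --------------------------------

_KNOWN_ELEMENT_KEYS = {
    "id", "path", "sliceName", "min", "max", "type", "binding", "slicing",
    "short", "definition", "comment", "mustSupport", "base", "alias",
    "isModifier", "isSummary", "representation", "requirements",
}

_CDS_URL_HINTS = ("medizininformatik-initiative", "/cds", "core/modul")
_FDPG_URL_HINTS = ("fdpg", "feasibility")


def infer_layer(url: str) -> Layer:
    lowered = url.lower()
    if lowered.startswith("http://hl7.org/fhir/structuredefinition/"):
        return Layer.FHIR_BASE
    if any(hint in lowered for hint in _FDPG_URL_HINTS):
        return Layer.FDPG
    if any(hint in lowered for hint in _CDS_URL_HINTS):
        return Layer.CDS
    raise ProfileImportError(f"cannot infer conformance layer for {url!r}")


def _parse_max(raw: str | None) -> tuple[int | None, bool]:
    if raw is None:
        return None, False
    if raw == "*":
        return None, True
    return int(raw), True


def load_structure_definition(document: Mapping,
                              layer: Layer | None = None) -> ProfileDefinition:
    """Import the pragmatic subset of a StructureDefinition resource.

    Differential elements are canonical; when only a snapshot is present
    it is read the same way and the fact is noted in the import report
    (origin-layer attribution then reflects the snapshot's flattening).
    Cardinality, types and reference targets, fixed[x]/pattern[x],
    bindings, and pattern-discriminated slicing are imported; FHIRPath
    invariants and unrecognized features go to the import report.
    """
    if document.get("resourceType") != "StructureDefinition":
        raise ProfileImportError("not a StructureDefinition")
    url = document.get("url")
    resource_type = document.get("type")
    if not url or not resource_type:
        raise ProfileImportError("StructureDefinition without url or type")
    report: list[str] = []
    elements = document.get("differential", {}).get("element")
    if elements is None:
        elements = document.get("snapshot", {}).get("element", [])
        report.append("no differential: snapshot read and re-derived")

    constraints: list[ElementConstraint] = []
    for element in elements:
        element_id = element.get("id") or element.get("path", "")
        if element_id == resource_type:
            continue  # root element carries no per-path constraints here
        path = element_id.split(".", 1)[1] if "." in element_id else element_id

        types: list[str] = []
        ref_targets: list[str] = []
        for type_entry in element.get("type", ()):
            code = type_entry.get("code")
            if code:
                types.append(code)
            if code == "Reference":
                for target in type_entry.get("targetProfile", ()):
                    ref_targets.append(target.rsplit("/", 1)[-1])

        fixed = fixed_type = pattern = pattern_type = None
        for key, value in element.items():
            if key.startswith("fixed"):
                fixed, fixed_type = value, key[len("fixed"):]
            elif key.startswith("pattern"):
                pattern, pattern_type = value, key[len("pattern"):]
            elif key == "constraint":
                for invariant in value:
                    report.append(
                        f"FHIRPath invariant {invariant.get('key')} on "
                        f"{path} skipped")
            elif key not in _KNOWN_ELEMENT_KEYS \
                    and not key.startswith("_"):
                report.append(f"unsupported feature {key!r} on {path}")

        binding = None
        raw_binding = element.get("binding")
        if raw_binding and raw_binding.get("valueSet"):
            binding = Binding(valueset=raw_binding["valueSet"].split("|")[0],
                              strength=raw_binding.get("strength", "required"))

        slicing = None
        raw_slicing = element.get("slicing")
        if raw_slicing:
            discriminators = raw_slicing.get("discriminator", [])
            if discriminators:
                slicing = Slicing(
                    discriminator_path=discriminators[0].get("path", "$this"),
                    discriminator_type=discriminators[0].get("type",
                                                             "pattern"),
                )

        maximum, max_stated = _parse_max(element.get("max"))
        constraints.append(ElementConstraint(
            path=path,
            min=element.get("min"),
            max=maximum,
            max_stated=max_stated,
            types=tuple(types) or None,
            ref_targets=tuple(ref_targets) or None,
            fixed=fixed,
            fixed_type=fixed_type,
            pattern=pattern,
            pattern_type=pattern_type,
            binding=binding,
            slicing=slicing,
        ))

    return ProfileDefinition(
        url=url,
        name=document.get("name", url.rsplit("/", 1)[-1]),
        resource_type=resource_type,
        layer=layer if layer is not None else infer_layer(url),
        base_url=document.get("baseDefinition"),
        constraints=constraints,
        import_report=report,
    )


def write_structure_definition(profile: ProfileDefinition) -> dict:
    """Export a profile as differential StructureDefinition JSON."""
    elements: list[dict] = [{
        "id": profile.resource_type,
        "path": profile.resource_type,
    }]
    for constraint in profile.constraints:
        element_id = f"{profile.resource_type}.{constraint.path}"
        fhir_path = ".".join(seg.split(":")[0]
                             for seg in element_id.split("."))
        element: dict[str, Any] = {"id": element_id, "path": fhir_path}
        last = constraint.path.rsplit(".", 1)[-1]
        if ":" in last:
            element["sliceName"] = last.split(":", 1)[1]
        if constraint.min is not None:
            element["min"] = constraint.min
        if constraint.max_stated:
            element["max"] = "*" if constraint.max is None \
                else str(constraint.max)
        if constraint.types is not None:
            element["type"] = []
            for code in constraint.types:
                entry: dict[str, Any] = {"code": code}
                if code == "Reference" and constraint.ref_targets:
                    entry["targetProfile"] = [
                        f"http://hl7.org/fhir/StructureDefinition/{target}"
                        for target in constraint.ref_targets]
                element["type"].append(entry)
        if constraint.fixed is not None:
            element[f"fixed{constraint.fixed_type or 'String'}"] = \
                constraint.fixed
        if constraint.pattern is not None:
            element[f"pattern{constraint.pattern_type or 'String'}"] = \
                constraint.pattern
        if constraint.binding is not None:
            element["binding"] = {
                "strength": constraint.binding.strength,
                "valueSet": constraint.binding.valueset,
            }
        if constraint.slicing is not None:
            element["slicing"] = {
                "discriminator": [{
                    "type": constraint.slicing.discriminator_type,
                    "path": constraint.slicing.discriminator_path,
                }],
                "rules": "open",
            }
        elements.append(element)
    return {
        "resourceType": "StructureDefinition",
        "url": profile.url,
        "name": profile.name,
        "status": "active",
        "kind": "resource",
        "abstract": False,
        "type": profile.resource_type,
        "baseDefinition": profile.base_url,
        "derivation": "constraint",
        "differential": {"element": elements},
    }


def load_package_dir(path: str | Path, registry: ProfileRegistry,
                     layer: Layer | None = None) -> list[ProfileDefinition]:
    """Read every ``*.json`` StructureDefinition in a package directory."""
    loaded = []
    for file in sorted(Path(path).glob("*.json")):
        document = json.loads(file.read_text(encoding="utf-8"))
        if document.get("resourceType") != "StructureDefinition":
            continue
        profile = load_structure_definition(document, layer=layer)
        registry.register(profile)
        loaded.append(profile)
    return loaded


def write_package_dir(profiles: Iterable[ProfileDefinition],
                      path: str | Path) -> None:
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    for profile in profiles:
        name = profile.url.rsplit("/", 1)[-1]
        (directory / f"StructureDefinition-{name}.json").write_text(
            json.dumps(write_structure_definition(profile), indent=2,
                       sort_keys=True) + "\n",
            encoding="utf-8")


def strip_layer_constraints(profile: ProfileDefinition) -> ProfileDefinition:
    """A copy of the profile without constraints (for tests/fixtures)."""
    return replace(profile, constraints=[])
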