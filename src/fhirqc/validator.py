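"""Resource validation against a layered profile chain.

Each violated constraint produces one :class:`ValidationIssue` attributed
to the conformance level (FHIR base / CDS / FDPG) that *introduced* the
constraint: profiles are evaluated base-to-leaf and the first layer whose
stated constraint a value violates owns the issue.  This makes the issue
subset attributed to an ancestor layer identical to what validating that
ancestor alone would produce, which is what allows a single validation
run to report compliance per level.

Resources are plain FHIR R4 JSON dicts.  References are checked for
presence and declared target type only — the pipeline runs offline on
extracts, so no resolution into a server is attempted.  Display strings
are ignored unless ``check_display`` is set (then mismatches are
warnings): generating displays for the national code systems is known to
vary between sites and is treated as noise by default.
"""

from __future__ import annotations

import copy
import random
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Any, Iterable, Mapping

from .profiles import (ElementConstraint, Layer, ProfileChain,
                       ProfileDefinition)
from .terminology import MembershipStatus, TerminologyStore


class TypeMismatchError(TypeError):
    """The resource's type differs from the chain's resource type."""


class EmptyStoreWarning(UserWarning):
    """No instance claims the requested profile."""


class ConstraintKind(str, Enum):
    CARDINALITY = "CARDINALITY"
    FIXED = "FIXED"
    PATTERN = "PATTERN"
    TYPE = "TYPE"
    BINDING = "BINDING"
    SLICE = "SLICE"
    REFERENCE = "REFERENCE"
    NARROWING = "NARROWING"


_KIND_ORDER = {kind: index for index, kind in enumerate(ConstraintKind)}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # error | warning | information
    path: str
    constraint_kind: ConstraintKind
    origin_layer: Layer
    origin_profile: str
    expected: str
    observed: str
    case_only: bool = False  # BINDING issues: only the casing mismatched

    def sort_key(self) -> tuple:
        return (self.path, _KIND_ORDER[self.constraint_kind],
                int(self.origin_layer), self.expected, self.observed)


# -- element navigation ----------------------------------------------------


def _as_list(value: Any) -> list:
    if value is None:
        return []
    return value if isinstance(value, list) else [value]


def _choice_values(obj: Mapping, stem: str) -> list[tuple[str, Any]]:
    """``(type name, value)`` pairs for a choice element like value[x]."""
    out = []
    for key, value in obj.items():
        if key.startswith(stem) and len(key) > len(stem) \
                and key[len(stem)].isupper():
            suffix = key[len(stem):]
            out.append((suffix, value))
    return out


def _fmt(value: Any) -> str:
    """Issue detail text: scalars verbatim, structures via repr."""
    return value if isinstance(value, str) else repr(value)


def matches_pattern(value: Any, pattern: Any) -> bool:
    """FHIR pattern semantics: structural containment.

    Scalars compare exactly; objects must contain every pattern property
    (recursively); each pattern array element must match some instance
    array element.
    """
    if isinstance(pattern, Mapping):
        if not isinstance(value, Mapping):
            return False
        return all(key in value and matches_pattern(value[key], sub)
                   for key, sub in pattern.items())
    if isinstance(pattern, list):
        if not isinstance(value, list):
            return False
        return all(any(matches_pattern(item, sub) for item in value)
                   for sub in pattern)
    return value == pattern


def _slice_discriminating_constraint(chain: ProfileChain,
                                     slice_path: str) -> Any:
    """The pattern (or fixed value) that defines slice membership."""
    element = chain.effective.get(slice_path)
    if element is None:
        return None
    return element.facet_value("pattern") or element.facet_value("fixed")


def _resolve_segment(obj: Any, segment: str, absolute: str,
                     chain: ProfileChain) -> list:
    if not isinstance(obj, Mapping):
        return []
    if ":" in segment:
        base = segment.split(":", 1)[0]
        candidates = _resolve_segment(obj, base,
                                      absolute.split(":", 1)[0], chain)
        discriminator = _slice_discriminating_constraint(chain, absolute)
        if discriminator is None:
            return []
        return [c for c in candidates if matches_pattern(c, discriminator)]
    if segment.endswith("[x]"):
        return [value for _, value in _choice_values(obj, segment[:-3])]
    return _as_list(obj.get(segment))


def element_values(resource: Mapping, path: str,
                   chain: ProfileChain) -> list:
    """All instance values at a dotted (possibly sliced) element path."""
    values: list[Any] = [resource]
    absolute = ""
    for segment in path.split("."):
        absolute = f"{absolute}.{segment}" if absolute else segment
        nxt: list[Any] = []
        for value in values:
            nxt.extend(_resolve_segment(value, segment, absolute, chain))
        values = nxt
    return values


def _parent_contexts(resource: Mapping, path: str,
                     chain: ProfileChain) -> tuple[str, list]:
    parent_path, _, last = path.rpartition(".")
    if not parent_path:
        return last, [resource]
    return last, element_values(resource, parent_path, chain)


# -- validation ------------------------------------------------------------


def _coding_candidates(value: Any) -> list[dict]:
    """Codings inside a bindable element (CodeableConcept or Coding)."""
    if not isinstance(value, Mapping):
        return []
    if "coding" in value:
        return [c for c in _as_list(value["coding"]) if isinstance(c, Mapping)]
    if "code" in value or "system" in value:
        return [dict(value)]
    return []


class _Evaluation:
    def __init__(self, resource: Mapping, chain: ProfileChain,
                 store: TerminologyStore, check_display: bool):
        self.resource = resource
        self.chain = chain
        self.store = store
        self.check_display = check_display
        self.issues: list[ValidationIssue] = []
        self._claimed: set[tuple[str, ConstraintKind]] = set()

    def emit(self, profile: ProfileDefinition, path: str,
             kind: ConstraintKind, expected: str, observed: str,
             severity: str = "error", case_only: bool = False) -> None:
        key = (path, kind)
        if key in self._claimed:
            return  # a more permissive layer already owns this violation
        self._claimed.add(key)
        self.issues.append(ValidationIssue(
            severity=severity, path=path, constraint_kind=kind,
            origin_layer=profile.layer, origin_profile=profile.url,
            expected=expected, observed=observed, case_only=case_only))

    # -- per-constraint checks --------------------------------------------

    def check_cardinality(self, profile: ProfileDefinition,
                          constraint: ElementConstraint) -> None:
        if constraint.min is None and not constraint.max_stated:
            return
        last, parents = _parent_contexts(self.resource, constraint.path,
                                         self.chain)
        if constraint.is_slice:
            kind = ConstraintKind.SLICE
        elif constraint.types == ("Reference",):
            kind = ConstraintKind.REFERENCE
        else:
            kind = ConstraintKind.CARDINALITY
        absolute = constraint.path
        for parent in parents:
            count = len(_resolve_segment(parent, last, absolute, self.chain))
            if constraint.min is not None and count < constraint.min:
                self.emit(profile, constraint.path, kind,
                          expected=f"min {constraint.min}",
                          observed=f"count {count}")
            elif constraint.max_stated and constraint.max is not None \
                    and count > constraint.max:
                self.emit(profile, constraint.path, kind,
                          expected=f"max {constraint.max}",
                          observed=f"count {count}")

    def check_fixed_pattern(self, profile: ProfileDefinition,
                            constraint: ElementConstraint) -> None:
        values = element_values(self.resource, constraint.path, self.chain)
        if constraint.fixed is not None:
            for value in values:
                if value != constraint.fixed:
                    self.emit(profile, constraint.path, ConstraintKind.FIXED,
                              expected=_fmt(constraint.fixed),
                              observed=_fmt(value))
        if constraint.pattern is not None and not constraint.is_slice:
            # a slice's own pattern is its membership discriminator, not a
            # constraint on the members
            for value in values:
                if not matches_pattern(value, constraint.pattern):
                    self.emit(profile, constraint.path,
                              ConstraintKind.PATTERN,
                              expected=repr(constraint.pattern),
                              observed=repr(value))

    def check_types(self, profile: ProfileDefinition,
                    constraint: ElementConstraint) -> None:
        if constraint.types is None or not constraint.path.endswith("[x]"):
            return
        stem = constraint.path.rsplit(".", 1)[-1][:-3]
        allowed = {t.lower() for t in constraint.types}
        _, parents = _parent_contexts(self.resource, constraint.path,
                                      self.chain)
        for parent in parents:
            if not isinstance(parent, Mapping):
                continue
            for suffix, _value in _choice_values(parent, stem):
                if suffix.lower() not in allowed:
                    self.emit(profile, constraint.path, ConstraintKind.TYPE,
                              expected="|".join(constraint.types),
                              observed=suffix)

    def check_binding(self, profile: ProfileDefinition,
                      constraint: ElementConstraint) -> None:
        binding = constraint.binding
        if binding is None or binding.strength != "required":
            return
        if binding.valueset not in self.store.valuesets:
            return  # unexpandable binding: out of reach, not a data issue
        values = element_values(self.resource, constraint.path, self.chain)
        for value in values:
            codings = _coding_candidates(value)
            if not codings:
                continue  # presence is a cardinality concern
            case_matches = []
            exact = None
            for coding in codings:
                result = self.store.vs_contains(
                    binding.valueset, coding.get("system", ""),
                    coding.get("code", ""))
                if result.status is MembershipStatus.EXACT:
                    exact = coding
                    break
                if result.status is MembershipStatus.CASE_ONLY:
                    case_matches.append((coding, result.matched_code))
            if exact is not None:
                if self.check_display:
                    self._check_display(profile, constraint, exact)
                continue
            observed = ", ".join(
                f"{c.get('system')}|{c.get('code')}" for c in codings)
            if case_matches:
                coding, matched = case_matches[0]
                self.emit(profile, constraint.path, ConstraintKind.BINDING,
                          expected=f"{binding.valueset} (e.g. {matched})",
                          observed=observed, case_only=True)
            else:
                self.emit(profile, constraint.path, ConstraintKind.BINDING,
                          expected=binding.valueset, observed=observed)

    def _check_display(self, profile: ProfileDefinition,
                       constraint: ElementConstraint,
                       coding: Mapping) -> None:
        system = self.store.systems.get(coding.get("system", ""))
        if system is None:
            return
        concept = system.concepts.get(coding.get("code", ""))
        if concept is None or concept.display is None:
            return
        display = coding.get("display")
        if display is not None and display != concept.display:
            self.emit(profile, constraint.path, ConstraintKind.BINDING,
                      expected=f"display {concept.display!r}",
                      observed=f"display {display!r}", severity="warning")

    def check_reference_targets(self, profile: ProfileDefinition,
                                constraint: ElementConstraint) -> None:
        if constraint.ref_targets is None:
            return
        values = element_values(self.resource, constraint.path, self.chain)
        reference_only = constraint.types == ("Reference",)
        for value in values:
            if not isinstance(value, Mapping):
                continue
            reference = value.get("reference")
            if reference is None:
                # a choice element may legitimately hold a non-Reference
                # type; only a pure Reference element demands a literal
                if reference_only:
                    self.emit(profile, constraint.path,
                              ConstraintKind.REFERENCE,
                              expected="literal reference",
                              observed=repr(value))
                continue
            target_type = str(reference).split("/", 1)[0]
            if target_type not in constraint.ref_targets:
                self.emit(profile, constraint.path,
                          ConstraintKind.REFERENCE,
                          expected="|".join(constraint.ref_targets),
                          observed=str(reference))

    def run(self) -> list[ValidationIssue]:
        for profile in self.chain.profiles:
            for constraint in profile.constraints:
                self.check_cardinality(profile, constraint)
                self.check_types(profile, constraint)
                self.check_fixed_pattern(profile, constraint)
                self.check_binding(profile, constraint)
                self.check_reference_targets(profile, constraint)
        return sorted(self.issues, key=ValidationIssue.sort_key)


def validate_resource(resource: Mapping, chain: ProfileChain,
                      store: TerminologyStore | None = None,
                      check_display: bool = False) -> list[ValidationIssue]:
    """Validate one resource against a resolved profile chain.

    Issue lists are order-stable (sorted by path, then constraint kind).
    """
    if resource.get("resourceType") != chain.resource_type:
        raise TypeMismatchError(
            f"resource is {resource.get('resourceType')!r}, chain expects "
            f"{chain.resource_type!r}")
    store = store if store is not None else TerminologyStore()
    return _Evaluation(resource, chain, store, check_display).run()


# -- sampling & profile substitution ---------------------------------------


@dataclass
class SampleSet:
    """A deterministic per-profile equivalence-class sample."""

    profile_url: str
    instances: list[Mapping]
    cap: int
    seed: int
    total_available: int

    @property
    def ids(self) -> list[str]:
        return [r.get("id", "") for r in self.instances]


def sample_instances(store: Iterable[Mapping], profile_url: str,
                     cap: int = 500, seed: int = 0) -> SampleSet:
    """Sample up to ``cap`` instances claiming ``profile_url``.

    Claimers are sorted by resource id, then sampled uniformly without
    replacement with the stated seed, so runs with equal seed and store
    contents return identical id lists.  The default cap of 500 mirrors
    the per-profile equivalence-class sample size of the validation
    pipeline this package reimplements.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    claimers = [r for r in store
                if profile_url in (r.get("meta", {}) or {}).get("profile", ())]
    claimers.sort(key=lambda r: str(r.get("id", "")))
    total = len(claimers)
    if total == 0:
        warnings.warn(f"no instances claim {profile_url!r}",
                      EmptyStoreWarning, stacklevel=2)
    if total > cap:
        rng = random.Random(seed)
        indices = sorted(rng.sample(range(total), cap))
        claimers = [claimers[i] for i in indices]
    return SampleSet(profile_url=profile_url, instances=claimers, cap=cap,
                     seed=seed, total_available=total)


def substitute_profiles(resource: Mapping,
                        substitution: Mapping[str, str]) -> dict:
    """Swap claimed profile URLs according to a CDS→FDPG substitution map.

    Returns a modified deep copy; unmapped claims are untouched.
    """
    out = copy.deepcopy(dict(resource))
    meta = out.get("meta")
    if meta and "profile" in meta:
        meta["profile"] = [substitution.get(url, url)
                           for url in meta["profile"]]
    return out
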