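"""End-to-end validation pipeline: sample → substitute → validate → classify.

Instances are grouped into equivalence classes by the profile they claim
in ``meta.profile``, sampled per class up to a cap (default 500), their
CDS profile claims substituted with the corresponding use-case profile,
validated against the resolved chain, and the issues classified into the
discrepancy taxonomy.  Everything runs offline on in-memory resources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .classifier import (ClassificationContext, DiscrepancyRecord,
                         classify_resource)
from .forge import SubstitutionMap
from .profiles import ProfileChain, ProfileRegistry, resolve_chain
from .terminology import TerminologyStore
from .validator import (ValidationIssue, sample_instances,
                        substitute_profiles, validate_resource)


@dataclass
class ResourceResult:
    resource_id: str
    resource_type: str
    claimed_profile: str
    validated_profile: str | None
    issues: list[ValidationIssue] = field(default_factory=list)
    records: list[DiscrepancyRecord] = field(default_factory=list)


@dataclass
class PipelineResult:
    results: list[ResourceResult] = field(default_factory=list)

    @property
    def issues(self) -> list[ValidationIssue]:
        return [issue for result in self.results for issue in result.issues]

    @property
    def records(self) -> list[DiscrepancyRecord]:
        return [rec for result in self.results for rec in result.records]


def _claimed_profiles(resources: Iterable[Mapping]) -> list[str]:
    urls = set()
    for resource in resources:
        urls.update((resource.get("meta", {}) or {}).get("profile", ()))
    return sorted(urls)


def run_pipeline(resources: list[Mapping], registry: ProfileRegistry,
                 substitution: SubstitutionMap | Mapping[str, str],
                 store: TerminologyStore, ctx: ClassificationContext,
                 cap: int = 500, seed: int = 0,
                 check_display: bool = False,
                 skip_types: tuple[str, ...] = ("Patient",)
                 ) -> PipelineResult:
    """Run the full pipeline over one site's resources.

    Patient resources are sampled but not validated by default,
    mirroring the privacy-driven exclusion of patient data from the
    analysis.
    """
    if not isinstance(substitution, SubstitutionMap):
        substitution = SubstitutionMap(static=dict(substitution))
    out = PipelineResult()
    chains: dict[str, ProfileChain] = {}
    for profile_url in _claimed_profiles(resources):
        sample = sample_instances(resources, profile_url, cap=cap, seed=seed)
        for resource in sample.instances:
            if resource.get("resourceType") in skip_types:
                continue
            target = substitution.resolve(profile_url, resource)
            result = ResourceResult(
                resource_id=str(resource.get("id", "")),
                resource_type=str(resource.get("resourceType", "")),
                claimed_profile=profile_url,
                validated_profile=target if target in registry else None,
            )
            if result.validated_profile is not None:
                if target not in chains:
                    chains[target] = resolve_chain(target, registry)
                substituted = substitute_profiles(
                    resource, {profile_url: target})
                result.issues = validate_resource(
                    substituted, chains[target], store,
                    check_display=check_display)
                result.records = classify_resource(resource, result.issues,
                                                   ctx)
            out.results.append(result)
    return out


def issues_report(result: PipelineResult, site_id: str = "") -> dict:
    """JSON-able validation report (schema version 1).

    Layout: ``{"schema_version": 1, "site_id": ..., "results": [
    {"resource_id", "resource_type", "claimed_profile",
    "validated_profile", "issues": [{severity, path, constraint_kind,
    origin_layer, origin_profile, expected, observed, case_only}]}]}``.
    """
    return {
        "schema_version": 1,
        "site_id": site_id,
        "results": [
            {
                "resource_id": r.resource_id,
                "resource_type": r.resource_type,
                "claimed_profile": r.claimed_profile,
                "validated_profile": r.validated_profile,
                "issues": [
                    {
                        "severity": issue.severity,
                        "path": issue.path,
                        "constraint_kind": issue.constraint_kind.value,
                        "origin_layer": issue.origin_layer.name,
                        "origin_profile": issue.origin_profile,
                        "expected": issue.expected,
                        "observed": issue.observed,
                        "case_only": issue.case_only,
                    }
                    for issue in r.issues
                ],
            }
            for r in result.results
        ],
    }
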