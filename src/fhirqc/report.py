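"""Aggregation of discrepancy records into site and cross-site reports.

Includes the stepwise unit-discrepancy reduction analysis: distinct
discrepant codes, the share resolved by lexical (case/Greek)
normalization, the subset whose observed units appear on the
common-unit list, and the partition of the remainder into powers of
ten versus conversions needing more complex calculation.  Because it is
ambiguous whether such analyses should count codes, code–unit pairs, or
instances, both the pair-level and the instance-level view are emitted.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable

from .classifier import DiscrepancyCategory, DiscrepancyRecord
from .ucum import UnitCategory

_LEXICAL = (UnitCategory.CASE_VARIANT, UnitCategory.GREEK_VARIANT)
_POWER = (UnitCategory.POWER_OF_TEN,)


@dataclass
class SiteReport:
    site_id: str
    n_records: int = 0
    per_layer: dict[str, int] = field(default_factory=dict)
    per_category: dict[str, int] = field(default_factory=dict)
    lab_table: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "schema_version": 1,
            "site_id": self.site_id,
            "n_records": self.n_records,
            "per_layer": self.per_layer,
            "per_category": self.per_category,
            "lab_table": self.lab_table,
        }


def summarize(records: Iterable[DiscrepancyRecord],
              site_id: str = "") -> SiteReport:
    """Per-site counts by layer and category plus the lab unit table.

    Totals equal the sum of their breakdowns; ordering is deterministic.
    """
    records = list(records)
    report = SiteReport(site_id=site_id, n_records=len(records))
    lab: dict[tuple, int] = {}
    for record in records:
        layer = record.layer.name if record.layer is not None else "NONE"
        report.per_layer[layer] = report.per_layer.get(layer, 0) + 1
        category = record.category.value
        report.per_category[category] = \
            report.per_category.get(category, 0) + 1
        if record.category is DiscrepancyCategory.UNIT_DISCREPANCY:
            key = (record.loinc or "", record.expected, record.observed,
                   record.unit_class.category.value)
            lab[key] = lab.get(key, 0) + 1
    report.per_layer = dict(sorted(report.per_layer.items()))
    report.per_category = dict(sorted(report.per_category.items()))
    report.lab_table = [
        {"loinc": loinc, "expected_unit": expected, "observed_unit": observed,
         "unit_class": category, "count": count}
        for (loinc, expected, observed, category), count in sorted(lab.items())
    ]
    return report


@dataclass
class ReductionPipeline:
    """Stepwise reduction of unit discrepancies (pair and instance view).

    Counts are monotonically nonincreasing along
    ``n_unit_discrepancies → after lexical normalization → on the
    common-unit list``, and ``n_power_of_ten + n_complex`` equals the
    list-filtered remainder.
    """

    n_discrepant_codes: int = 0  # distinct LOINC codes with >=1 discrepancy
    n_pairs: int = 0  # distinct (loinc, observed unit) pairs
    n_case_greek_resolved: int = 0
    n_after_lexical: int = 0
    n_after_bfarm: int = 0
    n_power_of_ten: int = 0
    n_complex: int = 0
    power_of_ten_share: float = 0.0  # of the list-filtered remainder
    instance_counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_discrepant_codes": self.n_discrepant_codes,
            "n_pairs": self.n_pairs,
            "n_case_greek_resolved": self.n_case_greek_resolved,
            "n_after_lexical": self.n_after_lexical,
            "n_after_bfarm": self.n_after_bfarm,
            "n_power_of_ten": self.n_power_of_ten,
            "n_complex": self.n_complex,
            "power_of_ten_share": self.power_of_ten_share,
            "instance_counts": dict(self.instance_counts),
        }


def reduction_analysis(records: Iterable[DiscrepancyRecord]
                       ) -> ReductionPipeline:
    """Replicate the stepwise unit-reduction analysis on a record set.

    Order: collect distinct discrepant (LOINC, observed unit) pairs;
    remove the pairs resolved by case/Greek normalization; keep the
    remainder whose observed unit is on the common-unit list (the
    ``bfarm_listed`` flag each record's unit class already carries);
    partition that into powers of ten versus everything needing more
    than a power of ten.  Aggregation commutes with concatenation and is
    invariant to record order and site partitioning.
    """
    pairs: dict[tuple[str, str], UnitCategory] = {}
    listed: dict[tuple[str, str], bool] = {}
    instance = {"unit_discrepancies": 0, "case_greek_resolved": 0,
                "after_lexical": 0, "after_bfarm": 0, "power_of_ten": 0,
                "complex": 0}
    for record in records:
        if record.category is not DiscrepancyCategory.UNIT_DISCREPANCY:
            continue
        unit_class = record.unit_class
        pair = (record.loinc or "", record.observed)
        pairs[pair] = unit_class.category
        listed[pair] = unit_class.bfarm_listed
        instance["unit_discrepancies"] += 1
        if unit_class.category in _LEXICAL:
            instance["case_greek_resolved"] += 1
            continue
        instance["after_lexical"] += 1
        if not unit_class.bfarm_listed:
            continue
        instance["after_bfarm"] += 1
        if unit_class.category in _POWER:
            instance["power_of_ten"] += 1
        else:
            instance["complex"] += 1

    out = ReductionPipeline(instance_counts=instance)
    out.n_discrepant_codes = len({loinc for loinc, _ in pairs})
    out.n_pairs = len(pairs)
    lexical = {pair for pair, category in pairs.items()
               if category in _LEXICAL}
    out.n_case_greek_resolved = len(lexical)
    remaining = {pair for pair in pairs if pair not in lexical}
    out.n_after_lexical = len(remaining)
    on_list = {pair for pair in remaining if listed[pair]}
    out.n_after_bfarm = len(on_list)
    power = {pair for pair in on_list if pairs[pair] in _POWER}
    out.n_power_of_ten = len(power)
    out.n_complex = out.n_after_bfarm - out.n_power_of_ten
    if out.n_after_bfarm:
        out.power_of_ten_share = out.n_power_of_ten / out.n_after_bfarm
    return out


def records_to_csv(records: Iterable[DiscrepancyRecord]) -> str:
    """One row per record; fixed, documented column set."""
    buffer = io.StringIO()
    writer = csv.writer(buffer)
    writer.writerow(["site_id", "resource_id", "resource_type", "category",
                     "layer", "path", "loinc", "unit_class",
                     "power_exponent", "bfarm_listed",
                     "invalid_measurement_flag", "expected", "observed",
                     "severity"])
    for record in records:
        unit_class = record.unit_class
        writer.writerow([
            record.site_id, record.resource_id, record.resource_type,
            record.category.value,
            record.layer.name if record.layer is not None else "",
            record.path, record.loinc or "",
            unit_class.category.value if unit_class else "",
            unit_class.power_exponent if unit_class
            and unit_class.power_exponent is not None else "",
            unit_class.bfarm_listed if unit_class else "",
            record.invalid_measurement_flag,
            record.expected, record.observed, record.severity,
        ])
    return buffer.getvalue()


def reduction_to_csv(pipeline: ReductionPipeline) -> str:
    """The reduction table, mirroring the appendix-style columns."""
    buffer = io.StringIO()
    writer = csv.writer(buffer)
    writer.writerow(["step", "pairs", "instances"])
    instances = pipeline.instance_counts
    writer.writerow(["unit_discrepancies", pipeline.n_pairs,
                     instances.get("unit_discrepancies", 0)])
    writer.writerow(["case_greek_resolved", pipeline.n_case_greek_resolved,
                     instances.get("case_greek_resolved", 0)])
    writer.writerow(["after_lexical", pipeline.n_after_lexical,
                     instances.get("after_lexical", 0)])
    writer.writerow(["after_bfarm", pipeline.n_after_bfarm,
                     instances.get("after_bfarm", 0)])
    writer.writerow(["power_of_ten", pipeline.n_power_of_ten,
                     instances.get("power_of_ten", 0)])
    writer.writerow(["complex", pipeline.n_complex,
                     instances.get("complex", 0)])
    return buffer.getvalue()
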