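"""Reporting: summaries, the stepwise unit reduction, and the CLI."""

import json
import random

import pytest
from typer.testing import CliRunner

from fhirqc.classifier import DiscrepancyCategory, DiscrepancyRecord
from fhirqc.profiles import Layer
from fhirqc.report import (records_to_csv, reduction_analysis,
                           reduction_to_csv, summarize)
from fhirqc.ucum import UnitCategory, UnitPairClass

D = DiscrepancyCategory
C = UnitCategory


def unit_record(loinc, observed, category, listed=True, expected="mg/dL",
                site="s1", rid="r1", exponent=None):
    return DiscrepancyRecord(
        site_id=site, resource_id=rid, resource_type="Observation",
        category=D.UNIT_DISCREPANCY, layer=Layer.FDPG,
        path="valueQuantity.code", loinc=loinc,
        unit_class=UnitPairClass(category, power_exponent=exponent,
                                 bfarm_listed=listed),
        expected=expected, observed=observed)


def plain_record(category, layer=Layer.CDS, site="s1", rid="r2"):
    return DiscrepancyRecord(
        site_id=site, resource_id=rid, resource_type="Condition",
        category=category, layer=layer, path="code")


class TestSummarize:
    def test_empty_records_all_zero(self):
        report = summarize([], "s0")
        assert report.n_records == 0
        assert report.per_category == {}
        assert report.per_layer == {}

    def test_category_counts_sum_to_total(self):
        records = [plain_record(D.MISSING_MANDATORY) for _ in range(4)]
        records += [plain_record(D.WRONG_SYSTEM_URL) for _ in range(6)]
        report = summarize(records, "s1")
        assert report.n_records == 10
        assert sum(report.per_category.values()) == 10
        assert report.per_category["MISSING_MANDATORY"] == 4

    def test_layer_counts_sum_to_total(self):
        records = [plain_record(D.MISSING_MANDATORY, Layer.FHIR_BASE),
                   plain_record(D.BINDING_VIOLATION, Layer.CDS),
                   unit_record("718-7", "g/l", C.CASE_VARIANT)]
        report = summarize(records, "s1")
        assert sum(report.per_layer.values()) == report.n_records == 3

    def test_lab_table_rows_aggregate_by_pair(self):
        records = [unit_record("718-7", "g/l", C.CASE_VARIANT, rid=f"r{i}")
                   for i in range(3)]
        report = summarize(records, "s1")
        assert report.lab_table == [{
            "loinc": "718-7", "expected_unit": "mg/dL",
            "observed_unit": "g/l", "unit_class": "CASE_VARIANT",
            "count": 3}]


class TestReductionAnalysis:
    def test_all_case_variants_fully_resolve(self):
        records = [unit_record(f"l{i}", "g/l", C.CASE_VARIANT)
                   for i in range(5)]
        out = reduction_analysis(records)
        assert out.n_after_lexical == 0
        assert out.n_power_of_ten == 0

    def test_zero_records_all_zero(self):
        out = reduction_analysis([])
        assert out.n_discrepant_codes == out.n_pairs == 0
        assert out.power_of_ten_share == 0.0

    def test_known_partition_recovered_exactly(self):
        records = [
            unit_record("l1", "g/l", C.CASE_VARIANT),
            unit_record("l2", "μmol/L", C.GREEK_VARIANT,
                        expected="umol/L"),
            unit_record("l3", "mg/dL", C.POWER_OF_TEN, exponent=2),
            unit_record("l4", "ug/L", C.POWER_OF_TEN, exponent=-3),
            unit_record("l5", "Gpt/L", C.INVALID_UCUM, listed=False),
            unit_record("l6", "mmol/L", C.MOLAR_MASS_REQUIRED),
            unit_record("l7", "kPa", C.COMPLEX_CONVERSION,
                        expected="mm[Hg]"),
        ]
        out = reduction_analysis(records)
        assert out.n_discrepant_codes == 7
        assert out.n_case_greek_resolved == 2
        assert out.n_after_lexical == 5
        assert out.n_after_bfarm == 4  # the invalid unit is not listed
        assert out.n_power_of_ten == 2
        assert out.n_complex == 2
        assert out.power_of_ten_share == pytest.approx(0.5)

    def test_injected_power_complex_split_recovers(self):
        """60/40 power-of-ten vs complex split at n=500 is recovered."""
        rng = random.Random(7)
        records = []
        for i in range(500):
            if rng.random() < 0.6:
                records.append(unit_record(f"l{i}", "ug/dL",
                                           C.POWER_OF_TEN, exponent=1,
                                           rid=f"r{i}"))
            else:
                records.append(unit_record(f"l{i}", "mmol/L",
                                           C.MOLAR_MASS_REQUIRED,
                                           rid=f"r{i}"))
        out = reduction_analysis(records)
        n_power = sum(1 for r in records
                      if r.unit_class.category is C.POWER_OF_TEN)
        assert out.n_power_of_ten == n_power
        assert out.n_complex == 500 - n_power

    def test_aggregation_commutes_with_concatenation(self):
        site_a = [unit_record("l1", "g/l", C.CASE_VARIANT, site="a"),
                  unit_record("l2", "mg/dL", C.POWER_OF_TEN, exponent=2,
                              site="a")]
        site_b = [unit_record("l3", "kPa", C.COMPLEX_CONVERSION, site="b")]
        combined = reduction_analysis(site_a + site_b)
        reversed_order = reduction_analysis(site_b + site_a)
        assert combined.as_dict() == reversed_order.as_dict()

    def test_counts_monotonically_nonincreasing(self):
        records = [
            unit_record("l1", "g/l", C.CASE_VARIANT, listed=True),
            unit_record("l2", "mg/dL", C.POWER_OF_TEN, exponent=2,
                        listed=False),
            unit_record("l3", "kPa", C.COMPLEX_CONVERSION, listed=True),
            unit_record("l4", "mmol/L", C.MOLAR_MASS_REQUIRED,
                        listed=False),
        ]
        out = reduction_analysis(records)
        assert out.n_pairs >= out.n_after_lexical >= out.n_after_bfarm
        assert out.n_after_bfarm == out.n_power_of_ten + out.n_complex


class TestCsvOutputs:
    def test_records_csv_has_one_row_per_record(self):
        records = [plain_record(D.MISSING_MANDATORY),
                   unit_record("718-7", "g/l", C.CASE_VARIANT)]
        lines = records_to_csv(records).strip().splitlines()
        assert len(lines) == 3  # header + 2 rows
        assert lines[0].startswith("site_id,resource_id")

    def test_reduction_csv_shape(self):
        out = reduction_analysis([unit_record("l1", "mg/dL",
                                              C.POWER_OF_TEN, exponent=2)])
        lines = reduction_to_csv(out).strip().splitlines()
        assert lines[0] == "step,pairs,instances"
        assert len(lines) == 7


class TestCli:
    def test_five_command_round_trip(self, tmp_path):
        """forge → simulate → validate → classify → report on fixtures."""
        from fhirqc.cli import app

        runner = CliRunner()
        package_dir = tmp_path / "package"
        submap = tmp_path / "substitution.csv"
        result = runner.invoke(app, ["forge", "--out", str(package_dir),
                                     "--substitution-map", str(submap)])
        assert result.exit_code == 0, result.output
        assert submap.exists()
        assert list(package_dir.glob("StructureDefinition-*.json"))

        config = tmp_path / "sites.json"
        config.write_text(json.dumps({"sites": [{
            "site_id": "cli-site", "seed": 3, "n_patients": 10,
            "n_per_type": {"Observation": 10, "Condition": 5,
                           "Procedure": 5, "MedicationAdministration": 5,
                           "Consent": 3, "Specimen": 2},
            "injection_rates": {"UNIT_DISCREPANCY": 0.5,
                                "MISSING_MANDATORY": 0.5}}]}))
        sim_dir = tmp_path / "sim"
        result = runner.invoke(app, ["simulate", "--config", str(config),
                                     "--out", str(sim_dir)])
        assert result.exit_code == 0, result.output
        bundle = sim_dir / "cli-site.ndjson"
        assert bundle.exists()
        assert (sim_dir / "cli-site.ground_truth.csv").exists()

        issues = tmp_path / "issues.json"
        result = runner.invoke(app, ["validate", "--bundle", str(bundle),
                                     "--out", str(issues), "--seed", "1",
                                     "--site-id", "cli-site"])
        assert result.exit_code == 0, result.output
        report_doc = json.loads(issues.read_text())
        assert report_doc["schema_version"] == 1

        records = tmp_path / "records.ndjson"
        records_csv = tmp_path / "records.csv"
        result = runner.invoke(app, ["classify", "--bundle", str(bundle),
                                     "--issues", str(issues),
                                     "--out", str(records),
                                     "--records-csv", str(records_csv)])
        assert result.exit_code == 0, result.output
        assert records.exists() and records_csv.exists()

        site_report = tmp_path / "report.json"
        reduction = tmp_path / "reduction.csv"
        result = runner.invoke(app, ["report", "--records", str(records),
                                     "--out", str(site_report),
                                     "--reduction-csv", str(reduction),
                                     "--site-id", "cli-site"])
        assert result.exit_code == 0, result.output
        payload = json.loads(site_report.read_text())
        assert payload["n_records"] >= 1
        assert "reduction" in payload

    def test_validate_with_missing_bundle_fails_cleanly(self, tmp_path):
        from fhirqc.cli import app

        runner = CliRunner()
        result = runner.invoke(app, ["validate", "--bundle",
                                     str(tmp_path / "nope.ndjson"),
                                     "--out", str(tmp_path / "o.json")])
        assert result.exit_code != 0
        assert not (tmp_path / "o.json").exists()
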