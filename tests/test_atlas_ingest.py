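"""Ingest, validity screens and population resolution."""

from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhcoverage.atlas_ingest import (AtlasRecord, CountryContext, Disorder,
                                     ExclusionReason, IncomeGroup,
                                     ContextLookupError, SchemaError,
                                     ValidationError, read_atlas_table,
                                     read_country_context, resolve_population,
                                     screen_completeness, screen_records,
                                     visits_per_case_check)

HEADER = ("country_code,disorder,inpatient_cases,outpatient_cases,"
          "inpatient_visits,outpatient_visits,representativeness,"
          "followup_category,reported_population\n")


def write_atlas(tmp_path, rows):
    path = tmp_path / "atlas_records.csv"
    path.write_text(HEADER + "".join(r + "\n" for r in rows))
    return path


class TestReadAtlasTable:
    def test_well_formed_rows_round_trip(self, tmp_path):
        path = write_atlas(tmp_path, [
            "AAA,psychosis,100,500,400,2000,0.8,2,5000000",
            "AAA,bipolar,10,50,40,200,0.8,2,5000000",
            "BBB,depression,7,90,,,1.0,,",
        ])
        records = read_atlas_table(path)
        assert len(records) == 3
        assert records[0].inpatient_cases == 100
        assert records[0].disorder is Disorder.PSYCHOSIS

    def test_empty_cell_is_absent_not_zero(self, tmp_path):
        path = write_atlas(tmp_path, ["AAA,psychosis,,500,,,0.8,,"])
        (record,) = read_atlas_table(path)
        assert record.inpatient_cases is None
        assert record.outpatient_cases == 500
        assert record.followup_category is None

    def test_negative_count_names_the_row(self, tmp_path):
        path = write_atlas(tmp_path, [
            "AAA,psychosis,100,500,,,0.8,,",
            "BBB,psychosis,-5,500,,,0.8,,",
        ])
        with pytest.raises(ValidationError, match="row 2"):
            read_atlas_table(path)

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("country_code,disorder\nAAA,psychosis\n")
        with pytest.raises(SchemaError, match="inpatient_cases"):
            read_atlas_table(path)

    def test_bad_representativeness_rejected(self, tmp_path):
        path = write_atlas(tmp_path, ["AAA,psychosis,1,2,,,1.4,,"])
        with pytest.raises(ValidationError):
            read_atlas_table(path)


class TestScreenCompleteness:
    def test_fully_reported_record_included(self, complete_record):
        decision = screen_completeness(complete_record)
        assert decision.included and decision.reason is ExclusionReason.OK

    @pytest.mark.parametrize("missing, reason", [
        ("inpatient_cases", ExclusionReason.MISSING_INPATIENT_OR_OUTPATIENT),
        ("outpatient_cases", ExclusionReason.MISSING_INPATIENT_OR_OUTPATIENT),
        ("representativeness", ExclusionReason.MISSING_REPRESENTATIVENESS),
    ])
    def test_missing_required_field_excludes(self, complete_record, missing,
                                             reason):
        record = replace(complete_record, **{missing: None})
        decision = screen_completeness(record)
        assert not decision.included and decision.reason is reason

    def test_zero_is_a_legitimate_report(self, complete_record):
        record = replace(complete_record, inpatient_cases=0)
        assert screen_completeness(record).included


class TestVisitsPerCase:
    @pytest.mark.parametrize("in_c,out_c,in_v,out_v,included", [
        (100, 100, 150, 150, True),    # ratio 1.5
        (100, 0, 50, 0, False),        # ratio 0.5
        (100, 100, 100, 100, True),    # ratio exactly 1: strict "< 1"
        (0, 0, 10, 0, False),          # visits against zero cases
    ])
    def test_pooled_ratio_rule(self, complete_record, in_c, out_c, in_v,
                               out_v, included):
        record = replace(complete_record, inpatient_cases=in_c,
                         outpatient_cases=out_c, inpatient_visits=in_v,
                         outpatient_visits=out_v)
        assert visits_per_case_check(record).included is included

    def test_absent_visits_skip_the_check(self, complete_record):
        record = replace(complete_record, inpatient_visits=None,
                         outpatient_visits=None)
        assert visits_per_case_check(record).included


class TestResolvePopulation:
    CTX = CountryContext("AAA", IncomeGroup.HIGH, "EUR", "Western Europe",
                         "High-income", 5_000_000)

    def test_absent_report_uses_un_estimate(self, complete_record):
        record = replace(complete_record, reported_population=None)
        assert resolve_population(record, self.CTX) == 5_000_000

    def test_close_report_is_kept(self, complete_record):
        ctx = replace(self.CTX, un_population=1_050_000)
        record = replace(complete_record, reported_population=1_000_000)
        assert resolve_population(record, ctx, 0.30) == 1_000_000

    def test_divergent_report_replaced_by_un(self, complete_record):
        ctx = replace(self.CTX, un_population=1_000_000)
        record = replace(complete_record, reported_population=100_000)
        assert resolve_population(record, ctx, 0.30) == 1_000_000

    def test_missing_context_names_country(self, complete_record):
        with pytest.raises(ContextLookupError, match="AAA"):
            resolve_population(complete_record, {})

    @given(reported=st.floats(1.0, 1e9), un=st.floats(1.0, 1e9),
           limit=st.floats(0.0, 2.0))
    @settings(max_examples=100, derandomize=True)
    def test_result_is_always_positive(self, reported, un, limit):
        record = AtlasRecord("AAA", Disorder.BIPOLAR,
                             reported_population=reported)
        ctx = CountryContext("AAA", IncomeGroup.LOW, "AFR", "r", "sr", un)
        assert resolve_population(record, ctx, limit) > 0


class TestScreenProperties:
    def test_screens_are_idempotent(self, default_cohort):
        for record in default_cohort.records:
            first = screen_completeness(record)
            assert screen_completeness(record) == first
            if first.included:
                second = visits_per_case_check(record)
                assert visits_per_case_check(record) == second

    def test_ledger_conserves_records(self, default_cohort):
        passed, ledger = screen_records(default_cohort.records)
        assert len(passed) + len(ledger) == len(default_cohort.records)
        reasons = {reason for _, _, reason in ledger}
        assert ExclusionReason.OK not in reasons


class TestReadCountryContext:
    def test_duplicate_country_rejected(self, tmp_path):
        path = tmp_path / "country_context.csv"
        path.write_text(
            "country_code,income_group,who_region,gbd_region,"
            "gbd_super_region,un_population\n"
            "AAA,low,AFR,r,sr,1000\nAAA,low,AFR,r,sr,1000\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_country_context(path)

    def test_round_trip(self, tmp_path, default_cohort):
        paths = default_cohort.write(tmp_path)
        contexts = read_country_context(paths["context"])
        assert contexts == default_cohort.contexts
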