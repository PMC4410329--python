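"""CSV ingestion, aggregation, configuration and report rendering."""

import json

import pytest

from cdsmp_savings import (
    CSV_COLUMNS,
    ConfigError,
    IngestionError,
    ParticipantRecord,
    ReachScenario,
    ReportFormatError,
    ScenarioMode,
    UnderageParticipantError,
    UndefinedDenominatorError,
    aggregate,
    attach_projection,
    build_report,
    config_from_dict,
    default_config,
    read_config,
    read_participants,
    render_report,
    usd,
)
from cdsmp_savings.cohort import CollapsedCountWarning


def write_csv(tmp_path, rows, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(",".join(CSV_COLUMNS) + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return str(path)


class TestReadParticipants:
    def test_national_fixture_round_trip(self, national_cohort_csv):
        records = read_participants(national_cohort_csv)
        assert len(records) == 1170
        er, hosp, mix = aggregate(records)
        assert (er.n_baseline, er.events_baseline, er.n_6mo, er.events_6mo,
                er.n_12mo, er.events_12mo) == (1170, 211, 903, 118, 825, 108)
        assert (hosp.n_baseline, hosp.events_baseline, hosp.n_6mo, hosp.events_6mo,
                hosp.n_12mo, hosp.events_12mo) == (1170, 164, 903, 100, 825, 116)
        # 117/363/690 of 1170
        assert mix.w18_44 == pytest.approx(0.1)

    def test_header_only_gives_empty_list(self, tmp_path):
        path = write_csv(tmp_path, [])
        assert read_participants(path) == []
        with pytest.raises(UndefinedDenominatorError):
            aggregate([])

    def test_attrition_semantics(self, tmp_path):
        path = write_csv(tmp_path, ["p1,65+,1,,,0,,"])
        (record,) = read_participants(path)
        assert record.er_6mo is None and record.er_12mo is None
        er, hosp, mix = aggregate([record])
        assert (er.n_baseline, er.events_baseline, er.n_6mo, er.n_12mo) == (1, 1, 0, 0)
        assert mix.w65plus == 1.0

    def test_wave_specific_response_is_legal(self, tmp_path):
        # missing 6-month answer, present 12-month answer
        path = write_csv(tmp_path, ["p1,45-64,0,,1,0,0,0"])
        (record,) = read_participants(path)
        assert record.er_6mo is None and record.er_12mo is True

    def test_integer_age_mapped_to_bins(self, tmp_path):
        path = write_csv(tmp_path, ["p1,44,0,,,0,,", "p2,45,0,,,0,,", "p3,65,0,,,0,,"])
        groups = [r.age_group for r in read_participants(path)]
        assert groups == ["18-44", "45-64", "65+"]

    def test_underage_rejected_with_line_number(self, tmp_path):
        path = write_csv(tmp_path, ["p1,45-64,0,,,0,,", "p2,17,0,,,0,,"])
        with pytest.raises(UnderageParticipantError, match="line 3"):
            read_participants(path)

    def test_unknown_age_group_rejected(self, tmp_path):
        path = write_csv(tmp_path, ["p1,middle-aged,0,,,0,,"])
        with pytest.raises(IngestionError, match="age group"):
            read_participants(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = write_csv(tmp_path, ["p1,65+,0,,,0,,", "p1,65+,0,,,0,,"])
        with pytest.raises(IngestionError, match="duplicate"):
            read_participants(path)

    def test_missing_baseline_indicator_rejected(self, tmp_path):
        path = write_csv(tmp_path, ["p1,65+,,,,0,,"])
        with pytest.raises(IngestionError, match="baseline"):
            read_participants(path)

    def test_raw_counts_collapse_with_warning(self, tmp_path):
        path = write_csv(tmp_path, ["p1,65+,3,,,0,,"])
        with pytest.warns(CollapsedCountWarning):
            (record,) = read_participants(path)
        assert record.er_baseline is True

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,age_group\np1,65+\n")
        with pytest.raises(IngestionError, match="missing required columns"):
            read_participants(str(path))


class TestAggregate:
    def test_permutation_invariant(self, national_cohort_csv):
        records = read_participants(national_cohort_csv)
        forward = aggregate(records)
        backward = aggregate(list(reversed(records)))
        assert forward[0] == backward[0]
        assert forward[1] == backward[1]
        assert forward[2] == backward[2]

    def test_category_specific_denominators(self):
        records = [
            ParticipantRecord("p1", "65+", True, True, None, False, None, False),
            ParticipantRecord("p2", "65+", False, None, None, False, True, None),
        ]
        er, hosp, _ = aggregate(records)
        assert (er.n_6mo, er.events_6mo) == (1, 1)
        assert (hosp.n_6mo, hosp.events_6mo) == (1, 1)
        assert (er.n_12mo, hosp.n_12mo) == (0, 1)


class TestConfig:
    def test_empty_config_reproduces_national_defaults(self):
        report = build_report(config_from_dict({}))
        assert usd(report.er_adjusted_cost) == "1,513.05"
        assert usd(report.breakdown.annual_savings) == "713.81"
        assert usd(report.breakdown.net_savings) == "363.81"
        assert report.warnings == []

    def test_class_size_override_only(self):
        config = config_from_dict({"program_cost": {"class_size": 8}})
        report = build_report(config)
        assert report.breakdown.program_cost == 438
        assert usd(report.er_adjusted_cost) == "1,513.05"  # all else default

    def test_bad_weights_rejected_with_pointer(self):
        with pytest.raises(ConfigError, match="/age_distribution"):
            config_from_dict({"age_distribution": {"w18_44": 0.5, "w45_64": 0.3, "w65plus": 0.3}})

    def test_unknown_field_rejected_with_pointer(self):
        with pytest.raises(ConfigError, match="/inflation"):
            config_from_dict({"inflation": 0.02})

    def test_scenario_parsing(self):
        config = config_from_dict(
            {"scenario": {"mode": "local_counts", "expected18_44": 102,
                          "expected45_64": 66, "expected65plus": 32}}
        )
        assert config.scenario is not None
        assert config.scenario.expected_total == 200

    def test_read_config_file(self, tmp_path, case_metro_city):
        path = tmp_path / "config.json"
        path.write_text(json.dumps(case_metro_city))
        report = build_report(read_config(str(path)))
        assert usd(report.breakdown.net_savings) == "691.55"

    def test_invalid_json_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ConfigError, match="invalid JSON"):
            read_config(str(path))


class TestRenderReport:
    def test_text_contains_published_cells(self):
        text = render_report(build_report(default_config()), "text")
        for cell in ("1,513.05", "18,750.18", "75.65", "562.51", "151.31",
                     "713.81", "350.00", "363.81"):
            assert cell in text

    def test_stability_warning_in_body(self):
        config = config_from_dict(
            {"er_series": {"n_baseline": 99, "events_baseline": 18, "n_6mo": 99,
                           "events_6mo": 13, "n_12mo": 99, "events_12mo": 13},
             "hosp_series": {"n_baseline": 99, "events_baseline": 14, "n_6mo": 99,
                             "events_6mo": 11, "n_12mo": 99, "events_12mo": 14}}
        )
        text = render_report(build_report(config), "text")
        assert "WARNINGS" in text and "at least 100" in text

    def test_negative_reduction_warning(self):
        config = config_from_dict(
            {"er_series": {"n_baseline": 100, "events_baseline": 10, "n_6mo": 100,
                           "events_6mo": 20, "n_12mo": 100, "events_12mo": 10}}
        )
        report = build_report(config)
        assert any("increased" in w for w in report.warnings)
        assert report.breakdown.er_savings_first < 0

    @pytest.mark.parametrize("fmt", ["text", "json", "csv"])
    def test_rendering_is_deterministic(self, fmt):
        config = default_config()
        first = render_report(build_report(config), fmt)
        second = render_report(build_report(config), fmt)
        assert first.encode() == second.encode()

    def test_json_unrounded_values_re_render(self):
        report = attach_projection(
            build_report(default_config()),
            default_config(),
            ReachScenario(ScenarioMode.NATIONAL_FRACTION, reach_fraction=0.05),
        )
        payload = json.loads(render_report(report, "json"))
        from cdsmp_savings import whole

        for name, entry in payload["quantities"].items():
            expected = whole(entry["value"]) if name == "projection_headcount" else usd(entry["value"])
            assert entry["rendered"] == expected

    def test_csv_rows_parse(self):
        document = render_report(build_report(default_config()), "csv")
        lines = document.strip().splitlines()
        assert lines[0] == "quantity,value,rendered"
        assert any(line.startswith("net_savings,") for line in lines)

    def test_unknown_format_rejected(self):
        with pytest.raises(ReportFormatError):
            render_report(build_report(default_config()), "xml")

    def test_national_projection_section(self):
        config = default_config()
        report = attach_projection(
            build_report(config), config,
            ReachScenario(ScenarioMode.NATIONAL_FRACTION, reach_fraction=0.05),
        )
        text = render_report(report, "text")
        assert "180,614,335" in text
        assert "65,709,373,342.03" in text
        assert "3,285,468,667.10" in text
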