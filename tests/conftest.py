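import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# Config overrides reproducing the two worked examples: whole-percent wave
# rates realized as counts over 100 respondents per wave.
CASE_SMALL_COUNTY = {
    "age_distribution": {"w18_44": 0.56, "w45_64": 0.23, "w65plus": 0.21},
    "er_series": {
        "n_baseline": 100, "events_baseline": 16,
        "n_6mo": 100, "events_6mo": 11,
        "n_12mo": 100, "events_12mo": 11,
    },
    "hosp_series": {
        "n_baseline": 100, "events_baseline": 12,
        "n_6mo": 100, "events_6mo": 10,
        "n_12mo": 100, "events_12mo": 11,
    },
    "program_cost": {"workshop_cost": 3500, "class_size": 8},  # -> $438
}

CASE_METRO_CITY = {
    "age_distribution": {"w18_44": 0.72, "w45_64": 0.16, "w65plus": 0.12},
    "er_series": {
        "n_baseline": 100, "events_baseline": 15,
        "n_6mo": 100, "events_6mo": 12,
        "n_12mo": 100, "events_12mo": 11,
    },
    "hosp_series": {
        "n_baseline": 100, "events_baseline": 16,
        "n_6mo": 100, "events_6mo": 11,
        "n_12mo": 100, "events_12mo": 15,
    },
    "program_cost": {"workshop_cost": 3500, "class_size": 14},  # -> $250
}


@pytest.fixture
def case_small_county():
    return dict(CASE_SMALL_COUNTY)


@pytest.fixture
def case_metro_city():
    return dict(CASE_METRO_CITY)


@pytest.fixture
def national_cohort_csv(tmp_path):
    """Participant CSV generated from the EXACT national cohort spec."""
    from cdsmp_savings import generate_cohort, national_cohort_spec, write_participants_csv

    path = tmp_path / "national.csv"
    write_participants_csv(generate_cohort(national_cohort_spec()), str(path))
    return str(path)
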