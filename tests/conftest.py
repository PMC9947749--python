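import pytest

from pufftopo import SyntheticCohortConfig, generate_cohort

PUFF_HEADER = ("device_id,timestamp,duration_s,power_setting,"
               "nicotine_conc_mg_ml,pg_vg_ratio,brand")
SURVEY_HEADER = "device_id,sex,age_band,smoking_history,ends_years_band"


@pytest.fixture
def write_puff_csv(tmp_path):
    """Write a puff-log CSV from raw data rows and return its path."""

    def _write(rows, name="puffs.csv", header=PUFF_HEADER):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write


@pytest.fixture
def write_survey_csv(tmp_path):
    def _write(rows, name="survey.csv", header=SURVEY_HEADER):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort at study-condition defaults."""
    return generate_cohort(SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast structural tests."""
    cfg = SyntheticCohortConfig(n_users=8, n_days=14, seed=5, n_extra_profiles=1)
    return generate_cohort(cfg)
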