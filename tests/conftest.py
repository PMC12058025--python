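import pandas as pd
import pytest

from limnoindex import GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def survey():
    """Default synthetic survey (7 sites x 3 seasons x 3 layers)."""
    return generate_survey(GeneratorConfig(), seed=1)


@pytest.fixture
def survey_csv(tmp_path, survey):
    """The default survey written to a CSV file."""
    from limnoindex import write_survey
    path = tmp_path / "survey.csv"
    write_survey(survey, path)
    return path


@pytest.fixture
def small_frame():
    """A tiny hand-written valid survey frame."""
    rows = []
    for site in ("A", "B"):
        for season, month in (("dry", 4), ("wet", 7)):
            for layer, depth in (("upper", 0.5), ("middle", 3.0), ("lower", 5.0)):
                rows.append({
                    "site_id": site, "season": season, "month": month,
                    "layer": layer, "depth_m": depth, "temp_C": 15.2,
                    "pH": 8.0, "DO_mgL": 9.0, "turbidity_NTU": 5.0,
                    "SDD_m": 1.2, "TN_mgL": 2.0, "TP_mgL": 0.05,
                    "NH3N_mgL": 0.5, "CODMn_mgL": 2.0, "TOC_mgL": 3.5,
                    "ChlA_mgL": 0.02,
                })
    return pd.DataFrame(rows)
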