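"""Survey IO, validation and standardization."""

import numpy as np
import pandas as pd
import pytest

from limnoindex import (DegenerateInputError, StandardsConfigError,
                        SurveyDataset, SurveyFormatError,
                        SurveyValidationError, default_standards,
                        read_standards, read_survey, season_from_month,
                        standardize, write_survey)
from limnoindex.standards import ParameterStandard, _parse_toml


class TestReadSurvey:
    def test_roundtrip_preserves_structure_and_values(self, survey, tmp_path):
        path = tmp_path / "s.csv"
        write_survey(survey, path)
        back = read_survey(path)
        assert len(back) == 63
        assert sorted(back.sites) == sorted(survey.sites)
        pd.testing.assert_frame_equal(
            back.frame.reset_index(drop=True).astype({"month": "Int64"}),
            survey.frame.reset_index(drop=True).astype({"month": "Int64"}),
            check_dtype=False)

    def test_negative_concentration_rejected_with_row_diagnostic(
            self, small_frame, tmp_path):
        small_frame.loc[3, "TP_mgL"] = -0.01
        path = tmp_path / "bad.csv"
        small_frame.to_csv(path, index=False)
        with pytest.raises(SurveyValidationError, match=r"row 3.*TP_mgL"):
            read_survey(path)

    def test_empty_cell_becomes_missing_not_error(self, small_frame, tmp_path):
        small_frame.loc[2, "ChlA_mgL"] = np.nan
        path = tmp_path / "gap.csv"
        small_frame.to_csv(path, index=False)
        back = read_survey(path)
        assert pd.isna(back.frame.loc[2, "ChlA_mgL"])

    def test_garbled_cell_is_diagnosed_not_coerced(self, small_frame, tmp_path):
        small_frame["TN_mgL"] = small_frame["TN_mgL"].astype(object)
        small_frame.loc[1, "TN_mgL"] = "oops"
        path = tmp_path / "garbled.csv"
        small_frame.to_csv(path, index=False)
        with pytest.raises(SurveyValidationError, match=r"row 1.*TN_mgL"):
            read_survey(path)

    def test_missing_columns_is_format_error(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("site_id,month\nA,4\n")
        with pytest.raises(SurveyFormatError, match="missing required"):
            read_survey(path)

    def test_unknown_layer_label_rejected(self, small_frame, tmp_path):
        small_frame.loc[0, "layer"] = "benthic"
        path = tmp_path / "lay.csv"
        small_frame.to_csv(path, index=False)
        with pytest.raises(SurveyValidationError, match="unknown layer"):
            read_survey(path)


class TestSurveyDataset:
    def test_duplicate_triple_rejected(self, small_frame):
        frame = pd.concat([small_frame, small_frame.iloc[[0]]])
        with pytest.raises(SurveyValidationError, match="duplicate"):
            SurveyDataset(frame)

    def test_layer_depth_ordering_enforced(self, small_frame):
        # make the upper layer deeper than the lower layer at one site
        small_frame.loc[0, "depth_m"] = 9.0
        with pytest.raises(SurveyValidationError, match="not ordered"):
            SurveyDataset(small_frame)

    def test_ph_outside_physical_range_rejected(self, small_frame):
        small_frame.loc[0, "pH"] = 15.0
        with pytest.raises(SurveyValidationError, match="pH"):
            SurveyDataset(small_frame)


@pytest.mark.parametrize("month,season", [(1, "dry"), (4, "dry"), (5, "wet"),
                                          (9, "wet"), (10, "normal"),
                                          (12, "normal")])
def test_season_from_month(month, season):
    assert season_from_month(month) == season


class TestStandardize:
    def test_closed_form(self):
        out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_mean_zero_unit_sd(self, survey):
        out = standardize(survey, parameters=["TN", "TP"])
        assert abs(out["TN"].mean()) < 1e-12
        assert abs(out["TN"].std(ddof=1) - 1) < 1e-12

    def test_idempotent(self, survey):
        once = standardize(survey, parameters=["TP"])
        twice = standardize(once)
        pd.testing.assert_frame_equal(once, twice, check_exact=False, atol=1e-12)

    def test_constant_column_degenerate(self):
        with pytest.raises(DegenerateInputError, match="zero variance"):
            standardize(pd.DataFrame({"x": [5.0, 5.0, 5.0]}))

    def test_missing_values_propagate(self):
        out = standardize(pd.DataFrame({"x": [1.0, np.nan, 2.0, 3.0]}))
        assert pd.isna(out["x"][1])


class TestStandards:
    def test_default_config(self):
        cfg = default_standards()
        assert cfg.m == 10
        assert cfg["SDD"].direction == "benefit"
        assert (cfg["pH"].ph_lower, cfg["pH"].ph_upper) == (6.0, 9.0)
        assert cfg["SDD"].standard_value == 2.5
        assert cfg["ChlA"].standard_value == 0.04

    def test_restricted_to_class_iii_six(self):
        cfg = default_standards().restrict(
            ["pH", "DO", "CODMn", "NH3N", "TP", "TN"])
        assert cfg.m == 6

    def test_duplicate_parameter_is_config_error(self):
        text = "[TP]\nstandard = 0.05\n[TP]\nstandard = 0.1\n"
        with pytest.raises(StandardsConfigError):
            _parse_toml(text)

    def test_ph_without_bounds_is_config_error(self):
        with pytest.raises(StandardsConfigError, match="both lower and upper"):
            ParameterStandard(parameter="pH", family="pH", ph_lower=6.0)

    def test_custom_file_roundtrip(self, tmp_path):
        path = tmp_path / "std.toml"
        path.write_text('[TP]\nstandard = 0.02\ndirection = "cost"\n')
        cfg = read_standards(path)
        assert cfg.m == 1
        assert cfg["TP"].standard_value == 0.02
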