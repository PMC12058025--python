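"""Readers and writers for monitoring survey CSVs.

Dialect: UTF-8, comma-separated, ``.`` decimal, mandatory header.  Empty
cells are missing values.  Numeric round-trips are exact for finite
decimals because values are written with :func:`repr`-faithful pandas
formatting.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SurveyFormatError, SurveyValidationError
from .schema import (OPTIONAL_COLUMNS, SURVEY_COLUMNS, SurveyDataset,
                     season_from_month)

_NUMERIC = [c for c in SURVEY_COLUMNS if c not in ("site_id", "season", "layer")]


def read_survey(path, schema: dict | None = None,
                provenance: str = "observed") -> SurveyDataset:
    """Read a monitoring CSV into a validated :class:`SurveyDataset`.

    Parameters
    ----------
    path
        CSV file with the canonical columns (see :data:`SURVEY_COLUMNS`).
    schema
        Optional map from file column names to canonical names, for files
        whose headers deviate from the standard schema.
    """
    path = Path(path)
    if not path.exists():
        raise SurveyFormatError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if schema:
        frame = frame.rename(columns=schema)
    missing = [c for c in SURVEY_COLUMNS if c not in frame.columns
               and c not in ("season", "month")]
    if missing:
        raise SurveyFormatError(
            f"{path}: missing required columns {missing} "
            "(is the header row present?)")
    if "season" not in frame.columns and "month" not in frame.columns:
        raise SurveyFormatError(f"{path}: need a season or a month column")
    bad_cells = []
    for col in frame.columns:
        if col in _NUMERIC:
            raw = frame[col]
            num = pd.to_numeric(raw, errors="coerce")
            # a cell that was non-empty but did not parse is an error, not
            # a missing value
            garbled = raw.notna() & raw.str.strip().ne("") & num.isna()
            for idx in frame.index[garbled]:
                bad_cells.append(f"row {idx}: {col} = {raw[idx]!r} is not numeric")
            frame[col] = num
    if bad_cells:
        raise SurveyValidationError(bad_cells)
    if "month" in frame.columns:
        frame["month"] = frame["month"].astype("Int64")
        if "season" not in frame.columns:
            frame["season"] = [season_from_month(m) if pd.notna(m) else None
                               for m in frame["month"]]
    else:
        frame["month"] = pd.NA
    keep = [c for c in SURVEY_COLUMNS + OPTIONAL_COLUMNS if c in frame.columns]
    return SurveyDataset(frame[keep], provenance=provenance)


def write_survey(dataset: SurveyDataset, path) -> None:
    """Write a survey back to the canonical CSV schema."""
    cols = [c for c in SURVEY_COLUMNS + OPTIONAL_COLUMNS
            if c in dataset.frame.columns]
    dataset.frame[cols].to_csv(path, index=False)
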