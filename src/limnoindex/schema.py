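"""Survey table schema, validation and the :class:`SurveyDataset` container.

A survey is a long-format table with one row per (site, season, layer)
sampling event.  The canonical in-memory container is a pandas DataFrame
with the columns in :data:`SURVEY_COLUMNS`; :class:`SurveyDataset` wraps it
together with its provenance and validates every monitoring-record
invariant on construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SurveyValidationError

#: Canonical column order of a monitoring CSV.
SURVEY_COLUMNS = [
    "site_id", "season", "month", "layer", "depth_m",
    "temp_C", "pH", "DO_mgL", "turbidity_NTU", "SDD_m",
    "TN_mgL", "TP_mgL", "NH3N_mgL", "CODMn_mgL", "TOC_mgL", "ChlA_mgL",
]

#: Columns measured in the field but unused by the index engines; accepted
#: and carried through if present.
OPTIONAL_COLUMNS = ["TDS_mgL", "salinity_PSU", "EC_uScm"]

#: Factor columns identifying a sampling event.
FACTOR_COLUMNS = ["site_id", "season", "layer"]

#: Measured parameter name -> survey column.
PARAMETER_COLUMNS = {
    "pH": "pH",
    "DO": "DO_mgL",
    "CODMn": "CODMn_mgL",
    "NH3N": "NH3N_mgL",
    "TP": "TP_mgL",
    "TN": "TN_mgL",
    "turbidity": "turbidity_NTU",
    "TOC": "TOC_mgL",
    "SDD": "SDD_m",
    "ChlA": "ChlA_mgL",
}

SEASONS = ("dry", "wet", "normal")
LAYERS = ("upper", "middle", "lower")

#: Columns that must be non-negative when present.
_NONNEGATIVE = ["depth_m", "DO_mgL", "turbidity_NTU", "TN_mgL", "TP_mgL",
                "NH3N_mgL", "CODMn_mgL", "TOC_mgL", "ChlA_mgL"]
#: Columns that must be strictly positive when present.
_POSITIVE = ["SDD_m"]


def season_from_month(month: int) -> str:
    """Map a calendar month to the basin's precipitation season.

    January–April is the dry season, May–September the wet season and
    October–December the normal water season.
    """
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month {month} outside 1..12")
    if month <= 4:
        return "dry"
    if month <= 9:
        return "wet"
    return "normal"


def validate_survey(frame: pd.DataFrame) -> list[str]:
    """Return the full list of row-level diagnostics for ``frame``.

    Every violating row yields a diagnostic naming the row label and the
    offending field; an empty list means the table satisfies all
    monitoring-record invariants.
    """
    diags: list[str] = []
    for col in FACTOR_COLUMNS + ["depth_m"]:
        if col not in frame.columns:
            diags.append(f"missing required column {col!r}")
    if diags:
        return diags

    for idx, row in frame.iterrows():
        where = f"row {idx}"
        if row["season"] not in SEASONS:
            diags.append(f"{where}: unknown season label {row['season']!r}")
        if row["layer"] not in LAYERS:
            diags.append(f"{where}: unknown layer label {row['layer']!r}")
        for col in _NONNEGATIVE:
            v = row.get(col)
            if v is not None and pd.notna(v) and v < 0:
                diags.append(f"{where}: {col} = {v} is negative")
        for col in _POSITIVE:
            v = row.get(col)
            if v is not None and pd.notna(v) and v <= 0:
                diags.append(f"{where}: {col} = {v} must be > 0")
        ph = row.get("pH")
        if ph is not None and pd.notna(ph) and not 0 < ph < 14:
            diags.append(f"{where}: pH = {ph} outside (0, 14)")

    dup = frame.duplicated(subset=FACTOR_COLUMNS, keep=False)
    for idx in frame.index[dup & ~frame.duplicated(subset=FACTOR_COLUMNS)]:
        key = tuple(frame.loc[idx, FACTOR_COLUMNS])
        diags.append(f"duplicate (site, season, layer) triple {key}")

    # layer depths must be ordered upper < middle < lower within a site visit
    order = {lay: i for i, lay in enumerate(LAYERS)}
    for (site, season), grp in frame.groupby(["site_id", "season"], sort=False):
        known = grp.dropna(subset=["depth_m"])
        known = known[known["layer"].isin(LAYERS)]
        ranked = known.sort_values("depth_m")
        ranks = [order[lay] for lay in ranked["layer"]]
        if ranks != sorted(ranks):
            diags.append(
                f"site {site} season {season}: layer depths not ordered "
                "upper < middle < lower"
            )
    return diags


@dataclass
class SurveyDataset:
    """A validated collection of monitoring records.

    Parameters
    ----------
    frame
        Long-format monitoring table (one row per site/season/layer).
    provenance
        ``"observed"`` for field data, ``"synthetic"`` for generated data.
    """

    frame: pd.DataFrame
    provenance: str = "observed"

    def __post_init__(self):
        if self.provenance not in ("observed", "synthetic"):
            raise ValueError(f"provenance {self.provenance!r} must be observed|synthetic")
        diags = validate_survey(self.frame)
        if diags:
            raise SurveyValidationError(diags)
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.frame["site_id"]))

    @property
    def seasons(self) -> list[str]:
        return [s for s in SEASONS if s in set(self.frame["season"])]

    @property
    def layers(self) -> list[str]:
        return [l for l in LAYERS if l in set(self.frame["layer"])]

    def parameter_table(self, parameters=None) -> pd.DataFrame:
        """Return the measured-parameter matrix (columns renamed to
        parameter names) for the requested parameters."""
        params = list(parameters) if parameters is not None else list(PARAMETER_COLUMNS)
        cols = {PARAMETER_COLUMNS[p]: p for p in params}
        return self.frame[list(cols)].rename(columns=cols)


def standardize(data, parameters=None) -> pd.DataFrame:
    """Z-score each parameter column: mean 0, sample (ddof=1) SD 1.

    Missing values propagate as missing.  A column with fewer than two
    non-missing values or zero variance raises
    :class:`~limnoindex.errors.DegenerateInputError`.
    """
    if isinstance(data, SurveyDataset):
        table = data.parameter_table(parameters)
    else:
        table = pd.DataFrame(data)
        if parameters is not None:
            table = table[list(parameters)]
    out = {}
    for col in table.columns:
        x = pd.to_numeric(table[col], errors="coerce")
        n = x.notna().sum()
        if n < 2:
            raise DegenerateInputError(f"parameter {col!r}: fewer than 2 values")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateInputError(f"parameter {col!r}: zero variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)
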