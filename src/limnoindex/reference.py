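"""Bundled reference assessment tables for Lake Aha (2023 campaigns).

Site-mean composite index tables from a published seven-site survey of
Lake Aha, a karst plateau reservoir near Guiyang: TLI and WQI by season
(April dry, July wet, October normal) and by vertical layer, each a
7-site row.  These are fixture inputs for the statistics stage — the raw
per-record concentrations behind them are not part of the package — plus
the published ANOVA summaries and seasonal means used as cross-checks.
"""

from __future__ import annotations

import pandas as pd

SITES = ["YY", "CC", "LN", "SS", "LC", "BY", "JZ"]

_TLI_SEASON = {
    "April": [16.940, 24.740, 25.917, 32.840, 28.160, 29.320, 42.570],
    "July": [20.200, 27.750, 30.824, 35.540, 29.430, 30.530, 43.163],
    "October": [10.220, 15.850, 16.970, 20.850, 15.160, 20.420, 22.927],
}

_TLI_LAYER = {
    "upper": [19.013, 20.265, 25.781, 31.418, 24.378, 23.797, 34.685],
    "middle": [19.639, 22.074, 25.741, 29.955, 24.527, 21.337, 32.318],
    "lower": [18.375, 23.210, 26.167, 27.933, 24.139, 24.028, 32.499],
}

_WQI_SEASON = {
    "April": [69, 108, 105, 111, 101, 98, 172],
    "July": [67, 75, 97, 96, 82, 78, 150],
    "October": [56, 56, 60, 66, 63, 62, 73],
}

_WQI_LAYER = {
    "upper": [65, 82, 83, 107, 90, 82, 136],
    "middle": [68, 82, 87, 97, 91, 69, 125],
    "lower": [66, 83, 88, 85, 81, 70, 134],
}


def _table(data) -> pd.DataFrame:
    return pd.DataFrame.from_dict(data, orient="index", columns=SITES).astype(float)


def tli_by_season() -> pd.DataFrame:
    """TLI site means per campaign (rows: April/July/October)."""
    return _table(_TLI_SEASON)


def tli_by_layer() -> pd.DataFrame:
    """TLI site means per vertical layer (rows: upper/middle/lower)."""
    return _table(_TLI_LAYER)


def wqi_by_season() -> pd.DataFrame:
    """WQI site means per campaign."""
    return _table(_WQI_SEASON)


def wqi_by_layer() -> pd.DataFrame:
    """WQI site means per vertical layer."""
    return _table(_WQI_LAYER)


#: Published ANOVA summaries for the six factor analyses:
#: (SS between, SS within, df between, df within, F).
PUBLISHED_ANOVA = {
    "tli_season": (734.1882, 781.0117, 2, 18, 8.460429),
    "tli_layer": (1.1203, 437.2782, 2, 18, 0.023058),
    "tli_site": (418.9555, 19.44304, 6, 14, 50.27829),
    "wqi_season": (7877.4286, 10603.14286, 2, 18, 6.6864),
    "wqi_layer": (107.8095, 8426.0, 2, 18, 0.115154),
    "wqi_site": (8037.8095, 496.0, 6, 14, 37.812276),
}

#: Published seasonal means of the composite indices.
PUBLISHED_MEANS = {
    "tli_april": 28.64,
    "tli_july": 31.06,
    "wqi_april": 109.14,
    "wqi_july": 92.14,
}
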