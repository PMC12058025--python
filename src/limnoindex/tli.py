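"""Trophic level index (TLI).

Five log-linear sub-indices quantify trophic state from chlorophyll-a,
total phosphorus, total nitrogen, Secchi depth and the permanganate
index::

    TLI(Chl-a)   = 10 * (2.5   + 1.0861 * ln Chl-a)
    TLI(TP)      = 10 * (9.436 + 1.624  * ln TP)
    TLI(TN)      = 10 * (5.453 + 1.694  * ln TN)
    TLI(SDD)     = 10 * (5.118 - 1.94   * ln SDD)
    TLI(COD_Mn)  = 10 * (0.109 + 2.661  * ln COD_Mn)

with TP, TN and COD_Mn in mg/L, SDD in m, and Chl-a in the formula's
native mg/m^3 convention (an input-unit flag converts mg/L columns).
The composite is a convex combination

    TLI(sum) = sum_j W_j * TLI(j),     W_j = r_j^2 / sum r^2,

weighted by squared correlations of each indicator with the reference
chlorophyll-a.  The default r-vector is the national multi-lake survey
calibration (1, 0.84, 0.82, -0.83, 0.83 for Chl-a, TP, TN, SDD, COD_Mn);
setting ``reweight_from_data=True`` re-estimates it from the fitted
survey instead.  Trophic state runs Oligotrophic (< 30) through Severely
Eutrophic (> 70).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, DomainError, StandardsConfigError
from .schema import PARAMETER_COLUMNS, SurveyDataset

#: (intercept, slope) of 10*(a + b*ln x) per indicator.
TLI_COEFFICIENTS = {
    "ChlA": (2.5, 1.0861),
    "TP": (9.436, 1.624),
    "TN": (5.453, 1.694),
    "SDD": (5.118, -1.94),
    "CODMn": (0.109, 2.661),
}

TLI_INDICATORS = tuple(TLI_COEFFICIENTS)

#: National multi-lake calibration of indicator correlations with Chl-a.
NATIONAL_R = {"ChlA": 1.0, "TP": 0.84, "TN": 0.82, "SDD": -0.83, "CODMn": 0.83}

#: Trophic classes as (lower, upper, lower-inclusive, upper-inclusive).
TLI_CLASSES = [
    (-math.inf, 30.0, False, False, "Oligotrophic"),
    (30.0, 50.0, True, True, "Mesotrophic"),
    (50.0, 60.0, False, True, "Slightly Eutrophic"),
    (60.0, 70.0, False, True, "Moderately Eutrophic"),
    (70.0, math.inf, False, False, "Severely Eutrophic"),
]


def tli_subindex(parameter: str, value: float) -> float:
    """One trophic sub-index, value in formula units (Chl-a in mg/m^3)."""
    try:
        a, b = TLI_COEFFICIENTS[parameter]
    except KeyError:
        raise StandardsConfigError(
            f"unknown TLI indicator {parameter!r}; expected one of "
            f"{TLI_INDICATORS}") from None
    if value <= 0:
        raise DomainError(f"{parameter}: value {value} must be > 0 (log domain)")
    return 10.0 * (a + b * math.log(value))


@dataclass
class TliWeights:
    """Chl-a-referenced correlative weights ``W_j = r_j^2 / sum r^2``."""

    r: dict[str, float]
    r_squared: dict[str, float]
    w: dict[str, float]


def compute_weights(r: dict[str, float]) -> TliWeights:
    """Turn a correlation vector into normalized squared-correlation
    weights."""
    if not r:
        raise StandardsConfigError("empty correlation map")
    for p, v in r.items():
        if abs(v) > 1:
            raise StandardsConfigError(f"{p}: |r| = {abs(v)} > 1")
    r2 = {p: v * v for p, v in r.items()}
    total = sum(r2.values())
    if total <= 0:
        raise DegenerateInputError("all correlations are zero")
    return TliWeights(r=dict(r), r_squared=r2,
                      w={p: v / total for p, v in r2.items()})


def classify_tli(tli: float) -> str:
    """Trophic state label for a composite TLI value."""
    if not np.isfinite(tli):
        raise DomainError(f"TLI {tli} must be finite")
    for lo, hi, lo_inc, hi_inc, label in TLI_CLASSES:
        above = tli >= lo if lo_inc else tli > lo
        below = tli <= hi if hi_inc else tli < hi
        if above and below:
            return label
    raise AssertionError("unreachable")  # classes cover the real line


@dataclass
class TliBreakdown:
    """Composite TLI for one record with its sub-indices."""

    sub_indices: dict[str, float]
    m: int
    tli: float
    trophic_state: str


class TLICalculator(BaseEstimator, TransformerMixin):
    """Compute per-record TLI breakdowns for a survey table.

    ``transform`` maps a survey frame (or :class:`SurveyDataset`) to a
    frame with one ``TLI_<indicator>`` column per indicator plus the
    weighted composite ``TLI``, the ``trophic_state`` label and ``m``
    (indicators present).  Missing indicators have their weights
    renormalized over the present subset, so the composite stays a convex
    combination of the available sub-indices.

    Parameters
    ----------
    r : mapping, optional
        Indicator-to-Chl-a correlations; defaults to the national
        multi-lake calibration.
    reweight_from_data : bool
        If True, ``fit`` re-estimates r as the Pearson correlation of
        each indicator with Chl-a on the fitted survey (Chl-a keeps
        r = 1).
    chla_unit : {"mg/L", "mg/m3"}
        Unit of the incoming Chl-a column; mg/L values are converted
        (x 1000) to the formula's mg/m^3 convention.
    """

    def __init__(self, r: dict[str, float] | None = None,
                 reweight_from_data: bool = False,
                 chla_unit: str = "mg/L"):
        self.r = r
        self.reweight_from_data = reweight_from_data
        self.chla_unit = chla_unit

    def _indicator_table(self, X) -> pd.DataFrame:
        frame = X.frame if isinstance(X, SurveyDataset) else pd.DataFrame(X)
        cols = {}
        for p in TLI_INDICATORS:
            col = PARAMETER_COLUMNS.get(p, p)
            src = frame[col] if col in frame.columns else frame.get(p)
            if src is None:
                cols[p] = pd.Series(np.nan, index=frame.index)
            else:
                cols[p] = pd.to_numeric(src, errors="coerce")
        table = pd.DataFrame(cols)
        if self.chla_unit not in ("mg/L", "mg/m3"):
            raise StandardsConfigError(
                f"chla_unit {self.chla_unit!r} must be 'mg/L' or 'mg/m3'")
        if self.chla_unit == "mg/L":
            table["ChlA"] = table["ChlA"] * 1000.0
        return table

    def fit(self, X=None, y=None):
        if self.reweight_from_data:
            if X is None:
                raise DegenerateInputError(
                    "reweight_from_data=True needs a survey to fit")
            table = self._indicator_table(X)
            r = {"ChlA": 1.0}
            for p in TLI_INDICATORS:
                if p == "ChlA":
                    continue
                pair = table[["ChlA", p]].dropna()
                if len(pair) < 3:
                    raise DegenerateInputError(
                        f"{p}: need >= 3 complete pairs with Chl-a to reweight")
                r[p] = float(pair["ChlA"].corr(pair[p]))
            self.r_ = r
        else:
            self.r_ = dict(self.r) if self.r is not None else dict(NATIONAL_R)
        self.weights_ = compute_weights(self.r_)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "weights_"):
            self.fit(X)
        table = self._indicator_table(X)
        sub = pd.DataFrame(index=table.index)
        for p in TLI_INDICATORS:
            if p not in self.weights_.w:
                continue
            a, b = TLI_COEFFICIENTS[p]
            x = table[p].to_numpy(dtype=float)
            bad = x[~np.isnan(x)] <= 0
            if bad.any():
                raise DomainError(
                    f"{p}: {int(bad.sum())} non-positive value(s) outside the "
                    "log domain")
            with np.errstate(invalid="ignore"):
                sub[f"TLI_{p}"] = 10.0 * (a + b * np.log(x))
        present = sub.notna()
        m = present.sum(axis=1)
        if (m == 0).any():
            bad_rows = list(table.index[m == 0])
            raise DegenerateInputError(f"records {bad_rows}: no TLI indicator present")
        w = np.array([self.weights_.w[p] for p in TLI_INDICATORS
                      if p in self.weights_.w])
        vals = sub.to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        wsum = (np.where(mask, w, 0.0)).sum(axis=1)
        comp = np.nansum(vals * w, axis=1) / wsum
        result = sub.copy()
        result["m"] = m
        result["TLI"] = comp
        result["trophic_state"] = [classify_tli(t) for t in comp]
        return result


def composite_tli(record, weights: TliWeights | None = None,
                  chla_unit: str = "mg/L") -> TliBreakdown:
    """Compute the TLI breakdown of a single monitoring record."""
    calc = TLICalculator(r=weights.r if weights is not None else None,
                         chla_unit=chla_unit).fit()
    res = calc.transform(pd.DataFrame([dict(record)])).iloc[0]
    subs = {p: res[f"TLI_{p}"] for p in TLI_INDICATORS
            if f"TLI_{p}" in res and not pd.isna(res[f"TLI_{p}"])}
    return TliBreakdown(sub_indices=subs, m=int(res["m"]),
                        tli=float(res["TLI"]), trophic_state=res["trophic_state"])
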