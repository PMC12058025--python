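"""Composite water quality index (WQI).

The WQI averages per-parameter pollution sub-indices and scales by 100:

    WQI = 100 * (1/m) * sum_i WQI_i

where each WQI_i is one of

* the single-factor ratio ``c_i / c_s`` (cost direction) or ``c_s / c_i``
  (benefit direction, e.g. Secchi depth),
* the piecewise dissolved-oxygen index built on the saturated DO
  concentration ``DO_f = 468 / (31.6 + T)``::

      WQI_DO = |DO_f - DO| / (DO_f - DO_s)   if DO >= DO_s
      WQI_DO = 10 - 9 * DO / DO_s            if DO <  DO_s

* the two-sided pH index measuring distance from neutrality relative to
  the regulatory band (pH_sd, pH_su)::

      WQI_pH = (7 - pH) / (7 - pH_sd)        if pH <= 7
      WQI_pH = (pH - 7) / (pH_su - 7)        if pH >  7

A sub-index of 1 means "exactly at the standard"; higher means more
polluted.  The composite is graded Excellent (< 60) through Very Poor
(>= 200).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, DomainError
from .schema import PARAMETER_COLUMNS, SurveyDataset
from .standards import ParameterStandard, StandardsConfig, default_standards

#: Grade bounds: [lower, upper) except the open-ended last class.
WQI_GRADES = [
    (0.0, 60.0, "Excellent"),
    (60.0, 80.0, "Good"),
    (80.0, 100.0, "Moderate"),
    (100.0, 200.0, "Poor"),
    (200.0, math.inf, "Very Poor"),
]


def do_saturation(temperature: float) -> float:
    """Saturated dissolved-oxygen concentration (mg/L) at water
    temperature ``temperature`` (deg C): ``468 / (31.6 + T)``."""
    if not -2.0 < temperature < 45.0:
        raise DomainError(f"temperature {temperature} degC outside (-2, 45)")
    return 468.0 / (31.6 + temperature)


def do_index(do: float, temperature: float, do_standard: float = 5.0) -> float:
    """Dissolved-oxygen pollution sub-index.

    At or above the standard the index measures distance from saturation
    relative to the saturation-to-standard gap; below the standard it
    rises linearly from 1 (at the standard) to 10 (anoxic).
    """
    if do < 0:
        raise DomainError(f"DO = {do} must be >= 0")
    if do_standard <= 0:
        raise DomainError(f"DO standard {do_standard} must be > 0")
    if do >= do_standard:
        do_f = do_saturation(temperature)
        if do_f <= do_standard:
            raise DegenerateInputError(
                f"saturated DO {do_f:.3f} <= standard {do_standard}: "
                "sub-index denominator non-positive")
        return abs(do_f - do) / (do_f - do_standard)
    return 10.0 - 9.0 * do / do_standard


def ph_index(ph: float, ph_lower: float = 6.0, ph_upper: float = 9.0) -> float:
    """pH pollution sub-index: scaled distance from neutrality."""
    if not ph_lower < 7.0 < ph_upper:
        raise DomainError(f"pH bounds ({ph_lower}, {ph_upper}) must bracket 7")
    if ph <= 7.0:
        return (7.0 - ph) / (7.0 - ph_lower)
    return (ph - 7.0) / (ph_upper - 7.0)


def single_factor_index(value: float, standard: ParameterStandard) -> float:
    """Single-factor pollutant index ``c_i/c_s`` (cost) or ``c_s/c_i``
    (benefit)."""
    if value < 0:
        raise DomainError(f"{standard.parameter}: value {value} must be >= 0")
    if standard.family != "simple":
        raise DomainError(
            f"{standard.parameter}: single_factor_index needs family 'simple'")
    if standard.direction == "cost":
        return value / standard.standard_value
    if value == 0:
        raise DegenerateInputError(
            f"{standard.parameter}: benefit-direction index undefined at 0")
    return standard.standard_value / value


def parameter_subindex(parameter: str, value: float,
                       standard: ParameterStandard,
                       temperature: float | None = None) -> float:
    """Dispatch to the right sub-index family for one measurement."""
    if standard.family == "pH":
        return ph_index(value, standard.ph_lower, standard.ph_upper)
    if standard.family == "DO":
        if temperature is None:
            raise DomainError("DO sub-index needs the water temperature")
        return do_index(value, temperature, standard.standard_value)
    return single_factor_index(value, standard)


def classify_wqi(wqi: float) -> str:
    """Quality grade for a composite WQI value."""
    if not np.isfinite(wqi) or wqi < 0:
        raise DomainError(f"WQI {wqi} must be finite and >= 0")
    for lo, hi, grade in WQI_GRADES:
        if lo <= wqi < hi:
            return grade
    raise AssertionError("unreachable")  # grades cover [0, inf)


@dataclass
class WqiBreakdown:
    """Composite WQI for one record with its per-parameter sub-indices."""

    per_parameter: dict[str, float]
    m_effective: int
    wqi: float
    grade: str
    do_f: float | None = None


class WQICalculator(BaseEstimator, TransformerMixin):
    """Compute per-record WQI breakdowns for a survey table.

    A stateless scikit-learn transformer: ``fit`` resolves and validates
    the standards configuration, ``transform`` maps a survey frame (or
    :class:`SurveyDataset`) to a result frame with one sub-index column
    per parameter plus ``WQI``, ``grade`` and ``m`` (the number of
    parameters actually present per record).

    Parameters
    ----------
    standards : StandardsConfig, optional
        Evaluation standards; defaults to the packaged ten-parameter
        Class III configuration.
    parameters : sequence of str, optional
        Restrict the evaluated set (``m`` in the composite formula).
    """

    def __init__(self, standards: StandardsConfig | None = None,
                 parameters=None):
        self.standards = standards
        self.parameters = parameters

    def fit(self, X=None, y=None):
        config = self.standards if self.standards is not None else default_standards()
        if self.parameters is not None:
            config = config.restrict(self.parameters)
        self.standards_ = config
        self.parameters_ = list(config.evaluated)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "standards_"):
            self.fit()
        frame = X.frame if isinstance(X, SurveyDataset) else pd.DataFrame(X)
        n = len(frame)
        temp = pd.to_numeric(frame.get("temp_C", pd.Series(np.nan, index=frame.index)),
                             errors="coerce")
        sub = pd.DataFrame(index=frame.index)
        for param in self.parameters_:
            std = self.standards_[param]
            col = PARAMETER_COLUMNS.get(param, param)
            if col in frame.columns:
                values = pd.to_numeric(frame[col], errors="coerce")
            else:
                values = pd.Series(np.nan, index=frame.index)
            out = np.full(n, np.nan)
            for i, (v, t) in enumerate(zip(values.to_numpy(dtype=float),
                                           temp.to_numpy(dtype=float))):
                if np.isnan(v):
                    continue
                out[i] = parameter_subindex(
                    param, v, std, temperature=None if np.isnan(t) else t)
            sub[f"WQI_{param}"] = out
        m_eff = sub.notna().sum(axis=1)
        if (m_eff == 0).any():
            bad = list(frame.index[m_eff == 0])
            raise DegenerateInputError(
                f"records {bad}: no evaluated parameter present")
        result = sub.copy()
        result["m"] = m_eff
        result["WQI"] = 100.0 * sub.mean(axis=1, skipna=True)
        result["grade"] = [classify_wqi(w) for w in result["WQI"]]
        return result


def composite_wqi(record, standards: StandardsConfig | None = None,
                  parameters=None) -> WqiBreakdown:
    """Compute the WQI breakdown of a single monitoring record
    (mapping or Series of survey columns)."""
    row = pd.DataFrame([dict(record)])
    calc = WQICalculator(standards=standards, parameters=parameters).fit()
    res = calc.transform(row).iloc[0]
    per = {p: res[f"WQI_{p}"] for p in calc.parameters_
           if not pd.isna(res[f"WQI_{p}"])}
    t = dict(record).get("temp_C")
    do_f = do_saturation(t) if t is not None and not pd.isna(t) else None
    return WqiBreakdown(per_parameter=per, m_effective=int(res["m"]),
                        wqi=float(res["WQI"]), grade=res["grade"], do_f=do_f)
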