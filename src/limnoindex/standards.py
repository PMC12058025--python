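"""Evaluation standards: per-parameter reference values for the WQI.

Each evaluated parameter carries a standard value (the ``c_s`` of the
single-factor pollutant index), a direction (cost: lower is better;
benefit: higher is better) and a sub-index family:

``simple``
    plain ratio of measurement to standard,
``DO``
    the piecewise dissolved-oxygen index built on the temperature-dependent
    saturation concentration,
``pH``
    the two-sided index measuring distance from neutrality relative to the
    regulatory band.

The packaged default configuration holds the ten parameters of the
default evaluated set: the six with Class III limits under China's surface
water quality standard (GB 3838-2002) — pH 6–9, DO 5 mg/L, COD_Mn 6 mg/L,
NH3-N 1.0 mg/L, TP 0.05 mg/L, TN 1.0 mg/L — plus turbidity 5 NTU, TOC
5 mg/L, Secchi depth 2.5 m and chlorophyll-a 0.04 mg/L from companion
standards.  All values are editable via a TOML file.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import StandardsConfigError

FAMILIES = ("simple", "DO", "pH")
DIRECTIONS = ("cost", "benefit")


@dataclass(frozen=True)
class ParameterStandard:
    """Evaluation standard for one parameter."""

    parameter: str
    family: str = "simple"
    direction: str = "cost"
    standard_value: float | None = None
    ph_lower: float | None = None
    ph_upper: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise StandardsConfigError(
                f"{self.parameter}: unknown family {self.family!r}")
        if self.direction not in DIRECTIONS:
            raise StandardsConfigError(
                f"{self.parameter}: unknown direction {self.direction!r}")
        if self.family == "pH":
            if self.ph_lower is None or self.ph_upper is None:
                raise StandardsConfigError(
                    f"{self.parameter}: pH family needs both lower and upper bounds")
            if not self.ph_lower < 7 < self.ph_upper:
                raise StandardsConfigError(
                    f"{self.parameter}: pH bounds must bracket 7, got "
                    f"({self.ph_lower}, {self.ph_upper})")
        else:
            if self.standard_value is None or self.standard_value <= 0:
                raise StandardsConfigError(
                    f"{self.parameter}: {self.family} family needs a positive "
                    f"standard value, got {self.standard_value}")


@dataclass
class StandardsConfig:
    """The full evaluated-parameter set and its standards.

    ``evaluated`` fixes the order of the parameters entering the composite
    index; its length is the nominal ``m``.
    """

    standards: dict[str, ParameterStandard]
    evaluated: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.evaluated:
            self.evaluated = list(self.standards)
        if len(set(self.evaluated)) != len(self.evaluated):
            raise StandardsConfigError("duplicate parameter in evaluated list")
        missing = [p for p in self.evaluated if p not in self.standards]
        if missing:
            raise StandardsConfigError(f"no standard for evaluated parameters {missing}")
        if len(self.evaluated) < 1:
            raise StandardsConfigError("at least one evaluated parameter required")

    @property
    def m(self) -> int:
        return len(self.evaluated)

    def __getitem__(self, parameter: str) -> ParameterStandard:
        return self.standards[parameter]

    def restrict(self, parameters) -> "StandardsConfig":
        """A copy evaluating only ``parameters`` (order preserved)."""
        params = list(parameters)
        return StandardsConfig(
            standards={p: self.standards[p] for p in params}, evaluated=params)


def _parse_toml(text: str) -> StandardsConfig:
    try:
        doc = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:  # duplicate tables land here too
        raise StandardsConfigError(f"cannot parse standards config: {exc}") from exc
    evaluated = doc.pop("evaluated", None)
    standards = {}
    for name, entry in doc.items():
        if not isinstance(entry, dict):
            raise StandardsConfigError(f"top-level key {name!r} is not a parameter block")
        standards[name] = ParameterStandard(
            parameter=name,
            family=entry.get("family", "simple"),
            direction=entry.get("direction", "cost"),
            standard_value=entry.get("standard"),
            ph_lower=entry.get("lower"),
            ph_upper=entry.get("upper"),
        )
    return StandardsConfig(standards=standards, evaluated=evaluated or [])


def read_standards(path: str | Path | None = None) -> StandardsConfig:
    """Read a standards configuration, or the packaged default if ``path``
    is None."""
    if path is None:
        text = resources.files("limnoindex.data").joinpath(
            "standards_class3.toml").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return _parse_toml(text)


def default_standards() -> StandardsConfig:
    """The packaged ten-parameter default configuration."""
    return read_standards(None)
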