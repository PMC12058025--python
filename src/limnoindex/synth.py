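"""Synthetic lake-survey generator.

Emulates a plateau reservoir monitoring design: 7 sites (one heavily
polluted urban inflow, one clean forested inflow, intermediates and a
lake-center/southern pair) sampled in three campaigns (dry April, wet
July, normal October) at three vertical layers.  Concentrations follow
lognormal bases (positive, right-skewed); pH and DO follow truncated
normals.  Two physical couplings are built in: Secchi depth decreases
with turbidity, and chlorophyll-a increases with TP and TN.  Default
locations are calibrated to realistic seasonal medians for a
mesotrophic-to-oligotrophic karst reservoir (e.g. April turbidity median
7.5 NTU falling to 3 NTU in October, TN 3.2 -> 2.0 mg/L, NH3-N
1.3 -> 0.05 mg/L, water temperature 20.1 / 26.7 / 17.0 degC).

Output uses the standard monitoring CSV schema, so generated surveys are
indistinguishable from observed ones to the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import StandardsConfigError
from .schema import LAYERS, SurveyDataset

#: Per-site pollution multipliers, worst (urban inflow JZ) to best
#: (forested inflow YY).
DEFAULT_SITES = {
    "JZ": 2.2, "SS": 1.5, "BY": 1.15, "LC": 1.1, "LN": 1.0, "CC": 0.85,
    "YY": 0.6,
}

#: Layer depths (m) per site: (upper, middle, lower).
DEFAULT_DEPTHS = {
    "BY": (0.5, 3.0, 4.5), "JZ": (0.5, 5.0, 8.0), "SS": (0.5, 5.0, 10.0),
    "LC": (0.5, 5.0, 8.0), "YY": (0.5, 5.0, 8.0), "CC": (0.5, 3.0, 4.5),
    "LN": (0.5, 2.0, 4.0),
}

#: Campaign months: season -> calendar month.
DEFAULT_MONTHS = {"dry": 4, "wet": 7, "normal": 10}

#: Seasonal medians for the lognormal/normal bases.
DEFAULT_SEASON_MEDIANS = {
    "temp_C": {"dry": 20.1, "wet": 26.7, "normal": 17.0},
    "TN_mgL": {"dry": 3.2, "wet": 3.0, "normal": 2.0},
    "TP_mgL": {"dry": 0.05, "wet": 0.035, "normal": 0.05},
    "NH3N_mgL": {"dry": 1.3, "wet": 0.2, "normal": 0.05},
    "CODMn_mgL": {"dry": 2.0, "wet": 1.75, "normal": 1.5},
    "TOC_mgL": {"dry": 3.8, "wet": 3.7, "normal": 3.6},
    "turbidity_NTU": {"dry": 7.5, "wet": 5.0, "normal": 3.0},
    "DO_mgL": {"dry": 14.0, "wet": 9.0, "normal": 8.0},
    "ChlA_mgL": {"dry": 0.05, "wet": 0.04, "normal": 0.008},
}

#: Sensitivity of each pollution-driven parameter to the site multiplier
#: (exponent on the multiplier).
DEFAULT_SITE_ELASTICITY = {
    "TN_mgL": 0.5, "TP_mgL": 1.0, "NH3N_mgL": 1.0, "CODMn_mgL": 0.4,
    "TOC_mgL": 0.2, "turbidity_NTU": 0.3,
}


@dataclass
class GeneratorConfig:
    """Everything the survey generator needs; defaults emulate the
    7-site x 3-season x 3-layer design with a JZ-worst / YY-best
    pollution gradient and no vertical stratification."""

    sites: dict = field(default_factory=lambda: dict(DEFAULT_SITES))
    depths: dict = field(default_factory=lambda: dict(DEFAULT_DEPTHS))
    months: dict = field(default_factory=lambda: dict(DEFAULT_MONTHS))
    season_medians: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SEASON_MEDIANS.items()})
    site_elasticity: dict = field(
        default_factory=lambda: dict(DEFAULT_SITE_ELASTICITY))
    #: multiplicative per-layer effect on pollution-driven parameters
    layer_effects: dict = field(
        default_factory=lambda: {"upper": 1.0, "middle": 1.0, "lower": 1.0})
    #: lognormal sigma (log scale) for concentrations
    sigma: float = 0.18
    #: normal SDs for pH / DO / temperature
    ph_mean: float = 8.0
    ph_sd: float = 0.2
    do_sd: float = 1.2
    temp_sd: float = 0.8
    #: Secchi ~ sdd_scale / turbidity**sdd_exponent
    sdd_scale: float = 6.1
    sdd_exponent: float = 0.9
    #: Chl-a ~ median * (TP/tp_ref)**chla_tp_exp * (TN/tn_ref)**chla_tn_exp
    chla_tp_exp: float = 0.6
    chla_tn_exp: float = 0.3
    tp_ref: float = 0.05
    tn_ref: float = 3.0
    #: global scaling of all noise terms
    noise_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if any(m <= 0 for m in self.sites.values()):
            raise StandardsConfigError("site multipliers must be > 0")
        if self.sigma <= 0 or self.noise_scale < 0:
            raise StandardsConfigError("scales must be positive")

    @property
    def is_null(self) -> bool:
        """True when site, season and layer effects are all absent, so
        records are exchangeable across factor levels."""
        flat_sites = all(m == 1.0 for m in self.sites.values())
        flat_layers = all(v == 1.0 for v in self.layer_effects.values())
        flat_seasons = all(len(set(v.values())) == 1
                           for v in self.season_medians.values())
        return flat_sites and flat_layers and flat_seasons

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """A configuration with all factor effects removed: every season
        uses the pooled median and every site multiplier is 1."""
        pooled = {param: {s: float(np.median(list(v.values())))
                          for s in DEFAULT_MONTHS}
                  for param, v in DEFAULT_SEASON_MEDIANS.items()}
        cfg = cls(sites={s: 1.0 for s in DEFAULT_SITES},
                  season_medians=pooled, **overrides)
        return cfg

    def with_seasonal_shift(self, factors: dict[str, dict[str, float]]) -> "GeneratorConfig":
        """A copy with seasonal medians multiplied by ``factors``
        (parameter -> season -> multiplier); used to inject or amplify
        seasonal effects."""
        med = {p: dict(v) for p, v in self.season_medians.items()}
        for param, per_season in factors.items():
            for season, f in per_season.items():
                med[param][season] *= f
        return replace(self, season_medians=med)


def generate_survey(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> SurveyDataset:
    """Generate one synthetic survey (one record per site/season/layer).

    Deterministic given the seed (argument overrides ``config.seed``;
    default 0).
    """
    cfg = config if config is not None else GeneratorConfig()
    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0
    rng = np.random.default_rng(seed)
    sig = cfg.sigma * cfg.noise_scale

    def lognoise(n=1):
        return np.exp(rng.normal(0.0, sig, size=n))

    rows = []
    for site, mult in cfg.sites.items():
        for season, month in cfg.months.items():
            for layer, depth in zip(LAYERS, cfg.depths.get(site, (0.5, 3.0, 4.5))):
                lay_eff = cfg.layer_effects[layer]
                med = {p: cfg.season_medians[p][season]
                       for p in cfg.season_medians}
                conc = {}
                for p, elast in cfg.site_elasticity.items():
                    conc[p] = med[p] * mult ** elast * lay_eff * lognoise()[0]
                turb = conc["turbidity_NTU"]
                sdd = cfg.sdd_scale / turb ** cfg.sdd_exponent * lognoise()[0]
                chla = (med["ChlA_mgL"]
                        * (conc["TP_mgL"] / cfg.tp_ref) ** cfg.chla_tp_exp
                        * (conc["TN_mgL"] / cfg.tn_ref) ** cfg.chla_tn_exp
                        * lognoise()[0])
                temp = rng.normal(med["temp_C"], cfg.temp_sd * cfg.noise_scale)
                temp = float(np.clip(temp, 0.5, 38.0))
                do = rng.normal(med["DO_mgL"], cfg.do_sd * cfg.noise_scale)
                do = float(np.clip(do, 0.5, None))
                ph = rng.normal(cfg.ph_mean, cfg.ph_sd * cfg.noise_scale)
                ph = float(np.clip(ph, 6.2, 9.4))
                rows.append({
                    "site_id": site, "season": season, "month": month,
                    "layer": layer, "depth_m": depth,
                    "temp_C": round(temp, 2), "pH": round(ph, 2),
                    "DO_mgL": round(do, 2),
                    "turbidity_NTU": round(turb, 2),
                    "SDD_m": round(sdd, 2),
                    "TN_mgL": round(conc["TN_mgL"], 3),
                    "TP_mgL": round(conc["TP_mgL"], 4),
                    "NH3N_mgL": round(conc["NH3N_mgL"], 3),
                    "CODMn_mgL": round(conc["CODMn_mgL"], 3),
                    "TOC_mgL": round(conc["TOC_mgL"], 2),
                    "ChlA_mgL": round(chla, 4),
                })
    return SurveyDataset(pd.DataFrame(rows), provenance="synthetic")


def generate_null_survey(config: GeneratorConfig | None = None,
                         n_datasets: int = 1, seed: int = 0):
    """Yield ``n_datasets`` surveys with no site/season/layer effects.

    Used for type-I-error and permutation-null studies; refuses a config
    that still carries factor effects (null mode must be pure).
    """
    cfg = config if config is not None else GeneratorConfig.null()
    if not cfg.is_null:
        raise StandardsConfigError(
            "generate_null_survey needs a pure null config "
            "(use GeneratorConfig.null())")
    root = np.random.default_rng(seed)
    for _ in range(n_datasets):
        child = int(root.integers(0, 2**31 - 1))
        yield generate_survey(cfg, seed=child)
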