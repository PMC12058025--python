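# limnoindex

Composite water-quality and trophic-state assessment for lake and
reservoir monitoring programmes, with the seasonal/spatial statistics
that typically accompany them.

The package is aimed at limnologists and environmental analysts who run
multi-site, multi-season, multi-depth surveys (the built-in scenario is
a seven-site karst plateau reservoir sampled in April, July and October
at three vertical layers) and want a reproducible path from a raw
monitoring CSV to classified indices, ANOVA tables, correlation matrices
and Mantel screens.

## The two indices

**Water Quality Index (WQI).** Each evaluated parameter *i* gets a
pollution sub-index relative to its regulatory standard *c<sub>s</sub>*:

- simple factors: WQI<sub>i</sub> = c<sub>i</sub>/c<sub>s</sub> (cost
  direction) or c<sub>s</sub>/c<sub>i</sub> (benefit direction, e.g.
  Secchi depth);
- dissolved oxygen, via the saturation concentration
  DO<sub>f</sub> = 468/(31.6 + T):
  WQI<sub>DO</sub> = |DO<sub>f</sub> − DO| / (DO<sub>f</sub> − DO<sub>s</sub>)
  when DO ≥ DO<sub>s</sub>, and 10 − 9·DO/DO<sub>s</sub> below the standard;
- pH: distance from neutrality scaled by the regulatory band,
  (7 − pH)/(7 − pH<sub>sd</sub>) or (pH − 7)/(pH<sub>su</sub> − 7).

The composite is WQI = 100 · (1/m) Σ WQI<sub>i</sub>, graded Excellent
(< 60), Good [60, 80), Moderate [80, 100), Poor [100, 200), Very Poor
(≥ 200). The packaged default standard set has m = 10 (Class III limits
of GB 3838-2002 for pH, DO, COD_Mn, NH₃-N, TP, TN plus companion
standards for turbidity, TOC, SDD and Chl-a), editable via TOML.

**Trophic Level Index (TLI).** Five log-linear sub-indices —
TLI(Chl-a) = 10(2.5 + 1.0861 ln Chl-a), TLI(TP) = 10(9.436 + 1.624 ln TP),
TLI(TN) = 10(5.453 + 1.694 ln TN), TLI(SDD) = 10(5.118 − 1.94 ln SDD),
TLI(COD_Mn) = 10(0.109 + 2.661 ln COD_Mn) — combined as
TLI(Σ) = Σ W<sub>j</sub>·TLI(j) with weights
W<sub>j</sub> = r<sub>j</sub>²/Σr² from each indicator's correlation
with the reference Chl-a (national multi-lake calibration by default, or
re-estimated from your data). States: Oligotrophic (< 30), Mesotrophic
[30, 50], Slightly (50, 60], Moderately (60, 70], Severely Eutrophic
(> 70).

The statistics layer provides the one-way ANOVA decomposition in the
conventional SS/df/MS/F/P/F-crit layout for the season, layer and site
factors, Kolmogorov–Smirnov normality screening, pairwise-complete
Pearson matrices, and a seeded permutation Mantel test relating each
parameter's distance matrix to the WQI and TLI matrices.

## Worked example

```python
from limnoindex import generate_survey, assess

survey = generate_survey(seed=1)          # 7 sites x 3 seasons x 3 layers
report = assess(survey, n_permutations=199, seed=1)

print(report.tli_by_site_season.round(2))
print(report.anova["tli_season"].to_frame().to_string(index=False))
```

```
site_id     BY     CC     JZ     LC     LN     SS     YY
season
dry      55.39  50.17  60.40  55.13  53.21  56.21  48.98
wet      48.64  44.57  55.50  49.02  49.20  52.31  44.63
normal   42.24  38.21  49.22  42.87  43.15  46.68  34.92

Source of Variation         SS  df         MS         F  P-value   F crit
     Between Groups 485.425253   2 242.712626 13.644599 0.000247 3.554557
      Within Groups 320.187299  18  17.788183       NaN      NaN      NaN
              Total 805.612552  20        NaN       NaN      NaN      NaN
```

The generated reservoir has a polluted urban inflow (JZ) and a clean
forested inflow (YY): JZ carries the highest TLI in every season, and
the seasonal ANOVA (7 site means per season, df 2/18) rejects at
F = 13.64, p ≈ 2.5 × 10⁻⁴ — the dry campaign is the most eutrophic under
the default seasonal effects. The Mantel screen on the same run ranks
chlorophyll-a first against the TLI matrix (r = 0.71, p = 0.005 at 199
permutations), with Secchi depth and turbidity close behind — the
nutrient–algae–transparency couplings the generator builds in.

The same pipeline runs from the shell:

```sh
limnoindex simulate --out survey.csv --seed 1
limnoindex assess --input survey.csv --out report/ --permutations 999
limnoindex anova --input survey.csv --index tli --factor season
```

`report/` then contains per-record breakdowns (`records.csv`), the
site × season and site × layer index tables, the six ANOVA tables, the
Pearson matrices, the Mantel screen and a `metadata.json` sufficient to
re-run bit-identically.

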