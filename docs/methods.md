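# Methods

## Indices

### WQI

The composite water quality index is the equally-weighted mean of
per-parameter pollution sub-indices, scaled by 100. A sub-index of 1
means "exactly at the standard"; the composite therefore reads 100 when
every parameter sits at its limit, and grades follow fixed cut points
(Excellent < 60 ≤ Good < 80 ≤ Moderate < 100 ≤ Poor < 200 ≤ Very Poor).
Boundaries belong to the upper class (60 is Good, 100 is Poor), matching
the half-open intervals of the grading scheme.

Three sub-index families:

* **Simple ratio.** `c_i/c_s` for cost-direction parameters. For
  benefit-direction parameters (higher is better; only Secchi depth in
  the default set) the ratio is inverted to `c_s/c_i`, so that halving
  transparency doubles the sub-index. The direction is an explicit
  per-parameter flag in the standards config rather than a hard-coded
  special case, because a plain ratio would reward turbid water for
  losing transparency. A benefit parameter measured at exactly 0 has no
  defined sub-index and raises a degenerate-input error.
* **Dissolved oxygen.** Uses the saturation concentration
  `DO_f = 468/(31.6 + T)` (T in °C, valid on −2 < T < 45; strictly
  decreasing). At or above the standard the sub-index is
  `|DO_f − DO|/(DO_f − DO_s)`; below it, `10 − 9·DO/DO_s`. Both branches
  give exactly 1 at `DO = DO_s`, so the branch assignment at the
  boundary is observationally neutral; the implementation uses the
  `DO ≥ DO_s` branch. Supersaturated water (`DO > DO_f`) takes the
  absolute value as written, yielding a small penalty growing with
  distance from equilibrium. In very warm water the saturation value can
  drop to the standard; the non-positive denominator is reported as a
  degenerate-standard error rather than silently clamped.
* **pH.** Distance from neutrality scaled by the regulatory band; both
  branches vanish at pH 7 (continuous join) and equal 1 at the band
  edges.

Sub-indices are not capped: extreme exceedances propagate linearly into
the mean, which is what makes the Very Poor grade (≥ 200) reachable.

**Standards.** The packaged default evaluates m = 10 parameters: the six
with Class III limits in China's surface-water standard (pH 6–9, DO
5 mg/L, COD_Mn 6 mg/L, NH₃-N 1.0 mg/L, TP 0.05 mg/L, TN 1.0 mg/L) plus
turbidity 5 NTU, TOC 5 mg/L, SDD 2.5 m and Chl-a 0.04 mg/L from
companion scenic/drinking-water and key-lake standards. The full-set
default was chosen because the composite magnitudes it produces are the
ones the grading scheme is calibrated to; any subset (e.g. the six
Class III parameters alone) is one `restrict()` call or TOML edit away.

**Missing values.** A record's composite is the mean over the parameters
actually present, and the effective m is reported alongside. No
imputation is attempted; a record with no evaluated parameter at all is
an error, not a silent NaN.

### TLI

Five log-linear sub-indices (chlorophyll-a, TP, TN, Secchi depth,
permanganate index) are combined with weights proportional to each
indicator's squared correlation with the reference chlorophyll-a.
Defaults use the national multi-lake calibration
r = (1, 0.84, 0.82, −0.83, 0.83), giving weights
(0.2663, 0.1879, 0.1790, 0.1834, 0.1834); `reweight_from_data=True`
re-estimates r on the fitted survey instead (Chl-a keeps r = 1), which
is the one genuinely stateful "fit" in the package. Weights over a
missing-indicator subset are renormalized so the composite remains a
convex combination — hence always bracketed by the smallest and largest
available sub-index — and m reports the count actually used.

**Units.** TP, TN and COD_Mn enter in mg/L and SDD in m, the standard
parameterization. The Chl-a formula is conventionally parameterized in
mg/m³ while monitoring tables (including this package's CSV schema)
usually record mg/L; the calculator takes a `chla_unit` flag declaring
the input unit and converts mg/L inputs ×1000. Published assessments are
not always explicit about this conversion, so both readings are
reproducible by flipping the flag; the default is the declared-unit
(mg/L, converted) reading.

**Classification** follows the inclusive-bound scheme as printed:
Oligotrophic < 30, Mesotrophic [30, 50], Slightly Eutrophic (50, 60],
Moderately Eutrophic (60, 70], Severely Eutrophic > 70. Both
classifiers are verified against brute-force interval lookups on dense
grids.

## Statistics

**ANOVA.** Classical one-way fixed-effects decomposition; p from the
upper tail of F(df_between, df_within) and the critical value at the
supplied α (default 0.05). The factor layouts mirror the monitoring
design: season and layer factors treat the 7 per-site means as
replicates (df 2/18), the site factor treats the 3 per-layer means as
replicates (df 6/14). Unbalanced groups are accepted; groups with fewer
than two observations, or zero pooled within-group variance, are
degenerate errors. The implementation is cross-checked in the tests
against an explicit brute-force oracle and `scipy.stats.f_oneway` to
1e−9 relative.

**Normality screening.** One-sample K-S against a normal with moments
estimated from the data (sample SD, ddof = 1), asymptotic two-tailed p —
the common statistics-package convention. Because estimating the moments
from the same sample makes the plain K-S conservative, a
Lilliefors-corrected variant (statsmodels) is available behind a flag.
Fewer than 5 observations or a constant sample is an error.

**Pearson matrices** are pairwise-complete; pairs with fewer than 3
complete observations or zero variance are reported as NaN — flagged,
never silently zeroed.

**Mantel test.** Pearson correlation of the unfolded upper triangles;
the null permutes the objects of the second matrix. The p-value uses the
add-one rule `(1 + #{r* ≥ r})/(1 + N)` so it is never exactly zero and
lives on a grid of resolution 1/(N+1). Defaults: 999 permutations,
one-sided greater, seed 0 — all exposed. Determinism given the seed is
part of the contract; the same seed is reused for every parameter in the
per-parameter screen so duplicated columns give identical rows. The
screen builds Euclidean distances on z-scored single-parameter vectors
(for a single variable this is |xᵢ − xⱼ| up to scale, and Mantel r is
scale-invariant) and flags r ≥ 0.4 as "strong". Distance metric, the
permutation count and the threshold are configuration, since reasonable
programmes differ on all three.

## Synthetic surveys

The generator emulates a 7-site × 3-season × 3-layer reservoir survey:

* **Distributions.** Concentrations are lognormal (positive,
  right-skewed, σ = 0.18 on the log scale by default); pH, DO and
  temperature are truncated normals. Reported values are rounded to
  realistic field precision (2–4 decimals).
* **Seasonal medians** (dry April / wet July / normal October): water
  temperature 20.1 / 26.7 / 17.0 °C; TN 3.2 / 3.0 / 2.0 mg/L; TP
  0.05 / 0.035 / 0.05 mg/L; NH₃-N 1.3 / 0.2 / 0.05 mg/L; COD_Mn
  2.0 / 1.75 / 1.5 mg/L; TOC 3.8 / 3.7 / 3.6 mg/L; turbidity
  7.5 / 5.0 / 3.0 NTU; DO 14 / 9 / 8 mg/L; Chl-a 0.05 / 0.04 / 0.008
  mg/L — typical of a mesotrophic-to-oligotrophic karst reservoir with a
  turbid, nutrient-rich dry season.
* **Spatial gradient.** Per-site multipliers (JZ 2.2 worst → YY 0.6
  best) act on the pollution-driven parameters with per-parameter
  elasticities (TP and NH₃-N fully, TN, COD_Mn, TOC and turbidity more
  weakly), reproducing the urban-inflow-worst / forested-inflow-best
  ordering such programmes report.
* **Couplings.** Secchi depth is a decreasing power law of turbidity
  (scale 6.1, exponent 0.9: 7.5 NTU → ≈1 m), and Chl-a follows a
  Cobb-Douglas link in TP and TN (exponents 0.6 and 0.3) — so
  transparency–turbidity and nutrient–algae correlations hold in sample
  without being wired into the indices.
* **Vertical layers** carry depth bookkeeping from a realistic site
  roster but no systematic concentration effect by default, matching the
  common field finding that vertical variation is minor; layer effects
  are configurable.
* **Null mode.** `GeneratorConfig.null()` pools the seasonal medians and
  flattens all site/layer effects, making records exchangeable across
  factor levels; `generate_null_survey` refuses configs that still carry
  effects. Because every TLI-relevant quantity is built from logs of
  lognormals, the index is (near-)normal and the seasonal F-test on null
  surveys holds its nominal size.

What the generator does *not* emulate: hydrodynamics, nutrient cycling,
rainfall-runoff loading, measurement-instrument error structure, serial
correlation between campaigns, or the exact covariance of any real lake.
Passing tests on synthetic surveys therefore demonstrate that the
pipeline recovers effects of the stated size and holds its error rates
under the stated distributional shapes — not that any particular field
data set satisfies those shapes.

## Validation studies and problem sizes

The acceptance layer runs, at default sizes chosen to keep the whole
study under a minute:

* six factor ANOVA tables recomputed from the bundled reference index
  tables (site-mean TLI/WQI by season and by layer from a published
  seven-site survey) and compared at 4 significant figures, plus the
  four seasonal means at 2 decimals and the per-site classification
  statements;
* ANOVA vs a brute-force oracle on 100 random small instances (2–5
  groups of 2–8 observations), 1e−9 relative;
* seasonal ANOVA power on 200 effect surveys (the default seasonal
  shifts have log-scale standardized mean differences well above 1.5 on
  the index-driving parameters) — expected ≥ 90% rejection;
* type-I error on 1000 null surveys — expected 5% ± 2%;
* Mantel p-value uniformity under the null: 500 independent pairs of
  random 20-point Euclidean distance matrices at 99 permutations,
  10-bin chi-square goodness-of-fit at α = 0.01.

The raw per-record concentrations behind the bundled reference tables
are not distributed with the package, so those tables are fixtures for
the statistics stage: the index engines are validated by their exact
algebraic identities and property tests rather than by regenerating the
reference tables from concentrations.

## Known limitations

* Only the equal-weights mean-type WQI and the Chl-a-referenced TLI are
  implemented — no NSF/CCME-style or weighted-geometric variants, and no
  Carlson TSI.
* No post-hoc multiple-comparison procedures after ANOVA, and no two-way
  or repeated-measures designs.
* The Mantel screen's per-parameter distances assume interval-scaled
  measurements; ordinal or censored data (values below detection limits)
  are not modelled.
* Report output is tabular (CSV/JSON); radar-chart or map graphics are
  out of scope.
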