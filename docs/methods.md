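# Methods

This note documents the models, numerical choices and limitations of
`divclim`, in the order the pipeline runs.

## Data model and filtering

A plot sample is a species → count mapping for stems that qualify under
the inventory rule: height ≥ 3 m **and** diameter at breast height
(1.30 m) ≥ 7.5 cm. Both thresholds are inclusive; the standard inventory
convention reads "at least 3 m" and "of 7.5 cm" as ≥, and the 7.5 cm
boundary case is covered by a unit test. Plots with no qualifying stem are
excluded before any diversity computation. Stem-level and pre-aggregated
count inputs are both supported, selected by an explicit reader (no
auto-detection: a mislabelled file should fail loudly, not be guessed at).
Coordinates are decimal degrees with west longitudes negative. Species
labels are opaque strings; no taxonomic normalization is attempted.

Malformed stem rows (unparseable numerics, non-positive measurements) are
skipped, logged, and returned with their 1-based line numbers; a missing
required column aborts the read.

## Hill diversity

For relative frequencies p, the order-a diversity is
v_a = (Σ p_i^a)^(1/(1−a)), with v_0 the species count, v_1 the Shannon
limit exp(−Σ p log p) (continuous extension; the pipeline itself never
evaluates a = 1, it is an API extension), v_2 = 1/Σ p² and
v_∞ = 1/max p computed directly rather than by large-a approximation.
General a keeps the monotonicity property (v_a non-increasing in a)
testable; only the (v_0, v_2, v_∞) profile is surfaced in pipeline
outputs. Frequencies are normalized within the plot; the four subplots of
an inventory plot are pooled, not weighted.

## Climate variables and aridity

The 19 geographic/climatic variables are treated as opaque inputs (no
climate-surface interpolation; point estimates come from an external
model). The annual aridity index is AAI = sqrt(DD5)/MAP
(days^0.5·mm⁻¹); it is recomputed from DD5 and MAP when absent and
cross-checked when present, with relative mismatch above 1e-6 reported as
a warning only, since distributed tables typically carry rounded values.
Validation distinguishes hard constraints (MAP > 0, 0 ≤ GSP ≤ MAP,
DD5 ≥ 0, FFP ≥ 0, and the ordering MMIN ≤ MTCM ≤ MAT ≤ MTWM ≤ MMAX) from
soft range checks against the packaged Durango summary (warnings only —
the pipeline must run on other regions). Note the published regional
summary itself contains implausible pairings for some degree-day rows;
the package does not attempt to re-derive them.

## Screening

Spearman correlations use midranks, with two-sided p-values from the
t-approximation on n − 2 degrees of freedom (the exact permutation
distribution is used only as a test oracle at small n). The significance
convention throughout is |r_s| > 0.3 and p < 0.01; p-values are reported
raw, with no multiplicity correction, matching the fixed-threshold
convention of the original analysis.

PCA operates on the correlation matrix (the variables' units differ by
orders of magnitude), retains 2 factors by default, and rotates them by
the orthogonal varimax criterion (via statsmodels); factors are ordered
by rotated variance explained and signed so each factor's dominant
variable loads positively. Each variable is assigned to its
largest-|loading| factor. Predictor selection keeps main-factor variables
significantly correlated (per the rule above) with *any* of the three
diversity indices — the "any" reading is what reproduces the realized
published set {MAT, MTWM, MMAX, DD5, GSDD5} — plus AAI and NIP
unconditionally.

Bartlett's sphericity statistic is the standard
χ² = −(n−1−(2p+5)/6)·ln det(R) on p(p−1)/2 degrees of freedom. The
published analysis reports "Bartlett's test … 0.864 (p<0.001)", which
cannot be a χ² value on 171 degrees of freedom and resembles a KMO
measure; the package therefore reports both the χ² statistic and the KMO
measure of sampling adequacy, and makes no attempt to match the printed
0.864.

## Quantile regression

All models are linear in their parameters; the polynomial "nonlinear"
models are fitted as basis-expanded linear quantile regressions. The
fit minimizes the pinball loss exactly as a linear program: the compact
dual (max y'a s.t. X'a = (1−τ)X'1, 0 ≤ a ≤ 1; n variables, p
constraints) is solved with HiGHS, the coefficients are recovered from
the interpolated observations, and the solution is accepted only after a
complementary-slackness optimality check — otherwise the full primal
split-residual LP is solved. This makes the fit deterministic given row
order and exact to LP tolerance (verified against exhaustive
combinatorial search over basic solutions at small n), at roughly 30×
the speed of the primal on inventory-scale data. statsmodels' IRLS
QuantReg serves as an independent cross-check in the tests, never as the
implementation.

The covariate is centred and scaled before polynomial expansion (a raw
quartic in AAI ≈ 0.05 would involve 1e-5-scale regressors and wreck LP
conditioning); coefficients are back-transformed and always reported on
the raw scale, highest-degree term first (a..e layout).

Inference is by xy-pair bootstrap (default B = 1000, default seed
20140815): rows resampled with replacement, model refitted, SE = the
across-replicate standard deviation, p from a two-sided normal
approximation of coef/SE. Replicates with rank-deficient resampled
designs are redrawn (at most 10·B attempts). The original tables'
inference method is unstated, so printed p-values are not replication
targets; bootstrap p-values can legitimately differ from them.

Two fit measures are reported side by side: the Koenker–Machado
R¹(τ) = 1 − V(model)/V(unconditional τ-quantile) (default, in [0, 1] for
models with an intercept), and a "rho" variant — the squared correlation
between fitted values and fitted values plus per-observation pinball
contributions — which is statistically unconventional but needed for
comparability with the published r² values. Quantile crossing is not
structurally prevented; non-crossing of the fitted 0.1/0.5/0.9 curves is
a statistical property checked on known-truth data at n ≥ 2000.

## Curve analysis and scenario projection

Critical points of a fitted polynomial are the real roots of its
derivative (companion-matrix roots polished by Newton steps to
|f′| < 1e-9 of the derivative's coefficient scale), classified by the
sign of f″; near-degenerate points (|f″| below tolerance) are treated as
inflections and dropped. A quartic has at most 3 critical points and
consecutive extrema alternate min/max, both property-tested. Report
tables follow the convention: the tabulated "Min" is the in-range local
minimum with smallest fitted value and "Max" the in-range local maximum
with largest fitted value (some printed quartics have a third in-range
critical point that display tables omit; this rule is an inference and
values are rounded half-up to two decimals). Search intervals default to
the observed covariate range; for the packaged replication coefficients
the aridity interval is [0.03, 0.16] — the published extrema at
AAI = 0.04 lie below the summary table's observed minimum of 0.060, so
the plotted curve range, not the summary range, must be used. Temperature
covariates use their observed min/max and the density models their stated
validity range [1, 120].

Replication caveat: the fitted value at the flat maximum of the τ = 0.9
richness-aridity quartic computes to 11.015 from the printed (rounded)
coefficients and so rounds to 11.02 against a published 11.01; the
temperature-covariate extremum positions are even more sensitive to
quartic-coefficient rounding (> 1 °C shifts) and are deliberately not
asserted anywhere.

The water-energy (WED) model is v_a = a·MAP + b·MMAX + c. The
end-of-century scenario applies ΔT (default 3.75 °C, the midpoint of the
forecast 3.7–3.8 °C range) to **MMAX** — the model's temperature
covariate — even though such forecasts are phrased for mean annual
temperature; the published reduction percentages are only reproducible
under this reading, so it is adopted and flagged here. Precipitation is
scaled by 0.818 (an 18.2 % decrease). The "mean plot" baseline evaluates
the model at the regional mean MAP and MMAX rather than averaging
per-plot predictions. percent change = 100·(baseline − scenario)/baseline;
a non-positive baseline is an error and a negative scenario prediction is
flagged, not hidden.

## Synthetic inventories

The generator emulates the documented structure of the study system, not
its ecology: a jittered lat/long grid; elevation uniform on 390–3,156 m;
MAT = 28 − 6.5·ELEV/1000 °C plus 0.3 °C noise; the other temperature-group
variables affine in MAT with small (partly one-sided, so the
MMIN ≤ MTCM ≤ MAT ≤ MTWM ≤ MMAX ordering always holds) noise, slopes
chosen so no variable hits a physical floor/ceiling — clipping would
break the planted within-group collinearity (pairwise |r_s| > 0.9). FFP
is FDAY − SDAY plus independent noise; without that noise the correlation
matrix is exactly singular and Bartlett's test undefined. MAP rides a
latitudinal gradient independent of elevation (≈917 ± 226 mm),
GSP ≈ 0.75·MAP, and AAI is computed exactly as sqrt(DD5)/MAP, which makes
it load with the precipitation factor (its relative variation is
dominated by MAP).

Stand density NIP is negative-binomial (k = 3) with mean
170·exp(−14·AAI) ≈ 70 at the mean aridity; zero-NIP draws are omitted
(they would be filtered anyway). Log mean richness is quadratic in
standardized MAT and AAI (baseline 1.4, i.e. ~5 expected species, chosen
so the realized profile means ≈ 6.6/3.5/2.4 match the regional summary)
plus 0.35·log(NIP/70) for the accumulation effect, giving the planted
negative aridity-diversity and positive density-diversity signs and
saturating density curves. Abundances follow a geometric series with
ratio θ = 0.55, one individual guaranteed per species and the remainder
multinomial, over a 327-label pool with skewed draw weights. A single
seed drives named substreams (climate / communities / stems / quantile
data) so stages regenerate independently.

Known-truth quantile data are location-scale: y = m(x) + s(x)·ε with
ε = Exp(1) − ln 2 (median zero, right-skewed so the three quantile curves
differ materially); Q_τ(y|x) = m(x) + z_τ·s(x) is then itself a
polynomial with z_τ = −ln(1−τ) − ln 2.

What passing on synthetic data does **not** show: real inventories have
spatial autocorrelation, detection/measurement error, taxonomic drift and
non-stationary climate-diversity relations, none of which are modelled.
Recovery results demonstrate the *estimators* work where the truth is
known, not that the published ecological conclusions are correct.

## Problem sizes and tolerances in the test suite

Simulation-based tests use sizes chosen to exercise the asymptotics while
keeping the suite quick: quartic quantile recovery at n = 5,000 with
B = 150 bootstrap replicates (assertion: within 3 SEs of truth per
coefficient and τ); oracle equivalence over 200 random instances with
n ≤ 8, p ≤ 2 at 1e-9; factor recovery over 50 seeds at n = 1,000 plots;
bootstrap interval coverage over 60 repeats at n = 120, B = 100 with a
binomial acceptance band of [0.85, 1] around the nominal 0.95. Hill-number
inequalities are checked on 10⁴ random abundance vectors at 1e-12-scale
tolerances. The pipeline smoke tests run at 150 plots with inference
switched off (`bootstrap_b = 0`).

## Known limitations

- No quantile-crossing constraints, censored quantile regression,
  rank-inversion confidence intervals, smoothing splines, rarefaction or
  coverage standardization, beta/gamma diversity partitioning, oblique
  factor rotations, or GIS/mapping output.
- Scenario projections propagate no coefficient uncertainty (a bootstrap
  extension would be straightforward but is not implemented).
- Printed-coefficient replication inherits the precision of the published
  rounding, as quantified above.
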