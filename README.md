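# divclim

Tree-species diversity versus climate, the quantile-regression way.

`divclim` is a reusable pipeline for a question macroecologists and forest
scientists keep returning to: how do the *minimum*, *median* and *maximum*
levels of local tree diversity respond to temperature, precipitation and
aridity across a large forest inventory? It was built around the analysis
of the Sierra Madre Occidental (Durango, Mexico) inventory — ~1,600 plots
on a 5 × 5 km grid, stems ≥ 3 m tall and ≥ 7.5 cm diameter at breast
height — but every stage runs on any plot-level species tally plus a
climate table.

## What it computes

**Diversity profiles.** Per plot, the Hill-number family

&nbsp;&nbsp;&nbsp;&nbsp;*v<sub>a</sub>* = (Σ<sub>i</sub> p<sub>i</sub><sup>a</sup>)<sup>1/(1−a)</sup>

with the three classic orders: *v₀* (species richness), *v₂* (effective
species number, the reciprocal of Simpson's concentration Σp<sub>i</sub>²)
and *v<sub>∞</sub>* = 1/max p<sub>i</sub> (number of prevalent species).
Always *v₀* ≥ *v₂* ≥ *v<sub>∞</sub>* ≥ 1, with equality exactly at even
abundances.

**Climate indices.** The 19-variable climate catalogue (MAT, MMAX, DD5,
MAP, …) and the annual aridity index AAI = √DD5 / MAP (higher = more arid).

**Screening.** Spearman correlation matrices with the |r<sub>s</sub>| > 0.3,
p < 0.01 significance rule, Bartlett's sphericity test, the KMO measure,
and PCA of the correlation matrix with varimax rotation, which separates a
"temperature" factor from a "precipitation" factor and drives predictor
selection.

**Quantile regression.** Conditional quantiles Q<sub>τ</sub>(*v<sub>a</sub>* | x)
at τ ∈ {0.1, 0.5, 0.9} by exact pinball-loss minimization
(ρ<sub>τ</sub>(u) = u(τ − 1[u<0]), solved as a linear program), for
univariate polynomials of degree 1–4 and the bivariate water-energy (WED)
form *v<sub>a</sub>* = a·MAP + b·MMAX + c. Inference is by xy-pair
bootstrap; goodness of fit by the Koenker–Machado R¹(τ) and a
squared-correlation variant kept for comparability with published tables.

**Curve analysis.** Interior extrema of the fitted polynomials (the
hollow/hump shapes), and projection of the WED models under a climate
scenario (default: +3.75 °C and 18.2 % less precipitation by 2090).

**Synthetic inventories.** A generator that plants all of this structure —
collinear temperature group, independent precipitation gradient,
aridity-driven stand density, climate-responsive richness with
geometric-series evenness, and location-scale datasets whose conditional
quantiles are known polynomials — so the whole pipeline is testable
without the (undeposited) raw inventory data.

## Worked example

```python
from divclim import (diversity_profile, polynomial_extrema, best_min_max,
                     project_scenario, ScenarioSpec)
from divclim.datasets import quartic_quantile_fits, REPLICATION_RANGES

# one plot's tally -> its diversity profile
counts = {"Pinus durangensis": 38, "Quercus sideroxyla": 12,
          "Arbutus xalapensis": 5, "Juniperus deppeana": 3, "Pinus cooperi": 2}
print(diversity_profile(counts))
# DiversityProfile(v0=5.0, v2=2.2140221402214024, v_inf=1.5789473684210527)

# extrema of the published median richness-aridity quartic
fits = quartic_quantile_fits()
row = fits.query("response=='v0' and covariate=='AAI' and tau==0.5").iloc[0]
pts = polynomial_extrema(row[list("abcde")].astype(float), REPLICATION_RANGES["AAI"])
lo, hi = best_min_max(pts)
print(f"local max at AAI={hi.x:.3f}: v0={hi.y:.2f}")   # local max at AAI=0.038: v0=8.11
print(f"local min at AAI={lo.x:.3f}: v0={lo.y:.2f}")   # local min at AAI=0.103: v0=3.99

# end-of-century scenario on the median WED model for species richness
res = project_scenario((0.00286, -0.32059, 12.25270), baseline_map=916.8,
                       baseline_mmax=26.5, scenario=ScenarioSpec(), response="v0")
print(f"baseline {res.baseline_pred:.2f} -> scenario {res.scenario_pred:.2f} "
      f"({res.percent_change:.1f}% reduction)")
# baseline 6.38 -> scenario 4.70 (26.3% reduction)
```

Five species, but heavy dominance by one pine: the effective number is
2.2 and only ~1.6 species are "prevalent". The median richness-aridity
curve peaks at ~8 species on humid sites (AAI ≈ 0.04) and bottoms out
near 4 on the arid edge (AAI ≈ 0.10); under the 2090 scenario the median
WED model loses about a quarter of the mean plot's species richness.

The same stages are available from the shell:

```sh
divclim simulate --n-plots 400 --seed 42 --out sim/      # synthetic inventory
divclim run --out results/ --n-plots 400 --seed 42       # full pipeline
divclim run --replication --out replication/             # from packaged coefficients
divclim extrema --out extrema.csv
divclim project --out projection.csv
```

`divclim run` writes every stage table (climate, diversity, correlations,
factor loadings, quantile fits, extrema, WED fits, scenario projection)
plus a `report.md` that is assembled only from those files.

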