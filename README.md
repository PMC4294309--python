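# paddygeo

Field-scale geostatistics for soil macronutrients in lowland rice
(paddy) fields.

Paddy soils look deceptively uniform — flat, levelled, seasonally
flooded — yet plant-available ammonium nitrogen (NH₄⁺-N), Olsen P and
Mehlich-1 K vary strongly over tens of metres, and their spatial
patterns shift over the growing season as flooding changes pH and redox
state.  `paddygeo` packages the standard analysis chain used to
quantify that variability from intensive point sampling, for
agronomists and soil scientists working on site-specific nutrient
management:

* descriptive statistics per dataset (mean, sample variance, CV %,
  extremes, skewness g₁, excess kurtosis g₂, Lilliefors/KS normality
  screening, Pearson correlation, compact-letter group comparison);
* the empirical (experimental) semivariogram

  γ̂(h) = 1/(2N(h)) Σᵢ [Z(xᵢ) − Z(xᵢ+h)]²,

  binned isotropically over lag distance h;
* weighted least-squares fitting of spherical, exponential and Gaussian
  variogram models γ(h; C₀, C₁, a) — nugget C₀, structural variance C₁,
  sill C₀+C₁, (practical) range a — with leave-one-out ordinary-kriging
  cross-validation (r², mean error ME, standardized mean squared error
  NMSE with ideal value 1) used for model selection;
* classification of spatial dependence from the nugget-to-sill ratio
  100·C₀/(C₀+C₁): strong < 25 %, moderate 25–75 %, weak > 75 %;
* ordinary kriging with a Lagrange multiplier (weights summing to one)
  for point prediction and raster maps with kriging variance, written
  as ESRI ASCII grids;
* a seeded Gaussian-random-field generator that emulates a 27-dataset
  liming trial (3 nutrients × 3 dolomite doses × 3 sampling dates,
  93 samples per 1.7-ha parcel on an 11.9 × 20 m grid), so the whole
  chain can be exercised end-to-end without any field data.

The package ships that trial's published per-dataset summary table
(means, variances and fitted variogram parameters for all 27 datasets)
as `paddygeo/data/scenarios.csv`; it is the generating truth for the
simulator and the input for the study-level summaries.

## Worked example

```python
import paddygeo as pg

# one seeded realization of the control NH4-N dataset at sowing:
# spherical variogram, C0=1.09, C1=14.20 (mg/kg)^2, range 47 m, mean 20.07
model = pg.VariogramModel("spherical", 1.09, 14.20, 47.0)
cfg = pg.SimulationConfig(model=model, mean_level=20.07, seed=42,
                          dataset_code="NH4-10")
samples = pg.simulate_gaussian_field(cfg)          # 93 points

report = pg.run_dataset(samples, pg.AnalysisOptions(
    families=("spherical", "exponential")))
m = report.fit.model
print(f"n={report.stats.n}  mean={report.stats.mean:.2f}  "
      f"CV={report.stats.cv_percent:.1f}%")
print(f"fitted {m.family.value}: C0={m.c0:.2f} C1={m.c1:.2f} "
      f"a={m.range_a:.1f} m  ratio={m.nugget_ratio:.1f}%  "
      f"({report.dependence_class.value})")
print(f"LOO CV: r2={report.cv.r2:.3f}  ME={report.cv.me:.3f}  "
      f"NMSE={report.cv.nmse:.3f}")
```

prints

```
n=93  mean=20.25  CV=12.8%
fitted exponential: C0=0.00 C1=7.54 a=57.5 m  ratio=0.0%  (strong)
LOO CV: r2=0.413  ME=0.003  NMSE=0.956
```

i.e. this realization's 93 samples come back with the right
spatial-dependence class ("strong": nugget ratio 0 % vs the generating
7.1 %) and a comparable range (57.5 m vs 47 m), with well-calibrated
cross-validation (NMSE ≈ 1, ME ≈ 0); with only one realization of a
field this size, family selection and the fitted sill fluctuate
noticeably from seed to seed, which is exactly what the
parameter-recovery rates in `scripts/acceptance.py` quantify.  `pg.summarize_study(pg.load_scenarios())`
aggregates the published table itself: nugget ratios between 0 and
43.7 % (zero at 4 datasets, 25–50 % at 12), sills 1.82–6.67 (mg kg⁻¹)²
for Olsen P and 6.17–89.81 (mg kg⁻¹)² for Mehlich-1 K, ranges up to
84.6 m.

A thin CLI wraps the same calls:

```sh
paddygeo simulate --seed 1 --out-dir sim/
paddygeo analyze sim/NH4-10.csv --out-dir out/ --map
paddygeo summarize --out summary.json
```

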