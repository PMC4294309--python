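# Methods

This note records the statistical model behind `paddygeo`, the
conventions and defaults the package commits to, and what the synthetic
fields used by the tests do and do not establish about real data.

## Setting and model

The package analyses georeferenced point measurements of plant-available
soil nutrients (NH₄⁺-N, Olsen P, Mehlich-1 K; mg kg⁻¹) from an
intensively sampled rice parcel.  Each dataset — one nutrient under one
dolomite dose at one sampling date — is treated as a realization of a
second-order stationary, isotropic random field Z(x).  Spatial structure
is carried entirely by the semivariogram γ(h) = ½ E[(Z(x) − Z(x+h))²],
assumed to follow one of three bounded parametric families with nugget
C₀ ≥ 0, structural variance C₁ ≥ 0 and range a > 0:

* spherical: γ(h) = C₀ + C₁(1.5 h/a − 0.5 (h/a)³) for h ≤ a, C₀ + C₁
  beyond;
* exponential: γ(h) = C₀ + C₁(1 − e^(−3h/a));
* Gaussian: γ(h) = C₀ + C₁(1 − e^(−3(h/a)²)).

For the unbounded-approach families, a is the **practical range** (95 %
of the sill), so fitted ranges are directly comparable across families
and to the spherical range.  γ(0) = 0 exactly with a jump to C₀ as
h → 0⁺: the nugget is read as micro-scale plus measurement variance, and
the covariance dual C(h) = (C₀+C₁) − γ(h) consequently has C(0) = sill.
With that convention ordinary kriging interpolates the data exactly
while still attributing nugget variance to unsampled locations.
Datasets are analysed independently; no temporal or cross-nutrient
correlation is modelled.

The degree of spatial dependence is classified from the nugget-to-sill
ratio 100·C₀/(C₀+C₁): strong below 25 %, moderate from 25 to 75 %
(inclusive), weak above.

## Field geometry

The emulated trial splits a field into three 1.7-ha parcels (one per
dolomite dose: 0, 625, 1250 kg ha⁻¹), each containing 32 plots of
50 m × 11.9 m separated by 1.9 m channels and sampled on a basic
11.9 × 20 m grid, three positions per plot — 96 lattice positions, of
which the protocol uses 93.

`FieldLayout` idealizes this as a uniform 8-column × 12-row lattice of
exact 11.9 m × 20 m spacing (plots arranged 8 across × 4 along; each
plot is one column × 3 consecutive rows).  The idealization keeps every
nearest-neighbour distance at exactly 11.9 or 20 m; the ~10 m gaps and
margins that literal plot boundaries and channels would introduce are
not reproduced because the source protocol reports only the basic grid.
Coordinates are local Cartesian metres from the parcel's south-west
corner; no projection is attached.  The 93-point default drops the last
three positions of the northernmost row (which three were dropped in the
field is unrecorded; the choice is immaterial to any statistic the
package computes).

## Estimation choices

**Empirical semivariogram.**  Omnidirectional, unordered pairs binned
into half-open intervals [k·w, (k+1)·w).  Defaults: lag width w = 12 m
(just above the 11.9 m minimum spacing, so the first bin isolates
nearest neighbours) and maximum lag = half the maximum pairwise distance
(≈ 118 m on the default lattice, ~10 bins).  Bin abscissae default to
the **mean pair distance** per bin rather than the midpoint: on gridded
data pair distances are discrete and can sit far from the midpoint (the
first bin contains only 11.9 m pairs but would be plotted at 6 m), and
midpoint centring measurably biases nugget and range estimates in
parameter-recovery simulations.  Midpoint centring remains available.

**Model fitting.**  Weighted least squares over (C₀, C₁, a), weights
defaulting to Cressie's N(h)/γ_model(h)² (plain pair counts N(h)
optional).  Cressie weights emphasise short lags, where γ is small and
the nugget and range are determined; pure pair-count weights let the
plateau bins (which hold most pairs) dominate and visibly degrade
nugget/range recovery at n = 93.  The optimizer is a bounded
trust-region least-squares solver multi-started from a fixed 10-point
range grid × 3 nugget fractions (0, 0.25, 0.5 of the plateau guess),
with bounds C₀, C₁ ∈ [0, 3·max γ̂] and a ∈ [w, 1.5·max lag]; the fixed
start set makes fits exactly reproducible.  Noiseless model-generated
variograms are recovered to ≤ 10⁻⁴ relative error in all three families.

**Cross-validation.**  Each point is predicted by ordinary kriging from
the other n − 1 (global neighbourhood).  Reported indicators: r² (squared
Pearson correlation of observed and predicted; the observed-on-predicted
regression slope/intercept are emitted as diagnostics), ME = mean
(predicted − observed), and NMSE = mean[(observed − predicted)² /
kriging variance], dimensionless with ideal value 1.  Model selection
among candidate families minimizes |NMSE − 1|, ties broken by larger r²
then smaller |ME|.  NMSE calibration is a weak filter — a model with
poor predictive skill can still standardize its residuals correctly — so
selection noise contributes to scenario-level classification error (see
below).

**Ordinary kriging.**  Covariance-form system with Lagrange multiplier;
the diagonal carries C(0) = sill.  All n points enter every prediction
(n ≤ 96 here, so dense solves are cheap and search-neighbourhood
artefacts are avoided).  Negative weights are permitted, as is standard;
predictions may leave the data range and are not clipped.  Kriging
variance is clipped at zero against roundoff; it depends only on
geometry and model, never on values.  Maps default to 5 m cells over the
sample bounding box, written as single-band ESRI ASCII grids (values and
variances separately).

**Descriptive statistics.**  Sample variance (n − 1); CV % =
100·√variance/mean; skewness and kurtosis default to the biased moment
coefficients g₁ and excess g₂ (the bias-adjusted G₁/G₂ are an option —
the source tables do not state their convention, and the mix of small
negative kurtosis values is consistent with either).  Normality
screening uses the Lilliefors-corrected one-sample KS test (moments
estimated from the data).  Group comparison uses pairwise Welch t-tests
with Holm adjustment at α = 0.05, rendered as a compact letter display
via maximal cliques of the non-significance graph.

## Synthetic data

The raw field measurements were never published; the package instead
ships the study's 27-row summary table (per-dataset mean, variance,
skewness, fitted family, C₀, C₁, a, and the reported cross-validation
indicators) and simulates from it.  Fields are drawn as
Z = μ + Lε with LLᵀ the model covariance matrix at the lattice
coordinates (diagonal = sill) and ε seeded i.i.d. standard normal; a
10⁻¹⁰·sill diagonal jitter is the fallback for the four nugget-free
scenarios where roundoff can break positive definiteness.  Because
nutrient concentrations are positive, the generator redraws from the
same seeded stream in the rare event a draw crosses zero (only plausible
for the low-mean Olsen-P scenarios); output is deterministic per seed,
and per-scenario sub-seeds derive reproducibly from one master seed.
Fields are Gaussian by default — all 27 real datasets passed normality
screening — and a shifted-lognormal moment-matching transform can impose
the mild reported skewness (−0.46 to 1.07) when non-Gaussian behaviour
is wanted; it preserves mean and variance exactly for exactly-normal
input and to ~2 % for sample input.

What passing simulation-based tests shows: the estimators recover known
second-order structure from 93 lattice points, with honest uncertainty.
What it cannot show: anything about features the generator omits —
anisotropy, trends, outliers, proportional effects, measurement error
beyond the nugget, or the real fields' deviation from Gaussianity and
stationarity.

## Repeatability of the study's classifications

Single-realization variograms from 93 points over a ~95 × 240 m domain
with ranges of 40–85 m are intrinsically noisy (the domain spans only a
few range diameters).  Under the package's defaults, refitting the
strongest-structured scenario (spherical, C₀ 1.09, C₁ 14.20, a 47 m)
recovers the range within ±40 % with NMSE ∈ [0.6, 1.4] in roughly 80 %
of seeds, and the full pipeline returns the generating
strong/moderate/weak class for a majority (typically 15–20) of the 27
scenarios at a given seed — many scenarios sit close to the 25 %
class boundary, where a single realization cannot classify reliably.
These rates are properties of the study design itself, not removable by
implementation choices short of likelihood-based estimation, which is
deliberately out of scope.

## Numerical details and edge cases

* Duplicate coordinates are rejected at container construction; kriging
  systems therefore only become singular through pathological models,
  and such failures raise a dedicated numerical error.
* Constant fields: semivariogram is all-zero (fitting refuses it);
  describe() reports zero variance with undefined skewness/kurtosis.
* Empty bins are dropped; fitting requires ≥ 4 non-empty bins,
  variogram estimation and LOO require n ≥ 10.
* All report rounding (1 d.p. for CV/ratio/range display, 2 d.p. for
  means) happens at display; JSON and CSV artefacts carry full
  precision, and floats are serialized with shortest round-trip repr so
  write→read is bit-faithful.
* Problem sizes in the test-suite Monte-Carlo runs (60–500 seeds
  depending on the statistic, 100 seeds for recovery rates) were chosen
  to keep each estimate's own sampling error well inside the asserted
  bands.
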