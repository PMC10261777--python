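# Methods

## Scope and data model

The package analyses rehydration of dehydrated sweet corn kernels across a
4 × 4 factorial design: pretreatment ∈ {control, hot-water blanched (HB),
steam blanched (SB), microwave blanched (MB)} × drying temperature ∈
{55, 60, 65, 70 °C}. A `RehydrationCurve` holds one condition's soaking
time series — times in minutes (default every 5 min up to 60 min) and
dry-basis moisture X in g water / g dry matter. All moistures are dry
basis: the published equilibrium magnitudes (3.07–6.85 g/g) are consistent
with dry basis given fresh kernels at 75 % wet basis (= 3.0 g/g dry basis);
conversion helpers `moisture_wb_to_db`/`moisture_db_to_wb` are provided.
The initial moisture X₀ is always the measured t = 0 value and is never
fitted.

## Models and estimation

* **Peleg**, X(t) = X₀ + t/(k₁ + k₂ t), Z = 2 parameters. Estimation first
  solves the linearisation t/(X − X₀) = k₁ + k₂ t by ordinary least squares
  over points with X > X₀, then refines (k₁, k₂) by trust-region least
  squares on the moisture residuals (scipy `least_squares`, ftol = xtol =
  gtol = 1e-12, ≤ 1000 evaluations, positivity bounds). The derived
  equilibrium is X_eq = X₀ + 1/k₂.
* **Weibull**, X(t) = X_eq + (X₀ − X_eq)·exp(−(t/β)^α), Z = 3. The forward
  model is evaluated in convex-combination form X_eq(1 − d) + X₀ d with
  d = exp(−(t/β)^α) so that t = 0 returns X₀ exactly in floating point.
  Initialisation: α = 1, X_eq = 1.05 × max observed moisture, β = the
  observation time nearest the 63 % level of (X_eq,init − X₀). Bounds:
  α ∈ (0, 5], β > 0, X_eq ≥ 0.5 × max observed moisture.
* **Logarithmic**, X(t) = X_eq + (X₀ − X_eq)·ln(k t), Z = 2, domain t > 0;
  t = 0 points are excluded from evaluation and fitting rather than
  clipped. The model is linear in ln t (slope b = X₀ − X_eq, intercept
  a = X_eq + b·ln k), so the least-squares solution is closed-form:
  X_eq = X₀ − b, k = exp((a − X_eq)/b). The equation is implemented exactly
  as published, including its counter-intuitive sign behaviour: an
  increasing curve forces X_eq < X₀, so the fitted "equilibrium"
  coefficient is typically negative and must not be read as a physical
  moisture. Measured curves are validated non-negative; only synthetic
  logarithmic-model curves may carry negative values (an explicit
  `allow_negative_moisture` opt-in), since for realistic rate parameters
  the printed form is negative at short times.

Goodness of fit: RMSE = √(SSE/N), reduced χ² = SSE/(N − Z), and
R² = 1 − SSE/SST about the observed mean. Residuals are computed on
moisture content by default; `residual_on="moisture_ratio"` normalises both
observations and predictions by (X_last − X₀) before computing the
statistics (an affine change, so parameter estimates are unchanged).
Models are ranked by R² descending, ties broken by RMSE, then χ², then
fewer parameters; the sort is stable. Failed or degenerate fits are
flagged and excluded from the per-model averages, with the exclusion count
reported. No confidence intervals, multi-start optimisation or
AIC/BIC-style selection is attempted.

## Quality metrics

Rehydration ratio RR = rehydrated mass / dried mass. Rehydration rate is
reported both as per-interval finite differences (X_{i+1} − X_i)/(t_{i+1} −
t_i) and as the endpoint average (X_N − X₀)/(t_N − t₀), explicitly
labelled, since published figures do not state which convention they use.
Geometric mean diameter D_g = (L W T)^⅓ with L the maximum kernel
dimension. Colour difference is the original CIE76 Euclidean ΔE in CIELAB,
not CIEDE2000, matching the published formula; the reference triple is the
fresh kernel's colour.

## Compound-correlation clustering

Treatments are clustered agglomeratively on z-scored property columns
(population SD; zero-variance columns are dropped with a warning).
Distance is Euclidean; linkage defaults to Ward — the published description
names neither, and Ward best reproduces the compact temperature-dominated
clusters described there; average and complete linkage are available.
Two default feature sets mirror the published dendrograms: "physical"
(dried and rehydrated mass, RR, D_g, ΔE) and "overall" (physical plus total
sugar, ascorbic acid, sensory score); both are configurable. The merge tree
is serialised to Newick with branch lengths equal to merge-height
differences; children are ordered by smallest original row index so output
is deterministic. Flat clusters come from cutting at a fraction of the
root height (default 0.5); a fraction of exactly 0 is special-cased to
singletons so that duplicate rows (merged at height 0) still separate.

## Synthetic-data generator

The raw measurements behind the study are unpublished, so the generator
emulates the study conditions rather than any real dataset:

* **Curves.** Default generating model is Peleg with the published
  per-condition (k₁, k₂) — the only complete per-condition parameter sets
  available — on the 0–60 min grid with X₀ = 0.10 g/g (a typical dried-corn
  initial moisture) and additive Gaussian noise of sd 0.05 g/g on moisture,
  truncated below at 0 (a slight bias source at early times). Weibull
  generation uses the mid-range published shape factor per pretreatment, a
  scale factor falling with temperature across the published span, and the
  Peleg-derived equilibrium; logarithmic generation uses a rate rising with
  temperature within the published span and an equilibrium coefficient
  rising from −2.5 to −1.5 (unpublished; chosen to give slopes well above
  the noise floor).
* **Treatment table.** Per-condition property means interpolate the
  published per-pretreatment spans linearly between 55 and 70 °C (masses,
  ΔE, total sugar, ascorbic acid, sensory score, kernel dimensions), so
  the simulated design covers each published range; per-property
  measurement noise is scaled at instrument precision (e.g. 0.003–0.01 g
  for masses, 0.3 ΔE units). CIELAB triples are placed at the target ΔE
  from a fixed fresh reference (L* = 72, a* = 5.5, b* = 42, typical sweet
  corn) along a fixed browning direction (darker, redder, less yellow).
* **Determinism.** All randomness derives from one integer seed through
  per-(purpose, condition) `SeedSequence` substreams; a fixed seed gives
  bitwise-identical output.

What passing tests on these data do **not** show: the generator draws
independent Gaussian noise per time point on a curve that follows one of
the candidate models exactly, whereas real kernels have serially correlated
measurement error, kernel-to-kernel heterogeneity, leaching of solubles,
and no guarantee that any of the three forms is the true mechanism. Model
ranking on synthetic data therefore favours the generating model by
construction and says nothing about which model real sweet corn follows.

## Numerical and testing notes

* Parameter-recovery behaviour (13 points, noise sd 0.05 g/g, parameters
  drawn from the published ranges): median relative errors are ≈4 % (Peleg
  k₁), ≈2 % (k₂), ≈4–5 % (Weibull α, X_eq) and ≈9 % (Weibull β, estimated
  at 9.15 % from 2000 draws). β is the weakest because the published SB
  scale-factor span reaches 82.85 min while sampling stops at 60 min, so β
  and X_eq are partly confounded; the logarithmic model's closed form
  recovers its parameters to ≈1 % median. With zero noise all recoveries
  are exact to better than 1e-6 relative.
* Grid-search cross-checks in the test suite use vectorised SSE
  evaluation over coarse parameter boxes; the nonlinear fits always reach
  or beat the best grid point.
* Tables are written comma-delimited UTF-8 with a fixed `%.12g` float
  format (tab accepted on read), which is what makes repeated runs
  byte-identical.
* Problem sizes used by the test suite and drivers — 16 curves × 13 points,
  200 recovery draws per model, 20 grid-oracle curves per model — keep any
  single test file under a few seconds while leaving the recovery medians'
  sampling error near 1 %.

## Known limitations

* The published average statistics for the Peleg model (R² printed as
  0.0986 with RMSE 0.987) are internally inconsistent with the published
  per-condition table (R² 0.986–0.998, RMSE 0.026–0.098); the pipeline
  reports averages computed from its own fits and makes no attempt to
  reconcile the printed figures.
* Per-condition Weibull and logarithmic-model parameters were published
  only as per-pretreatment ranges, so those generator settings are
  interpolations, not reproductions.
* The published per-kernel masses imply rehydration ratios (≈4.5–5.4)
  inconsistent with the separately published RR range (2.88–3.54); RR is
  computed strictly from the mass ratio and the discrepancy is surfaced,
  not resolved.
* Temperature dependence is not modelled (no Arrhenius parameterisation);
  each condition is fitted independently, matching the source analysis.
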