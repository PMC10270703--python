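# Methods

## Thermal-time phenology

All stage rules use daily *mean* temperature only, with growing degree days
(GDD) defined as Σ max(t̄ − base, 0) over a half-open date window
[start, end), base 0 °C. The half-open convention makes GDD exactly additive
across consecutive stages, which the tests exploit
(`gdd(a,b) + gdd(b,c) = gdd(a,c)`).

* **Regreening** is predicted from the negative accumulated temperature
  X = Σ t̄ over days with t̄ strictly below 0 °C, 1 Oct–15 Feb (inclusive),
  via Y = −0.0703·X + 20.339 with Y = 1 ⇔ 1 Feb. Y is rounded to the nearest
  day (halves up); values beyond February roll into March, a day later in
  leap years. A day at exactly 0 °C contributes to neither GDD nor X.
* **Jointing / filling** are the first dates at which 380 / 1160 GDD
  accumulate from regreening (minimal crossing: the previous day is below
  threshold).
* **Maturity** interprets the growth-rate regression
  rate = 0.0014 + 0.0006·GDD(regreening→now) as a threshold: maturity is the
  first date with cumulative GDD ≥ (1 − 0.0014)/0.0006 ≈ 1664.33. The
  alternative reading (summing daily rate increments) was rejected because
  the threshold reading puts filling→maturity thermal time at
  1664.33 − 1160 ≈ 504 GDD, consistent with the ~500–530 GDD that window
  spans in regional practice; the daily-rate reading has no such anchor.
  A consistency test asserts the simulated filling→maturity GDD lands near
  504.
* **Flowering** is back-calculated as the latest date at least 300 GDD
  before filling (maximal: one day later would drop below 300).
* **Dormancy onset** is defined operationally — the first date on/after
  1 Nov starting 5 consecutive sub-zero days, falling back to 15 Dec — since
  the stage rules upstream only need it to terminate the sowing
  accumulation, and near-dormancy days contribute almost no GDD.
* **Sowing** is the candidate in 20 Sep–20 Oct whose sowing→dormancy GDD
  falls in the suitable 570–770 band closest to 670 (later date wins ties;
  if no candidate reaches the band the nearest one is returned with a
  warning rather than an error, because downstream whole-season averages are
  insensitive to a few days' shift).

Degenerate inputs (threshold never reached, series too short, inverted
windows) raise `PhenologyError` carrying the failing stage name; an
out-of-order calendar is never returned.

## The 29 predictors

Latitude and longitude, plus window aggregates: for sowing→maturity the
seven aggregates mean t̄/t̂/ť, GDD, mean RH, Σ precip, Σ sunshine; for each of
regreening→maturity, jointing→flowering, flowering→filling and
filling→maturity the five aggregates mean t̄, GDD, mean RH, Σ precip,
Σ sunshine (2 + 7 + 4×5 = 29). Temperatures and humidity are averaged;
thermal time, precipitation and sunshine accumulated. No predictor is
computed for the dormancy window (growth has ceased) or the
regreening→jointing window (little between-county variation, and extra
inputs dilute a small-sample model). Daily max/min temperature enter only
the whole-season window. This composition is a reconstruction — regional
survey studies rarely enumerate their variable list — and is pinned by a
unit test plus a JSON schema sidecar written next to every feature table.

Cultivar replicates within a county-year share identical weather, so GPC is
averaged to one response per county-year before modelling; `average_gpc` is
idempotent and tested on a 306-row → 176-county-year replicate layout.
Quality classes follow the national bread-wheat convention: high ≥ 14 %,
medium [13, 14), low < 13 % GPC (boundaries assigned upward).

## Gradient-boosted trees

`fit_gbdt` is the forward-stagewise additive model with squared loss:
f₀ = mean(y) (the loss minimizer; the recursion needs an explicit anchor),
then for k = 1…N a CART is fit to the residuals y − f_{k−1}(X) and
f_k = f_{k−1} + α·T_k. For any α ∈ (0, 1] the training SSE is
non-increasing in k (each tree is a projection onto leaf indicators, so the
update removes 2α−α² of its captured energy); a test replays the recursion.

CART details, fixed for determinism where textbook definitions are silent:
candidate thresholds are midpoints of consecutive sorted unique values;
`x ≤ threshold` routes left; ties in SSE reduction break by lowest feature
index then lowest threshold; stopping on depth, `min_leaf` (both children),
or no strictly positive gain (greater than 1e-12, guarding float noise on
constant responses). Defaults N = 100, α = 0.1, depth 3, min_leaf 5 — a
conventional small-data configuration, exposed in `RunConfig`. No
subsampling: given the split, fitting is deterministic.

Feature importance is impurity (Gini) importance: SSE reductions summed per
feature within a tree, averaged over trees, normalized to 1. Predictions
match scikit-learn's `GradientBoostingRegressor` (same hyperparameters)
bit-for-bit on the synthetic study; importances match except where two
features induce *identical* partitions (exact ties — e.g. tmax = tmean +
constant in the simulator), which either implementation attributes
arbitrarily. The cross-check test therefore asserts identical top-3 ranking
on the full-size study, where tie mass is negligible relative to the gaps.

Evaluation: seeded 80/20 split (train size = round(0.8·n)); R² = 1 −
SSE/SST about the *test* mean (reported as undefined when the test response
is constant); MAE; and permissible-error accuracy, the fraction of test
samples within ±0.3 / ±0.6 GPC percentage points.

## Interpretation

Partial dependence is computed exactly: for each grid value the feature is
overwritten in every reference row and predictions averaged — no quantile
approximation of the average, no ICE subsampling. The grid is the sorted
unique values when ≤ `max_grid` (default 10), otherwise empirical quantiles
at evenly spaced probabilities. 1-D profiles are centered at the leftmost
grid point (read as "change relative to the low end"); 2-D surfaces are
left uncentered so cells read as absolute predicted GPC.

The broken-stick fit y = a + b₁(x−c) for x ≤ c, a + b₂(x−c) for x > c is
continuous at c with three free parameters. c is profiled over interior
observed x values (two extreme unique values excluded per side so both
segments keep support), solving OLS at each candidate; ties go to the
smaller c. The single-line OLS SSE is reported alongside so callers can
judge whether the break is real (the piecewise SSE can never exceed it).
`n_boot` resamples give a 95 % percentile CI for c.

## Synthetic study design

`generate_weather` draws one county-season (1 Sep–31 Jul, fixed window
covering any realistic sowing and maturity): daily mean temperature is a
sinusoid with minimum mid-January (annual mean 13 °C at 38° N, half-range
14.5 °C, −0.8 °C per degree latitude northward) plus iid N(0, 2.5 °C) noise;
tmax/tmin bracket it by ±5.5 °C; RH ~ N(57, 12) % clamped to [0, 100];
precipitation is Bernoulli(0.15) wet days with Exp(4 mm) amounts; sunshine
~ N(5.65 + 0.35·(lat − 38), 2) h/day clamped at 0. `generate_dataset`
additionally gives every county persistent offsets N(0, 0.6 °C) and
N(0, 0.6 h/day) to its temperature level and sunshine mean. These offsets
matter: without them weather is a *deterministic* function of latitude, all
season-mean temperature features become perfect latitude proxies, and no
attribution method could distinguish them; real counties differ by
elevation, aspect and local cloudiness. The settings were calibrated once
so long-run window summaries resemble a North China Plain wheat band —
filling→maturity mean temperature ≈ 24.6 °C, whole-season sunshine
≈ 1510 ± 160 h straddling the 1500 h threshold, filling→maturity GDD
≈ 506 ± 10 straddling 515, filling→maturity RH ≈ 57 ± 2 % straddling 59 —
and then frozen.

GPC per cultivar record is baseline 14.0 % + a broken-stick latitude ramp
(−0.4 %/deg south of 38.0° N, +0.25 %/deg north) + 0.5 %·1[whole-season
sun > 1500 h] + 0.4 %·1[filling→maturity GDD ≥ 515] + 0.3 %·1[filling→
maturity RH ≥ 59 %] + N(0, 0.5 %). Effects were sized so the total signal
is comparable to the ~0.9 % GPC standard deviation seen in regional
surveys. The default study is 40 counties (latitudes evenly spaced
36.2–40.0° N) × 4 harvest years × 3 cultivar replicates.

What the generator does *not* emulate: spatial correlation between
counties, day-to-day weather autocorrelation, extreme events (e.g. a
season-dominating rainstorm), cultivar genetic differences (replicates
differ only by noise), and trends across years. Passing recovery tests
therefore show the chain can detect threshold-plus-ramp structure under
realistic confounding and noise — not that real GPC obeys this surface.

### Recovery behaviour and a known bias

The latitude–sunshine confounding is deliberate (sunnier north), so the
+0.5 % sunshine step's 1500 h crossing sits near 38° N. Its latitude-blurred
sigmoid adds curvature south of the latitude kink, giving the raw-data
broken-stick breakpoint a small southward bias: over 20 simulated studies
the estimate is 37.90 ± 0.34° N against the true 38.0 (the estimator itself
is exact on noiseless broken sticks and lands within ±0.3 in ≥ 90 % of
clean noisy replicates). Equally, importance credit can be shared with
strongly correlated windows (regreening→maturity sunshine proxies
whole-season sunshine). Both behaviours are properties of attribution under
confounding, not implementation defects; single-seed recovery tests sit in
this stochastic regime, and one such assertion can fail for an unlucky
dataset draw.

## Orchestration and problem sizes

`run_pipeline` fans a single global seed out to per-stage child seeds by
fixed offsets (dataset +0, split +1, bootstrap +2), so stages are
independently reproducible; outputs embed no timestamps and re-running a
config reproduces every file byte-for-byte. Test-suite and demo problem
sizes (40×4 study, 100-tree models, 100-replicate Monte-Carlo loops) were
chosen so the whole suite runs in well under a minute on one CPU while
keeping the Monte-Carlo assertions' binomial noise small.
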