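# Methods

This note documents the models the package implements, the choices made
where the methods literature leaves room, and what the synthetic-data
generator does and does not emulate.

## Growth rates from fluorescence series

Chlorophyll-a fluorescence (RFU) proxies cell density, so exponential
growth is a straight line in ln(RFU) vs time. Readings below the
detection limit — half the median fluorescence of blank media — are
removed before the log (strict `<` comparison, so a reading exactly at the
limit is kept). Four candidate mean models are fit to each well:

| model | segments | parameters p |
|---|---|---|
| exponential | one line | 2 |
| lag | flat level, then line | 3 |
| saturation | line, then flat level | 4 − 1 = 3 |
| lag_saturation | flat, line, flat | 4 |

Segments are disjoint partitions of the observed timepoints with at least
two points per segment; within a partition each segment is fit exactly
(segment mean / segment OLS line), and the partition is found by
enumerating the time grid. This makes the least-squares search exact and
identical to a brute-force scan (a property the test suite asserts), and
it means μ is always the OLS slope of the line-segment points, estimated
the same way in every model. Negative μ is legitimate (declining wells)
and propagated; downstream stages decide exclusion. Lag/saturation times
are reported as the intersection of the fitted line with the adjacent flat
level, which is well defined even when a point sits exactly on two
segments.

Models are compared with the Gaussian constant-dropped AICc,
`n·ln(rss/n) + 2p + 2p(p+1)/(n−p−1)`, where p counts mean-model parameters
(breakpoints included, error variance not); only differences matter for
selection. A model enters the candidate set only when n ≥ p + 2 so its
AICc is finite — except the plain exponential, which is always fit for
n ≥ 3 (at n = 3 it is the only candidate and carries AICc = +∞). Ties are
broken toward fewer parameters. Wells with fewer than 3 usable points are
excluded and counted.

## Thermal performance curves

Growth rate vs temperature follows the Thomas-2012 form
`R(T) = a·e^{bT}·(1 − u²)`, `u = (T − T_ref)/(w/2)`, which is zero at
T_ref ± w/2 (the thermal niche edges) and whose optimum has the closed
form `T_opt = T_ref + b·h²/(1 + √(1 + b²h²))`, h = w/2 — algebraically
equal to `T_ref + (√(1+b²h²) − 1)/b` but continuous at b = 0.

Fitting is multi-start nonlinear least squares (scipy `least_squares`,
trust-region-reflective, analytic Jacobian) with starts drawn uniformly
inside generous boxes: a ∈ (0, 10], b ∈ [−1, 1], T_ref ∈ [0, 40] °C,
w ∈ (5, 80] °C; one deterministic start (a = 0.2, b = 0.05,
T_ref = mean(T), w = 2.5·range(T)) is always included so the multi-start
result can never be worse than that single documented start. 250 starts
by default; fits to all-nonpositive rates are flagged non-estimable.

AUTPC is the trapezoidal integral of the *fitted* curve on a 0.1 °C grid
over the experimental range 12–26 °C (the grid always hits the endpoints,
so a constant curve integrates exactly).

Activation energy: over the rising part of the TPC (observations with
μ > 0 and T ≤ T_opt; if T_opt exceeds the warmest level, every positive
observation — an `empirical` mode using the temperature of maximal mean
rate is available, fitted-T_opt is the default), ln μ is regressed on
1/(kT_K), k = 8.62 × 10⁻⁵ eV K⁻¹, T_K = T °C + 273.15. We report
**Ea = −slope**, so rates that rise with temperature give Ea > 0,
consistent with R = A·e^{−Ea/kT}. At least 3 points at ≥ 3 distinct
temperatures are required; per strain, the Ea values across phosphorus
levels are summarized by mean, SD and a two-sided one-sample t-test
against 0.32 eV (with identical values the test degenerates to t = 0,
p = 1 on the reference).

## Monod kinetics and P*

μ = μ_max·S/(K_s + S) is fit per strain × temperature by the same
multi-start scheme within μ_max ∈ (0, 5] day⁻¹ and K_s ∈ (10⁻⁴, 100]
μmol·L⁻¹ (log-uniform starts for K_s, plus a heuristic start at
μ_max ≈ max μ, K_s ≈ median S). Negative rates are included by default —
the Monod form cannot go negative, so they penalize the low-S region —
and can be dropped with a switch. A fit whose K_s lands on a bound is
flagged (`boundary_hit`): flat curves are degenerate for K_s.

P* = K_s·m/(μ_max − m) with m = 0.1 day⁻¹ (a configurable loss/dilution
rate). Fits with negative K_s or P*, μ_max ≤ m, or a boundary hit are
excluded from K_s/P* trait analyses; μ_max is retained whenever the fit
converged. P* is undefined at μ_max = m (raises).

## Bootstraps

Both the TPC band and the Monod intervals use the nonparametric **case
bootstrap**: each resample draws n observations with replacement from the
(x, μ) pairs, the model is refit (from the point estimate plus a few
random starts), and 2.5/97.5 percentiles form the 95% interval (pointwise
over a 0.1 °C grid for the TPC band; per parameter and for the derived P*
for Monod, along with the bootstrap-mean P* as a sanity check against the
point estimate). Resamples that lose too many distinct levels (< 4
temperatures, < 3 substrate levels) or whose refit fails are skipped and
counted. B = 1000 by default.

Resampling is deliberately *not* stratified by level: a calibration
experiment (200 simulated experiments at the generator's default noise,
truth-in-interval frequency for nominal 95% intervals) measured stratified
percentile intervals at 87–90% coverage versus 91–93% unstratified —
stratification shrinks the variability of resamples and narrows the
intervals. Residual resampling was better calibrated still (95–97%) but
case resampling is the standard reading of "resampled datasets" and is
kept as the default.

## Trait-response smooths

Penalized regression splines with a natural cubic basis on k = 3 knots
(quantiles of the distinct gradient values), an integrated squared second
derivative penalty, a sum-to-zero constraint absorbed by
reparameterization, and an unpenalized intercept. The penalty null space
is then exactly the linear trend, so the smooth's effective degrees of
freedom run from 1 (straight line) to k − 1 = 2 (unpenalized). The
smoothing parameter minimizes the Gaussian REML criterion
`(n − M_p)·log(P(λ)) + log|X'X + λS| − rank(S)·log λ` (P = penalized RSS,
M_p = penalty null-space dimension), optimized on a log-λ grid plus local
refinement. On a shared fixture this implementation agrees with R's mgcv
(`s(x, k = 3, bs = "cr")`, REML) to ~7 decimal places in EDF and deviance
explained; the agreement is asserted in the test suite, with mgcv as the
independent reference.

When a plain line already fits the data essentially exactly the REML
scale profile degenerates (σ̂² → 0); that case is detected and returns the
straight-line fit (EDF = 1) directly.

The smooth-term p-value is an approximate F-test of the penalized fit
against the intercept-only model on (EDF, n − EDF_total) degrees of
freedom. It tests "any relationship", linear included, which matches how
EDF = 1 fits with small p are read as significant linear responses; like
all GAM smooth-term p-values it is approximate. Deviance explained is
1 − RSS/TSS; for penalized fits this equals the squared correlation
between fitted and observed values only approximately (the tests allow a
0.02 discrepancy). Linearity is classified by EDF < 1.5 (linear) vs
≥ 1.5 (nonlinear); the threshold dichotomizes the observed gap between
EDF ≈ 1.0 and EDF ≈ 1.6–2.0 responses and is configurable.

## Lake environment

Growing-season summaries are two-stage means — within-year mean of
August–October measurements at 5 m depth (± 1 m tolerance; records with
missing depth are treated as integrated samples and pass through), then an
unweighted mean across 2018–2022 — so unevenly sampled years carry equal
weight. Phosphorus is summarized the same way but never modeled (it shows
no seasonal cycle at these depths).

Sparse temperature series are densified with OLS of temperature on
(decimal year, sin 2π·dayfrac, cos 2π·dayfrac): a linear trend plus one
annual harmonic (≥ 8 records spanning ≥ 2 years required; same-day-of-year
designs are rank deficient and rejected). The modeled seasonal mean
averages six predicted dates per year placed at the midpoints of six
equal subintervals of [Aug 1, Nov 1). Midpoint placement matters: an
endpoints-inclusive grid overweights the window edges and misses the dense
seasonal mean by ~0.15 °C at a typical 6 °C annual amplitude, while
midpoints agree within ~0.03 °C, which keeps modeled and direct summaries
consistent (± 0.1 °C) on dense series.

## Two-stage local adaptation analysis

Stage 1: per experimental temperature, OLS of a strain trait (canonically
P*) on the lake environmental variable (canonically total phosphorus,
μg·L⁻¹) across strains; strains with an excluded trait at that temperature
or without lake chemistry are dropped from that regression only; fewer
than 3 complete pairs makes the estimate untestable. Stage 2: weighted
least squares of the stage-1 slopes on experimental temperature with
weights 1/SE², so precise slopes dominate; requires ≥ 3 testable slopes
and rejects zero SEs. The machinery is generic over any trait / lake
variable pair. Stage-1 regressions are fit independently per temperature
(no pooling or interaction model), and no multiple-testing correction is
applied across trait–environment combinations.

## Synthetic-data generator

Each synthetic strain carries a growth surface
R(T, S) = μ_max(T)·S/(K_s(T) + S) with μ_max(T) a Thomas-2012 curve
(a ~ U(0.15, 0.30) day⁻¹, b ~ U(0.04, 0.08) °C⁻¹, T_ref ~ U(16, 22) °C,
w ~ U(28, 40) °C — rates of 0.2–1.2 day⁻¹ over the experimental range,
typical of mesophilic freshwater diatoms) and
K_s(T) = K_base + s·(T − T_min)², K_base ~ U(0.5, 2.5) μmol·L⁻¹,
T_min ~ U(14, 17) °C. The quadratic gives the U-shaped P*(T) expectation,
with its minimum low enough that K_s mostly rises over 12–26 °C. The
curvature is s = 0.002 + strength·0.003·(lake P in μg·L⁻¹): a
deterministic increasing function of source-lake phosphorus (drawn
U(5, 60) μg·L⁻¹, oligotrophic to eutrophic), identical across strains at
strength 0. That is the planted local-adaptation signal the end-to-end
tests detect.

Observation model: per well a lag is drawn from Exponential(mean
lag_mean ~ U(0.1, 0.4) days — short, as for acclimated cultures); the
latent density starts at 10 RFU, grows at R(T, S) and optionally saturates
logistically at a 500 RFU carrying capacity (so warm, phosphorus-rich
wells saturate within 6 days and exercise the saturation models);
observed RFU is latent × mean-one lognormal noise with CV 0.10.
Fluorescence noise scaling with signal motivates the multiplicative form
(it also preserves positivity); the 10% CV is a stated default of the
study conditions. Readings below the 2.25 RFU detection floor are emitted
unchanged — filtering is the pipeline's job. Blank media fluoresce
lognormally around 4.5 RFU (5% CV), so the half-median detection limit
lands near 2.25 RFU.

Lake records: monthly temperature with a 6 °C annual harmonic peaking in
late July, a 0.03 °C yr⁻¹ trend and 0.5 °C noise; lake mean temperature
rises mildly with lake phosphorus (the positive correlation seen across
peri-alpine lakes); total phosphorus scatters (2% CV) around the strain's
true source-lake concentration with no seasonal cycle.

What the generator does **not** emulate: plate effects and well position
biases, evaporation drift, instrument saturation at high density beyond
the logistic cap, truly negative growth (R(T, S) ≥ 0 by construction, so
detection-floor crossings arise only from low inocula, not death),
intracellular quota (Droop) dynamics, and strain-level phylogenetic
correlation. Passing end-to-end tests therefore demonstrate correctness
of the estimation machinery under a realistic noise model, not robustness
to every artifact of real plate-reader data.

All stochastic operations take explicit integer seeds; the pipeline
expands one master seed into independent per-stage seeds via
`numpy.random.SeedSequence(seed).spawn`, recorded in the run manifest, so
any stage is reproducible in isolation.

## Problem sizes used by the test suite

Replicated studies run at sizes chosen to give tight Monte-Carlo error
while keeping the suite practical on one CPU: 200 end-to-end replicates
each for the planted-signal and null studies; 200 simulated experiments
for Monod recovery and bootstrap coverage (B = 200 per experiment); 30
replicates × B = 60 for the TPC band coverage check; 200 fits for the
EDF-under-linearity and Arrhenius-bias checks. Defaults in the package
itself stay at the full sizes (B = 1000, 250 TPC starts).

## Known limitations

- The growth models are segment partitions, not smooth (Baranyi/Gompertz)
  curves; breakpoint uncertainty is not propagated into μ's SE.
- Percentile bootstrap intervals undercover slightly (~92% measured for
  nominal 95% at n = 24); bias-corrected variants were not implemented.
- The smooth-term p-value is a coarse approximation; EDF, not p, should
  carry the linearity interpretation.
- Stage-1 regressions treat strains as independent; lakes that share
  genotypes or environmental drivers violate that silently.
- Monod fits at a single temperature assume phosphorus is the only
  limiting resource; colimitation is out of scope.
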