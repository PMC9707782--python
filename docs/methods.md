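# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
places where the design was genuinely open.

## Detection events and effort

A detection record opens a new independent event when it is at least the
independence gap (default 30 min) after the *immediately preceding record*;
a gap exactly equal to the threshold counts as independent. The alternative
reading — measuring the gap from the event's opening record, which splits
very long bursts — is available via `independent_events(...,
from_event_start=True)`; the two coincide except on pathological record
streams. Events are per site and per species, and a sow with cubs is a
single event (an upstream classification concern; each record row is one
detection).

Month boundaries use the site's civil time at a fixed configurable UTC
offset (default −8 h, Pacific Standard Time). No daylight-saving logic is
applied: the study envelope is a single fixed-offset region and keeping the
offset explicit makes diel labels invariant to the offset the timestamps
happened to be stored in. Site-months with zero active days are retained in
the table but dropped (with a count) at model time, since the log-effort
offset is undefined; the monthly detection *rate*
(count/effort × days-in-month) is likewise flagged missing, not zero, at
zero effort.

## Solar geometry

Sunrise and sunset come from the NOAA/Meeus low-precision solar position
series with the conventional −0.833° rise/set altitude (solar radius plus
standard refraction), evaluated once at solar noon and refined once at the
event time. A year-long sweep at the study latitude agrees with an
independent Fourier-series ephemeris (Spencer's expansion) to within that
series' own ~3–4 minute truncation accuracy; minute-level agreement is far
tighter than the minutes-scale precision the day/night classification
needs. Latitudes at or beyond 66.5° are rejected explicitly: polar day and
night are outside the supported regime, and silently returning degenerate
times would corrupt diel labels.

## Covariate extraction

Raster covariates are averaged over a 150 m disc buffer with each cell
weighted by the area of its intersection with the disc. Intersection areas
are estimated by regular sub-cell sampling (32 × 32 points per cell by
default) rather than exact circle–square geometry: the approximation error
at the default resolution is far below the ecological signal, it handles
missing cells uniformly (excluded from numerator and denominator), and the
resolution is an explicit, tested knob. Conflict reports are counted in a
500 m disc with boundary points included (distance ≤ radius).

The monthly vegetation index weights each 16-day composite window by the
number of days it shares with the focal calendar month, then applies the
same disc-buffer average to the window's raster; zero total overlap yields
a missing value. Distance-to-feature layers (urban, agriculture,
freshwater) are consumed as precomputed grids or per-site values —
polygon geoprocessing is out of scope — and the per-season conflict
probability surface is an input whose upstream uncertainty is not
propagated.

Continuous covariates are standardized with the sample (n−1) standard
deviation; a constant column is an error naming the column. Collinearity
screening flags pairs at |Pearson r| ≥ 0.7 — the absolute value, since
collinearity is sign-agnostic.

## The count model

The observation model for site-month counts is a zero-inflated negative
binomial with a site random intercept and a log-effort offset. Zero
inflation is intercept-only on the logit scale; this is the minimal mixture
that accommodates the ~80% zero site-months and it exactly reproduces the
published candidate tables' parameter accounting (k = fixed effects +
random-intercept SD + dispersion + zero-inflation intercept; e.g. 13 for
the conflict-hypothesis model with the trail×human-density interaction).
Both NB parameterizations are available: NB1 with variance μ(1+α)
(size μ/α, success probability 1/(1+α)) and NB2 with variance μ(1+μ/θ)
(size θ). Factor terms use treatment coding with spring as the season
reference and a configurable stratum reference (wild by default);
continuous-by-factor "interaction" terms expand to the interaction columns
only, with main effects listed explicitly, and polynomials are raw (not
orthogonal) on the standardized covariates.

### Marginal likelihood and optimization

The random intercept is integrated out per site with adaptive Gauss–Hermite
quadrature: a safeguarded Newton iteration finds each site's posterior mode
and curvature (analytic first and second derivatives of the zero-inflated
NB log density with respect to the random effect, including the
digamma/trigamma terms the NB1 size parameterization requires), and 15
Hermite nodes are centred and scaled there. One node recovers the Laplace
approximation; the test suite holds the default against brute-force
trapezoid integration to better than 1e−6 relative. The optimizer is
L-BFGS-B on [β, logit π, log dispersion, log σ] from five documented
starting points (a moments-based start — intercept at log of the overall
detection rate — plus four seeded variations of the zero-inflation and
random-effect scale); the best optimum is kept and refits under the same
seed are bit-identical. Log-scale parameters are clamped to wide bounds
(e.g. log dispersion ∈ [−20, 25]) purely to keep optimizer excursions from
under/overflowing. Standard errors come from the central-difference Hessian
at the optimum; Wald p-values are reported without multiple-testing
correction, mirroring standard practice for this analysis type.

AICc uses n = the number of site-month rows entering the fit (702 under the
default design). The effective sample size for a mixed model is ambiguous
(rows vs sites); rows is the convention adopted and documented here. Akaike
weights are normalized over whatever model collection is compared, and the
published-table presentation rule (report sub-models within 2 ΔAICc of
their set's best) is exposed as a `retained` flag. The seasonal-conflict
candidate list is fit under both NB1 and NB2 with the lower-AICc family
retained. The published seasonal table's df column is internally
inconsistent for two rows (values 87 and 4 cannot follow from any term
accounting); parameter counts here are always derived from the model
specification instead.

## Nocturnality inference

The log risk ratio RR = ln(X_h/X_l) compares nocturnal proportions between
a disturbed class and the wild class; its variance is
1/O_h,night − 1/O_h + 1/O_l,night − 1/O_l. The observed 95% interval is
Wald on the log-ratio scale with z = 1.960 — the construction that uniquely
reproduces both published intervals from the published point estimates and
the variance formula. Any zero cell makes the ratio undefined and is an
explicit error rather than a sentinel value.

The null distribution re-assigns the observed detections (diel labels
fixed) to urban/rural/wild classes uniformly at random, preserving the
observed class totals — the randomization consistent with fixed sampling
effort per stratum. Implementation draws the per-class night counts by
sequential hypergeometric sampling, which is exactly the permutation
distribution but order-invariant and vectorized; iterations producing an
empty cell are recorded as missing and excluded from the interval with a
logged count. The 95% highest-density interval of the null is the shortest
contiguous window of sorted draws containing ⌈0.95 n⌉ points, ties broken
toward the lower start. A shift is declared significant when the observed
CI and the null HPDI are disjoint; a shared endpoint counts as overlap
(the conservative direction).

With 1000 null draws the HPDI endpoints carry Monte-Carlo noise of roughly
0.015–0.025 on the log-ratio scale, so repeated runs scatter by a few
hundredths; tests compare against converged (large-draw) endpoint values
with a tolerance derived from that noise. Season-stratified risk ratios are
implemented (`by_season=True`) but disabled by default: at study-sized
counts the per-season cells are too small for stable ratios.

The decision rule's operating characteristics at study-sized counts
(77/368/103 detections), measured by simulation in the test suite rather
than assumed: under a shared nocturnal probability the CI/HPDI overlap rule
rejected in 0% of 500 replicates (it is conservative — the two intervals
jointly cover far more than 95%), and under a true log risk ratio of 0.8 it
rejected in 62% (urban-sized) and 90% (rural-sized) of replicates.

## Spatial diagnostics

Moran's I is computed on per-site means of Pearson residuals,
(observed − fitted mean)/√fitted variance under the zero-inflated marginal
distribution evaluated at the population level (random intercept at zero).
Weights default to inverse Euclidean distance with zero diagonal,
row-standardized; neither the residual type nor the weight scheme is
canonical for this diagnostic, so both are recorded in the output and a
user-supplied weight matrix is accepted. The permutation p-value is
one-sided for positive autocorrelation, p = (1 + #{I* ≥ I})/(n_perm + 1) —
the sidedness under which a negative I with p near 1 is the natural
"no autocorrelation" outcome.

## The synthetic-data generator

The generator emulates the study conditions, not bear biology: 54 sites
(11 urban, 19 rural, 24 wild; overridable) over 13 months from July 2018;
monthly effort as binomial active days with activity probability 0.78
(chosen so total effort ≈ 16.5k camera-days); counts from the exact
zero-inflated NB mixed model above under a default truth of
log-link coefficients (intercept −4.27 at wild, +0.90 urban, +1.66 rural,
vegetation-index effect 0.34 per SD), NB2 dispersion θ = 0.4, zero-inflation
π = 0.39 and site SD σ = 0.8. The intercepts and π were calibrated
analytically (Gauss–Hermite integration of the zero probability over the
random effect and covariate distribution) so the default design lands at a
~80% zero fraction and stratum detection totals near 77/368/103 — the
study's stated summary conditions. Per-stratum nocturnal probabilities
default to 40/77, 173/368 and 23/103, the day/night splits recovered by
integer inversion of the published risk ratios and intervals.

Covariates have stratum-level structure (human/road/trail density,
elevation, land-use distances with stratum-dependent log-normal scales; a
summer-peaked sinusoidal vegetation index; autumn-only salmon presence near
freshwater; conflict probability peaked at intermediate human density and
in autumn). Detection timestamps are placed uniformly inside the correct
solar day/night window on a random day of the month, re-drawn if closer
than the independence gap to another event at the site, so the event
pipeline reproduces the simulated counts and diel labels exactly.

What the generator does *not* emulate — and therefore what passing tests do
not demonstrate about field data: animal movement and home-range overlap
(counts are conditionally independent across months given the site
intercept, with no temporal autocorrelation beyond the seasonal covariate),
detectability differences among camera models, covariate measurement error,
spatially autocorrelated habitat beyond the stratum blocks, and
reporting bias in conflict data. Recovery and calibration results validate
the estimation machinery under the model's own assumptions.

## Problem sizes used in validation

Frequentist calibration of the fitter uses 200 simulated studies of 200
sites × 13 months with a single-covariate truth (Wald coverage 90–98%
band); model selection uses 50 replicates at 150 sites with two moderate
effects (0.35 SD⁻¹); decision-rule error rates use 500 replicates at the
study's detection totals. These sizes give binomial noise on the measured
rates of 1–2 percentage points, small against the tested bands.
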