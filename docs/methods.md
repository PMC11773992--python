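# Methods

`mobrisk` implements a complete digital-phenotyping analysis chain for
short-term suicide-risk research in intensive longitudinal cohorts: raw
smartphone GPS streams are reduced to daily mobility features, aggregated
into survey-aligned weekly panels, decomposed into within- and
between-person terms, and related to rare weekly binary outcomes through a
random-intercept logistic model, with two predictive-validation designs on
top. A synthetic cohort generator with fully known ground truth makes
every stage testable in the absence of shareable raw data.

## Daily mobility features

Each fix receives a **dwell** weight: the forward interval to the next
fix, capped at `gap_cap_s` (default 30 min) so observation gaps do not
inflate any location's time; the last fix of a local day is credited up to
the cap or local midnight, whichever is sooner. A day's *observed span* is
its total assigned dwell, which bounds homestay by construction.

**Location clusters** come from a greedy sequential pass: fixes in time
order join the nearest existing cluster whose dwell-weighted centroid lies
within `radius_m` (default 200 m) or open a new cluster. The radius test
runs in a per-participant equirectangular projection (error < 0.1% at city
scale); all reported distances use the haversine formula with Earth radius
6371.0088 km. The procedure is deterministic and O(n·K).

**Home** is the centroid of the cluster with the largest summed dwell in
the 02:00–06:00 window over the whole observation period; ties break by
total dwell, then earliest first visit. Participants with no night-window
fixes are excluded from homestay analyses (an explicit error, mirroring
exclusion of participants without usable geolocation).

Daily features:

* **homestay** (h): dwell within 200 m (haversine) of home;
* **entropy** (nats): Shannon entropy −Σ pᵢ ln pᵢ of the day's dwell
  fractions over clusters. Natural log is used; the base only rescales a
  feature that is later z-scored, so inference is invariant;
* **distance** (km): sum of consecutive-fix haversine segments, after
  dropping segments implying > 300 km/h (GPS teleports) and segments
  shorter than `min_segment_m` (default 150 m). The second filter matters:
  with 25 m isotropic jitter the stationary step length is Rayleigh with
  scale ≈ 35 m, and summing those steps inflates a day's path by
  kilometres; 150 m is ≈ 6 Rayleigh scales (tail mass ~10⁻⁴), so true
  movement at fix cadence passes while noise is removed. Both filters are
  configurable and off-able.

## Weekly panels

Weeks run Wednesday 00:00 to Tuesday 24:00 local time (weekly surveys go
out Wednesdays); week 0 starts on the Wednesday on or before enrollment.
A weekly feature is the arithmetic mean of available daily values; weeks
with fewer than 3 GPS days keep their row but carry missing features.

Suicidal **events** (actual/aborted/interrupted attempts, suicide-related
ED visits, psychiatric hospitalizations) are merged before weekly
flagging: an ED visit or hospitalization within 7 days *after* an attempt
by the same participant is the same event and keeps the attempt's date;
attempts never merge with each other. The merge is idempotent.
**Clinically meaningful ideation** on a responded weekly survey means
ideation frequency ≥ 4 (1–5 scale) or an endorsed plan; non-responded
weeks are missing outcomes and are dropped from ideation panels (no
imputation). Event outcomes are exhaustively ascertained, so weeks with
no record count as 0.

Each feature is decomposed into

* a **within-person** term, (x_it − x̄_i) / SD_w, where SD_w is the SD of
  *all* person-centred values pooled across the sample — a unit is "1 SD
  above one's own mean" on a scale common to everyone; and
* a **between-person** term, (x̄_i − grand mean of person means) / SD of
  person means.

Participants with fewer than two feature-bearing weeks get missing within
terms. A lag-L panel pairs the outcome in week T with within terms from
week T−L (between terms are constant), plus weeks-since-baseline as a
covariate; the reversed-direction builder pairs the event indicator at
T−1 with each within-person feature at T as a continuous outcome for OLS.

## The random-intercept logistic model

For participant i, week t:

    y_it ~ Bernoulli(logit⁻¹(x_itᵀβ + u_i)),   u_i ~ N(0, σ_u²)

The marginal likelihood integrates u_i out per participant. Each
one-dimensional integral is evaluated by **adaptive Gauss–Hermite
quadrature**: with the standardized parameterisation u = σv, the
integrand's mode v̂_i is found by a vectorised Newton iteration (the
objective is strictly concave in v) and the 25 default nodes are recentred
at v̂_i and scaled by the posterior curvature. Results at 25 vs 51 nodes
agree to < 10⁻⁶, and the likelihood matches brute-force trapezoid
integration (20 001 points, ±10σ) to 10⁻⁸ relative on small fixtures.

The variance is optimised as ln σ_u (unconstrained); σ_u = 0 is handled by
an analytic plain-logistic branch. Gradients differentiate the quadrature
approximation with the adaptive centring frozen at the current parameters;
the resulting error is of the same order as the quadrature error itself.
Optimisation runs L-BFGS-B from a deterministic start (β from an IRLS
logistic fit, σ_u = 0.5) followed by Newton polishing; the covariance of
the fixed effects is the corresponding block of the inverse observed
information, computed as a central-difference Jacobian of the analytic
score. On simulated panels the full fit agrees with `lme4::glmer`
(nAGQ = 25) to ~10⁻⁴ in coefficients, SEs, σ_u and log-likelihood.

Quasi-separation (any |β_j| > 15 on standardized columns) triggers a
deterministic ridge-penalised refit (default strength 0.5, intercept
unpenalised), flagged `penalized` in all reports. Wald intervals
(exp(β ± z·SE)) are used throughout because published tables in this
literature are symmetric on the log-odds scale; p-values are two-sided
Wald. Note that at the σ_u = 0 boundary the MLE of σ_u is positive on
roughly half of null datasets (the usual boundary mixture); the degenerate
branch, not the stochastic estimate, is what reduces to plain logistic
regression.

## Predictive validation

**AUC** uses the Mann–Whitney formulation with midrank ties, equal to
trapezoidal ROC integration; it is implemented in-package (and verified
against exhaustive pairwise counting) because the validation machinery is
part of what is under test.

**Leave-future-out**: each participant's panel weeks are split at the
midpoint of their own span; models are fit on pooled first halves and
score only later weeks, using fixed effects alone — random intercepts are
excluded so that a participant's past outcomes cannot predict their future
ones. Five model cards are compared: all-geolocation, homestay-only,
baseline-only (SSI, site, sex, age, device), homestay+baseline, and
all+baseline. AUC uncertainty is a percentile bootstrap (default 2000
resamples of test rows, i.i.d.; a per-participant stratified option is not
currently provided). "Above chance" means the lower 95% bound ≥ 0.5.

**Between-person**: daily features averaged over the first 28 days from
enrollment (≥ 12 observed days required) predict which participants have
any event (or any ideation week) afterwards; a plain logistic model per
card is refit over repeated random 70/30 participant splits (default
10 000), reporting the mean AUC and the 2.5/97.5 percentiles of the AUC
distribution. Splits without a test-side positive are redrawn and counted.
A caution from the package's own calibration runs: repeated splits of one
finite *null* dataset give a mean AUC slightly below 0.5 (train and test
deviations from a ~zero full-sample association are anti-correlated), so
the meaningful null check is "never flagged above chance", not "mean
exactly 0.5".

## The synthetic cohort

The generator emulates the study conditions the analysis assumes: 186
participants × 26 weeks, one fix per 10 minutes (the cadence is a
configurable convention, not a measured value), whole days missing
completely at random with probability 0.25, weekly survey response 0.41,
event intercept −4.7 (≈ 1% weekly rate before random-intercept spread),
a within-person homestay log-odds of ln 2 at lag 1, and a participant
random intercept with SD 0.6.

Each participant has a home and 4 anchor sites 0.6–5 km away (≥ 2× the
200 m radius, keeping homestay and entropy identifiable). The daily
at-home fraction follows a logit-AR(1) process (ρ = 0.6); the night window
is spent at home on 95% of days so the night-window home rule is well
posed. A second, independent AR(1) "evenness" process controls how
away-time spreads over anchors via a Dirichlet concentration. Fixes at
segment transitions sit mid-leg (a fix caught in transit) and all fixes
get isotropic Gaussian jitter (default SD 25 m). Events draw from the
random-intercept logistic model on the *latent* standardized lagged
features, with dates uniform inside the week and occasional ED/hospital
follow-up records within 7 days to exercise the merge rule; baseline SSI
correlates 0.4 with the random intercept so baseline-feature models have
signal. Everything derives from one seed through named substreams; output
files are byte-identical across runs.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: multiple or moving homes, indoor GPS dropout
correlated with place, informative missingness (an MCAR day-dropout knob
only), measurement differences between phone platforms, and within-week
timing of risk. One intrinsic feature deserves emphasis: dwell-share
entropy is mathematically dominated by the home share, so synthetic
homestay and entropy within-person terms correlate strongly (≈ −0.9),
more than typical real data; joint-model coefficients on synthetic
cohorts are therefore wide, and single-feature models are the right
readout for the generative homestay effect.

## Monte-Carlo experiment scales

The self-validation experiments simulate weekly panels directly from the
generative model (no GPS layer) at the study's scale: 186 participants ×
25 weeks, homestay log-OR ln 2, σ_u 0.6, intercept −4.6 (≈ 1.4% weekly
event rate). Parameter recovery uses 200 replicates (bias vs 2 Monte-Carlo
SEs; 95% Wald coverage), the type-I error check 400 null replicates, and
the leave-future-out power/calibration runs 50 replicates each with
2000-fold bootstraps. These sizes give binomial standard errors of ~1.5%
on coverage and ~1.1% on the rejection rate.

## Known limitations

* One home per participant; moves or second homes bias homestay downward.
* The greedy clustering is order-dependent by design (deterministic), and
  running centroids can drift; a density-based alternative would change
  cluster boundaries but not the dwell-fraction entropy materially.
* The bootstrap resamples test rows i.i.d.; within-participant
  correlation of weeks makes the intervals slightly anti-conservative.
* The separation fallback is ridge-penalised maximum likelihood, not a
  Bayesian refit; its tuning constant is a convention.
* Between-person validation inherits the finite-split pessimism described
  above; comparisons between cards are fair, absolute levels are not.
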