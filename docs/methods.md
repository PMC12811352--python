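# Methods

## Scientific setting

Grey and harbour seals are central-place foragers: they make discrete
foraging trips from terrestrial haulout sites, and their at-sea movement
alternates between fast, directed transit and slow, tortuous area-restricted
search (ARS), the conventional movement proxy for foraging. This package
implements a multi-scale version of that inference: a discrete-time hidden
Markov model (HMM) in which ARS is split into a *broad* scale (intermediate
speed and tortuosity) and a *focussed* scale (lowest speed, highest
tortuosity), plus two a-priori *known* states, followed by nested binomial
habitat-association models that ask which seabed and water-column habitats
each ARS scale is associated with, given the habitat was encountered along
the track.

## The movement model

Telemetry is regularised to 2-h intervals (midpoints of the tag's dive
summary intervals, positions by linear interpolation between cleaned GPS
fixes). Each interval carries a step length `l_t` (Euclidean km between
consecutive midpoint positions), a turn angle `phi_t` in (-pi, pi], a dive
proportion `omega_t`, and a reliability flag.

States:

* **Known states.** Seals must surface to breathe and can spend at most
  88.8% of a 2-h interval underwater. An interval with `omega_t < 0.444`
  (half that maximum) is coded non-diving (`N`) a priori — haulout or
  surface activity. An interval flagged unreliable (missing summary data or
  a fix gap strictly greater than 6 h around the midpoint) is coded unknown
  (`Unk`). Known states enter the likelihood by masking: at such an interval
  the emission vector is zeroed on every other state. At unflagged diving
  intervals `N` and `Unk` are masked out — the model knows those intervals
  are movement.
* **Movement states.** Transit (`Tr`), broad ARS (`bARS`) and focussed ARS
  (`fARS`), or a single merged `ARS` state in the 4-state variant.

Emissions, per emitting state `z`:

* `l_t | Z_t = z ~ Gamma(mean mu_z, SD sigma_z)` (shape `mu_z^2/sigma_z^2`,
  scale `sigma_z^2/mu_z`), optionally mixed with a point mass `pi_z` at
  exactly zero. The zero mass is estimated only for states that can actually
  see zero steps in the data (by default the non-diving state, whose haulout
  intervals have zero displacement); the Gamma density is undefined at zero,
  so the atom is both a numerical and a biological necessity.
* `phi_t | Z_t = z ~ wrapped Cauchy(0, gamma_z)`, `gamma_z` in [0, 1); the
  mean angle is fixed at zero for biological interpretability. `gamma_z = 0`
  is the circular uniform.
* `Unk` emits nothing; it participates only through the transition matrix
  and masking. Missing streams contribute a likelihood factor of 1.

Estimation is by direct maximum likelihood: a scaled forward recursion over
each individual's full regularised series (one HMM sequence per individual),
optimised by L-BFGS on an unconstrained re-parameterisation (log for
`mu`/`sigma`, logit for `gamma`/`pi`, multinomial logit for transition rows
and the initial distribution). The gradient is computed exactly from
forward–backward sufficient statistics (smoothed state probabilities and
expected transition counts) passed through the chain rule of the working
parameterisation; this makes a 30,000-interval fit a matter of seconds per
start. 25 random initial-value sets (configurable) are drawn between
biologically motivated bounds — mean steps in [0.01, 1], [1, 5] and [5, 12]
km for the three movement states, SDs in [0.2, 1.5] x the mean, angle
concentrations in [0.01, 0.95], transition-matrix diagonals in [0.6, 0.95] —
and the best optimum is kept, with the full restart table retained for
inspection. After fitting, movement states are relabelled by ascending mean
step so the slowest distribution is focussed ARS and the fastest is transit.

Decoding uses the Viterbi algorithm under the same masks (ties broken toward
the lower state index); local state probabilities come from forward–backward
smoothing; goodness of fit from one-step-ahead forecast pseudo-residuals
(forecast CDF of each stream under the state-probability mixture, mapped
through the standard normal quantile; the atom at zero steps uses the
mid-point of the CDF jump, a deterministic analogue of randomised PIT).

Model order (4 vs 5 states) is compared by BIC, `-2 logL + p log(T)` with
`T` the number of intervals carrying at least one observed emission stream
(BIC's effective sample size under partly missing data is genuinely
ambiguous; this choice is conservative and recorded here). BIC is treated as
a guideline: the order-selection report also includes the overlap
coefficients of fitted step-length densities and the per-individual
difference in decoded ARS intervals between orders, supporting a pragmatic
final choice rather than a purely metric-driven one.

## Preprocessing rules

Printed thresholds are implemented exactly as stated, with boundary
semantics chosen once and documented:

* fixes kept with >= 5 satellites and residual error <= 25 (inclusive);
* unreliable flag for fix gaps strictly > 6 h; non-diving for `omega`
  strictly < 0.444; dive proportions above 0.888 clamped with a warning;
* trips are maximal at-sea runs between haulout events; dry-at-sea events
  shorter than 10 min are treated as erroneous and ignored (a simplified
  stand-in for the full erroneous-haulout protocol);
* trips starting within 168 h of capture and trips shorter than 8 h are
  excluded; seasons are clipped per species (grey: May–September; harbour:
  September–May; boundary months inclusive);
* trips whose start and end haulouts lie in different regions are split at
  the temporal midpoint, the first `floor(n/2)` intervals to the departure
  region ("midpoint" is undefined for odd lengths; floor is the convention
  here);
* coordinates are planar km throughout; inputs are assumed projected.
  Geographic inputs would need an external projection step — geodesy is out
  of scope.

## Habitat covariates

The original (not regularised) fix series is densified to 1-min spacing by
piecewise-linear interpolation, each timestamp appearing once. Habitat
layers are looked up at every dense point by nearest cell (no bilinear
smoothing, for consistency with the categorical layers), and points are
assigned to 2-h intervals half-open on the right. Within an interval, PEA
(potential energy anomaly, J/m^3 — the energy needed to fully mix the water
column; intermediate values mark tidal-mixing fronts) is summarised by the
median, and seabed geomorphology and substrate by the mode, ties broken by
the earliest occurrence within the interval. Intervals whose points all lack
habitat data are flagged and excluded from modelling.

## Nested binomial habitat models

Movement-state intervals (non-diving and unknown excluded) are coded into
two stacked binary responses: (i) ARS (focussed or broad) = 1 versus transit
= 0, and (ii) focussed = 1 versus broad = 0 within ARS rows. Each is
modelled on the logit scale with

* treatment-coded categorical terms up to the three-way interaction
  region x geomorphology x substrate;
* optionally a cubic-spline smooth of PEA, by default one smoother per
  region, with a curvature penalty plus a null-space (double) penalty so an
  uninformative smooth can be penalised entirely to zero — the "select"
  device. The basis dimension `k` is chosen over the grid {4, 5, 6, 8, 10}
  by minimum AIC;
* a per-individual Gaussian random intercept, implemented as ridge-penalized
  dummy coefficients, preventing data-rich individuals from dominating.

Fitting is penalized IRLS; each smoothing parameter and the random-intercept
precision are updated by the generalized Fellner–Schall step, which ascends
the Laplace-approximate restricted marginal likelihood (REML). Every penalty
is diagonal after an eigen-reparameterisation of the spline penalty (the
constant direction of each smooth's null space is dropped to keep the model
identifiable against the intercept and categorical terms), which makes the
updates cheap and numerically robust. The coefficient covariance is the
Bayesian posterior approximation `(X'WX + S)^{-1}`; effective degrees of
freedom are `tr[(X'WX + S)^{-1} X'WX]`, and AIC is the conditional
`deviance + 2 edf`.

Backwards model selection drops, at each step, the candidate term whose
removal yields the lowest AIC, provided that AIC does not exceed the current
one by more than 2 (the boundary counts as removable), honouring marginality
(no main effect is dropped while an interaction containing it remains).

Predictions use posterior sampling: 1000 coefficient vectors drawn from
`N(beta_hat, cov)` per model, random intercepts set to zero (population-level
curves), inverse-logit per draw. Draws from the two models are taken
independently — they are fitted on nested but distinct response sets — and
multiplied: `P(fARS) = P(ARS|enc) P(fARS|ARS)` and
`P(bARS) = P(ARS|enc) - P(fARS)`. Storing the propagated pair and defining
`P(ARS|enc)` as their sum makes the propagation identity exact in floating
point (the reported `P(ARS|enc)` differs from the raw draw by at most one
ulp). Habitat combinations with fewer than 100 observations are suppressed
from default prediction grids.

State-assignment uncertainty is propagated by redrawing, per interval, a
state from the HMM's local state probabilities, rebuilding the responses,
refitting both models and repeating 100 times; the spread of predictions
across iterations is compared with the posterior spread. Deviance residuals
are checked for within-individual serial autocorrelation at lags 1–10
against +-1.96/sqrt(n) white-noise bands.

## The synthetic-data generator

No telemetry is distributed with this package, so every input is generated:

* **Tracks** are simulated from the movement HMM itself, using the fitted
  parameter sets published for grey and harbour seals in the southern North
  Sea (step means/SDs 0.09/0.09, 3.38/1.76, 7.63/2.18 km for grey focussed
  ARS, broad ARS and transit; 0.07/0.06, 2.70/1.50, 6.41/2.19 km for
  harbour; concentrations 0.07/0.53/0.81 and 0.005/0.46/0.76 — the harbour
  focussed-ARS concentration is published only as "< 0.01" and 0.005 is used
  here). Movement-state transition rows combine the published switching
  probabilities with self-transitions as row complements. The full 5-state
  chain needs rows into and out of `N` and `Unk`, which are not published;
  the package uses small plausible leak probabilities (6% to `N`, 2% to
  `Unk` from each movement state) and its own `N`/`Unk` rows. The initial
  state is the stationary distribution. Step units are km per 2-h interval
  (the source never states units; at these magnitudes km is the only
  biologically plausible reading). Positions are planar dead reckoning;
  an initial heading is uniform. Dive proportions are drawn from scaled
  Beta(2, 2) distributions on (0.444, 0.888) for movement states and
  (0, 0.444) for the non-diving state — only the threshold and the cap are
  specified anywhere, so the Beta shape is a stand-in choice.
* **Seascapes** are smooth Gaussian random fields thresholded at quantiles
  into geomorphology (peak / steep slope / gradual slope / trough) and
  substrate (sand / gravel / rock reef / mud) patches; PEA is a softplus of
  a smoother random field scaled to roughly 0–60 J/m^3; regions are
  contiguous bands, each containing one haulout site. Grids are written as
  plain-text rasters with a JSON legend.
* **Habitat-driven states** are generated by the nested binomial model
  itself: two Bernoulli draws per interval from logit-linear predictors over
  the habitat layers with Normal(0, sd^2) per-individual intercepts, with the
  generating probabilities stored alongside for recovery tests.

What the generator does *not* emulate — and hence what passing tests cannot
show about real data: Fastloc-GPS error structure, tidal haulout
availability, serial correlation of habitat along real trajectories (dense
points here are looked up on smooth synthetic fields), inter-annual
variation, and any misspecification of the emission families themselves.
Recovery tests demonstrate that the estimators are correct and well
calibrated under the stated model, not that the model is right for seals.

## Problem sizes and numerical choices

Recovery runs use 60 tracks of 500 intervals (30,000 intervals per species),
matched to the scale at which the published parameters are distinguishable
within Monte-Carlo error; GAMM recovery uses 100 individuals x 500 intervals
(50,000 rows, random-intercept SD 0.5); order-selection property runs use 6
tracks of 250 intervals and 10 seeds per direction; interval-coverage checks
use 50 replicate fits. Optimiser convergence: relative log-likelihood change
below 1e-11 or gradient norm below 1e-6; restarts whose optima differ by
less than ~1 log-likelihood unit are treated as the same optimum. Outer
(smoothing) iterations stop when no log smoothing parameter moves by more
than 1e-3, with update factors clamped to [1/30, 30] per step and lambda to
[1e-7, 1e8]. Forecast CDF values are clamped to [1e-12, 1 - 1e-12] before
the normal quantile.

## Known limitations

* The known-state masks make the likelihood of `N`-state emission parameters
  separable; if a dataset contains no coded `N` intervals the 4/5-state fits
  degrade gracefully but the `N` parameters are unidentified.
* The Fellner–Schall/PQL-style variance estimation carries the usual small
  downward bias for binary data with few observations per individual; with
  the sample sizes used here the bias is well inside the acceptance
  tolerances, but sparse designs should expect attenuated random-intercept
  SDs.
* Backwards AIC selection explores single-term removals only; it will not
  find a better model reachable only through a non-greedy path.
* The covariate extractor assumes fixes dense enough that 1-min linear
  interpolation is sensible; multi-hour gaps produce long straight dense
  segments whose habitat summaries inherit that artefact (mirroring the
  flagged-unreliable logic upstream).
* The command-line entry points are deliberately not provided: this is an
  analysis library, and the documented functions plus `scripts/acceptance.py`
  are its interface.
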