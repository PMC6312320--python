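# Methods

## Psychometric model

A stop-trial at delay `ssd` fails (signal-respond) with probability
given by a lapse-bounded sigmoid.  The logistic form, used throughout
the simulations,

    p(error | ssd) = e + (1 − 2e) / (1 + exp(−k (ssd − θ)))

has threshold θ (ms; the critical SSD, where the probability is exactly
0.5), rate k (1/ms) and lapse/error rate e ∈ [0, 0.5), which bounds the
function inside [e, 1 − e] at both ends.  The Weibull form
`e + (1 − 2e)(1 − 2^(−(ssd/θ)^k))` (dimensionless shape k) is provided
for threshold-space sessions; it shares the θ-at-0.5 property.  The
multiplicative lapse composition is the only one that keeps the
function normalised while preserving that property.  At θ = 0 the
Weibull is defined by its limit (0.5 at ssd = 0, upper bound above), so
grids may include zero.

The lapse term has a generative reading: if a participant's recorded
response is inverted on a random fraction e of stop-trials, the
observed error probability is `e + (1 − 2e) F(ssd + SSRT)` with F the
Go-RT distribution function — exactly a lapse-bounded sigmoid (a
property test checks this against the ex-Gaussian CDF).

## Grid-Bayesian SSD selection

Candidate parameter vectors live on a 3-axis lattice (primary ×
slope × error rate, primary = threshold or SSRT).  Starting from a
uniform prior, each observed outcome multiplies every cell by its
likelihood and renormalises.  Before each stop-trial, every candidate
SSD is scored by the posterior entropy expected after the trial,

    E[H](ssd) = Σ_r p(r | ssd) · H(p(· | ssd, r)),   r ∈ {success, error},

and the minimiser is presented.  `marginalize="primary"` computes H on
the posterior collapsed onto the primary axis (the marginal variant —
nuisance information about slope and lapse does not drive SSD choice);
`"none"` gives the original full-posterior criterion.

Numerical choices:

* Entropy in nats (the argmin is base-invariant); 0·log 0 := 0
  (`scipy.special.xlogy`).
* Expected entropy is accumulated as
  `Σ_r (−Σ_i a_i log a_i + Z_r log Z_r)` with `a_i` the unnormalised
  joint mass and `Z_r = Σ_i a_i`, avoiding explicit per-response
  normalisation; a response with zero predictive probability
  contributes zero.
* Posterior arithmetic is linear-space with per-update renormalisation;
  the grids in use (≤ ~17k cells) never approach underflow within a
  session.  An observation with zero likelihood in *every* cell raises
  `DegenerateUpdateError` (a mis-specified grid) rather than silently
  renormalising.
* Ties in the entropy scan resolve to the smallest candidate SSD
  (candidates ascending, first minimiser wins) for reproducibility.
* The kernels accept a leading batch axis on the mass array; the
  marginal-entropy scan runs as a threshold-batched matrix product, so
  a whole cohort of posteriors sharing one grid updates in single
  matrix operations.  The scalar controller API calls the same kernels.

## RT-adjusted controller

Threshold-space PSI fails under response slowing: the critical SSD
tracks `mean Go-RT − SSRT`, so when Go-RTs lengthen the posterior walks
into the top of its threshold grid and the estimate saturates.  The
adjusted controller instead estimates SSRT — a stable characteristic —
and re-derives the threshold each trial:

1. Predict the current mean Go-RT by OLS of recent includable Go-RTs on
   global trial number, evaluated at the current trial.  Window: at
   most 40 and at least 15 Go-trials (defaults); with fewer than 15 the
   scalar fallback (400 ms in simulations; sessions may seed it with
   the previous block's mean) is used instead of a partial fit.
   Excluded conditions (e.g. a certain-Go condition whose RTs differ
   systematically) never enter the fit.
2. Map every candidate SSRT s to a threshold `g − s` (g the predicted
   Go-RT) and rebuild the SSD candidates to span
   `[g − max(SSRT), g − min(SSRT)]`, endpoints rounded to the nearest
   50 ms step (half away from zero), clamped to the floor (0 ms) and
   optional cap; clamping may collapse the range to one candidate.
3. Run the marginal-entropy scan in SSRT space and update the
   posterior with the outcome, using the *selection-time* g for the
   likelihood so selection and update share one SSRT→threshold mapping
   within a trial.

With a flat Go-RT history the controller is trial-for-trial equivalent
to threshold-space PSI on the mirrored grid (tested).

## SSRT readouts

At any cut-point: mean method `mean(Go-RT) − mean(presented SSDs)`;
integration method `sorted Go-RTs[n] − mean(SSDs)` with
`n = round(p·N)` (half away from zero, clamped to [1, N]) and p the
signal-respond fraction; PSI readouts `mean Go-RT − E[θ]`
(threshold space) or `E[SSRT]` (SSRT space).  The critical-SSD summary
for both staircase readouts is the mean of *all* SSDs presented up to
the cut-point — the convention that exposes the early-trial bias of the
mean method, since pre-convergence SSDs do not yet correspond to
0.5 performance.  (The terminal or tail-averaged SSD would be an
alternative; the mean-of-all convention is the one whose bias the
slope-ordering results describe.)

## Virtual participants and what they do and do not emulate

Go-RTs are ex-Gaussian — Normal(μ, σ) plus Exponential(mean ν) — with
defaults μ = 360, σ = 40, ν = 40 ms (mean 400, variance 3200).  Draws
are not truncated; negative draws are astronomically rare at these
parameters.  Stop outcomes follow the race rule (error iff
Go-RT < ssd + SSRT) with an independent Bernoulli inversion of the
outcome at the configured rate.  Response slowing adds
`rate × completed stop-trials` to μ.

One caveat the simulator makes visible: the race rule's 0.5-crossing
sits at the *median* Go-RT, while the threshold relation uses the
*mean*; for the default ex-Gaussian the gap is ≈ 13 ms.  Small
systematic offsets of that order in recovered SSRTs are inherent, not
bugs.

The simulator emulates stationary or linearly-slowing RT means only: no
RT autocorrelation, no non-linear or strategic slowing schedules, no
trigger failures (stop process never starting), no condition structure.
Passing recovery tests therefore demonstrates estimator behaviour under
the race model's own assumptions, not robustness to their violation in
real data.

## Simulation studies

Each experiment simulates a 41-participant cohort (SSRTs 50–250 ms in
5 ms steps) for 100 stop-trials, each followed by two Go-trials (300
trials).  Controllers run in parallel on the same cohort; one Go-RT is
drawn per Go-trial slot and shared by all participants and controllers,
while each (controller, participant) pair receives its own latent
stop-trial Go-RTs and inversion draws.  Both staircase readouts share
one SSD stream.  Controller grids: thresholds 0–500 ms step 5, SSRTs
−100–400 ms step 5, slopes {0.003, 0.0052, 0.01, 0.019, 0.029, 0.04},
error rates 0–0.3 step 0.05, SSD candidates 0–500 ms step 50; staircase
from 250 ms, ±50 ms, floored at 0.

* Study 1: stationary RTs, inversion rates {0, 0.05, 0.1}.
* Study 2: slowing 5/10/15 ms per stop-trial via μ, inversion 0.05.
* Study 3: same slowing, threshold grids enlarged to 0–1000/1500/2000 ms
  (a 150 ms buffer beyond the cohort's largest critical SSD at trial
  100) and runs extended to the first trial at which every critical SSD
  has reached the grid maximum — 170/135/124 trials by closed form.

Per cut-point and estimator the harness computes cohort Pearson
correlation, mean absolute deviation and OLS slope of estimate on
truth, per experiment, then averages over experiments (pooling
inversion or slowing rates where a study reports a single curve);
uncertainty bands are the SEM over experiments.  Study 2's headline
curves are per-rate metrics averaged afterwards.  Optional diagnostics
record per-axis marginal entropies and the fraction of runs whose
maximum-probability primary value sits at a grid edge.

Problem sizes in the shipped tests and the acceptance script are 20
experiments per inversion rate (study 1), 20 per slowing rate
(study 2) and 10 per rate (study 3), master-seeded through
`numpy.random.SeedSequence` spawning (experiment → stream), which makes
runs bit-reproducible and enforces the Go-RT-sharing contract
structurally.  Monte-Carlo error scales as 1/√reps relative to the
50-experiment design.

## Known limitations

* The linear RT predictor cannot track non-linear RT drift; richer
  trend models (splines, ex-Gaussian parameter tracking) are out of
  scope.
* The adjusted method shows a small residual low-end SSRT drift for
  strongly slowing participants (under-predicted Go-RTs make long-SSD
  stops look too easy); no corrective mechanism is applied.
* After a cohort saturates at a threshold-grid boundary, cohort
  correlation becomes a degenerate statistic: estimate spread collapses
  to ~1 ms and the Pearson r then reflects a frozen micro-ordering
  (and any sub-ms noise source) rather than recoverable signal.  MAD
  and slope are the informative metrics in that regime.
* One-trial lookahead only; no particle or continuous-parameter
  posteriors; the regression window counts includable Go-trials after
  condition exclusion.
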