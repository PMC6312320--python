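# psistop

Adaptive stop-signal-delay controllers and SSRT estimation for the
stop-signal task.

In the stop-signal task a participant responds to Go-signals as fast as
possible; on a minority of trials a Stop-signal follows after a delay
(the stop-signal delay, SSD) and the response must be withheld.  Under
the independent horse-race model the response escapes whenever the
Go-process beats the Stop-process, i.e. when Go-RT < SSD + SSRT, where
the stop-signal reaction time (SSRT) is the latency of the covert
stopping process.  Estimating SSRT requires placing SSDs near the
*critical SSD* — the delay at which stopping fails half the time —
which obeys

    critical SSD  =  mean Go-RT − SSRT.

This package is for researchers who run or simulate stop-signal
experiments and need efficient, bias-aware SSD placement:

* **Staircase** — the classical one-up/one-down tracker (±50 ms steps).
* **PSI** — grid-Bayesian adaptive selection: keep a posterior `p(λ)`
  over candidate parameter vectors λ = (threshold, slope, lapse rate) of
  a psychometric function `p(error | SSD, λ)` (logistic or Weibull,
  lapse-bounded), and present the SSD minimising the expected posterior
  entropy `E[H] = Σ_r p(r|SSD) · H(p(λ|SSD, r))`.  The *marginal*
  variant minimises the entropy of the posterior marginalised onto the
  threshold axis, ignoring the nuisance slope and lapse parameters.
* **RT-adjusted PSI** — the same machinery re-parameterised over
  ω = (SSRT, slope, lapse rate).  Each stop-trial the current mean Go-RT
  is predicted by sliding-window linear regression (15–40 most recent
  Go-trials on trial number, 400 ms fallback), every candidate SSRT is
  mapped to a threshold via `threshold = predicted Go-RT − SSRT`, and
  the candidate SSD range is rebuilt to span those thresholds.  Because
  SSRT, unlike the critical SSD, does not drift when participants slow
  their responses, the posterior stays inside its grid under response
  slowing — the failure mode of threshold-space PSI.

SSRT readouts: *mean method* (mean Go-RT − mean presented SSD),
*integration method* (p-quantile Go-RT − mean SSD, with p the
signal-respond fraction), and posterior expectations for the PSI
variants.  A race-model participant simulator (ex-Gaussian Go-RTs,
optional linear slowing, fixed response-inversion rate) and a
cohort-level simulation harness reproduce parameter-recovery studies of
estimator bias and precision.

## Worked example

```python
import numpy as np
from psistop import (Session, SessionConfig, TrialRecord,
                     VirtualParticipant, sample_go_rt, stop_trial_outcome)

rng = np.random.default_rng(7)
truth = VirtualParticipant(true_ssrt=180.0)   # ex-Gaussian Go-RTs, mean 400 ms
session = Session(SessionConfig.from_preset("sim1", method="psi_adjusted",
                                            primary_axis=tuple(np.arange(-100., 401., 5.))))
index = 0
for _ in range(40):                            # 40 stop-trials, 2 go-trials each
    index += 1
    ssd = session.next_trial_ssd()
    outcome = stop_trial_outcome(truth, ssd, sample_go_rt(truth, rng), rng)
    session.record_trial(TrialRecord(index, "stop", ssd=ssd, outcome=outcome))
    for _ in range(2):
        index += 1
        session.record_trial(TrialRecord(index, "go", go_rt=sample_go_rt(truth, rng)))
    print(f"trial {index:3d}  ssd {ssd:5.0f}  E[SSRT] {session.ssrt_estimate():6.1f}")
```

The first stop-trial uses the 400 ms fallback grid (SSDs 0–500 ms); the
printed `E[SSRT]` trace converges on the true 180 ms:

```
trial   3  ssd   250  E[SSRT]  210.0
trial   6  ssd   200  E[SSRT]  156.4
trial   9  ssd   250  E[SSRT]  197.4
...
trial 114  ssd   200  E[SSRT]  186.8
trial 117  ssd   250  E[SSRT]  188.9
trial 120  ssd   200  E[SSRT]  192.1
```

`ssd` hovers around the implied critical SSD (~220 ms), which is where
stop-trials are most informative about SSRT.

The simulation studies are driven from the CLI:

```sh
psistop simulate --preset sim2 --experiments 10 --seed 0 --out scratch/sim2
psistop report --out scratch/sim2
```

which prints, per estimator, the terminal-trial cohort correlation, mean
absolute deviation (ms) and regression slope of estimated on true SSRT.
`psistop replay --log <file>` rebuilds controller state and the SSRT
estimate from a plain-text trial log.

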