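"""Virtual stop-signal-task participants.

Go-RTs follow an ex-Gaussian distribution (Normal(mu, sigma) plus an
independent Exponential with mean nu; expected RT mu + nu).  Stop-trial
outcomes follow the independent horse-race model: the response escapes
(signal-respond) iff the latent Go-RT beats the stop process, i.e.
Go-RT < SSD + SSRT.  A fixed inversion rate flips the outcome on a random
subset of stop-trials, which generatively produces the lapse-bounded
psychometric function the PSI grids assume.  Strategic response slowing
is modelled as a linear increase of mu per completed stop-trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["VirtualParticipant", "sample_go_rt", "stop_trial_outcome", "apply_slowing"]


@dataclass(frozen=True)
class VirtualParticipant:
    true_ssrt: float
    mu: float = 360.0
    sigma: float = 40.0
    nu: float = 40.0
    slowing_per_stop_trial: float = 0.0
    inversion_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.nu <= 0:
            raise ValueError("sigma and nu must be positive")
        if not 0.0 <= self.inversion_rate <= 0.5:
            raise ValueError("inversion_rate must lie in [0, 0.5]")

    @property
    def mean_go_rt(self) -> float:
        return self.mu + self.nu


def sample_go_rt(participant: VirtualParticipant, rng: np.random.Generator, size=None):
    """Ex-Gaussian Go-RT draw(s); no truncation or flooring."""
    return rng.normal(participant.mu, participant.sigma, size) + rng.exponential(
        participant.nu, size
    )


def stop_trial_outcome(
    participant: VirtualParticipant, ssd: float, go_rt: float, rng: np.random.Generator
) -> str:
    """Race-model outcome with Bernoulli(inversion_rate) response inversion."""
    error = go_rt < ssd + participant.true_ssrt
    if participant.inversion_rate > 0 and rng.random() < participant.inversion_rate:
        error = not error
    return "error" if error else "success"


def apply_slowing(participant: VirtualParticipant, completed_stop_trials: int) -> VirtualParticipant:
    """Participant with mu shifted by slowing_per_stop_trial x completed stop-trials."""
    if completed_stop_trials < 0:
        raise ValueError("completed_stop_trials must be >= 0")
    return replace(
        participant,
        mu=participant.mu + participant.slowing_per_stop_trial * completed_stop_trials,
    )
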