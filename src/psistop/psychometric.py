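"""Psychometric functions linking stop-signal delay to stop-failure probability.

Both models map an SSD (ms) to the probability of a signal-respond
("error") outcome on a stop-trial.  They are lapse-bounded sigmoids: the
``error_rate`` parameter keeps the function inside
``[error_rate, 1 - error_rate]`` at both ends, and the ``threshold`` is the
SSD at which the failure probability is exactly 0.5.

* ``logistic``: p(error) = e + (1 - 2e) / (1 + exp(-k (ssd - thr)))
  with rate ``k`` in 1/ms.
* ``weibull``:  p(error) = e + (1 - 2e) (1 - 2^(-(ssd/thr)^k))
  with a dimensionless shape ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import expit

__all__ = ["Model", "PsychometricParams", "p_error", "p_success"]

_LN2 = np.log(2.0)


class Model(str, Enum):
    WEIBULL = "weibull"
    LOGISTIC = "logistic"


def _validate(slope, error_rate) -> None:
    slope = np.asarray(slope, dtype=float)
    error_rate = np.asarray(error_rate, dtype=float)
    if np.any(slope <= 0) or not np.all(np.isfinite(slope)):
        raise ValueError("slope must be positive and finite")
    if np.any(error_rate < 0) or np.any(error_rate >= 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")


def p_error(ssd, threshold, slope, error_rate, model: Model | str = Model.LOGISTIC):
    """Probability of a failed stop (signal-respond) at ``ssd``.

    All arguments broadcast; returns an ndarray (or scalar) of
    probabilities in ``[error_rate, 1 - error_rate]``.
    """
    _validate(slope, error_rate)
    ssd = np.asarray(ssd, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    slope = np.asarray(slope, dtype=float)
    error_rate = np.asarray(error_rate, dtype=float)
    model = Model(model)
    span = 1.0 - 2.0 * error_rate
    if model is Model.LOGISTIC:
        core = expit(slope * (ssd - threshold))
    else:
        if np.any(ssd < 0):
            raise ValueError("weibull model requires ssd >= 0")
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            ratio = np.where(threshold > 0, ssd / np.where(threshold > 0, threshold, 1.0), np.inf)
            core = -np.expm1(-_LN2 * np.power(ratio, slope))
        # threshold == 0 by limit convention: 0.5 at ssd == 0, upper bound above.
        core = np.where(threshold > 0, core, np.where(ssd > 0, 1.0, 0.5))
    out = error_rate + span * core
    return out if out.ndim else float(out)


def p_success(ssd, threshold, slope, error_rate, model: Model | str = Model.LOGISTIC):
    """Probability of a successful stop; the complement of :func:`p_error`."""
    out = 1.0 - np.asarray(p_error(ssd, threshold, slope, error_rate, model))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PsychometricParams:
    """One candidate performance vector.

    ``threshold`` is the critical SSD in ms (or, in SSRT-space grids, the
    SSRT in ms), ``slope`` the steepness (1/ms for logistic, dimensionless
    for Weibull), ``error_rate`` the lapse bound in [0, 0.5).
    """

    threshold: float
    slope: float
    error_rate: float
    model: Model = Model.LOGISTIC

    def __post_init__(self) -> None:
        _validate(self.slope, self.error_rate)

    def p_error(self, ssd):
        return p_error(ssd, self.threshold, self.slope, self.error_rate, self.model)

    def p_success(self, ssd):
        return p_success(ssd, self.threshold, self.slope, self.error_rate, self.model)
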