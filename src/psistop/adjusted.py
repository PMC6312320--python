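"""Reaction-time-adjusted PSI controller.

Instead of estimating the critical SSD (which drifts when participants
slow their Go-responses), this controller estimates the SSRT directly.
Each stop-trial it (1) predicts the current mean Go-RT by sliding-window
linear regression of recent Go-RTs on trial number, (2) maps every
candidate SSRT to a threshold via ``threshold = predicted_go_rt - ssrt``,
(3) rebuilds the candidate SSD range to span exactly the thresholds the
SSRT axis implies, and (4) runs the marginal-entropy PSI selection in
SSRT space.  Because the SSRT is a stable characteristic of the
participant, the posterior does not walk into a grid boundary when
Go-RTs slow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psi import (
    ConfigurationError,
    Marginalize,
    ParameterGrid,
    Posterior,
    error_likelihood_table,
    expected_entropy_scan,
    uniform_prior,
    update_mass,
)

__all__ = ["RtPredictor", "AdjustedController", "ssrt_to_threshold", "build_ssd_grid"]


def ssrt_to_threshold(ssrt: float, mean_go_rt: float):
    """Critical SSD implied by an SSRT under the race model: mean Go-RT - SSRT.

    May be negative; SSD grids clamp at their floor, this mapping does not.
    """
    return mean_go_rt - ssrt


def _round_to_step(x: float, step: float) -> float:
    # round half away from zero, to the nearest multiple of step
    return np.floor(x / step + 0.5) * step


def build_ssd_grid(
    predicted_go_rt: float,
    ssrt_axis: np.ndarray,
    step: float = 50.0,
    floor: float = 0.0,
    cap: float | None = None,
) -> np.ndarray:
    """Candidate SSDs spanning the thresholds implied by the SSRT axis.

    Endpoints ``predicted_go_rt - max(ssrt)`` and ``predicted_go_rt -
    min(ssrt)`` are rounded to the nearest multiple of ``step``, clamped to
    ``[floor, cap]``, and filled inclusively in steps of ``step``.  A range
    collapsed by clamping yields a single-candidate grid.
    """
    ssrt_axis = np.asarray(ssrt_axis, dtype=float)
    if ssrt_axis.size == 0:
        raise ConfigurationError("ssrt axis must be non-empty")
    if step <= 0:
        raise ConfigurationError("step must be positive")
    lo = _round_to_step(predicted_go_rt - ssrt_axis.max(), step)
    hi = _round_to_step(predicted_go_rt - ssrt_axis.min(), step)
    lo = max(lo, floor)
    hi = max(hi, floor)
    if cap is not None:
        lo, hi = min(lo, cap), min(hi, cap)
    if hi < lo:
        lo, hi = hi, lo
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass
class RtPredictor:
    """Sliding-window OLS predictor of the current mean Go-RT.

    Go-RTs from includable Go-trials are regressed on their global trial
    number over the most recent ``max_window`` trials; with fewer than
    ``min_window`` includable trials the scalar ``fallback_rt`` is used
    instead of a partial fit.
    """

    min_window: int = 15
    max_window: int = 40
    fallback_rt: float = 400.0
    _trials: list[int] = field(default_factory=list)
    _rts: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.min_window <= self.max_window):
            raise ConfigurationError("need 1 <= min_window <= max_window")

    def add(self, trial_index: int, go_rt: float, include: bool = True) -> None:
        """Record one Go-trial RT; excluded trials never enter the fit."""
        if self._trials and trial_index <= self._trials[-1]:
            raise ValueError("trial_index must be strictly increasing")
        if include:
            self._trials.append(int(trial_index))
            self._rts.append(float(go_rt))

    @property
    def n_included(self) -> int:
        return len(self._trials)

    def predict(self, at_trial: int) -> float:
        """Predicted Go-RT at ``at_trial`` from the fitted trend line."""
        n = len(self._trials)
        if n < self.min_window:
            return float(self.fallback_rt)
        k = min(self.max_window, n)
        x = np.asarray(self._trials[-k:], dtype=float)
        y = np.asarray(self._rts[-k:], dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        return float(intercept + slope * at_trial)


class AdjustedController:
    """SSRT-space PSI controller with per-trial RT prediction and SSD rebuild."""

    def __init__(
        self,
        grid: ParameterGrid,
        predictor: RtPredictor | None = None,
        ssd_step: float = 50.0,
        ssd_floor: float = 0.0,
        ssd_cap: float | None = None,
        marginalize: Marginalize = "primary",
        prior: Posterior | None = None,
    ) -> None:
        if grid.primary_name != "ssrt":
            raise ConfigurationError("AdjustedController requires an SSRT-space grid")
        self.grid = grid
        self.predictor = predictor if predictor is not None else RtPredictor()
        self.ssd_step = float(ssd_step)
        self.ssd_floor = float(ssd_floor)
        self.ssd_cap = None if ssd_cap is None else float(ssd_cap)
        self.marginalize: Marginalize = marginalize
        self.posterior = prior if prior is not None else uniform_prior(grid)
        # predicted Go-RT cached at selection time so that selection and the
        # subsequent Bayes update share one SSRT->threshold mapping
        self._pending: tuple[int, float] | None = None

    def add_go_rt(self, trial_index: int, go_rt: float, include: bool = True) -> None:
        self.predictor.add(trial_index, go_rt, include)

    def next_ssd(self, at_trial: int) -> float:
        g = self.predictor.predict(at_trial)
        candidates = build_ssd_grid(
            g, self.grid.primary, self.ssd_step, self.ssd_floor, self.ssd_cap
        )
        table = error_likelihood_table(
            self.grid, candidates, thresholds=g - self.grid.cell_primary
        )
        eh = expected_entropy_scan(self.posterior.mass, table, self.grid.shape, self.marginalize)
        self._pending = (int(at_trial), g)
        return float(candidates[int(np.argmin(eh))])

    def predicted_go_rt(self, at_trial: int) -> float:
        """Predicted Go-RT that will map SSRTs to thresholds for this trial."""
        if self._pending is not None and self._pending[0] == at_trial:
            return self._pending[1]
        return self.predictor.predict(at_trial)

    def record_stop(self, at_trial: int, ssd: float, response: str) -> None:
        """Bayes-update the SSRT posterior with the trial's outcome.

        Uses the Go-RT predicted at selection time for this trial when
        available, so likelihoods match the grid the SSD was drawn from.
        """
        if response not in ("success", "error"):
            raise ValueError(f"response must be 'success' or 'error', got {response!r}")
        g = self.predicted_go_rt(at_trial)
        perr = error_likelihood_table(
            self.grid, np.atleast_1d(float(ssd)), thresholds=g - self.grid.cell_primary
        )[0]
        lik = perr if response == "error" else 1.0 - perr
        self.posterior = Posterior(self.grid, update_mass(self.posterior.mass, lik))
        self._pending = None
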