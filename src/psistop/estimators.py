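"""SSRT estimators: mean method, integration method, and posterior readouts.

The classical readouts subtract a critical-SSD summary from a Go-RT
summary.  Here the critical SSD is taken as the mean of all SSDs
presented up to the cut-point, matching the logic that a converged
staircase's SSDs average to the 0.5-performance point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psi import Posterior

__all__ = [
    "InsufficientDataError",
    "SessionSlice",
    "ssrt_mean_method",
    "ssrt_integration_method",
    "psi_ssrt",
    "integration_rank",
]


class InsufficientDataError(ValueError):
    """Raised when a slice has no Go-RTs or no stop-trials."""


@dataclass(frozen=True)
class SessionSlice:
    """Trial data accumulated up to a cut-point.

    ``responded[i]`` is True for signal-respond (failed) stop-trials.
    """

    go_rts: np.ndarray
    ssds: np.ndarray
    responded: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "go_rts", np.asarray(self.go_rts, dtype=float))
        object.__setattr__(self, "ssds", np.asarray(self.ssds, dtype=float))
        object.__setattr__(self, "responded", np.asarray(self.responded, dtype=bool))
        if self.ssds.shape != self.responded.shape:
            raise ValueError("ssds and responded must have matching lengths")

    def _check(self) -> None:
        if self.go_rts.size == 0 or self.ssds.size == 0:
            raise InsufficientDataError("need at least one Go-RT and one stop-trial")


def ssrt_mean_method(data: SessionSlice) -> float:
    """mean(Go-RT) minus mean presented SSD."""
    data._check()
    return float(data.go_rts.mean() - data.ssds.mean())


def integration_rank(p: float, n: int) -> int:
    """Rank n = round(p * N), half away from zero, clamped to [1, N]."""
    return int(min(max(np.floor(p * n + 0.5), 1), n))


def ssrt_integration_method(data: SessionSlice) -> float:
    """p-quantile Go-RT (p = signal-respond fraction) minus mean presented SSD."""
    data._check()
    p = float(data.responded.mean())
    n = integration_rank(p, data.go_rts.size)
    return float(np.sort(data.go_rts)[n - 1] - data.ssds.mean())


def psi_ssrt(posterior: Posterior, mode: str = "ssrt", mean_go_rt: float | None = None) -> float:
    """SSRT from a PSI posterior.

    ``mode="ssrt"``: E[SSRT] of an SSRT-space posterior.
    ``mode="threshold"``: mean_go_rt - E[Threshold] of a threshold-space
    posterior (``mean_go_rt`` required).
    """
    e_primary = posterior.expected()["primary"]
    if mode == "ssrt":
        return float(e_primary)
    if mode == "threshold":
        if mean_go_rt is None:
            raise ValueError("mean_go_rt is required in threshold mode")
        return float(mean_go_rt - e_primary)
    raise ValueError(f"mode must be 'ssrt' or 'threshold', got {mode!r}")
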