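"""Classical one-up/one-down staircase tracking of the stop-signal delay.

A successful stop raises the SSD by one step, a failed stop lowers it,
saturating at the floor/ceiling; in the long run the SSD hovers around
the point where the stop-failure probability is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["StaircaseState", "staircase_update", "StaircaseTracker", "STAIRCASE_PRESETS"]


@dataclass(frozen=True)
class StaircaseState:
    current_ssd: float
    step: float = 50.0
    floor: float = 0.0
    ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.ceiling is not None and self.ceiling < self.floor:
            raise ValueError("ceiling must be >= floor")
        if not (self.floor <= self.current_ssd <= (self.ceiling if self.ceiling is not None else float("inf"))):
            raise ValueError("current_ssd must lie within [floor, ceiling]")


def staircase_update(state: StaircaseState, response: str) -> StaircaseState:
    """Next state after a stop-trial: success -> +step, error -> -step, clamped."""
    if response == "success":
        ssd = state.current_ssd + state.step
    elif response == "error":
        ssd = state.current_ssd - state.step
    else:
        raise ValueError(f"response must be 'success' or 'error', got {response!r}")
    ssd = max(ssd, state.floor)
    if state.ceiling is not None:
        ssd = min(ssd, state.ceiling)
    return replace(state, current_ssd=ssd)


# start / step / floor / ceiling as used in the simulations and the two
# behavioural sessions
STAIRCASE_PRESETS: dict[str, StaircaseState] = {
    "simulation": StaircaseState(current_ssd=250.0, step=50.0, floor=0.0, ceiling=None),
    "experiment1": StaircaseState(current_ssd=250.0, step=50.0, floor=50.0, ceiling=1200.0),
    "experiment2": StaircaseState(current_ssd=250.0, step=50.0, floor=0.0, ceiling=2300.0),
}


class StaircaseTracker:
    """Mutable wrapper with the same next/record surface as the PSI controllers."""

    def __init__(self, state: StaircaseState) -> None:
        self.state = state

    @classmethod
    def from_preset(cls, name: str) -> "StaircaseTracker":
        return cls(STAIRCASE_PRESETS[name])

    def next_ssd(self) -> float:
        return self.state.current_ssd

    def record(self, ssd: float, response: str) -> None:
        self.state = staircase_update(self.state, response)
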