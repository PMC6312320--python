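"""Live-session driver, trial-log I/O and named configurations.

A :class:`Session` wraps one controller (staircase, PSI, or adjusted
PSI) behind a two-call surface for experiment software: ask
``next_trial_ssd()`` before a stop-trial, then ``record_trial()`` every
trial.  Trial logs are plain delimited text (comma or tab, sniffed from
the header) and a log replayed through the same configuration
reconstructs the controller state exactly — posteriors never need to be
serialized.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .adjusted import AdjustedController, RtPredictor
from .estimators import SessionSlice, psi_ssrt, ssrt_integration_method
from .harness import SIM_ERROR_RATE_AXIS, SIM_SLOPES, SIM_SSD_CANDIDATES, SIM_THRESHOLD_AXIS
from .psi import ConfigurationError, ParameterGrid, PsiController
from .psychometric import Model
from .staircase import StaircaseState, StaircaseTracker

__all__ = [
    "TrialRecord",
    "SessionConfig",
    "Session",
    "read_log",
    "write_log",
    "replay",
    "fallback_from_previous_block",
]

_COLUMNS = (
    "trial_index",
    "trial_type",
    "condition",
    "include_in_rt_prediction",
    "ssd",
    "go_rt",
    "outcome",
)


@dataclass(frozen=True)
class TrialRecord:
    """One trial: a go-trial carries ``go_rt``, a stop-trial ``ssd`` + ``outcome``."""

    trial_index: int
    trial_type: str                      # "go" | "stop"
    condition: str = ""
    include_in_rt_prediction: bool = True
    ssd: float | None = None
    go_rt: float | None = None
    outcome: str | None = None           # "success" | "error" for stop-trials

    def __post_init__(self) -> None:
        if self.trial_type == "stop":
            if self.ssd is None or self.outcome not in ("success", "error"):
                raise ValueError("stop records need ssd and outcome ('success'/'error')")
        elif self.trial_type == "go":
            if self.go_rt is None:
                raise ValueError("go records need go_rt")
        else:
            raise ValueError(f"trial_type must be 'go' or 'stop', got {self.trial_type!r}")


@dataclass(frozen=True)
class SessionConfig:
    """Controller choice plus the grids and SSD settings it needs."""

    method: str = "psi_marginal"         # staircase | psi_original | psi_marginal | psi_adjusted
    model: Model = Model.LOGISTIC
    primary_axis: tuple[float, ...] = tuple(SIM_THRESHOLD_AXIS)
    slope_axis: tuple[float, ...] = tuple(SIM_SLOPES)
    error_rate_axis: tuple[float, ...] = tuple(SIM_ERROR_RATE_AXIS)
    ssd_candidates: tuple[float, ...] = tuple(SIM_SSD_CANDIDATES)
    ssd_step: float = 50.0
    ssd_floor: float = 0.0
    ssd_cap: float | None = None
    rt_min_window: int = 15
    rt_max_window: int = 40
    fallback_go_rt: float = 400.0
    staircase_start: float = 250.0
    staircase_step: float = 50.0
    staircase_floor: float = 0.0
    staircase_ceiling: float | None = None
    seed: int | None = None

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SessionConfig":
        try:
            config = _PRESETS[name]
        except KeyError:
            raise ConfigurationError(f"unknown preset {name!r}") from None
        return replace(config, **overrides) if overrides else config

    @classmethod
    def from_file(cls, path) -> "SessionConfig":
        """Load a config from YAML; keys mirror the fields, ``preset`` seeds
        defaults and the remaining keys override it."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must be a key-value mapping")
        preset = data.pop("preset", None)
        base = cls.from_preset(preset) if preset else cls()
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        if "model" in data:
            data["model"] = Model(data["model"])
        for key in ("primary_axis", "slope_axis", "error_rate_axis", "ssd_candidates"):
            if key in data:
                data[key] = tuple(float(v) for v in data[key])
        return replace(base, **data)


# the simulation presets share one logistic configuration; "sim3" is the
# 5 ms/stop-trial variant with the enlarged threshold grid
_PRESETS: dict[str, SessionConfig] = {
    "sim1": SessionConfig(),
    "sim2": SessionConfig(),
    "sim3": SessionConfig(
        primary_axis=tuple(np.arange(0.0, 1001.0, 5.0)),
        ssd_candidates=tuple(np.arange(0.0, 1001.0, 50.0)),
    ),
    "experiment1": SessionConfig(
        method="psi_marginal",
        model=Model.WEIBULL,
        primary_axis=tuple(np.arange(50.0, 1201.0, 50.0)),
        slope_axis=tuple(np.arange(1.0, 14.0, 1.0)),
        error_rate_axis=tuple(0.05 * np.arange(11)),
        ssd_candidates=tuple(np.arange(50.0, 1201.0, 50.0)),
        staircase_floor=50.0,
        staircase_ceiling=1200.0,
    ),
    "experiment2": SessionConfig(
        method="psi_adjusted",
        model=Model.LOGISTIC,
        primary_axis=tuple(np.round(np.linspace(0.0, 600.0, 25))),
        slope_axis=tuple(SIM_SLOPES),
        error_rate_axis=tuple(0.05 * np.arange(11)),
        ssd_cap=2300.0,
        staircase_ceiling=2300.0,
    ),
}


def fallback_from_previous_block(go_rts: Sequence[float]) -> float:
    """Scalar Go-RT fallback seeded from a preceding block's Go-RTs."""
    go_rts = np.asarray(go_rts, dtype=float)
    if go_rts.size == 0:
        raise ValueError("need at least one Go-RT from the previous block")
    return float(go_rts.mean())


class Session:
    """Stateful driver dispatching to the configured controller."""

    def __init__(self, config: SessionConfig) -> None:
        self.config = config
        self.records: list[TrialRecord] = []
        method = config.method
        if method == "staircase":
            self.controller = StaircaseTracker(
                StaircaseState(
                    current_ssd=config.staircase_start,
                    step=config.staircase_step,
                    floor=config.staircase_floor,
                    ceiling=config.staircase_ceiling,
                )
            )
        elif method in ("psi_original", "psi_marginal"):
            grid = ParameterGrid(
                np.asarray(config.primary_axis),
                np.asarray(config.slope_axis),
                np.asarray(config.error_rate_axis),
                model=config.model,
                primary_name="threshold",
            )
            self.controller = PsiController(
                grid,
                np.asarray(config.ssd_candidates),
                marginalize="none" if method == "psi_original" else "primary",
            )
        elif method == "psi_adjusted":
            grid = ParameterGrid(
                np.asarray(config.primary_axis),
                np.asarray(config.slope_axis),
                np.asarray(config.error_rate_axis),
                model=config.model,
                primary_name="ssrt",
            )
            self.controller = AdjustedController(
                grid,
                RtPredictor(config.rt_min_window, config.rt_max_window, config.fallback_go_rt),
                ssd_step=config.ssd_step,
                ssd_floor=config.ssd_floor,
                ssd_cap=config.ssd_cap,
            )
        else:
            raise ConfigurationError(f"unknown method {config.method!r}")

    @property
    def next_trial_index(self) -> int:
        return (self.records[-1].trial_index + 1) if self.records else 1

    def next_trial_ssd(self) -> float:
        """SSD the controller wants for a stop-trial issued now."""
        if isinstance(self.controller, AdjustedController):
            return self.controller.next_ssd(self.next_trial_index)
        return self.controller.next_ssd()

    def record_trial(self, record: TrialRecord) -> None:
        if self.records and record.trial_index <= self.records[-1].trial_index:
            raise ValueError("trial_index must be strictly increasing")
        if record.trial_type == "go":
            if isinstance(self.controller, AdjustedController):
                self.controller.add_go_rt(
                    record.trial_index, record.go_rt, record.include_in_rt_prediction
                )
        else:
            if isinstance(self.controller, AdjustedController):
                self.controller.record_stop(record.trial_index, record.ssd, record.outcome)
            else:
                self.controller.record(record.ssd, record.outcome)
        self.records.append(record)

    def _slice(self) -> SessionSlice:
        go = [r.go_rt for r in self.records if r.trial_type == "go"]
        stops = [r for r in self.records if r.trial_type == "stop"]
        return SessionSlice(
            go_rts=np.asarray(go),
            ssds=np.asarray([r.ssd for r in stops]),
            responded=np.asarray([r.outcome == "error" for r in stops]),
        )
    def ssrt_estimate(self) -> float:
        """Current SSRT readout appropriate to the configured method."""
        if isinstance(self.controller, StaircaseTracker):
            return ssrt_integration_method(self._slice())
        if isinstance(self.controller, AdjustedController):
            return psi_ssrt(self.controller.posterior, mode="ssrt")
        data = self._slice()
        return psi_ssrt(
            self.controller.posterior, mode="threshold", mean_go_rt=float(data.go_rts.mean())
        )

    @property
    def posterior(self):
        return getattr(self.controller, "posterior", None)


def _format(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_log(records: Iterable[TrialRecord], path, delimiter: str = ",") -> None:
    """Write records as delimited text with a header row."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.trial_index, r.trial_type, r.condition,
                    _format(r.include_in_rt_prediction), _format(r.ssd),
                    _format(r.go_rt), _format(r.outcome),
                ]
            )


def _parse_field(name: str, raw: str, line: int):
    raw = raw.strip()
    if raw == "":
        return None
    try:
        if name == "trial_index":
            return int(raw)
        if name in ("ssd", "go_rt"):
            return float(raw)
        if name == "include_in_rt_prediction":
            if raw.lower() in ("true", "1", "yes"):
                return True
            if raw.lower() in ("false", "0", "no"):
                return False
            raise ValueError(raw)
    except ValueError:
        raise ValueError(f"line {line}: cannot parse {name}={raw!r}") from None
    return raw


def read_log(path) -> list[TrialRecord]:
    """Parse a trial log; the delimiter (comma/tab) is sniffed from the header."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise ValueError("empty log file (expected a header row)")
    delimiter = "\t" if "\t" in text[0] else ","
    reader = csv.reader(text, delimiter=delimiter)
    header = next(reader)
    if [h.strip() for h in header] != list(_COLUMNS):
        unknown = set(h.strip() for h in header) - set(_COLUMNS)
        raise ValueError(f"line 1: unexpected columns {sorted(unknown)}")
    records: list[TrialRecord] = []
    last_index = 0
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) != len(_COLUMNS):
            raise ValueError(f"line {line_no}: expected {len(_COLUMNS)} fields, got {len(row)}")
        values = {name: _parse_field(name, raw, line_no) for name, raw in zip(_COLUMNS, row)}
        if values["trial_index"] is None or values["trial_index"] <= last_index:
            raise ValueError(f"line {line_no}: trial_index must be strictly increasing")
        last_index = values["trial_index"]
        if values["include_in_rt_prediction"] is None:
            values["include_in_rt_prediction"] = True
        if values["condition"] is None:
            values["condition"] = ""
        try:
            records.append(TrialRecord(**values))
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from None
    return records


def replay(records: Iterable[TrialRecord], config: SessionConfig) -> Session:
    """Rebuild a session's controller state by replaying a trial log."""
    session = Session(config)
    for record in records:
        session.record_trial(record)
    return session
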