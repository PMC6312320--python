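"""Simulation studies comparing SSD controllers on virtual cohorts.

Three study designs are provided:

* study 1 — stationary Go-RTs, inversion rates {0, 0.05, 0.1};
* study 2 — linear Go-RT slowing of 5/10/15 ms per stop-trial via the
  ex-Gaussian mu, inversion rate 0.05;
* study 3 — the same slowing but with the marginal method's threshold
  grid enlarged so the cohort stays inside it until stop-trial 100, and
  the run extended until every cohort member's critical SSD has crossed
  the grid maximum.

Each experiment simulates a 41-participant cohort (true SSRTs 50-250 ms
in 5 ms steps) through 100 stop-trials each followed by two Go-trials.
The controllers run in parallel on the same cohort: every Go-trial RT is
drawn once and shared by all participants and controllers, while each
(controller, participant) pair gets its own latent stop-trial Go-RT and
inversion draws.  Because the Go-RT stream is shared, the adjusted
controller's predicted Go-RT — and hence its per-trial likelihood table —
is identical across the cohort, so all posteriors are updated as one
batched matrix.

Per stop-trial cut-point the harness reads out four SSRT estimates
(staircase-mean, staircase-integration, PSI-marginal via
mean Go-RT − E[threshold], PSI-adjusted via E[SSRT]) and computes cohort
Pearson correlation, mean absolute deviation and regression slope of
estimate on truth, averaged over experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .adjusted import build_ssd_grid
from .psi import ParameterGrid, error_likelihood_table, expected_entropy_scan, normalize_mass
from .psychometric import Model

__all__ = [
    "SimulationDesign",
    "ExperimentResult",
    "StudyResult",
    "SIM_SLOPES",
    "sim1_designs",
    "sim2_designs",
    "sim3_designs",
    "boundary_crossing_trials",
    "run_experiment",
    "run_study",
    "compute_metric_traces",
    "accuracy_bins",
]

# grids used by the simulated controllers (logistic model throughout)
SIM_SLOPES = np.array([0.003, 0.0052, 0.01, 0.019, 0.029, 0.04])
SIM_ERROR_RATE_AXIS = 0.05 * np.arange(7)          # 0 .. 0.30
SIM_THRESHOLD_AXIS = np.arange(0.0, 501.0, 5.0)    # 101 thresholds
SIM_SSRT_AXIS = np.arange(-100.0, 401.0, 5.0)      # 101 SSRT candidates
SIM_SSD_CANDIDATES = np.arange(0.0, 501.0, 50.0)   # 11 SSDs
COHORT_SSRTS = np.arange(50.0, 251.0, 5.0)         # 41 participants

ESTIMATOR_NAMES = ("staircase_mean", "staircase_integration", "psi_marginal", "psi_adjusted")


@dataclass
class SimulationDesign:
    """One simulated condition: cohort, noise levels and controller grids."""

    n_stop_trials: int = 100
    go_per_stop: int = 2
    cohort_ssrts: np.ndarray = field(default_factory=lambda: COHORT_SSRTS.copy())
    inversion_rate: float = 0.0
    slowing_rate: float = 0.0           # ms of mu increase per completed stop-trial
    mu: float = 360.0
    sigma: float = 40.0
    nu: float = 40.0
    controllers: tuple[str, ...] = ("staircase", "psi_marginal", "psi_adjusted")
    # marginal (threshold-space) controller
    threshold_axis: np.ndarray = field(default_factory=lambda: SIM_THRESHOLD_AXIS.copy())
    ssd_candidates: np.ndarray = field(default_factory=lambda: SIM_SSD_CANDIDATES.copy())
    # adjusted (SSRT-space) controller
    ssrt_axis: np.ndarray = field(default_factory=lambda: SIM_SSRT_AXIS.copy())
    ssd_step: float = 50.0
    fallback_go_rt: float = 400.0
    rt_min_window: int = 15
    rt_max_window: int = 40
    # shared nuisance axes
    slopes: np.ndarray = field(default_factory=lambda: SIM_SLOPES.copy())
    error_rate_axis: np.ndarray = field(default_factory=lambda: SIM_ERROR_RATE_AXIS.copy())
    # staircase
    staircase_start: float = 250.0
    staircase_step: float = 50.0
    staircase_floor: float = 0.0
    staircase_ceiling: float | None = None

    @property
    def n_participants(self) -> int:
        return int(np.asarray(self.cohort_ssrts).size)


def sim1_designs() -> list[SimulationDesign]:
    """Stationary Go-RTs; one design per inversion rate 0 / 0.05 / 0.1."""
    return [SimulationDesign(inversion_rate=r) for r in (0.0, 0.05, 0.1)]


def sim2_designs(slowing_rates: Sequence[float] = (5.0, 10.0, 15.0)) -> list[SimulationDesign]:
    """Go-RT slowing via mu; inversion rate 0.05; one design per slowing rate."""
    return [SimulationDesign(inversion_rate=0.05, slowing_rate=r) for r in slowing_rates]


def boundary_crossing_trials(
    threshold_max: float,
    slowing_rate: float,
    initial_mean_go_rt: float = 400.0,
    max_cohort_ssrt: float = 250.0,
) -> int:
    """First stop-trial by which the whole cohort has left the threshold grid.

    The slowest-stopping participant (largest SSRT) has the smallest
    critical SSD, ``initial_mean_go_rt + rate * t - max_ssrt``; the run
    ends at the first t where even that reaches ``threshold_max``.
    """
    if slowing_rate <= 0:
        raise ValueError("boundary crossing requires a positive slowing rate")
    return math.ceil((threshold_max - initial_mean_go_rt + max_cohort_ssrt) / slowing_rate)


def sim3_designs(slowing_rates: Sequence[float] = (5.0, 10.0, 15.0)) -> list[SimulationDesign]:
    """Enlarged threshold grids keeping the cohort in-grid until trial 100.

    The grid maximum leaves a 150 ms buffer above the largest critical SSD
    at trial 100 (smallest SSRT 50 ms, initial mean Go-RT 400 ms); the run
    is extended until every participant's critical SSD has crossed it.
    Only the two PSI controllers run.
    """
    designs = []
    for rate in slowing_rates:
        thr_max = 400.0 + rate * 100.0 - 50.0 + 150.0
        designs.append(
            SimulationDesign(
                inversion_rate=0.05,
                slowing_rate=rate,
                n_stop_trials=boundary_crossing_trials(thr_max, rate),
                controllers=("psi_marginal", "psi_adjusted"),
                threshold_axis=np.arange(0.0, thr_max + 1.0, 5.0),
                ssd_candidates=np.arange(0.0, thr_max + 1.0, 50.0),
            )
        )
    return designs


@dataclass
class ControllerTrace:
    """Per-trial record of one controller on one experiment's cohort."""

    ssd: np.ndarray          # (T, P) presented SSDs
    responded: np.ndarray    # (T, P) True = signal-respond (failed stop)
    expected_primary: np.ndarray | None = None  # (T, P) E[threshold] or E[SSRT]
    argmax_primary: np.ndarray | None = None    # (T, P) primary index of MAP cell
    n_primary: int | None = None
    marginal_entropy: np.ndarray | None = None  # (T, 3) cohort-mean nats per axis


@dataclass
class ExperimentResult:
    design: SimulationDesign
    true_ssrts: np.ndarray                  # (P,)
    go_rts: np.ndarray                      # (T, G) shared Go-trial RTs
    predicted_go_rt: np.ndarray             # (T,) shared regression prediction
    mean_go_at_cut: np.ndarray              # (T,) running mean Go-RT
    controllers: dict[str, ControllerTrace]
    estimates: dict[str, np.ndarray]        # estimator name -> (T, P)


def _axis_entropies(mass: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Cohort-mean marginal entropy for each of the three axes; mass (P, C)."""
    cube = mass.reshape((mass.shape[0],) + shape)
    out = np.empty(3)
    for i, keep in enumerate(((2, 3), (1, 3), (1, 2))):
        m = cube.sum(axis=keep)
        out[i] = float(-xlogy(m, m).sum(axis=-1).mean())
    return out


def _run_psi_batch(
    design: SimulationDesign,
    grid: ParameterGrid,
    latent: np.ndarray,
    flips: np.ndarray,
    true_ssrts: np.ndarray,
    predicted: np.ndarray | None,
    diagnostics: bool,
) -> ControllerTrace:
    """Batched cohort run of a PSI controller (threshold- or SSRT-space).

    ``predicted`` (the shared Go-RT prediction) switches on SSRT space:
    thresholds and SSD candidates are then rebuilt every trial.
    """
    n_t, n_p = latent.shape
    n_cells = grid.n_cells
    k = grid.shape[1] * grid.shape[2]
    mass = np.full((n_p, n_cells), 1.0 / n_cells)
    static_table = None
    if predicted is None:
        static_table = error_likelihood_table(grid, design.ssd_candidates)
    ssd = np.empty((n_t, n_p))
    responded = np.empty((n_t, n_p), dtype=bool)
    e_primary = np.empty((n_t, n_p))
    amax = np.empty((n_t, n_p), dtype=np.int64)
    ments = np.empty((n_t, 3)) if diagnostics else None
    for t in range(n_t):
        if predicted is None:
            candidates, table = design.ssd_candidates, static_table
        else:
            candidates = build_ssd_grid(
                predicted[t], grid.primary, design.ssd_step, floor=0.0, cap=None
            )
            table = error_likelihood_table(
                grid, candidates, thresholds=predicted[t] - grid.cell_primary
            )
        eh = expected_entropy_scan(mass, table, grid.shape, "primary")
        sel = np.argmin(eh, axis=1)
        ssd_t = np.asarray(candidates)[sel]
        err = (latent[t] < ssd_t + true_ssrts) ^ flips[t]
        lik = np.where(err[:, None], table[sel], 1.0 - table[sel])
        mass = normalize_mass(mass * lik)
        marg = mass.reshape(n_p, grid.shape[0], k).sum(axis=2)
        ssd[t], responded[t] = ssd_t, err
        e_primary[t] = marg @ grid.primary
        amax[t] = mass.argmax(axis=1) // k
        if diagnostics:
            ments[t] = _axis_entropies(mass, grid.shape)
    return ControllerTrace(ssd, responded, e_primary, amax, grid.shape[0], ments)


def run_experiment(
    design: SimulationDesign, seed, diagnostics: bool = False
) -> ExperimentResult:
    """Simulate one experiment: the whole cohort under every controller.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  Go-trial
    RTs are drawn once per Go-trial slot and shared; stop-trial latent
    Go-RTs and inversion flips are drawn per (controller, participant).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    names = list(design.controllers)
    children = ss.spawn(1 + 2 * len(names))
    rng_go = np.random.default_rng(children[0])
    n_t, n_g = design.n_stop_trials, design.go_per_stop
    true_ssrts = np.asarray(design.cohort_ssrts, dtype=float)
    n_p = true_ssrts.size
    mu0, rate = design.mu, design.slowing_rate

    # shared Go-trials: the pair following stop-trial t has t completed stop-trials
    go_rts = np.empty((n_t, n_g))
    for t in range(n_t):
        mu_t = mu0 + rate * (t + 1)
        go_rts[t] = rng_go.normal(mu_t, design.sigma, n_g) + rng_go.exponential(design.nu, n_g)
    flat_go = go_rts.ravel()

    # global 1-based trial numbers: stop, go, go, stop, go, go, ...
    stop_number = np.arange(n_t) * (n_g + 1) + 1
    go_number = (np.arange(n_t)[:, None] * (n_g + 1) + 2 + np.arange(n_g)[None, :]).ravel()

    # shared sliding-window Go-RT prediction per stop-trial
    predicted = np.empty(n_t)
    for t in range(n_t):
        n_avail = t * n_g
        if n_avail < design.rt_min_window:
            predicted[t] = design.fallback_go_rt
        else:
            w = min(design.rt_max_window, n_avail)
            x = go_number[n_avail - w : n_avail]
            y = flat_go[n_avail - w : n_avail]
            b, a = np.polyfit(x, y, 1)
            predicted[t] = a + b * stop_number[t]

    counts = n_g * np.arange(1, n_t + 1)
    mean_go_at_cut = np.cumsum(flat_go)[counts - 1] / counts

    # per-controller latent stop-trial Go-RTs and inversion flips
    latent: dict[str, np.ndarray] = {}
    flips: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        rng_lat = np.random.default_rng(children[1 + 2 * i])
        rng_flip = np.random.default_rng(children[2 + 2 * i])
        lat = np.empty((n_t, n_p))
        for t in range(n_t):
            mu_t = mu0 + rate * t  # t stop-trials completed before stop-trial t+1
            lat[t] = rng_lat.normal(mu_t, design.sigma, n_p) + rng_lat.exponential(
                design.nu, n_p
            )
        latent[name] = lat
        flips[name] = (
            rng_flip.random((n_t, n_p)) < design.inversion_rate
            if design.inversion_rate > 0
            else np.zeros((n_t, n_p), dtype=bool)
        )

    controllers: dict[str, ControllerTrace] = {}

    if "staircase" in names:
        ssd = np.empty((n_t, n_p))
        responded = np.empty((n_t, n_p), dtype=bool)
        cur = np.full(n_p, design.staircase_start)
        for t in range(n_t):
            ssd[t] = cur
            err = (latent["staircase"][t] < cur + true_ssrts) ^ flips["staircase"][t]
            responded[t] = err
            cur = cur + np.where(err, -design.staircase_step, design.staircase_step)
            cur = np.maximum(cur, design.staircase_floor)
            if design.staircase_ceiling is not None:
                cur = np.minimum(cur, design.staircase_ceiling)
        controllers["staircase"] = ControllerTrace(ssd, responded)

    if "psi_marginal" in names:
        grid = ParameterGrid(
            design.threshold_axis, design.slopes, design.error_rate_axis,
            model=Model.LOGISTIC, primary_name="threshold",
        )
        controllers["psi_marginal"] = _run_psi_batch(
            design, grid, latent["psi_marginal"], flips["psi_marginal"],
            true_ssrts, None, diagnostics,
        )

    if "psi_adjusted" in names:
        grid = ParameterGrid(
            design.ssrt_axis, design.slopes, design.error_rate_axis,
            model=Model.LOGISTIC, primary_name="ssrt",
        )
        controllers["psi_adjusted"] = _run_psi_batch(
            design, grid, latent["psi_adjusted"], flips["psi_adjusted"],
            true_ssrts, predicted, diagnostics,
        )

    # per-cut-point SSRT estimates for the four reported methods
    estimates: dict[str, np.ndarray] = {}
    denom = np.arange(1, n_t + 1)[:, None]
    if "staircase" in controllers:
        tr = controllers["staircase"]
        mean_ssd = np.cumsum(tr.ssd, axis=0) / denom
        estimates["staircase_mean"] = mean_go_at_cut[:, None] - mean_ssd
        p_resp = np.cumsum(tr.responded, axis=0) / denom
        est_int = np.empty((n_t, n_p))
        for t in range(n_t):
            n_go = counts[t]
            ranked = np.sort(flat_go[:n_go])
            n = np.clip(np.floor(p_resp[t] * n_go + 0.5), 1, n_go).astype(int)
            est_int[t] = ranked[n - 1] - mean_ssd[t]
        estimates["staircase_integration"] = est_int
    if "psi_marginal" in controllers:
        estimates["psi_marginal"] = (
            mean_go_at_cut[:, None] - controllers["psi_marginal"].expected_primary
        )
    if "psi_adjusted" in controllers:
        estimates["psi_adjusted"] = controllers["psi_adjusted"].expected_primary

    return ExperimentResult(
        design, true_ssrts, go_rts, predicted, mean_go_at_cut, controllers, estimates
    )


def compute_metric_traces(estimates: np.ndarray, true_ssrts: np.ndarray) -> dict[str, np.ndarray]:
    """Cohort correlation, MAD and regression slope at every cut-point.

    ``estimates``: (T, P) one estimate per participant per cut-point.
    The slope is the OLS slope of estimate on truth; with fewer than three
    participants the correlation is undefined and an error is raised.
    """
    estimates = np.asarray(estimates, dtype=float)
    true_ssrts = np.asarray(true_ssrts, dtype=float)
    n_p = true_ssrts.size
    if n_p < 3:
        raise ValueError("correlation requires at least 3 participants")
    tc = true_ssrts - true_ssrts.mean()
    var_t = float(tc @ tc) / n_p
    ec = estimates - estimates.mean(axis=1, keepdims=True)
    cov = (ec @ tc) / n_p
    var_e = (ec**2).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(var_t * var_e)
    return {
        "correlation": corr,
        "mad": np.abs(estimates - true_ssrts).mean(axis=1),
        "slope": cov / var_t,
    }


def _sem(arr: np.ndarray) -> np.ndarray:
    """Standard error over the leading (runs) axis; NaN with fewer than 2 runs."""
    if arr.shape[0] < 2:
        return np.full(arr.shape[1], np.nan)
    return arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])


def accuracy_bins(success, bin_size: int = 8) -> pd.DataFrame:
    """Stop-accuracy averaged over consecutive bins of ``bin_size`` trials.

    ``success`` is a boolean array whose first axis is stop-trial order;
    remaining axes (participants, experiments) are averaged within each
    bin.  The trailing partial bin keeps its own trial count.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    success = np.asarray(success, dtype=float)
    n_t = success.shape[0]
    rows = []
    for start in range(0, n_t, bin_size):
        chunk = success[start : start + bin_size]
        rows.append(
            {
                "first_trial": start + 1,
                "n_trials": chunk.shape[0],
                "proportion_successful": float(chunk.mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Stacked per-experiment metric traces for one study.

    Arrays under ``metrics[estimator][metric]`` have shape (runs, T) with
    runs pooled over designs (inversion or slowing rates) and experiments.
    """

    n_stop_trials: int
    metrics: dict[str, dict[str, np.ndarray]]
    success: dict[str, np.ndarray]                    # controller -> (runs, T) cohort mean
    entropy: dict[str, np.ndarray] = field(default_factory=dict)   # (runs, T, 3)
    edge_upper: dict[str, np.ndarray] = field(default_factory=dict)  # (runs, T)
    edge_lower: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def trial(self) -> np.ndarray:
        return np.arange(1, self.n_stop_trials + 1)

    def metric_trace(self, estimator: str, metric: str) -> np.ndarray:
        """(T,) metric averaged over runs."""
        return self.metrics[estimator][metric].mean(axis=0)

    def metric_sem(self, estimator: str, metric: str) -> np.ndarray:
        return _sem(self.metrics[estimator][metric])

    def accuracy_trace(self, controller: str) -> np.ndarray:
        return self.success[controller].mean(axis=0)

    def entropy_trace(self, controller: str) -> pd.DataFrame:
        """Run-averaged marginal entropy (nats) per axis per stop-trial."""
        arr = self.entropy[controller].mean(axis=0)
        return pd.DataFrame(
            {"trial": self.trial, "primary": arr[:, 0], "slope": arr[:, 1],
             "error_rate": arr[:, 2]}
        )

    def boundary_hit_fraction(self, controller: str, edge: str = "upper") -> np.ndarray:
        """Fraction of runs x participants whose MAP primary value sits at a grid edge."""
        return {"upper": self.edge_upper, "lower": self.edge_lower}[edge][controller].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial summary: one row per (trial, estimator)."""
        rows = []
        for name, metrics in self.metrics.items():
            for metric, arr in metrics.items():
                mean = arr.mean(axis=0)
                sem = _sem(arr)
                rows.append(
                    pd.DataFrame(
                        {"trial": self.trial, "estimator": name, "metric": metric,
                         "mean": mean, "sem": sem}
                    )
                )
        return pd.concat(rows, ignore_index=True)


def run_study(
    designs: Iterable[SimulationDesign],
    n_experiments_per_design: int,
    master_seed,
    diagnostics: bool = False,
) -> StudyResult:
    """Run ``n_experiments_per_design`` seeded experiments per design and pool.

    All designs must share ``n_stop_trials``; run study 3's per-rate
    designs as separate studies.
    """
    designs = list(designs)
    n_t = designs[0].n_stop_trials
    if any(d.n_stop_trials != n_t for d in designs):
        raise ValueError("designs in one study must share n_stop_trials")
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    design_seeds = ss.spawn(len(designs))
    metrics: dict[str, dict[str, list[np.ndarray]]] = {}
    success: dict[str, list[np.ndarray]] = {}
    entropy: dict[str, list[np.ndarray]] = {}
    edge_up: dict[str, list[np.ndarray]] = {}
    edge_lo: dict[str, list[np.ndarray]] = {}
    for design, dseed in zip(designs, design_seeds):
        for eseed in dseed.spawn(n_experiments_per_design):
            result = run_experiment(design, eseed, diagnostics=diagnostics)
            for name, est in result.estimates.items():
                traces = compute_metric_traces(est, result.true_ssrts)
                store = metrics.setdefault(name, {k: [] for k in traces})
                for k, v in traces.items():
                    store[k].append(v)
            for name, tr in result.controllers.items():
                success.setdefault(name, []).append(1.0 - tr.responded.mean(axis=1))
                if tr.argmax_primary is not None:
                    edge_up.setdefault(name, []).append(
                        (tr.argmax_primary == tr.n_primary - 1).mean(axis=1)
                    )
                    edge_lo.setdefault(name, []).append((tr.argmax_primary == 0).mean(axis=1))
                if tr.marginal_entropy is not None:
                    entropy.setdefault(name, []).append(tr.marginal_entropy)
    return StudyResult(
        n_stop_trials=n_t,
        metrics={
            name: {k: np.stack(v) for k, v in store.items()} for name, store in metrics.items()
        },
        success={name: np.stack(v) for name, v in success.items()},
        entropy={name: np.stack(v) for name, v in entropy.items()},
        edge_upper={name: np.stack(v) for name, v in edge_up.items()},
        edge_lower={name: np.stack(v) for name, v in edge_lo.items()},
    )
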