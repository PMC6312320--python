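"""Grid-based Bayesian adaptive engine for stop-signal-delay selection.

The engine keeps a discrete posterior over a three-axis lattice of
candidate parameter vectors (primary x slope x error-rate), scores each
candidate SSD by the posterior entropy expected after observing the
stop-trial outcome at that SSD, and selects the SSD that minimizes it.
Entropy can be taken over the full posterior or over the posterior
marginalized onto the primary axis only (the "marginal" variant, which
ignores information about the nuisance slope and lapse parameters).

All posterior arithmetic is done in linear space with per-update
renormalization; entropies are in nats, with the 0*log(0) = 0 convention.
The numerical kernels accept a leading batch dimension on the mass array
so that a whole cohort of independent posteriors sharing one grid can be
updated with single matrix operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .psychometric import Model, PsychometricParams, p_error

__all__ = [
    "ConfigurationError",
    "DegenerateUpdateError",
    "Marginalize",
    "ParameterGrid",
    "Posterior",
    "uniform_prior",
    "bayes_update",
    "response_probabilities",
    "entropy",
    "expected_entropy",
    "expected_entropy_scan",
    "select_ssd",
    "expected_parameters",
    "error_likelihood_table",
    "PsiController",
]

Marginalize = Literal["none", "primary"]


class ConfigurationError(ValueError):
    """Raised for empty or ill-formed grids and candidate sets."""


class DegenerateUpdateError(ValueError):
    """Raised when an observation has zero likelihood under every grid cell."""


def _check_axis(name: str, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ConfigurationError(f"{name} axis must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(values)):
        raise ConfigurationError(f"{name} axis must be finite")
    if values.size > 1 and np.any(np.diff(values) <= 0):
        raise ConfigurationError(f"{name} axis must be strictly increasing")
    return values


@dataclass(frozen=True)
class ParameterGrid:
    """Three-axis candidate lattice.

    ``primary`` holds thresholds (ms) in threshold space or SSRTs (ms) in
    SSRT space, as indicated by ``primary_name``.  Cells are flattened in
    C order (primary slowest, error-rate fastest).
    """

    primary: np.ndarray
    slope: np.ndarray
    error_rate: np.ndarray
    model: Model = Model.LOGISTIC
    primary_name: str = "threshold"

    def __post_init__(self) -> None:
        object.__setattr__(self, "primary", _check_axis("primary", self.primary))
        object.__setattr__(self, "slope", _check_axis("slope", self.slope))
        object.__setattr__(self, "error_rate", _check_axis("error_rate", self.error_rate))
        object.__setattr__(self, "model", Model(self.model))
        if np.any(self.slope <= 0):
            raise ConfigurationError("slope axis must be positive")
        if np.any(self.error_rate < 0) or np.any(self.error_rate >= 0.5):
            raise ConfigurationError("error_rate axis must lie in [0, 0.5)")
        p, s, e = np.meshgrid(self.primary, self.slope, self.error_rate, indexing="ij")
        object.__setattr__(self, "_cells", (p.ravel(), s.ravel(), e.ravel()))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.primary.size, self.slope.size, self.error_rate.size)

    @property
    def n_cells(self) -> int:
        return self.primary.size * self.slope.size * self.error_rate.size

    @property
    def cell_primary(self) -> np.ndarray:
        return self._cells[0]

    @property
    def cell_slope(self) -> np.ndarray:
        return self._cells[1]

    @property
    def cell_error_rate(self) -> np.ndarray:
        return self._cells[2]


def error_likelihood_table(
    grid: ParameterGrid, ssds: np.ndarray, thresholds: np.ndarray | None = None
) -> np.ndarray:
    """p(error | cell, ssd) for every candidate SSD, shape ``(S, n_cells)``.

    ``thresholds`` overrides the per-cell threshold; the SSRT-space
    controller passes ``predicted_go_rt - cell_ssrt`` here.
    """
    ssds = np.asarray(ssds, dtype=float)
    if ssds.size == 0:
        raise ConfigurationError("candidate SSD set must be non-empty")
    thr = grid.cell_primary if thresholds is None else np.asarray(thresholds, dtype=float)
    return np.asarray(
        p_error(ssds[:, None], thr[None, :], grid.cell_slope[None, :],
                grid.cell_error_rate[None, :], grid.model)
    )


@dataclass
class Posterior:
    """Normalized probability mass over a :class:`ParameterGrid`."""

    grid: ParameterGrid
    mass: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mass is None:
            self.mass = np.full(self.grid.n_cells, 1.0 / self.grid.n_cells)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.grid.n_cells,):
            raise ConfigurationError("mass must have one entry per grid cell")
        if np.any(self.mass < 0) or abs(self.mass.sum() - 1.0) > 1e-9:
            raise ConfigurationError("mass must be non-negative and sum to 1")

    def marginal(self, axis: str) -> tuple[np.ndarray, np.ndarray]:
        """(axis values, marginal mass) for ``axis`` in {primary, slope, error_rate}."""
        cube = self.mass.reshape(self.grid.shape)
        idx = {"primary": 0, "slope": 1, "error_rate": 2}[axis]
        values = (self.grid.primary, self.grid.slope, self.grid.error_rate)[idx]
        keep = tuple(i for i in range(3) if i != idx)
        return values, cube.sum(axis=keep)

    def expected(self) -> dict[str, float]:
        out = {}
        for axis in ("primary", "slope", "error_rate"):
            values, m = self.marginal(axis)
            out[axis] = float(values @ m)
        return out

    def map_cell(self) -> dict[str, float]:
        """Parameter values of the maximum-probability cell (diagnostic)."""
        i = int(np.argmax(self.mass))
        return {
            "primary": float(self.grid.cell_primary[i]),
            "slope": float(self.grid.cell_slope[i]),
            "error_rate": float(self.grid.cell_error_rate[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per cell: primary, slope, error_rate, mass (heatmap export)."""
        return pd.DataFrame(
            {
                self.grid.primary_name: self.grid.cell_primary,
                "slope": self.grid.cell_slope,
                "error_rate": self.grid.cell_error_rate,
                "mass": self.mass,
            }
        )


def uniform_prior(grid: ParameterGrid) -> Posterior:
    """Uniform mass over every grid cell."""
    return Posterior(grid)


# ---------------------------------------------------------------------------
# batched kernels: mass has shape (..., C)

def normalize_mass(mass: np.ndarray) -> np.ndarray:
    total = mass.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise DegenerateUpdateError("all grid cells have zero posterior mass")
    return mass / total


def update_mass(mass: np.ndarray, likelihood: np.ndarray) -> np.ndarray:
    """Bayes update of (batched) mass by a per-cell likelihood; renormalized."""
    return normalize_mass(mass * likelihood)


def entropy_of_mass(
    mass: np.ndarray, shape: tuple[int, int, int], marginalize: Marginalize = "none"
) -> np.ndarray:
    """Shannon entropy (nats) of (batched) mass, optionally of its primary marginal."""
    if marginalize == "primary":
        t, s, e = shape
        mass = mass.reshape(mass.shape[:-1] + (t, s * e)).sum(axis=-1)
    elif marginalize != "none":
        raise ValueError(f"unknown marginalize mode {marginalize!r}")
    return -xlogy(mass, mass).sum(axis=-1)


def expected_entropy_scan(
    mass: np.ndarray,
    perr_table: np.ndarray,
    shape: tuple[int, int, int],
    marginalize: Marginalize = "primary",
) -> np.ndarray:
    """Expected posterior entropy after one trial, for every candidate SSD.

    ``mass``: (..., C) prior mass; ``perr_table``: (S, C) per-cell error
    probabilities from :func:`error_likelihood_table`.  Returns (..., S).

    Uses E[H] = sum_r (-sum_i a_i log a_i + Z_r log Z_r) where
    a_i = prior_i * p(r | i, ssd) is the unnormalized joint mass and
    Z_r = sum_i a_i the predictive probability of response r.
    """
    squeeze = mass.ndim == 1
    mass2 = np.atleast_2d(mass)  # (B, C)
    n_b = mass2.shape[0]
    n_s, n_c = perr_table.shape
    out = np.zeros((n_b, n_s))
    if marginalize == "primary":
        t, s, e = shape
        k = s * e
        pm = np.ascontiguousarray(mass2.reshape(n_b, t, k).transpose(1, 0, 2))  # (T,B,K)
        for lik in (1.0 - perr_table, perr_table):
            lt = np.ascontiguousarray(lik.reshape(n_s, t, k).transpose(1, 2, 0))  # (T,K,S)
            joint = np.moveaxis(pm @ lt, 0, -1)  # (B,S,T) marginal joint mass
            z = joint.sum(axis=-1)
            out += -xlogy(joint, joint).sum(axis=-1) + xlogy(z, z)
    elif marginalize == "none":
        for lik in (1.0 - perr_table, perr_table):
            joint = mass2[:, None, :] * lik[None, :, :]  # (B,S,C)
            z = joint.sum(axis=-1)
            out += -xlogy(joint, joint).sum(axis=-1) + xlogy(z, z)
    else:
        raise ValueError(f"unknown marginalize mode {marginalize!r}")
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Posterior-level operations

def bayes_update(prior: Posterior, ssd: float, response: str) -> Posterior:
    """Posterior after observing ``response`` ("success" or "error") at ``ssd``."""
    grid = prior.grid
    perr = np.asarray(
        p_error(float(ssd), grid.cell_primary, grid.cell_slope, grid.cell_error_rate, grid.model)
    )
    lik = perr if response == "error" else 1.0 - perr
    if response not in ("success", "error"):
        raise ValueError(f"response must be 'success' or 'error', got {response!r}")
    return Posterior(grid, update_mass(prior.mass, lik))


def response_probabilities(prior: Posterior, ssd: float) -> tuple[float, float]:
    """Predictive (p_success, p_error) at ``ssd`` under the current posterior."""
    grid = prior.grid
    perr = np.asarray(
        p_error(float(ssd), grid.cell_primary, grid.cell_slope, grid.cell_error_rate, grid.model)
    )
    pe = float(prior.mass @ perr)
    return 1.0 - pe, pe


def entropy(posterior: Posterior, marginalize: Marginalize = "none") -> float:
    return float(entropy_of_mass(posterior.mass, posterior.grid.shape, marginalize))


def expected_entropy(prior: Posterior, ssd: float, marginalize: Marginalize = "none") -> float:
    table = error_likelihood_table(prior.grid, np.atleast_1d(float(ssd)))
    return float(expected_entropy_scan(prior.mass, table, prior.grid.shape, marginalize)[0])


def select_ssd(
    prior: Posterior, candidates: np.ndarray, marginalize: Marginalize = "primary"
) -> float:
    """Candidate SSD minimizing expected posterior entropy.

    Ties resolve to the smallest SSD (candidates are ascending and argmin
    returns the first minimizer).
    """
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise ConfigurationError("candidate SSD set must be non-empty")
    table = error_likelihood_table(prior.grid, candidates)
    eh = expected_entropy_scan(prior.mass, table, prior.grid.shape, marginalize)
    return float(candidates[int(np.argmin(eh))])


def expected_parameters(posterior: Posterior) -> PsychometricParams:
    """Per-axis posterior expectations packed as a parameter vector.

    In SSRT-space grids the ``threshold`` slot carries E[SSRT]; see
    :meth:`Posterior.expected` for a labelled dict and
    :meth:`Posterior.map_cell` for the maximum-probability cell.
    """
    e = posterior.expected()
    return PsychometricParams(
        threshold=e["primary"], slope=e["slope"], error_rate=e["error_rate"],
        model=posterior.grid.model,
    )


class PsiController:
    """Sequential PSI controller over a fixed grid and fixed SSD candidates.

    ``marginalize="primary"`` gives the marginal variant used throughout the
    simulations; ``"none"`` gives the original full-posterior criterion.
    """

    def __init__(
        self,
        grid: ParameterGrid,
        ssd_candidates: np.ndarray,
        marginalize: Marginalize = "primary",
        prior: Posterior | None = None,
    ) -> None:
        self.grid = grid
        self.candidates = _check_axis("ssd", np.asarray(ssd_candidates, dtype=float))
        if np.any(self.candidates < 0):
            raise ConfigurationError("candidate SSDs must be non-negative")
        self.marginalize: Marginalize = marginalize
        self.posterior = prior if prior is not None else uniform_prior(grid)
        self._table = error_likelihood_table(grid, self.candidates)

    def next_ssd(self) -> float:
        eh = expected_entropy_scan(
            self.posterior.mass, self._table, self.grid.shape, self.marginalize
        )
        return float(self.candidates[int(np.argmin(eh))])

    def record(self, ssd: float, response: str) -> None:
        idx = np.flatnonzero(np.isclose(self.candidates, ssd))
        if idx.size:
            perr = self._table[int(idx[0])]
            lik = perr if response == "error" else 1.0 - perr
            self.posterior = Posterior(self.grid, update_mass(self.posterior.mass, lik))
        else:  # off-grid SSD: compute the likelihood directly
            self.posterior = bayes_update(self.posterior, ssd, response)
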