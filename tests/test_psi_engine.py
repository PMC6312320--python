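"""Bayesian engine: priors, updates, entropies, SSD selection vs brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_posterior
from psistop.psi import (
    ConfigurationError,
    DegenerateUpdateError,
    ParameterGrid,
    Posterior,
    bayes_update,
    entropy,
    entropy_of_mass,
    error_likelihood_table,
    expected_entropy,
    expected_entropy_scan,
    expected_parameters,
    response_probabilities,
    select_ssd,
    uniform_prior,
    update_mass,
)
from psistop.psychometric import p_error, p_success


# -- independent brute-force oracle, plain loops over cells -----------------

def brute_force_posterior(grid, mass, ssd, response):
    cells = list(zip(grid.cell_primary, grid.cell_slope, grid.cell_error_rate))
    liks = []
    for thr, k, e in cells:
        pe = p_error(ssd, thr, k, e, grid.model)
        liks.append(pe if response == "error" else 1.0 - pe)
    joint = [m * l for m, l in zip(mass, liks)]
    total = sum(joint)
    return [j / total for j in joint], total


def brute_force_marginal_entropy(grid, mass):
    per_primary = {}
    for m, thr in zip(mass, grid.cell_primary):
        per_primary[thr] = per_primary.get(thr, 0.0) + m
    return -sum(p * math.log(p) for p in per_primary.values() if p > 0)


def brute_force_select(grid, mass, candidates, marginalize):
    best_ssd, best_eh = None, None
    for ssd in candidates:
        eh = 0.0
        for response in ("success", "error"):
            post, z = brute_force_posterior(grid, mass, ssd, response)
            if marginalize == "primary":
                h = brute_force_marginal_entropy(grid, post)
            else:
                h = -sum(p * math.log(p) for p in post if p > 0)
            eh += z * h
        if best_eh is None or eh < best_eh - 1e-15:
            best_ssd, best_eh = ssd, eh
    return best_ssd, best_eh


# -- priors -----------------------------------------------------------------

def test_uniform_prior_masses(two_cell_grid):
    small = ParameterGrid([100.0, 200.0], [0.01], [0.0, 0.1], primary_name="threshold")
    post = uniform_prior(small)
    np.testing.assert_allclose(post.mass, 0.25)
    sim1 = ParameterGrid(
        np.arange(0.0, 501.0, 5.0),
        np.array([0.003, 0.0052, 0.01, 0.019, 0.029, 0.04]),
        0.05 * np.arange(7),
    )
    post = uniform_prior(sim1)
    assert sim1.n_cells == 4242
    np.testing.assert_allclose(post.mass, 1.0 / 4242)
    assert post.mass.sum() == pytest.approx(1.0, abs=1e-12)


def test_empty_axis_rejected():
    with pytest.raises(ConfigurationError):
        ParameterGrid([], [0.01], [0.0])


# -- Bayes updates ----------------------------------------------------------

def test_bayes_update_two_cell_hand_arithmetic():
    """Prior (.5, .5) with likelihoods (.8, .4) must give (2/3, 1/3)."""
    post = update_mass(np.array([0.5, 0.5]), np.array([0.8, 0.4]))
    np.testing.assert_allclose(post, [2.0 / 3.0, 1.0 / 3.0])


def test_bayes_update_matches_brute_force(tiny_grid):
    rng = np.random.default_rng(5)
    prior = random_posterior(tiny_grid, rng)
    for ssd, response in [(150.0, "error"), (250.0, "success")]:
        got = bayes_update(prior, ssd, response)
        want, _ = brute_force_posterior(tiny_grid, prior.mass, ssd, response)
        np.testing.assert_allclose(got.mass, want, atol=1e-12)
        assert got.mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_flat_likelihood_preserves_prior(tiny_grid):
    rng = np.random.default_rng(6)
    prior = random_posterior(tiny_grid, rng)
    post = update_mass(prior.mass, np.full(tiny_grid.n_cells, 0.37))
    np.testing.assert_allclose(post, prior.mass, atol=1e-12)


def test_sequential_updates_equal_joint(tiny_grid):
    rng = np.random.default_rng(7)
    prior = random_posterior(tiny_grid, rng)
    seq = bayes_update(bayes_update(prior, 150.0, "error"), 250.0, "success")
    lik1 = np.asarray(
        p_error(150.0, tiny_grid.cell_primary, tiny_grid.cell_slope,
                tiny_grid.cell_error_rate, tiny_grid.model)
    )
    lik2 = 1.0 - np.asarray(
        p_error(250.0, tiny_grid.cell_primary, tiny_grid.cell_slope,
                tiny_grid.cell_error_rate, tiny_grid.model)
    )
    joint = update_mass(prior.mass, lik1 * lik2)
    np.testing.assert_allclose(seq.mass, joint, atol=1e-12)


def test_degenerate_update_raises(two_cell_grid):
    prior = uniform_prior(two_cell_grid)
    with pytest.raises(DegenerateUpdateError):
        update_mass(prior.mass, np.zeros(two_cell_grid.n_cells))


# -- predictive response probabilities --------------------------------------

def test_response_probabilities_point_mass(two_cell_grid):
    mass = np.array([1.0, 0.0])
    post = Posterior(two_cell_grid, mass)
    ps, pe = response_probabilities(post, 180.0)
    assert pe == pytest.approx(p_error(180.0, 100.0, 0.01, 0.0))
    assert ps == pytest.approx(p_success(180.0, 100.0, 0.01, 0.0))
    assert ps + pe == pytest.approx(1.0, abs=1e-12)


def test_response_probabilities_mixture():
    """Uniform prior over cells with p_error .2 and .6 must predict .4."""
    grid = ParameterGrid([100.0, 300.0], [0.01], [0.2], primary_name="threshold")
    # at the midpoint ssd=200 the two cells give e+(1-2e)*expit(+-1)
    pe_cells = np.asarray(p_error(200.0, grid.cell_primary, 0.01, 0.2))
    _, pe = response_probabilities(uniform_prior(grid), 200.0)
    assert pe == pytest.approx(pe_cells.mean(), abs=1e-12)


# -- entropies ---------------------------------------------------------------

def test_entropy_uniform_and_point_mass(tiny_grid):
    assert entropy(uniform_prior(tiny_grid)) == pytest.approx(math.log(tiny_grid.n_cells))
    point = np.zeros(tiny_grid.n_cells)
    point[4] = 1.0
    assert entropy(Posterior(tiny_grid, point)) == 0.0


def test_marginal_entropy_of_uniform_is_log_primary():
    grid = ParameterGrid([1.0, 2.0, 3.0, 4.0], [0.01, 0.02], [0.0, 0.1])
    assert entropy(uniform_prior(grid), marginalize="primary") == pytest.approx(math.log(4))


def test_expected_entropy_two_cell_oracle(two_cell_grid):
    prior = uniform_prior(two_cell_grid)
    ssd = 200.0
    _, want = brute_force_select(two_cell_grid, prior.mass, [ssd], "none")
    assert expected_entropy(prior, ssd, "none") == pytest.approx(want, abs=1e-12)
    _, want_m = brute_force_select(two_cell_grid, prior.mass, [ssd], "primary")
    assert expected_entropy(prior, ssd, "primary") == pytest.approx(want_m, abs=1e-12)


def test_flat_likelihood_gives_prior_entropy():
    """An SSD that cannot discriminate leaves expected entropy at the prior's."""
    grid = ParameterGrid([100.0, 100.0 + 1e-9], [0.01], [0.0])
    prior = uniform_prior(grid)
    assert expected_entropy(prior, 100.0, "none") == pytest.approx(entropy(prior), abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), ssd=st.floats(0.0, 600.0))
def test_expected_entropy_never_exceeds_prior(seed, ssd):
    grid = ParameterGrid([100.0, 200.0, 300.0], [0.01, 0.02], [0.0, 0.1])
    rng = np.random.default_rng(seed)
    prior = random_posterior(grid, rng)
    for mode in ("none", "primary"):
        assert expected_entropy(prior, ssd, mode) <= entropy(prior, mode) + 1e-9


# -- SSD selection ----------------------------------------------------------

@pytest.mark.parametrize("marginalize", ["none", "primary"])
def test_select_ssd_matches_brute_force(tiny_grid, marginalize):
    rng = np.random.default_rng(11)
    candidates = [50.0, 150.0, 250.0, 400.0]
    for _ in range(10):
        prior = random_posterior(tiny_grid, rng)
        got = select_ssd(prior, candidates, marginalize)
        want, _ = brute_force_select(tiny_grid, prior.mass, candidates, marginalize)
        assert got == want


def test_single_candidate_returned(tiny_grid):
    assert select_ssd(uniform_prior(tiny_grid), [123.0]) == 123.0
    with pytest.raises(ConfigurationError):
        select_ssd(uniform_prior(tiny_grid), [])


def test_informative_ssd_preferred(two_cell_grid):
    """An SSD between the two thresholds beats one far beyond both."""
    prior = uniform_prior(two_cell_grid)
    eh_mid = expected_entropy(prior, 200.0, "none")
    eh_far = expected_entropy(prior, 5000.0, "none")
    assert eh_mid < eh_far
    assert select_ssd(prior, [200.0, 5000.0], "none") == 200.0


# -- expected parameters ----------------------------------------------------

def test_expected_parameters_cases(two_cell_grid):
    point = Posterior(two_cell_grid, np.array([0.0, 1.0]))
    assert expected_parameters(point).threshold == pytest.approx(300.0)
    uniform = uniform_prior(two_cell_grid)
    assert expected_parameters(uniform).threshold == pytest.approx(200.0)
    weighted = Posterior(two_cell_grid, np.array([0.25, 0.75]))
    assert expected_parameters(weighted).threshold == pytest.approx(250.0)


def test_map_cell_reports_maximum_probability_cell(tiny_grid):
    mass = np.zeros(tiny_grid.n_cells)
    mass[-1] = 0.6
    mass[0] = 0.4
    post = Posterior(tiny_grid, mass)
    assert post.map_cell()["primary"] == tiny_grid.primary[-1]


def test_posterior_export_frame(tiny_grid):
    frame = uniform_prior(tiny_grid).to_frame()
    assert list(frame.columns) == ["threshold", "slope", "error_rate", "mass"]
    assert len(frame) == tiny_grid.n_cells
    assert frame["mass"].sum() == pytest.approx(1.0)


# -- batched kernels back the scalar API ------------------------------------

def test_batched_kernels_match_scalar(tiny_grid):
    rng = np.random.default_rng(13)
    candidates = np.array([50.0, 150.0, 250.0, 400.0])
    table = error_likelihood_table(tiny_grid, candidates)
    batch = np.stack([random_posterior(tiny_grid, rng).mass for _ in range(5)])
    for mode in ("none", "primary"):
        eh_batch = expected_entropy_scan(batch, table, tiny_grid.shape, mode)
        for i in range(5):
            eh_one = expected_entropy_scan(batch[i], table, tiny_grid.shape, mode)
            np.testing.assert_allclose(eh_batch[i], eh_one, atol=1e-12)
            np.testing.assert_allclose(
                eh_one,
                [expected_entropy(Posterior(tiny_grid, batch[i]), s, mode) for s in candidates],
                atol=1e-12,
            )
    h = entropy_of_mass(batch, tiny_grid.shape, "primary")
    for i in range(5):
        assert h[i] == pytest.approx(entropy(Posterior(tiny_grid, batch[i]), "primary"))
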