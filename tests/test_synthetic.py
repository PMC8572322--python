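"""Synthetic response and burden generators."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

import raschmon as rm
from raschmon.errors import ConfigError


def test_default_bank_sums_to_zero_and_spans_the_logit_range():
    bank = np.array(list(rm.DEFAULT_ITEM_BANK.values()))
    assert bank.size == 25
    assert bank.sum() == pytest.approx(0.0, abs=1e-9)
    assert bank.min() == pytest.approx(-2.319)
    assert bank.max() == pytest.approx(2.009)


def test_fixed_seed_is_bit_reproducible():
    cfg = rm.SimulationConfig(n_persons=50, seed=9)
    a = rm.simulate_responses(cfg)
    b = rm.simulate_responses(rm.SimulationConfig(n_persons=50, seed=9))
    np.testing.assert_array_equal(a.matrix.responses, b.matrix.responses)
    np.testing.assert_array_equal(a.theta, b.theta)
    c = rm.simulate_responses(rm.SimulationConfig(n_persons=50, seed=10))
    assert not np.array_equal(a.matrix.responses, c.matrix.responses)


def test_theta_equal_beta_gives_half_probability():
    """All cells Bernoulli(0.5) when every theta matches every beta."""
    cfg = rm.SimulationConfig(
        n_persons=2000, item_difficulties=np.zeros(20),
        ability_mean=0.0, ability_sd=1e-9, seed=2,
    )
    sim = rm.simulate_responses(cfg)
    grand = sim.matrix.responses.mean()
    mc_se = 0.5 / np.sqrt(sim.matrix.responses.size)
    assert abs(grand - 0.5) < 4 * mc_se


def test_logistic_saturation_gives_all_ones():
    cfg = rm.SimulationConfig(
        n_persons=100, item_difficulties=np.zeros(10),
        ability_mean=10.0, ability_sd=1e-9, seed=4,
    )
    sim = rm.simulate_responses(cfg)
    assert sim.matrix.responses.mean() > 0.999


def test_item_proportions_match_analytic_cell_average(default_bank):
    """Observed per-item proportions track (1/n) sum_v P(theta_v, beta_i)
    within 3 Monte-Carlo standard errors."""
    cfg = rm.SimulationConfig(
        n_persons=5000, item_difficulties=default_bank, ability_sd=1.5, seed=13
    )
    sim = rm.simulate_responses(cfg)
    p = expit(sim.theta[:, None] - sim.beta[None, :])
    expected = p.mean(axis=0)
    se = np.sqrt((p * (1 - p)).sum(axis=0)) / cfg.n_persons
    observed = sim.matrix.responses.mean(axis=0)
    assert np.all(np.abs(observed - expected) < 3 * se)


def test_margins_track_the_generating_parameters(default_bank):
    """Row means rise with true theta, item means fall with true beta.

    The person-side check uses a 50-item bank: with few items the raw score
    is too coarse for the rank correlation to approach 1 however faithful the
    generator, so a finer score resolution isolates the property under test.
    """
    sim = rm.simulate_responses(
        rm.SimulationConfig(n_persons=5000, item_difficulties=default_bank, seed=21)
    )
    rho_item = spearmanr(sim.beta, sim.matrix.item_margins).statistic
    assert rho_item < -0.95

    fine = rm.simulate_responses(
        rm.SimulationConfig(
            n_persons=5000, item_difficulties=np.linspace(-2.3, 2.3, 50), seed=22
        )
    )
    rho_person = spearmanr(fine.theta, fine.matrix.raw_scores).statistic
    assert rho_person > 0.95


def test_dif_shift_targets_the_high_ability_group():
    shift = np.zeros(5)
    shift[0] = 1.0
    cfg = rm.SimulationConfig(
        n_persons=400, item_difficulties=np.linspace(-1, 1, 5),
        seed=3, dif_shift=shift,
    )
    sim = rm.simulate_responses(cfg)
    assert sim.dif_mask.sum() == 200
    assert np.all(sim.theta[sim.dif_mask] > np.median(sim.theta))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_persons": 1},
        {"item_difficulties": [0.0]},
        {"ability_sd": 0.0},
        {"ability_sd": -1.0},
        {"dif_shift": [1.0, 2.0]},
    ],
)
def test_invalid_simulation_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        rm.SimulationConfig(n_persons=kwargs.pop("n_persons", 10), **kwargs)


def test_zero_rates_give_zero_counts():
    cfg = rm.BurdenSimulationConfig(n_centres=30, sam_rate=0.0, mam_rate=0.0, seed=1)
    burden = rm.simulate_burden(cfg, np.zeros(30))
    assert np.all(burden.sam_count == 0) and np.all(burden.mam_count == 0)
    assert np.all(burden.adjusted == 0)


def test_burden_means_follow_linearity_of_expectation():
    """With SAM mean 2 and MAM mean 4 the adjusted burden averages
    2 + 0.5 * 4 = 4."""
    cfg = rm.BurdenSimulationConfig(
        n_centres=20000, sam_rate=2.0, mam_rate=4.0, seed=8
    )
    burden = rm.simulate_burden(cfg, np.random.default_rng(0).normal(size=20000))
    mc_se = burden.adjusted.std() / np.sqrt(20000)
    assert abs(burden.adjusted.mean() - 4.0) < 4 * mc_se


def test_uncorrelated_burden_is_rank_independent_of_ability():
    cfg = rm.BurdenSimulationConfig(
        n_centres=2000, sam_rate=2.0, mam_rate=6.0,
        ability_burden_correlation=0.0, seed=5,
    )
    abilities = np.random.default_rng(1).normal(size=2000)
    burden = rm.simulate_burden(cfg, abilities)
    rho = spearmanr(abilities, burden.adjusted).statistic
    assert abs(rho) < 0.05


def test_correlated_burden_tracks_the_requested_sign():
    cfg = rm.BurdenSimulationConfig(
        n_centres=2000, sam_rate=2.0, mam_rate=6.0,
        ability_burden_correlation=-0.5, seed=5,
    )
    abilities = np.random.default_rng(1).normal(size=2000)
    burden = rm.simulate_burden(cfg, abilities)
    rho = spearmanr(abilities, burden.adjusted).statistic
    assert -0.6 < rho < -0.35


def test_burden_length_mismatch_rejected():
    cfg = rm.BurdenSimulationConfig(n_centres=10, seed=0)
    with pytest.raises(ConfigError):
        rm.simulate_burden(cfg, np.zeros(9))
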