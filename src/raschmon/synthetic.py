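"""Synthetic data with the statistical structure the pipeline assumes.

The field data behind the CSAM (community-based management of severe acute
malnutrition) ability assessment — 197 front-line workers answering a 25-item
dichotomous questionnaire, plus per-centre counts of severely (SAM) and
moderately (MAM) malnourished children — is not publicly deposited. This
module generates Rasch-conforming response matrices and centre burden tables
so every downstream stage (calibration, diagnostics, prioritization) can be
exercised and validated end to end.

``DEFAULT_ITEM_BANK`` holds the 25-item default difficulty bank: 24 published
anchor difficulties spanning -2.32 to +2.01 logits plus one balancing value
that makes the bank sum to zero (the sum-zero normalisation used by the
calibrator). Abilities default to Normal(0, 1.5), wide enough to cover that
difficulty range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import poisson

from .core import ResponseMatrix
from .errors import ConfigError
from .prioritization import BurdenTable

__all__ = [
    "DEFAULT_ITEM_BANK",
    "SimulationConfig",
    "BurdenSimulationConfig",
    "SimulatedResponses",
    "simulate_responses",
    "simulate_burden",
]

# 24 anchor difficulties (logits) of the 25-item CSAM ability questionnaire,
# V2..V25; V1 balances the bank to sum zero.
_ANCHOR_BETAS = {
    "V2": 0.076,
    "V3": -2.319,
    "V4": 0.648,
    "V5": -1.344,
    "V6": -1.205,
    "V7": -1.659,
    "V8": -0.103,
    "V9": -1.344,
    "V10": 0.486,
    "V11": -0.965,
    "V12": -0.292,
    "V13": 1.56,
    "V14": 1.234,
    "V15": -0.684,
    "V16": 0.95,
    "V17": 0.051,
    "V18": -0.495,
    "V19": 2.009,
    "V20": 0.344,
    "V21": 0.695,
    "V22": 0.462,
    "V23": 0.672,
    "V24": 1.978,
    "V25": 0.368,
}

DEFAULT_ITEM_BANK: dict = {
    "V1": -round(sum(_ANCHOR_BETAS.values()), 3),
    **_ANCHOR_BETAS,
}


def _default_difficulties() -> np.ndarray:
    return np.array(list(DEFAULT_ITEM_BANK.values()))


@dataclass
class SimulationConfig:
    """Parameters of a Rasch response simulation.

    Attributes
    ----------
    n_persons
        Number of respondents (>= 2).
    item_difficulties
        Difficulty vector in logits (>= 2 items); defaults to the 25-item
        sum-zero bank in ``DEFAULT_ITEM_BANK``.
    ability_mean, ability_sd
        Normal ability distribution parameters in logits (sd > 0).
    seed
        Integer seed; all sub-streams derive from it deterministically.
    dif_shift
        Optional per-item logit offsets added to the difficulties faced by the
        high-ability subgroup (true theta above the cohort median), for
        differential-item-functioning power studies.
    """

    n_persons: int = 197
    item_difficulties: np.ndarray = field(default_factory=_default_difficulties)
    ability_mean: float = 0.0
    ability_sd: float = 1.5
    seed: int = 0
    dif_shift: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.item_difficulties = np.asarray(self.item_difficulties, dtype=float)
        if not isinstance(self.n_persons, (int, np.integer)) or self.n_persons < 2:
            raise ConfigError("n_persons must be an integer >= 2")
        if self.item_difficulties.ndim != 1 or self.item_difficulties.size < 2:
            raise ConfigError("item_difficulties must hold at least 2 items")
        if not np.all(np.isfinite(self.item_difficulties)):
            raise ConfigError("item_difficulties must be finite")
        if not np.isfinite(self.ability_mean):
            raise ConfigError("ability_mean must be finite")
        if not (self.ability_sd > 0):
            raise ConfigError("ability_sd must be > 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        if self.dif_shift is not None:
            self.dif_shift = np.asarray(self.dif_shift, dtype=float)
            if self.dif_shift.shape != self.item_difficulties.shape:
                raise ConfigError("dif_shift length must equal the item count")


@dataclass
class BurdenSimulationConfig:
    """Parameters of a centre-level malnutrition burden simulation.

    SAM and MAM counts per centre are Poisson with the stated means, coupled
    to worker ability through a Gaussian copula so their rank correlation with
    ability approximates ``ability_burden_correlation``.
    """

    n_centres: int
    sam_rate: float = 2.0
    mam_rate: float = 6.0
    ability_burden_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_centres, (int, np.integer)) or self.n_centres < 1:
            raise ConfigError("n_centres must be a positive integer")
        if not (self.sam_rate >= 0):
            raise ConfigError("sam_rate must be >= 0")
        if not (self.mam_rate >= 0):
            raise ConfigError("mam_rate must be >= 0")
        if not (-1.0 <= self.ability_burden_correlation <= 1.0):
            raise ConfigError("ability_burden_correlation must lie in [-1, 1]")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")


@dataclass
class SimulatedResponses:
    """A simulated response matrix with its generating truth attached."""

    matrix: ResponseMatrix
    theta: np.ndarray
    beta: np.ndarray
    dif_mask: np.ndarray

    def truth_persons(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "respondent_id": self.matrix.respondent_ids,
                "true_theta": self.theta,
                "dif_group": self.dif_mask,
            }
        )

    def truth_items(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item_code": self.matrix.item_codes, "true_beta": self.beta}
        )


def simulate_responses(config: SimulationConfig) -> SimulatedResponses:
    """Draw a binary response matrix from the Rasch model.

    Abilities theta_v ~ Normal(ability_mean, ability_sd); each cell is an
    independent Bernoulli with P(correct) = logistic(theta_v - beta_i). When
    ``dif_shift`` is set, persons with theta above the cohort median face
    difficulties beta + dif_shift instead (the shifted group is recorded in
    the returned ``dif_mask``). Output is bit-identical under a fixed seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_theta, rng_resp = (np.random.default_rng(c) for c in ss.spawn(2))
    n = config.n_persons
    beta = config.item_difficulties
    k = beta.size
    theta = config.ability_mean + config.ability_sd * rng_theta.standard_normal(n)
    dif_mask = np.zeros(n, dtype=bool)
    beta_eff = np.broadcast_to(beta, (n, k)).copy()
    if config.dif_shift is not None:
        dif_mask = theta > np.median(theta)
        beta_eff[dif_mask] += config.dif_shift
    prob = expit(theta[:, None] - beta_eff)
    x = (rng_resp.random((n, k)) < prob).astype(np.int64)
    width = max(3, len(str(n)))
    ids = [f"R{i + 1:0{width}d}" for i in range(n)]
    codes = [f"V{i + 1}" for i in range(k)]
    return SimulatedResponses(
        matrix=ResponseMatrix(ids, codes, x),
        theta=theta,
        beta=beta.copy(),
        dif_mask=dif_mask,
    )


def simulate_burden(config: BurdenSimulationConfig, abilities) -> BurdenTable:
    """Draw per-centre SAM and MAM counts coupled to worker ability.

    A latent standard-normal variable per centre mixes the standardised
    ability with independent noise at weight rho = ability_burden_correlation;
    its normal CDF value is pushed through the Poisson quantile function
    (Gaussian copula), giving exact Poisson margins and an approximate rank
    correlation rho between ability and burden.
    """
    abilities = np.asarray(abilities, dtype=float)
    if abilities.shape != (config.n_centres,):
        raise ConfigError(
            f"abilities length {abilities.size} != n_centres {config.n_centres}"
        )
    ss = np.random.SeedSequence(config.seed)
    rng_sam, rng_mam = (np.random.default_rng(c) for c in ss.spawn(2))
    sd = abilities.std()
    a_std = (abilities - abilities.mean()) / sd if sd > 0 else np.zeros_like(abilities)
    rho = config.ability_burden_correlation
    noise_w = np.sqrt(1.0 - rho**2)

    def draw(rng, rate):
        if rate == 0:
            return np.zeros(config.n_centres, dtype=int)
        z = rho * a_std + noise_w * rng.standard_normal(config.n_centres)
        u = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
        return poisson.ppf(u, rate).astype(int)

    sam = draw(rng_sam, config.sam_rate)
    mam = draw(rng_mam, config.mam_rate)
    width = max(3, len(str(config.n_centres)))
    centre_ids = [f"C{i + 1:0{width}d}" for i in range(config.n_centres)]
    return BurdenTable(centre_ids=centre_ids, sam_count=sam, mam_count=mam)
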