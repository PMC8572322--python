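"""Rasch model-fit diagnostics.

A calibrated Rasch model claims item difficulties are invariant across
subgroups of respondents (no differential item functioning, DIF). This module
checks that claim globally (Andersen likelihood-ratio test), per item (Wald
tests on subgroup difficulty contrasts and a goodness-of-fit scatter of the
two subgroup calibrations), and per item against the probabilistic response
structure (infit / outfit mean-square statistics).

The default subgrouping splits respondents at the median raw score, with ties
assigned to the LOW group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .core import (
    ItemParameters,
    PersonParameters,
    ResponseMatrix,
    fit_cml,
)
from .errors import DegenerateSplitError, DomainError

__all__ = [
    "AndersenResult",
    "WaldResult",
    "ItemFitResult",
    "split_sample",
    "andersen_lr_test",
    "wald_tests",
    "item_fit",
    "goodness_of_fit_plotdata",
]

#: Radius multiplier for a 95% bivariate-normal confidence ellipse.
ELLIPSE_Q95 = float(np.sqrt(chi2.ppf(0.95, df=2)))


@dataclass
class AndersenResult:
    """Global DIF test: twice the conditional log-likelihood gain from
    calibrating each subgroup separately, chi-square with (groups-1)(k'-1) df."""

    lr: float
    df: int
    p_value: float
    split_rule: str
    subgroup_fits: tuple
    retained_items: list
    dropped_items: list

    def summary(self) -> str:
        return (
            f"Andersen LR = {self.lr:.2f}, df = {self.df}, p = {self.p_value:.3f} "
            f"(split: {self.split_rule}; items retained: {len(self.retained_items)})"
        )


@dataclass
class WaldResult:
    """Per-item subgroup invariance tests.

    ``table`` columns: item_code, beta_low, beta_high, se_low, se_high, z,
    p_value (two-sided normal), and optionally p_bonferroni. Items that are
    inestimable in a subgroup carry NaN statistics and estimable=False.
    """

    table: pd.DataFrame
    split_rule: str


@dataclass
class ItemFitResult:
    """Per-item residual-based fit: outfit (unweighted) and infit
    (information-weighted) mean squares, expectation ~1 under the model."""

    table: pd.DataFrame


def split_sample(matrix: ResponseMatrix, rule="median") -> tuple:
    """Split respondents into LOW/HIGH subgroups.

    ``rule='median'`` assigns raw scores <= median to LOW and the rest to
    HIGH (ties go LOW). Alternatively pass an explicit binary label vector
    (0/False -> first group, 1/True -> second). Extreme-score respondents are
    retained here; they drop later inside each conditional fit.
    """
    if isinstance(rule, str):
        if rule != "median":
            raise DomainError(f"unknown split rule: {rule!r}")
        r = matrix.raw_scores
        low_mask = r <= np.median(r)
        tag = "median raw score"
    else:
        labels = np.asarray(rule)
        if labels.shape != (matrix.n_persons,):
            raise DomainError("label vector length must equal the number of respondents")
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise DegenerateSplitError(
                f"label vector must define exactly 2 groups, found {uniq.size}"
            )
        low_mask = labels == uniq[0]
        tag = "explicit labels"
    if low_mask.all() or not low_mask.any():
        raise DegenerateSplitError("split produced an empty subgroup")
    return matrix.subset_persons(low_mask), matrix.subset_persons(~low_mask), tag


def _inestimable_items(matrix: ResponseMatrix) -> set:
    """Items with margin 0 or n* among the interior-score respondents."""
    interior = matrix.subset_persons(matrix.interior_mask())
    if interior.n_persons == 0:
        return set(matrix.item_codes)
    s = interior.item_margins
    n = interior.n_persons
    return {c for c, si in zip(matrix.item_codes, s) if si == 0 or si == n}


def _harmonised_fits(matrix: ResponseMatrix, rule="median"):
    """Fit the pooled sample and both subgroups on a common estimable item set.

    Items inestimable in any of the three samples are removed pairwise from
    all fits (removal changes raw scores, so the check iterates to a fixed
    point). Returns (full_fit, low_fit, high_fit, kept_codes, dropped_codes,
    split_tag, reduced_full_matrix, low_matrix, high_matrix).
    """
    low, high, tag = split_sample(matrix, rule)
    kept = list(matrix.item_codes)
    dropped: list = []
    while True:
        full_m = matrix.subset_items(kept)
        low_m = low.subset_items(kept)
        high_m = high.subset_items(kept)
        bad = (
            _inestimable_items(full_m)
            | _inestimable_items(low_m)
            | _inestimable_items(high_m)
        )
        if not bad:
            break
        dropped.extend(sorted(bad, key=kept.index))
        kept = [c for c in kept if c not in bad]
        if len(kept) < 2:
            raise DomainError(
                "fewer than 2 items remain estimable in both subgroups"
            )
    fit_full = fit_cml(full_m)
    fit_low = fit_cml(low_m)
    fit_high = fit_cml(high_m)
    return fit_full, fit_low, fit_high, kept, dropped, tag, full_m, low_m, high_m


def andersen_lr_test(matrix: ResponseMatrix, rule="median") -> AndersenResult:
    """Andersen likelihood-ratio test for global differential item functioning.

    LR = 2 (ell_LOW + ell_HIGH - ell_FULL) at the respective conditional
    maxima, referred to chi-square with df = k' - 1 for the k' items estimable
    in every subsample.
    """
    fit_full, fit_low, fit_high, kept, dropped, tag, *_ = _harmonised_fits(matrix, rule)
    lr = 2.0 * (
        fit_low.conditional_loglik
        + fit_high.conditional_loglik
        - fit_full.conditional_loglik
    )
    if lr < -1e-8:
        raise DomainError(f"negative LR statistic ({lr:.3e}) indicates a fit failure")
    lr = max(lr, 0.0)
    df = len(kept) - 1
    return AndersenResult(
        lr=lr,
        df=df,
        p_value=float(chi2.sf(lr, df)),
        split_rule=tag,
        subgroup_fits=(fit_low, fit_high),
        retained_items=kept,
        dropped_items=dropped,
    )


def wald_tests(
    matrix: ResponseMatrix, rule="median", bonferroni: bool = False
) -> WaldResult:
    """Per-item Wald tests of difficulty invariance across the two subgroups.

    z_i = (beta_i^LOW - beta_i^HIGH) / sqrt(se_LOW^2 + se_HIGH^2) with both
    subgroup calibrations under the same sum-zero normalisation; two-sided
    normal p-values, uncorrected by default (a Bonferroni column is optional).
    Items dropped from the common estimable set appear with NaN statistics.
    """
    _, fit_low, fit_high, kept, dropped, tag, *_ = _harmonised_fits(matrix, rule)
    z = (fit_low.beta - fit_high.beta) / np.sqrt(fit_low.se**2 + fit_high.se**2)
    p = 2.0 * norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "item_code": kept,
            "beta_low": fit_low.beta,
            "beta_high": fit_high.beta,
            "se_low": fit_low.se,
            "se_high": fit_high.se,
            "z": z,
            "p_value": p,
            "estimable": True,
        }
    )
    if dropped:
        nan_rows = pd.DataFrame(
            {
                "item_code": dropped,
                "beta_low": np.nan,
                "beta_high": np.nan,
                "se_low": np.nan,
                "se_high": np.nan,
                "z": np.nan,
                "p_value": np.nan,
                "estimable": False,
            }
        )
        table = pd.concat([table, nan_rows], ignore_index=True)
        order = {c: i for i, c in enumerate(matrix.item_codes)}
        table = (
            table.assign(_o=table["item_code"].map(order))
            .sort_values("_o")
            .drop(columns="_o")
            .reset_index(drop=True)
        )
    if bonferroni:
        m = int(table["estimable"].sum())
        table["p_bonferroni"] = np.minimum(table["p_value"] * m, 1.0)
    return WaldResult(table=table, split_rule=tag)


def item_fit(
    matrix: ResponseMatrix,
    items: ItemParameters,
    persons: PersonParameters,
    clip: float = 1e-12,
) -> ItemFitResult:
    """Outfit and infit mean-square statistics per item.

    With p_vi = logistic(theta_v - beta_i) and w_vi = p_vi (1 - p_vi) over the
    n' interior-score respondents:

        outfit_i = (1/n') sum_v (x_vi - p_vi)^2 / w_vi
        infit_i  = sum_v (x_vi - p_vi)^2 / sum_v w_vi

    Probabilities are clipped to [clip, 1-clip] (and a warning issued) should
    an extreme theta push them to 0 or 1 numerically.
    """
    mask = matrix.interior_mask()
    sub = matrix.subset_persons(mask)
    theta = persons.theta_by_respondent().reindex(sub.respondent_ids).to_numpy()
    beta = np.asarray(items.beta, dtype=float)
    p = expit(theta[:, None] - beta[None, :])
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        warnings.warn("degenerate response probabilities clipped", RuntimeWarning)
        p = np.clip(p, clip, 1.0 - clip)
    x = sub.responses.astype(float)
    sq = (x - p) ** 2
    w = p * (1.0 - p)
    outfit = (sq / w).mean(axis=0)
    infit = sq.sum(axis=0) / w.sum(axis=0)
    return ItemFitResult(
        table=pd.DataFrame(
            {"item_code": matrix.item_codes, "infit_msq": infit, "outfit_msq": outfit}
        )
    )


def goodness_of_fit_plotdata(matrix: ResponseMatrix, rule="median") -> pd.DataFrame:
    """Subgroup-calibration scatter data for the graphical homogeneity check.

    One row per retained item with the LOW and HIGH subgroup difficulties,
    their SEs, and 95% confidence-ellipse half-axes (sqrt(chi2_{0.95,2}) * SE
    per axis). Under model fit the points lie on the identity line within
    their ellipses.
    """
    _, fit_low, fit_high, kept, dropped, tag, *_ = _harmonised_fits(matrix, rule)
    return pd.DataFrame(
        {
            "item_code": kept,
            "beta_low": fit_low.beta,
            "beta_high": fit_high.beta,
            "se_low": fit_low.se,
            "se_high": fit_high.se,
            "ellipse_half_low": ELLIPSE_Q95 * fit_low.se,
            "ellipse_half_high": ELLIPSE_Q95 * fit_high.se,
        }
    )
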