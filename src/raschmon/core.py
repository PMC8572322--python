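"""Conditional maximum likelihood (CML) estimation for the dichotomous Rasch model.

The Rasch model puts persons and items on one logit scale:

    P(X_vi = 1 | theta_v, beta_i) = exp(theta_v - beta_i) / (1 + exp(theta_v - beta_i))

with ``theta_v`` the ability of person v and ``beta_i`` the difficulty of item i
(negative beta = easy item). The raw score r_v = sum_i x_vi is sufficient for
theta_v, so conditioning on it eliminates the person parameters entirely; item
difficulties are then estimated by maximising the conditional likelihood, whose
normalising constants are the elementary symmetric functions (ESF)
gamma_r of the easiness parameters eps_i = exp(-beta_i).

This module provides the ESF machinery (values plus first and second partial
derivatives), the conditional log-likelihood, a Newton-Raphson CML fitter with
sum-to-zero normalisation and Wald confidence intervals, person-ability
estimation by raw score, and the item-characteristic-curve and person-item-map
plot-data exporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import (
    ConvergenceError,
    DomainError,
    InestimableItemError,
    RaschmonError,
)

__all__ = [
    "Z975",
    "ResponseMatrix",
    "ItemParameters",
    "ESFResult",
    "PersonParameters",
    "elementary_symmetric",
    "conditional_loglik",
    "fit_cml",
    "estimate_person_parameters",
    "icc_curve",
    "person_item_map",
]

#: Two-sided 97.5% standard-normal quantile used for 95% Wald intervals.
Z975 = 1.959964


# ---------------------------------------------------------------------------
# Response matrix container
# ---------------------------------------------------------------------------


@dataclass
class ResponseMatrix:
    """Complete n x k binary response matrix with respondent and item labels.

    Parameters
    ----------
    respondent_ids
        Unique identifiers, one per row.
    item_codes
        Unique identifiers, one per column (V-prefixed by convention).
    responses
        Integer array with entries in {0, 1}; no missing cells allowed.
    """

    respondent_ids: list
    item_codes: list
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.respondent_ids = [str(r) for r in self.respondent_ids]
        self.item_codes = [str(c) for c in self.item_codes]
        arr = np.asarray(self.responses)
        if arr.ndim != 2:
            raise DomainError("responses must be a 2-D matrix")
        if np.any(pd.isna(arr)):
            raise DomainError("responses contain missing cells; complete data required")
        arr = arr.astype(np.int64)
        if not np.isin(arr, (0, 1)).all():
            raise DomainError("responses must contain only 0/1 entries")
        n, k = arr.shape
        if len(self.respondent_ids) != n or len(self.item_codes) != k:
            raise DomainError("label lengths do not match the response matrix shape")
        if len(set(self.respondent_ids)) != n:
            raise DomainError("respondent ids are not unique")
        if len(set(self.item_codes)) != k:
            raise DomainError("item codes are not unique")
        self.responses = arr

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def raw_scores(self) -> np.ndarray:
        """Row sums r_v — the sufficient statistics for person ability."""
        return self.responses.sum(axis=1)

    @property
    def item_margins(self) -> np.ndarray:
        """Column sums s_i — the sufficient statistics for item difficulty."""
        return self.responses.sum(axis=0)

    def interior_mask(self) -> np.ndarray:
        """Boolean mask of respondents with 0 < r_v < k (the only ones that
        carry conditional information)."""
        r = self.raw_scores
        return (r > 0) & (r < self.n_items)

    def subset_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [rid for rid, m in zip(self.respondent_ids, mask) if m]
        return ResponseMatrix(ids, list(self.item_codes), self.responses[mask])

    def subset_items(self, codes) -> "ResponseMatrix":
        codes = [str(c) for c in codes]
        idx = [self.item_codes.index(c) for c in codes]
        return ResponseMatrix(list(self.respondent_ids), codes, self.responses[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_codes)
        df.insert(0, "respondent_id", self.respondent_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str = "respondent_id") -> "ResponseMatrix":
        items = [c for c in df.columns if c != id_column]
        return cls(df[id_column].tolist(), items, df[items].to_numpy())


# ---------------------------------------------------------------------------
# Elementary symmetric functions
# ---------------------------------------------------------------------------


@dataclass
class ESFResult:
    """Elementary symmetric function values and partial derivatives.

    ``gamma[r]`` is gamma_r(eps) for r = 0..k.  ``d1[r, i]`` = d gamma_r / d eps_i
    = gamma_{r-1} of the arguments without item i; ``d2[r, i, j]`` =
    d^2 gamma_r / d eps_i d eps_j = gamma_{r-2} without items i and j (zero on
    the diagonal). Derivative arrays are ``None`` unless requested.
    """

    eps: np.ndarray
    gamma: np.ndarray
    d1: np.ndarray | None = None
    d2: np.ndarray | None = None


def _esf_values(eps: np.ndarray) -> np.ndarray:
    """gamma_0..gamma_k by the summation recursion; O(k^2), all-positive."""
    k = eps.size
    g = np.zeros(k + 1)
    g[0] = 1.0
    for e in eps:
        g[1:] = g[1:] + e * g[:-1]
    return g


def _esf_leave_one_out(eps: np.ndarray) -> np.ndarray:
    """loo[i, r] = gamma_r of the arguments without item i, r = 0..k-1.

    All k reduced sets are advanced through the summation recursion together,
    skipping item m in row m. Purely additive, hence stable regardless of the
    spread of the arguments (backward "deflation" identities cancel
    catastrophically when one eps dominates and are avoided on purpose).
    """
    k = eps.size
    loo = np.zeros((k, k))
    loo[:, 0] = 1.0
    rows = np.arange(k)
    for m in range(k):
        mask = rows != m
        loo[mask, 1:] = loo[mask, 1:] + eps[m] * loo[mask, :-1]
    return loo


def _esf_leave_two_out(eps: np.ndarray) -> np.ndarray:
    """lto[i, j, r] = gamma_r without items i and j, r = 0..k-2 (diagonal 0).

    Same additive recursion as :func:`_esf_leave_one_out`, run jointly over
    all ordered pairs.
    """
    k = eps.size
    lto = np.zeros((k, k, k - 1))
    lto[:, :, 0] = 1.0
    idx = np.arange(k)
    for m in range(k):
        mask = (idx[:, None] != m) & (idx[None, :] != m)
        lto[mask, 1:] = lto[mask, 1:] + eps[m] * lto[mask, :-1]
    for i in range(k):
        lto[i, i, :] = 0.0
    return lto


def elementary_symmetric(eps, derivative_order: int = 0) -> ESFResult:
    """Elementary symmetric functions of positive arguments with derivatives.

    Parameters
    ----------
    eps
        Positive vector of easiness parameters, length k >= 2.
    derivative_order
        0 for values only, 1 to add first partials, 2 to add second partials.

    Returns
    -------
    ESFResult

    Notes
    -----
    Values and derivatives all use the purely additive summation recursion
    (derivatives via leave-one-out / leave-two-out reduced argument sets run
    jointly), which is numerically stable for k up to ~100 with logit-scale
    arguments.
    """
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 1 or eps.size < 2:
        raise DomainError("eps must be a 1-D vector with at least 2 entries")
    if not np.all(np.isfinite(eps)) or np.any(eps <= 0):
        raise DomainError("all ESF arguments must be finite and strictly positive")
    if derivative_order not in (0, 1, 2):
        raise DomainError("derivative_order must be 0, 1 or 2")

    k = eps.size
    gamma = _esf_values(eps)
    result = ESFResult(eps=eps, gamma=gamma)
    if derivative_order == 0:
        return result

    loo = _esf_leave_one_out(eps)
    d1 = np.zeros((k + 1, k))
    d1[1:, :] = loo.T
    result.d1 = d1
    if derivative_order == 1:
        return result

    lto = _esf_leave_two_out(eps)
    d2 = np.zeros((k + 1, k, k))
    for r in range(2, k + 1):
        d2[r] = lto[:, :, r - 2]
    result.d2 = d2
    return result


# ---------------------------------------------------------------------------
# Conditional likelihood and CML fit
# ---------------------------------------------------------------------------


def _interior_stats(matrix: ResponseMatrix):
    """Item margins and raw-score counts over interior-score respondents."""
    mask = matrix.interior_mask()
    sub = matrix.responses[mask]
    s = sub.sum(axis=0)
    r = sub.sum(axis=1)
    counts = np.bincount(r, minlength=matrix.n_items + 1)
    return s, counts, sub.shape[0]


def conditional_loglik(beta, matrix: ResponseMatrix) -> float:
    """Conditional log-likelihood of item difficulties given the raw scores.

    ell_C(beta) = -sum_i beta_i s_i - sum_v log gamma_{r_v}(eps), with the sums
    taken over respondents with interior raw scores (extreme rows contribute
    nothing). Invariant to adding a constant to every beta.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size != matrix.n_items:
        raise DomainError("beta length must equal the number of items")
    s, counts, n_int = _interior_stats(matrix)
    if n_int == 0:
        return 0.0
    eps = np.exp(-beta)
    gamma = _esf_values(eps)
    interior = np.arange(1, matrix.n_items)
    return float(-(beta @ s) - counts[interior] @ np.log(gamma[interior]))


def _conditional_probs(esf: ESFResult) -> np.ndarray:
    """pi[r-1, i] = P(X_i = 1 | raw score r) for r = 1..k-1."""
    k = esf.eps.size
    rows = np.arange(1, k)
    # d1[r, i] = gamma_{r-1}^{(i)}
    return esf.eps[None, :] * esf.d1[rows, :] / esf.gamma[rows, None]


def fit_cml(
    matrix: ResponseMatrix,
    normalization: str = "sum",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> "ItemParameters":
    """Calibrate item difficulties by conditional maximum likelihood.

    Newton-Raphson on the conditional log-likelihood in a reduced (k-1)
    parameterisation that enforces sum(beta) = 0, with step-halving whenever a
    step would decrease the likelihood. Standard errors come from the inverse
    of the negative reduced Hessian mapped back to the full parameter vector;
    95% CIs are beta +/- 1.959964 * se.

    Parameters
    ----------
    matrix
        Complete binary response matrix.
    normalization
        ``"sum"`` (default) recentres the bank to sum zero; ``"first"``
        anchors the first item at zero instead (SEs become contrast SEs
        against that item).
    tol
        Convergence tolerance on the gradient max-norm.
    max_iter
        Newton iteration cap.

    Raises
    ------
    InestimableItemError
        If any item is answered by all or by none of the interior-score
        respondents.
    ConvergenceError
        If the gradient tolerance is not reached within ``max_iter``.
    """
    if normalization not in ("sum", "first"):
        raise DomainError("normalization must be 'sum' or 'first'")
    k = matrix.n_items
    if k < 2:
        raise DomainError("at least 2 items are required")
    s, counts, n_int = _interior_stats(matrix)
    if n_int == 0:
        raise RaschmonError(
            "all respondents have extreme raw scores; no conditional information"
        )
    bad = np.flatnonzero((s == 0) | (s == n_int))
    if bad.size:
        raise InestimableItemError([matrix.item_codes[i] for i in bad])

    interior = np.arange(1, k)
    n_r = counts[interior].astype(float)

    # reduced parameterisation: beta = A @ b with sum(beta) = 0 built in
    A = np.vstack([np.eye(k - 1), -np.ones(k - 1)])

    def loglik(beta):
        eps = np.exp(-beta)
        gamma = _esf_values(eps)
        return -(beta @ s) - n_r @ np.log(gamma[interior])

    # moment start: logit of the observed wrong-answer fraction, centred
    beta = np.log((n_int - s) / s)
    beta -= beta.mean()
    b = beta[:-1].copy()
    ll = loglik(A @ b)

    grad_norm = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        beta = A @ b
        esf = elementary_symmetric(np.exp(-beta), derivative_order=2)
        pi = _conditional_probs(esf)  # (k-1, k)
        grad = -s + n_r @ pi
        grad_norm = float(np.max(np.abs(grad)))
        # Hessian of ell_C w.r.t. beta: minus the summed conditional covariances
        # (always assembled so the SE computation below has it on early exit)
        eps = esf.eps
        H = np.zeros((k, k))
        for idx, r in enumerate(interior):
            cov = (eps[:, None] * eps[None, :]) * esf.d2[r] / esf.gamma[r]
            cov -= np.outer(pi[idx], pi[idx])
            np.fill_diagonal(cov, pi[idx] * (1.0 - pi[idx]))
            H -= n_r[idx] * cov
        H_red = A.T @ H @ A
        if grad_norm < tol:
            converged = True
            break
        g_red = A.T @ grad
        try:
            step = np.linalg.solve(H_red, g_red)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ConvergenceError(grad_norm, n_iter) from exc
        # Newton direction; halve the step while the likelihood would drop.
        # The acceptance slack scales with |ll| so rounding noise near the
        # optimum cannot reject genuine Newton steps at large n.
        slack = 1e-12 * (1.0 + abs(ll))
        scale = 1.0
        for _ in range(40):
            b_new = b - scale * step
            ll_new = loglik(A @ b_new)
            if ll_new >= ll - slack:
                break
            scale *= 0.5
        b, ll = b_new, ll_new
    if not converged:
        raise ConvergenceError(grad_norm, n_iter)

    beta = A @ b
    beta -= beta.mean()  # exact recentring against accumulated round-off
    cov_full = A @ np.linalg.inv(-H_red) @ A.T
    if normalization == "first":
        # translate the anchor; SEs become SEs of beta_i - beta_1 contrasts
        c = cov_full
        var = np.diag(c) + c[0, 0] - 2.0 * c[0, :]
        var[0] = 0.0
        beta = beta - beta[0]
        se = np.sqrt(np.maximum(var, 0.0))
    else:
        se = np.sqrt(np.diag(cov_full))
    return ItemParameters(
        item_codes=list(matrix.item_codes),
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        normalization="sum-zero" if normalization == "sum" else "first-zero",
        conditional_loglik=float(loglik(beta)),
        n_iterations=n_iter,
        gradient_norm=grad_norm,
    )


@dataclass
class ItemParameters:
    """Calibrated item difficulties on the logit scale.

    ``beta`` follows the difficulty convention: negative values mark easy
    items, positive values hard items. Under the default normalisation the
    difficulties sum to zero.
    """

    item_codes: list
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    normalization: str = "sum-zero"
    conditional_loglik: float = float("nan")
    n_iterations: int = 0
    gradient_norm: float = float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_code": self.item_codes,
                "beta": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


# ---------------------------------------------------------------------------
# Person parameters
# ---------------------------------------------------------------------------


@dataclass
class PersonParameters:
    """Ability estimates theta_r per raw score, assigned to respondents.

    ``score_table`` maps every raw score 0..k to (theta, se, extreme);
    interior scores solve the ML score equation, extreme scores (0 and k)
    carry linearly extrapolated thetas and are flagged. ``assignments`` maps
    each respondent to their score's theta.
    """

    score_table: pd.DataFrame
    assignments: pd.DataFrame

    def theta_by_respondent(self) -> pd.Series:
        return self.assignments.set_index("respondent_id")["theta"]


def estimate_person_parameters(
    matrix: ResponseMatrix, items: ItemParameters
) -> PersonParameters:
    """Estimate person abilities on the calibrated logit scale.

    For each interior raw score r the ability theta_r solves
    r = sum_i logistic(theta - beta_i) by bracketed root-finding (the score
    function is strictly increasing in theta). The standard error is the
    inverse square root of the test information sum_i p_i (1 - p_i) at
    theta_r. Extreme scores get theta extrapolated linearly from the two
    adjacent interior values and are flagged ``extreme``.
    """
    k = matrix.n_items
    if k < 2:
        raise DomainError("at least 2 items are required")
    beta = np.asarray(items.beta, dtype=float)

    def score_fn(theta, target):
        return float(expit(theta - beta).sum() - target)

    lo, hi = beta.min() - 40.0, beta.max() + 40.0
    thetas = np.empty(k + 1)
    ses = np.full(k + 1, np.nan)
    for r in range(1, k):
        t = brentq(score_fn, lo, hi, args=(r,), xtol=1e-10)
        p = expit(t - beta)
        thetas[r] = t
        ses[r] = 1.0 / np.sqrt(np.sum(p * (1.0 - p)))
    if k >= 3:
        thetas[0] = thetas[1] - (thetas[2] - thetas[1])
        thetas[k] = thetas[k - 1] + (thetas[k - 1] - thetas[k - 2])
    else:
        # single interior score: fall back to a unit-logit offset
        thetas[0] = thetas[1] - 1.0
        thetas[k] = thetas[k - 1] + 1.0

    score_table = pd.DataFrame(
        {
            "raw_score": np.arange(k + 1),
            "theta": thetas,
            "se": ses,
            "extreme": [r in (0, k) for r in range(k + 1)],
        }
    )
    r_v = matrix.raw_scores
    assignments = pd.DataFrame(
        {
            "respondent_id": matrix.respondent_ids,
            "raw_score": r_v,
            "theta": thetas[r_v],
            "se": ses[r_v],
            "extreme_flag": np.isin(r_v, (0, k)),
        }
    )
    return PersonParameters(score_table=score_table, assignments=assignments)


# ---------------------------------------------------------------------------
# Plot-data exporters
# ---------------------------------------------------------------------------


def icc_curve(beta: float, theta_grid) -> np.ndarray:
    """Item characteristic curve: P(correct) over an ability grid."""
    theta = np.asarray(theta_grid, dtype=float)
    if not np.isfinite(beta) or not np.all(np.isfinite(theta)):
        raise DomainError("icc_curve requires finite inputs")
    return expit(theta - beta)


def person_item_map(items: ItemParameters, persons: PersonParameters) -> pd.DataFrame:
    """Tidy table for a Wright (person-item) map on the shared logit axis.

    One row per item (kind='item', position=beta) and one per respondent
    (kind='person', position=theta).
    """
    item_rows = pd.DataFrame(
        {"kind": "item", "id": items.item_codes, "position": items.beta}
    )
    person_rows = pd.DataFrame(
        {
            "kind": "person",
            "id": persons.assignments["respondent_id"],
            "position": persons.assignments["theta"],
        }
    )
    return pd.concat([item_rows, person_rows], ignore_index=True)
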