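# Methods

## Model and estimation

`raschmon` fits the dichotomous Rasch model
P(X_vi = 1) = logistic(θ_v − β_i). The sign convention is **difficulty**:
negative β marks easy items. Only difficulty *contrasts* are identified by
the data, so the bank is normalised to Σ β_i = 0 (an anchor-first-item-at-zero
alternative is available via `fit_cml(..., normalization="first")`).

Item difficulties are estimated by conditional maximum likelihood. With raw
score r_v sufficient for θ_v, the conditional log-likelihood is

    ℓ_C(β) = −Σ_i β_i s_i − Σ_v log γ_{r_v}(ε),   ε_i = exp(−β_i),

summed over respondents with interior raw scores (rows with r = 0 or r = k
carry no conditional information and drop out). The γ_r are elementary
symmetric functions of the ε_i. Values and their first and second partial
derivatives are computed by the purely additive summation recursion
γ_r^{(m)} = γ_r^{(m−1)} + ε_m γ_{r−1}^{(m−1)}, with derivatives obtained by
running the same recursion jointly over all leave-one-out and leave-two-out
argument subsets. The often-used backward "deflation" identity
γ_r^{(i)} = γ_r − ε_i γ_{r−1}^{(i)} is deliberately avoided: it cancels
catastrophically when one ε dominates (easily the case for a bank spanning
±2.3 logits, ε ∈ [0.1, 10]) and in practice corrupted the gradient beyond
~1e−2 at k = 25. The additive formulation is stable to k ≈ 100 at the cost
of O(k³) flops per Hessian, negligible at questionnaire sizes.

The optimiser is Newton–Raphson in a reduced (k−1)-dimensional
parameterisation that enforces the sum-zero constraint exactly, with
step-halving whenever a step would decrease ℓ_C. The step-acceptance slack
scales with |ℓ_C| (1e−12·(1+|ℓ_C|)) so that floating-point noise in the
log-likelihood at large n cannot reject genuine Newton steps near the
optimum. Convergence requires gradient max-norm < 1e−8 (cap 200 iterations;
typical fits converge in 4–6). Standard errors come from the inverse
negative reduced Hessian mapped back to the full vector; 95% CIs are
β ± 1.959964·SE. Items answered by everyone or no one among scoreable
respondents are inestimable and raise a named error.

Person parameters θ_r solve the score equation r = Σ_i logistic(θ − β_i) by
bracketed root-finding (tolerance 1e−10); SE(θ_r) = [Σ_i p_i(1−p_i)]^{−1/2}.
Extreme raw scores 0 and k have no finite MLE; they receive linearly
extrapolated values θ_1 − (θ_2 − θ_1) and θ_{k−1} + (θ_{k−1} − θ_{k−2}) and
are flagged so consumers can exclude them. For k = 2 (a single interior
score) the extrapolation degenerates and a ±1-logit offset is used instead —
a documented fallback, not a statistical claim.

## Diagnostics

All subgroup diagnostics split respondents at the **median raw score**; a
respondent exactly at the median goes to the LOW group (deterministic,
documented tie rule). Items inestimable in any of the pooled/LOW/HIGH
samples are removed pairwise from all three fits — a pairwise-complete
alternative would break the nesting of the likelihoods — and the item-removal
check iterates to a fixed point because removal changes raw scores. The
Andersen statistic is LR = 2(ℓ_LOW + ℓ_HIGH − ℓ_FULL) with df = k′ − 1 for
the k′ retained items, referred to the upper chi-square tail. Per-item Wald
statistics contrast the two subgroup calibrations under a common sum-zero
normalisation, z_i = (β̂_i^LOW − β̂_i^HIGH)/√(SE²_LOW + SE²_HIGH), with
two-sided normal p-values and **no multiple-testing correction by default**
(a Bonferroni column is optional); item retention after flagging is a
substantive reporting decision and is not automated. Infit and outfit mean
squares use the fitted p_vi = logistic(θ_v − β_i) over interior-score
respondents: outfit is the unweighted mean of squared standardised
residuals, infit the information-weighted ratio; both have expectation ≈ 1
under the model, and no misfit verdict threshold is imposed — values are
reported as is. The goodness-of-fit scatter exports per-item
(β̂_LOW, β̂_HIGH) with per-axis 95% confidence-ellipse half-axes
√χ²_{0.95,2}·SE ≈ 2.4477·SE; the half-axis multiplier is a presentation
choice for the confidence band.

If no split exists at all (every raw score identical — possible on tiny or
degenerate inputs), the pipeline completes with the invariance battery
reported as unavailable rather than aborting, since calibration and
prioritization remain well-defined.

## Prioritization

Adjusted burden per centre is SAM + w·MAM with w = 0.5 by default (a
moderately malnourished child counts half a severely malnourished one; w is
configurable in [0, 1]). Workers are placed at (adjusted burden of their
centre, ability θ) and both axes are split at the median **of the analysed
workers**; ties go to the low side on both axes, so a worker exactly at the
ability median is treated as low-ability — conservative for supervision
targeting. Segments: P1 = low ability & high burden, P2 = low & low,
P3 = high & high, P4 = high & low; P1 and P2 carry the priority flag. The
allocation depends only on ranks, hence is invariant under strictly
increasing transforms of either axis. Extreme-score workers participate via
their flagged extrapolated θ. Segment labels are semantic; where a plot
places them is left to the renderer.

## Synthetic data

The generator emulates the study conditions the pipeline is designed for:
n = 197 respondents, 25 dichotomous items, abilities Normal(0, 1.5) — the
default SD chosen so the ability distribution spans the default
bank's −2.32 to +2.01 logit range — and responses drawn independently per
cell from the Rasch probability. The default bank consists of 24 anchor
difficulties plus one balancing value (−1.123) completing a sum-zero bank;
the balancing value is a normalisation artifact, not a claim about any real
item. An optional `dif_shift` adds per-item offsets for the subgroup with
true θ above the cohort median, so a median-raw-score split approximately
recovers the shifted group in differential-item-functioning power studies.

Centre burdens are Poisson with configurable means (defaults SAM 2, MAM 6
per centre — SAM rarer than MAM, as in routine monthly reports) coupled to
ability by a Gaussian copula: a latent normal mixes standardised ability
with noise at weight ρ (`ability_burden_correlation`, pipeline default −0.3,
a modest inverse ability–burden relation), and its CDF value feeds the
Poisson quantile function, giving exact Poisson margins and rank correlation
≈ ρ. The generator does **not** emulate guessing on multiple-choice
distractors (consistent with the one-parameter model), missing responses,
multidimensional ability, or clustering of workers within supervision
blocks; a passing suite therefore validates the estimation machinery and
pipeline plumbing under model-conforming data, not robustness to those
real-data features.

One integer seed governs every draw; sub-streams are spawned
deterministically from it, and pipeline artifacts are byte-reproducible
under a fixed config and seed (manifests record config hash, seed, version
and convergence, and contain no timestamps).

## Problem sizes in the replicate studies

The validation studies use 100 replicate cohorts at 197 × 25 for difficulty
recovery (mean RMSE and 95% CI coverage), 500 replicates of n = 500, k = 10
for the Andersen type-I rate, and 200 replicates of n = 300, k = 9 (+1
injected noise item) for misfit detection — sizes chosen to give stable
Monte-Carlo estimates while keeping a full validation run in the minutes
range on one CPU.

## Known limitations

- Complete data only; any missing cell is a hard error by design.
- No polytomous models, discrimination (2PL) or guessing (3PL) parameters,
  marginal or joint ML, Martin-Löf or nonparametric quasi-exact tests.
- CML difficulty estimates carry O(1/n) finite-sample bias (verified to
  shrink with n in the test suite); SEs at extreme abilities are large, so
  quadrant placement of extreme scorers is less reliable than of mid-range
  scorers.
- The extrapolated θ for extreme raw scores is a pragmatic placement device
  for the person-item map and quadrant plot, not an estimate with valid SE.
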