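# raschmon

Rasch-model calibration and burden-adjusted supervision prioritization for
front-line health workers.

Community-based management of severe acute malnutrition (CSAM) depends on the
knowledge and skills of front-line workers (in India, Anganwadi workers — one
per Anganwadi centre). Supervisors need two things a raw test score cannot
give them: a worker-ability measure on a linear, item-difficulty-aware scale,
and a way to combine it with each centre's caseload so scarce supervision
visits go where they matter most. `raschmon` provides both as a reproducible
pipeline over a dichotomous questionnaire (typically 25 items) and a
per-centre table of severe (SAM) and moderate (MAM) acute malnutrition
counts.

## The model

Responses follow the dichotomous Rasch model: person *v* with ability
θ_v (logits) answers item *i* with difficulty β_i correctly with probability

    P(X_vi = 1) = exp(θ_v − β_i) / (1 + exp(θ_v − β_i)).

Item difficulties are estimated by **conditional maximum likelihood** (CML):
the raw score r_v = Σ_i x_vi is sufficient for θ_v, and conditioning on it
removes the person parameters, leaving

    ℓ_C(β) = −Σ_i β_i s_i − Σ_v log γ_{r_v}(ε),     ε_i = exp(−β_i),

where γ_r are the elementary symmetric functions of the ε_i and s_i are the
item margins. The fit is Newton–Raphson with analytic gradient and Hessian
(conditional item covariances), normalised to Σ β_i = 0, with Wald 95%
confidence intervals. Person abilities θ_r are then recovered per raw score
on the same logit scale. Model fit is checked by the Andersen
likelihood-ratio test (global difficulty invariance across a median-score
split), per-item Wald tests, infit/outfit mean squares, and a subgroup
goodness-of-fit scatter.

Prioritization crosses ability with the **adjusted burden** of each worker's
centre, SAM + 0.5·MAM, and splits both axes at their medians: P1 (low
ability, high burden) and P2 (low ability, low burden) are the priority
segments for supportive supervision; P3 and P4 are the high-ability
quadrants.

Because the original field responses are not deposited, the package ships a
synthetic-data module that simulates Rasch-conforming cohorts from a default
25-item bank spanning −2.32 to +2.01 logits, plus Poisson centre burdens with
a tunable rank correlation to ability.

## Worked example

```python
import numpy as np
import raschmon as rm

sim = rm.simulate_responses(rm.SimulationConfig(n_persons=197, seed=1))
items = rm.fit_cml(sim.matrix)
print(items.to_dataframe().head(3).round(3).to_string(index=False))
print(rm.andersen_lr_test(sim.matrix).summary())

persons = rm.estimate_person_parameters(sim.matrix, items)
burden = rm.simulate_burden(
    rm.BurdenSimulationConfig(n_centres=197, sam_rate=2, mam_rate=6,
                              ability_burden_correlation=-0.3, seed=2),
    sim.theta,
)
alloc = rm.allocate_quadrants(
    persons.theta_by_respondent(), burden,
    dict(zip(sim.matrix.respondent_ids, burden.centre_ids)),
)
print(alloc.segment_counts().to_dict())
```

prints

```
item_code   beta    se  ci_low  ci_high
       V1 -1.085 0.175  -1.427   -0.742
       V2 -0.142 0.166  -0.468    0.183
       V3 -2.226 0.212  -2.641   -1.811
Andersen LR = 21.38, df = 24, p = 0.616 (split: median raw score; items retained: 25)
{'P1': 54, 'P2': 49, 'P3': 35, 'P4': 59}
```

Item V3 is recovered as the easiest item (−2.23 logits: almost everyone
answers it correctly), V19 as the hardest (+2.20). The Andersen test has
df = k − 1 = 24 and its large p-value shows no global differential item
functioning in this model-conforming cohort. The segment counts place 103 of
197 workers (P1 + P2, the low-ability half) on the supervision priority
list, split by whether their centre's adjusted burden is above or below the
median.

The same pipeline runs from the shell:

```sh
raschmon run --seed 1 --out-dir run1        # simulate → fit → diagnose → prioritize
raschmon fit --responses responses.csv      # or stage by stage on real files
raschmon diagnose --responses responses.csv
raschmon prioritize --persons person_parameters.csv \
    --burden burden.csv --worker-map worker_centre_map.csv
```

Every run writes CSV artifacts (item and person parameters, diagnostics,
plot data for the ICC, person-item map and quadrant scatter, the allocation)
plus a manifest recording config, seed and convergence; identical config and
seed reproduce every file byte for byte.

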