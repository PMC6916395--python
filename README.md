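# jmie — joint models with intermediate events

`jmie` fits Bayesian joint models for a repeatedly measured biomarker and a
right-censored event time when an *intermediate event* — a reoperation, a
serious adverse event, a treatment change — occurs during follow-up at a
subject-specific time ρ and reshapes both the biomarker trajectory and the
instantaneous risk. It is aimed at biostatisticians building individualized
dynamic prediction tools: given a patient's biomarker history up to a
landmark time t, what is the probability of surviving to u under different
scenarios for a future intermediate event (never, now, at a chosen time s)?

## Model

Longitudinal submodel (mixed effects with a regime change at ρ):

    y_i(t) = η_i(t) + ε_i(t),  ε_i(t) ~ N(0, σ²)
    η_i(t) = x_i(t)'β + z_i(t)'b_i + R_i(t)·g(t)          R_i(t) = I(t ≥ ρ_i)

where under the drop-and-slope form g(t) = (β̃₁ + b̃ᵢ₁) + (β̃₂ + b̃ᵢ₂)·t⁺ with
t⁺ = max(0, t − ρᵢ), i.e. an instantaneous level change at the event and a
change in slope thereafter; a post-event B-spline form handles smooth
reshaping. (b_i, b̃_i) ~ N(0, D).

Survival submodel (relative risk, shared random effects):

    h_i(t) = h₀(t) exp{ γ'w_i + ζ R_i(t) + α' f(η_i; t) }

with f the association features — current value η_i(t), slope dη_i/dt,
and/or area ∫₀ᵗ η_i(s) ds — allowed to differ before and after ρ. Dynamic
predictions π(u | t, ρ-scenario) are posterior predictive Monte Carlo
estimates, and predictive accuracy is measured with an intermediate-event-
stratified time-dependent AUC and a Henderson-type expected prediction
error. See `docs/methods.md` for estimation details.

## Worked example

```python
import numpy as np
from jmie import (JointModel, PredictionScenario, SimulationConfig,
                  simulate_study)

cfg = SimulationConfig(n_subjects=300)          # scenario 1 defaults
sim = simulate_study(cfg, seed=21)
model = JointModel(seed=1).fit(sim.study)
print(model.summary_.loc[["beta:intercept", "beta:time", "beta:drop",
                          "beta:post_slope", "sigma"]].round(2))
```

```
                  mean    sd   q2.5  q97.5  rhat     ess
parameter
beta:intercept   20.94  0.38  20.19  21.67  1.01  401.22
beta:time         1.62  0.07   1.49   1.76  1.01   83.73
beta:drop       -16.06  0.70 -17.38 -14.70  1.01  259.70
beta:post_slope  -0.91  0.12  -1.14  -0.66  1.03  143.49
sigma             5.97  0.10   5.78   6.17  1.00  563.24
```

The generating values were intercept 20.7, slope 1.6, drop −15.5 and
post-event slope change −0.76 with σ = 6: every 95% credible interval
covers its target. Scenario-adaptive prediction for a new subject alive at
t = 20 who has not had the intermediate event:

```python
subj = next(s for s in sim.test().subjects
            if s.T_obs > 20 and (s.rho is None or s.rho > 20))
for sc in (PredictionScenario("none_through_u"),
           PredictionScenario("immediate")):
    pred = model.predict_survival(subj, 20.0, [20.0, 24.0], sc,
                                  n_mc=2000, seed=3)
    print(sc.kind, "pi(24 | 20) =", pred.median[1].round(3),
          "band", pred.lower[1].round(3), "-", pred.upper[1].round(3))
```

```
none_through_u pi(24 | 20) = 0.768 band 0.62 - 0.877
immediate pi(24 | 20) = 0.909 band 0.821 - 0.965
```

For this subject an immediate intermediate event raises the four-year-ahead
survival probability from 0.77 to 0.91: the direct risk increase ζ > 0 is
outweighed by the drop it induces in the biomarker, which feeds the hazard
through α > 0. A command-line interface exposes the same steps
(`jmie simulate`, `jmie fit`, `jmie predict`, `jmie evaluate`,
`jmie benchmark`); every run writes a JSON manifest with its configuration,
seed and output checksums.

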