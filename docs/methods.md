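# Methods

## Model

`jmie` fits a joint model for a repeatedly measured biomarker and a
right-censored event time in the presence of a single *intermediate event*
(a reoperation, a serious adverse event, a treatment switch) at a
subject-specific time ρᵢ. The event status Rᵢ(t) = I(t ≥ ρᵢ) and the
post-event clock tᵢ⁺ = max(0, t − ρᵢ) enter both submodels.

**Longitudinal submodel.** The observed biomarker is yᵢ(t) = ηᵢ(t) + εᵢ(t),
εᵢ(t) ~ N(0, σ²), with

    ηᵢ(t) = xᵢ(t)'β + zᵢ(t)'bᵢ                                   t < ρᵢ
    ηᵢ(t) = xᵢ(t)'β + zᵢ(t)'bᵢ + x̃ᵢ(t)'β̃ + z̃ᵢ(t)'b̃ᵢ             t ≥ ρᵢ

The pre-event design is an intercept, a linear or natural-cubic-spline time
trend, and baseline covariates. The post-event design x̃ is either
`drop_and_slope` — the columns [Rᵢ(t), tᵢ⁺], i.e. an instantaneous level
change plus a slope change — or `post_spline`, a cubic B-spline basis in
tᵢ⁺ (no separate R column: the basis carries the change). The stacked
random effects (bᵢ, b̃ᵢ) share one q×q covariance matrix D. The status is
closed at ρ: a record taken exactly at the event belongs to the post-event
regime, and one-sided derivatives at ρ use the post-event side.

**Survival submodel.** A relative-risk model

    hᵢ(t) = h₀(t) exp{ γ'wᵢ + ζ Rᵢ(t) + α' f(t) }

where ζ is the direct log hazard ratio of the intermediate event and f(t)
collects association features of the trajectory — current value ηᵢ(t),
current slope dηᵢ/dt, cumulative area ∫₀ᵗ ηᵢ(s)ds — with possibly different
feature sets before and after ρ, plus an optional Rᵢ(t)×slope interaction.
Each feature can be scaled (e.g. per 20 mmHg) before meeting its
coefficient. The baseline h₀ is Weibull (ξ t^(ξ−1)) or exp(B-spline).

Cumulative hazards are integrated with a 15-point Gauss–Kronrod rule
(7-point Gauss embedded) with adaptive bisection to relative tolerance 1e−8,
always splitting the interval at ρ because ζ and the feature switch make the
integrand jump there.

## Estimation

Estimation is Bayesian MCMC, Metropolis-within-Gibbs over (θ, {bᵢ}):

* **bᵢ** — independence MH. The full conditional under the longitudinal
  likelihood and the N(0, D) prior is Gaussian and is used as the proposal;
  the acceptance ratio reduces to the subject's survival log-likelihood
  change. All subjects update in parallel as dense-array arithmetic.
* **β** — the same construction at the population level.
* **σ², D** — conjugate inverse-gamma / inverse-Wishart Gibbs draws.
* **survival block (baseline, γ, ζ, α)** — when the baseline is Weibull and
  an intercept-like covariate is present, the level is absorbed
  (λ₀ = γ₀ + log ξ, λ₁ = ξ − 1) making the block's conditional a strictly
  log-concave Poisson-process likelihood, linear in all its parameters; a
  few Newton steps give a Laplace Gaussian used as an independence-MH
  proposal, which delivers near-independent draws and resolves the strong
  posterior correlations between the baseline level/shape, ζ and α (α·η has
  a large level component that γ₀ must absorb). The exp(B-spline) baseline
  is linear by construction and uses the same update. Without an absorbable
  level the block falls back to adaptive random-walk Metropolis
  (Haario-style covariance adaptation, 0.234 acceptance target).
* **funnel escape** — a multiplicative ensemble move rescales one
  random-effect column together with the matching row/column of D
  (b′ = Sb, D′ = SDS). The N(0, D) quadratic form is invariant; the prior
  normalization contributes −n log c and the map's Jacobian c^(n+q+1), so
  the net factor is (q+1) log c. This traverses the classic variance-
  component funnel that per-subject updates cross only slowly; the variance
  of weakly identified post-event random effects is where split-R̂ flags
  residual slowness first, and the fit reports it honestly.

The survival integral inside the sampler uses fixed (non-adaptive)
Gauss–Legendre abscissae per subject, split at ρᵢ; association features are
linear maps of (β, bᵢ), so every likelihood evaluation is vectorized.

Priors: N(0, 10²) on β, β̃, γ, ζ, α; N(0, 3²) on log ξ; inverse-gamma
(0.01, 0.01) on σ²; inverse-Wishart(q+2, I) on D (chosen conjugate to the
Gibbs blocks); first-order random-walk shrinkage with a Gamma(1, 0.005)
smoothing precision on log-baseline B-spline coefficients. Defaults: 2
chains, 1500 warmup + 1500 retained sweeps each. `fit` reports split-R̂ and
bulk ESS per parameter and flags (never suppresses) possible
non-convergence at R̂ ≥ 1.05. D is initialized from a method-of-moments
covariance of per-subject ridge solves so chains do not start deep in the
small-variance pinch.

## Dynamic prediction

For a new subject alive at landmark t, π(u | t, ρ) is estimated by Monte
Carlo over retained posterior draws θ⁽ᵐ⁾ (default M = 2000; M < 200 is
flagged in the output). Per draw, bⱼ is sampled from
p(b | T* > t, Y(t), θ⁽ᵐ⁾) by independence MH whose proposal is the exact
longitudinal conditional Gaussian, with the survival factor Pr(T* > t | b)
in the acceptance ratio (5 steps by default; all draws advance in
parallel). Scenarios place the intermediate event: never within the
horizon, immediately at t, at a chosen s ∈ (t, u], or at its observed time
ρ ≤ t. Random effects tied to post-event terms with no post-event data are
implicitly drawn from their conditional prior given the identified
components (through the joint N(0, D) in the proposal). The pointwise
median is the point estimate; the 2.5%/97.5% percentiles give the credible
band. Scenario hypotheticals never modify the likelihood of biomarker
values already observed by t.

## Predictive accuracy

At landmark t with horizon Δt, subjects at risk are stratified into A
(t < ρ or no event yet) and B (ρ ≤ t), and predictions are computed under
each subject's observed status. The time-dependent AUC decomposes over four
ordered-pair classes formed within a stratum (event/survivor pairs count 1;
pairs broken by censoring are weighted by the probability they would have
been comparable, ν̂₂ = 1 − π̂ᵢ(t+Δt | Tᵢ), ν̂₃ = π̂ⱼ(t+Δt | Tⱼ), ν̂₄ = ν̂₂ν̂₃).
Concordance is strict (ties contribute zero and are counted — a
predictor producing constant predictions within a stratum, like the
time-dependent Cox comparator here, scores 0 rather than ½). Because a sum
of two within-stratum ratios is not bounded by 1, the headline AUC pools
numerators and denominators across strata and classes; per-stratum and
per-class ratios are reported alongside. The expected prediction error is
the Brier-type square loss with the Henderson-style split for subjects
censored inside the window — their loss is the mixture of the two outcome
branches weighted by their own predicted survival from the censoring time —
averaged per stratum and pooled with at-risk weights. π̂ᵢ(u | Tᵢ) for a
censored subject is obtained by re-running the dynamic prediction from
landmark Tᵢ under the subject's observed status at Tᵢ.

## Synthetic-data generator

The generator emulates a follow-up study with a biomarker-triggered
intermediate event. Trajectories are linear with a drop and slope change,
with three scenario coefficient sets for (intercept, slope, drop, slope
change): (20.7, 1.6, −15.5, −0.76), the same with zero slope change, and
the same with zero drop. Per subject, 20 visit times are drawn U(0, 30);
bᵢ ~ N(0, D) with q = 4; the true event time solves H(T*) = E, E ~ Exp(1),
by bracketed root finding on the quadrature-evaluated cumulative hazard
under hᵢ(t) = ξ t^(ξ−1) exp{γ + ζRᵢ(t) + α ηᵢ(t)}; censoring is exponential
with mean 22.6 plus administrative censoring at the end of the visit window
(trajectories and visits are undefined beyond it). Visits after the
observed time are discarded, as is ρ when it exceeds the observed time.

Values the study design leaves open were fixed once: σ = 6 (moderate
measurement error for a biomarker of this scale), D with SDs
(4.5, 0.55, 4.0, 0.30) and a mild intercept–slope correlation 0.15,
γ = −7.6, ζ = 0.3, α = 0.08, Weibull shape ξ = 1.5, and a trigger threshold
of 42, calibrated only so that ≈35–40% of subjects experience the
intermediate event and ≈40–45% the endpoint within the window. The printed
design shape ξ = 20.4 makes t^ξ astronomically steep over (0, 30) unless
the hazard level is rebalanced; it remains settable
(`weibull_shape=20.4`) but is not the shipped default.

**Trigger variable.** The intermediate event is scheduled at the visit
*after* the first visit at which the biomarker exceeds the threshold. The
shipped default evaluates the *observed* (noisy) measurement — the quantity
a clinician actually acts on. This choice is also what makes the generator
coherent with the fitted model: a trigger on the latent trajectory makes ρ
depend on the random effects through information that never enters the
likelihood, a non-ignorable selection that visibly attenuates the
longitudinal coefficients (the slope-change coefficient shrinks by roughly
a third in our experiments), whereas triggering on observed values is
selection on modeled observables and leaves the likelihood valid. The
latent-trajectory variant remains available (`trigger_on_noisy=False`) for
studying exactly that misspecification.

What the generator does **not** emulate: visit schedules that react to the
biomarker, measurement-error autocorrelation, competing risks, more than
one intermediate event, or covariate-dependent censoring. Passing tests
therefore demonstrate internal consistency of estimator and generator under
these conditions, not robustness to those features of real data.

## Benchmark

`run_benchmark` simulates studies, splits them in half into train/test,
fits the whole-trajectory joint model, the extrapolation comparator (which
discards post-event biomarker records and carries the pre-event trajectory
forward, keeping ζ in the hazard), and the time-dependent Cox model (status
as the only time-varying covariate, start–stop episodes split at ρ), then
scores AUC(t, Δt) and PE(t+Δt | t) on the test half at landmarks 20, 22, 24
with Δt = 2. The packaged checks run 10 replicates of n = 400 split
200/200 at landmark t = 20, with single-chain fits of 500 warmup + 500
draws and M = 150 prediction draws. At this scale the AUC ordering
(whole trajectory > extrapolation > Cox) is decisive and the prediction-
error ordering is the reverse; the extrapolation-vs-Cox gap in prediction
error is small, because the Cox model's stratum-constant predictions are
reasonably calibrated even though they cannot discriminate and squared-
error loss rewards calibration.

## Numerical choices and edge cases

* Quadrature: GK15 adaptive for reference integrals and the simulator's
  inversion (|H(T*) − E| < 1e−8 recomputed); fixed GL15 per segment inside
  MCMC and prediction for speed and smoothness in θ.
* Ties in predicted probabilities contribute zero concordance and are
  reported (`n_ties`).
* Records with missing biomarker values are dropped with a logged warning.
* A subject whose records all fall after ρ contributes no longitudinal rows
  to the extrapolation fit (logged); the survival contribution remains.
* Empty prediction grids, subjects with no history (prior-limit sampling),
  and an all-censored stratum (flagged NaN rather than 0) are supported.
* AUC with no comparable mass and PE with nobody at risk are NaN plus an
  explanatory flag, never silently 0.

## Known limitations

* Single intermediate event; no competing risks; no interval censoring of ρ.
* The D block of the posterior mixes more slowly than regression
  coefficients; with few informative subjects its split-R̂ can sit above
  1.05 while all substantive parameters are well mixed — inspect the
  per-parameter table, and prefer longer chains when D itself is of
  interest.
* The extrapolation and Cox comparators are deliberately misspecified
  (that is their role); their predictions should not be used for anything
  but comparison.
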