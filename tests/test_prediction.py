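import numpy as np
import pandas as pd
import pytest

from jmie import (AssociationSpec, JointModel, LongitudinalSpec,
                  PredictionScenario, SubjectData, predict_survival,
                  predict_table, sample_conditional_random_effects)
from jmie.posterior import PosteriorDraws


def stub_model(n_draws=400, beta=(20.0, 1.0, -10.0, -0.5), sigma=2.0,
               D=None, xi=1.0, gamma=(-2.0,), zeta=0.0, alpha=(0.0,),
               jitter=0.0, seed=0):
    """A joint model with a hand-made (possibly degenerate) posterior.

    With jitter = 0 every draw is the same theta, which turns the Monte Carlo
    predictor into a deterministic map that closed-form identities can test.
    """
    rng = np.random.default_rng(seed)
    q = 4
    D = np.diag([1e-12] * q) if D is None else np.asarray(D, float)

    def rep(x):
        x = np.asarray(x, float)
        out = np.tile(x, (1, n_draws) + (1,) * x.ndim)
        if jitter:
            out = out + jitter * rng.standard_normal(out.shape)
        return out

    params = {
        "beta": rep(list(beta)),
        "sigma": rep(sigma),
        "D": np.tile(D, (1, n_draws, 1, 1)),
        "xi": rep(xi),
        "gamma": rep(list(gamma)),
        "zeta": rep(zeta),
        "alpha": rep(list(alpha)),
    }
    model = JointModel()
    model.posterior_ = PosteriorDraws(params=params,
                                      b=np.zeros((1, n_draws, 1, q)))
    model.lspec_ = LongitudinalSpec()
    model.assoc_ = AssociationSpec()
    model.baseline_kind_ = "weibull"
    model.bsp_knots_ = model.bsp_boundary_ = None
    return model


def _subject(rho=None, times=(1.0, 3.0, 5.0), level=20.0):
    times = np.asarray(times, float)
    return SubjectData(id="new", obs_times=times, y=level + times,
                       T_obs=max(times) + 1e-9, delta=0, rho=rho,
                       w_baseline=[1.0])


def test_curve_starts_at_one_and_is_monotone(fitted_small, sim_small):
    subj = next(s for s in sim_small.test().subjects if s.T_obs > 15)
    t = 15.0
    pred = fitted_small.predict_survival(
        subj, t, np.linspace(t, 24, 10), PredictionScenario(), n_mc=300,
        seed=1)
    assert pred.median[0] == 1.0 and pred.lower[0] == 1.0
    for curve in (pred.median, pred.lower, pred.upper):
        assert np.all(np.diff(curve) <= 1e-12)
        assert np.all((curve >= 0) & (curve <= 1))
    assert np.all(pred.lower <= pred.median + 1e-12)
    assert np.all(pred.median <= pred.upper + 1e-12)


def test_immediate_event_power_identity():
    """Fixed theta, alpha = 0, zeta = log 0.5: an immediate event halves the
    hazard, so pi_immediate = pi_none ** 0.5 exactly."""
    model = stub_model(zeta=np.log(0.5), alpha=(0.0,), n_draws=50)
    subj = _subject()
    t, grid = 6.0, np.linspace(6.0, 12.0, 7)
    none = predict_survival(model, subj, t, grid,
                            PredictionScenario("none_through_u"), n_mc=50,
                            seed=0)
    imm = predict_survival(model, subj, t, grid,
                           PredictionScenario("immediate"), n_mc=50, seed=0)
    assert np.allclose(imm.median, none.median ** 0.5, atol=1e-10)


def test_at_time_curves_overlap_until_s():
    """A scheduled future event leaves the curve untouched on [t, s] and
    separates it afterwards."""
    model = stub_model(zeta=np.log(0.5), n_draws=50)
    subj = _subject()
    t, s = 6.0, 9.0
    grid = np.linspace(6.0, 12.0, 13)
    none = predict_survival(model, subj, t, grid,
                            PredictionScenario("none_through_u"), n_mc=50,
                            seed=0)
    at = predict_survival(model, subj, t, grid,
                          PredictionScenario("at_time", s=s), n_mc=50, seed=0)
    pre = grid <= s
    assert np.allclose(at.median[pre], none.median[pre], atol=1e-12)
    assert np.all(at.median[~pre] > none.median[~pre])


@pytest.mark.parametrize("zeta,better", [(-0.8, "immediate"), (0.8, "none")])
def test_intervention_ordering(zeta, better):
    """With alpha = 0 a protective (harmful) zeta makes the immediate-event
    curve dominate (be dominated by) the event-free curve pointwise."""
    model = stub_model(zeta=zeta, n_draws=40)
    subj = _subject()
    grid = np.linspace(6.0, 14.0, 9)
    none = predict_survival(model, subj, 6.0, grid,
                            PredictionScenario("none_through_u"), n_mc=40,
                            seed=0).median
    imm = predict_survival(model, subj, 6.0, grid,
                           PredictionScenario("immediate"), n_mc=40,
                           seed=0).median
    hi, lo = (imm, none) if better == "immediate" else (none, imm)
    assert np.all(hi[1:] > lo[1:])


def test_scenario_validation():
    with pytest.raises(ValueError):
        PredictionScenario("at_time")          # needs s
    sc = PredictionScenario("at_time", s=5.0)
    with pytest.raises(ValueError, match="s="):
        sc.effective_rho(t=6.0, u_max=10.0)    # s <= t
    with pytest.raises(ValueError, match="already"):
        PredictionScenario("already_occurred").effective_rho(
            t=5.0, u_max=10.0, observed_rho=None)
    assert PredictionScenario("immediate").effective_rho(3.0, 9.0) == 3.0


def test_conditional_sampler_prior_limit():
    """No measurements and t = 0: draws must match the N(0, D) prior."""
    D = np.array([[4.0, 0.8, 0.0, 0.0], [0.8, 1.0, 0.0, 0.0],
                  [0.0, 0.0, 2.0, 0.3], [0.0, 0.0, 0.3, 0.5]])
    model = stub_model(D=D)
    subj = SubjectData(id="x", obs_times=[], y=[], T_obs=1e-9, delta=0,
                       w_baseline=[1.0])
    b, _ = sample_conditional_random_effects(model, subj, t=0.0,
                                             n_mc=6000, seed=4)
    assert np.allclose(b.mean(axis=0), 0.0, atol=0.12)
    assert np.allclose(np.cov(b.T), D, atol=0.25)


def test_conditional_sampler_matches_conjugate_normal():
    """Survival disabled (vanishing hazard): the sampler must reproduce the
    closed-form Gaussian conditional of a linear mixed model."""
    D = np.diag([4.0, 0.25, 2.0, 0.1])
    beta = np.array([20.0, 1.0, -10.0, -0.5])
    sigma = 2.0
    model = stub_model(beta=beta, sigma=sigma, D=D, gamma=(-60.0,))
    subj = _subject(times=(1.0, 2.0, 4.0), level=23.0)
    t = 5.0
    b, _ = sample_conditional_random_effects(model, subj, t=t, n_mc=8000,
                                             seed=11)
    X, Z = model.lspec_.design_matrices(subj.clock, subj.obs_times)
    prec = Z.T @ Z / sigma**2 + np.linalg.inv(D)
    V = np.linalg.inv(prec)
    mean = V @ Z.T @ (subj.y - X @ beta) / sigma**2
    assert np.allclose(b.mean(axis=0), mean, atol=0.1)
    assert np.allclose(np.cov(b.T), V, atol=0.15)
    # post-event components have no data: their conditional prior given the
    # identified ones is the Schur complement, here just the D block
    assert np.allclose(np.cov(b[:, 2:].T), D[2:, 2:], atol=0.1)


def test_mc_error_scales_as_inverse_sqrt_m():
    """The spread of the Monte Carlo median estimate shrinks ~ M^(-1/2)."""
    model = stub_model(jitter=0.03, D=np.diag([1.0, 0.04, 0.5, 0.01]),
                       alpha=(0.05,), n_draws=5000)
    subj = _subject()
    grid = np.array([6.0, 10.0])
    sds = []
    Ms = [100, 400, 1600]
    for M in Ms:
        vals = [predict_survival(model, subj, 6.0, grid,
                                 PredictionScenario(), n_mc=M,
                                 seed=100 + r).median[1] for r in range(40)]
        sds.append(np.std(vals))
    slope = np.polyfit(np.log(Ms), np.log(sds), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.2)


def test_small_mc_warning_recorded():
    model = stub_model(n_draws=100)
    pred = predict_survival(model, _subject(), 6.0, [6.0, 8.0],
                            PredictionScenario(), n_mc=80, seed=0)
    assert any("unreliable" in w for w in pred.warnings)


def test_predict_table_shapes_and_round_trip(tmp_path):
    model = stub_model(n_draws=60)
    subj = _subject()
    grid = np.linspace(6.0, 12.0, 10)
    scenarios = [PredictionScenario("none_through_u"),
                 PredictionScenario("immediate")]
    table = predict_table(model, subj, scenarios, 6.0, grid, n_mc=60, seed=1)
    assert len(table) == 20
    assert set(table["scenario"]) == {"none_through_u", "immediate"}
    path = tmp_path / "pred.csv"
    table.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert np.allclose(back["median"], table["median"])
    # empty grid: empty table, no failure
    empty = predict_table(model, subj, scenarios, 6.0, [], n_mc=60)
    assert len(empty) == 0


def test_already_occurred_uses_observed_event(fitted_small, sim_small):
    subj = next(s for s in sim_small.test().subjects
                if s.rho is not None and s.T_obs > s.rho + 2)
    t = subj.rho + 1.0
    pred = fitted_small.predict_survival(
        subj, t, np.linspace(t, t + 4, 5),
        PredictionScenario("already_occurred"), n_mc=200, seed=0)
    assert pred.median[0] == 1.0
    assert np.all(np.diff(pred.median) <= 1e-12)
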