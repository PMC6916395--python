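"""Scenario-adaptive individualized dynamic survival prediction.

For a new subject alive at landmark t with biomarker history Y(t), the
conditional survival probability

    pi(u | t, rho) = Pr(T* >= u | T* > t, Y(t), rho scenario)

is estimated by Monte Carlo: posterior draws theta^(m) are taken from the
fitted model; for each, a subject-level random-effects draw b^(m) is sampled
from p(b | T* > t, Y(t), theta^(m)) by independence Metropolis-Hastings
(Gaussian proposal = the exact longitudinal conditional; the acceptance
ratio is the survival factor Pr(T* > t | b)); then
pi^(m)(u) = exp(-int_t^u h(s) ds) is accumulated on the prediction grid.
The pointwise median is the point estimate and the 2.5%/97.5% percentiles
give a 95% credible band.

Scenarios place the intermediate event relative to the prediction window:
never within it, immediately at t, at a chosen future time s in (t, u], or
already observed at rho <= t.  Random effects attached to post-event terms
for which no post-event data exist are, through the joint N(0, D) prior in
the proposal, effectively drawn from their conditional prior given the
identified components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EventClock, SubjectData, event_indicator
from .mcmc import _GL15, _feature_designs

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionScenario",
    "ScenarioPrediction",
    "sample_conditional_random_effects",
    "predict_survival",
    "predict_table",
]

_KINDS = ("none_through_u", "immediate", "at_time", "already_occurred")


@dataclass(frozen=True)
class PredictionScenario:
    """Hypothetical placement of the intermediate event for prediction."""

    kind: str = "none_through_u"
    s: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "at_time" and self.s is None:
            raise ValueError("scenario 'at_time' needs a time s")

    def effective_rho(self, t, u_max, observed_rho=None):
        """The rho the hazard and trajectory see, or None for 'never'."""
        if self.kind == "none_through_u":
            return None
        if self.kind == "immediate":
            return float(t)
        if self.kind == "at_time":
            if not (t < self.s <= u_max):
                raise ValueError(
                    f"scenario time s={self.s} must satisfy t < s <= u_max "
                    f"({t} < s <= {u_max})")
            return float(self.s)
        if observed_rho is None or observed_rho > t:
            raise ValueError(
                "scenario 'already_occurred' requires an observed "
                "intermediate event at or before the landmark time")
        return float(observed_rho)

    def label(self) -> str:
        return self.kind if self.s is None else f"{self.kind}:{self.s:g}"


@dataclass
class ScenarioPrediction:
    """A predicted survival curve with its 95% credible band."""

    u_grid: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_mc: int
    scenario: PredictionScenario
    t: float
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scenario": self.scenario.label(),
            "t": self.t,
            "u": self.u_grid,
            "median": self.median,
            "lower": self.lower,
            "upper": self.upper,
        })


def _history_designs(model, subject, t, scenario_rho):
    """Design rows of the observed biomarker history under the scenario."""
    times, y = subject.obs_times, subject.y
    keep = times <= t
    times, y = times[keep], y[keep]
    if getattr(model, "_fits_pre_event_only", False) and scenario_rho is not None:
        keep = times < scenario_rho
        times, y = times[keep], y[keep]
    clock = EventClock(scenario_rho)
    if times.size == 0:
        p, q = model.lspec_.n_fixed, model.lspec_.n_random
        return np.zeros((0, p)), np.zeros((0, q)), np.zeros(0)
    X, Z = model.lspec_.design_matrices(clock, times, subject.x_baseline)
    return X, Z, y


def _interval_nodes(model, subject, segments, scenario_rho):
    """Fixed Gauss-Legendre nodes + folded feature designs on the segments."""
    nodes15, wts15 = _GL15
    clock = EventClock(scenario_rho)
    s_all, w_all, seg_id = [], [], []
    for k, (a, b) in enumerate(segments):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        s_all.append(mid + half * nodes15)
        w_all.append(half * wts15)
        seg_id.append(np.full(15, k))
    if not s_all:
        p, q = model.lspec_.n_fixed, model.lspec_.n_random
        nf = model.assoc_.n_alpha
        return (np.zeros(0), np.zeros(0), np.zeros(0, int), np.zeros(0),
                np.zeros((nf, 0, p)), np.zeros((nf, 0, q)))
    s = np.concatenate(s_all)
    w = np.concatenate(w_all)
    seg = np.concatenate(seg_id)
    R = np.asarray(event_indicator(clock, s), float)
    FX, FZ = _feature_designs(model.lspec_, model.assoc_, clock, s,
                              subject.x_baseline)
    return s, w, seg, R, FX, FZ


def _hazard_lp(model, arrays, idx, subject, s, R, FX, FZ, beta, b):
    """Log hazard at the nodes for every retained draw: (S, K)."""
    S = idx.size
    if model.baseline_kind_ == "weibull":
        xi = arrays["xi"][idx][:, None]
        logh0 = np.log(xi) + (xi - 1.0) * np.log(s)[None, :]
    else:
        coefs = arrays["baseline_coefs"][idx]
        from .longitudinal import _bspline_basis, _bspline_knots_full
        full = _bspline_knots_full(model.bsp_knots_, model.bsp_boundary_)
        basis = _bspline_basis(np.clip(s, *model.bsp_boundary_), full)
        logh0 = coefs @ basis.T
    lp = logh0
    if "gamma" in arrays:
        w = np.atleast_1d(subject.w_baseline)
        lp = lp + (arrays["gamma"][idx] @ w)[:, None]
    lp = lp + arrays["zeta"][idx][:, None] * R[None, :]
    alpha = arrays["alpha"][idx]  # (S, nf)
    feats = np.einsum("fkp,sp->fsk", FX, beta) + np.einsum(
        "fkq,sq->fsk", FZ, b)
    lp = lp + np.einsum("sf,fsk->sk", alpha, feats)
    return lp


def sample_conditional_random_effects(model, subject: SubjectData, t,
                                      scenario=None, n_mc=2000, seed=None,
                                      mh_steps=5, u_max=None,
                                      return_acceptance=False):
    """Draw b ~ p(b | T* > t, Y(t), theta^(m)) for resampled posterior draws.

    Returns an (n_mc, q) array of random-effect draws, one per retained
    posterior draw of theta (plus the draw indices used); optionally the
    average MH acceptance rate.
    """
    scenario = scenario or PredictionScenario()
    rng = np.random.default_rng(seed)
    arrays = model.posterior_arrays()
    total = arrays["beta"].shape[0]
    idx = rng.choice(total, size=n_mc, replace=n_mc > total)
    rho_eff = scenario.effective_rho(t, np.inf if u_max is None else u_max,
                                     subject.rho)
    X, Z, y = _history_designs(model, subject, t, rho_eff)
    q = model.lspec_.n_random
    beta = arrays["beta"][idx]          # (S, p)
    sigma2 = arrays["sigma"][idx] ** 2  # (S,)
    D = arrays["D"][idx]                # (S, q, q)
    Dinv = np.linalg.inv(D)
    if len(y):
        ZtZ = Z.T @ Z
        prec = ZtZ[None] / sigma2[:, None, None] + Dinv
        cov = np.linalg.inv(prec)
        resid_t = Z.T @ (y[None, :] - beta @ X.T).T  # (q, S)
        mean = np.einsum("sqr,rs->sq", cov, resid_t / sigma2[None, :])
    else:
        cov, mean = D, np.zeros((n_mc, q))
    chol = np.linalg.cholesky(cov)

    # survival factor Pr(T* > t | b): integrate the hazard over (0, t]
    segments = []
    if t > 0:
        segments = [(0.0, t)]
        if rho_eff is not None and 0.0 < rho_eff < t:
            segments = [(0.0, rho_eff), (rho_eff, t)]
    s, w, _, R, FX, FZ = _interval_nodes(model, subject, segments, rho_eff)

    def neg_H(b):
        if s.size == 0:
            return np.zeros(n_mc)
        lp = _hazard_lp(model, arrays, idx, subject, s, R, FX, FZ, beta, b)
        return -(np.exp(lp) @ w)

    def draw():
        return mean + np.einsum("sqr,sr->sq", chol,
                                rng.standard_normal((n_mc, q)))

    b = draw()
    log_s = neg_H(b)
    n_acc = 0
    for _ in range(mh_steps):
        prop = draw()
        log_s_prop = neg_H(prop)
        acc = np.log(rng.uniform(size=n_mc)) < log_s_prop - log_s
        b = np.where(acc[:, None], prop, b)
        log_s = np.where(acc, log_s_prop, log_s)
        n_acc += acc.mean()
    rate = n_acc / max(mh_steps, 1)
    if mh_steps and rate == 0.0 and s.size:
        raise RuntimeError(
            "conditional random-effects sampler accepted no proposals; "
            f"mean survival factor exp({np.mean(log_s):.2f}) — the landmark "
            "may be far outside the fitted model's support")
    if return_acceptance:
        return b, idx, rate
    return b, idx


def predict_survival(model, subject: SubjectData, t, u_grid, scenario=None,
                     n_mc=2000, seed=None, mh_steps=5) -> ScenarioPrediction:
    """Monte-Carlo dynamic prediction pi(u | t, scenario) on a grid of u."""
    scenario = scenario or PredictionScenario()
    u_grid = np.atleast_1d(np.asarray(u_grid, float))
    if u_grid.size and (np.any(np.diff(u_grid) < 0) or u_grid[0] < t):
        raise ValueError("u_grid must be sorted and >= t")
    warnings_list = []
    if n_mc < 200:
        warnings_list.append(
            f"n_mc={n_mc} Monte Carlo draws is small; credible bands are "
            "unreliable below 200")
        logger.debug(warnings_list[-1])
    if u_grid.size == 0:
        return ScenarioPrediction(u_grid, np.zeros(0), np.zeros(0),
                                  np.zeros(0), n_mc, scenario, float(t),
                                  warnings_list)
    u_max = float(u_grid[-1])
    rho_eff = scenario.effective_rho(t, u_max, subject.rho)
    b, idx = sample_conditional_random_effects(
        model, subject, t, scenario, n_mc=n_mc, seed=seed,
        mh_steps=mh_steps, u_max=u_max)
    arrays = model.posterior_arrays()
    beta = arrays["beta"][idx]

    # segment the prediction window at grid points and at the scenario rho
    edges = np.unique(np.concatenate([[t], u_grid]))
    if rho_eff is not None and t < rho_eff < u_max:
        edges = np.unique(np.append(edges, rho_eff))
    segments = list(zip(edges[:-1], edges[1:]))
    s, w, seg, R, FX, FZ = _interval_nodes(model, subject, segments, rho_eff)
    if s.size:
        lp = _hazard_lp(model, arrays, idx, subject, s, R, FX, FZ, beta, b)
        hz = np.exp(lp) * w[None, :]
        incr = np.zeros((n_mc, len(segments)))
        for k in range(len(segments)):
            incr[:, k] = hz[:, seg == k].sum(axis=1)
        H_edges = np.concatenate(
            [np.zeros((n_mc, 1)), np.cumsum(incr, axis=1)], axis=1)
    else:
        H_edges = np.zeros((n_mc, 1))
    curves = np.exp(-H_edges[:, np.searchsorted(edges, u_grid)])
    return ScenarioPrediction(
        u_grid=u_grid,
        median=np.median(curves, axis=0),
        lower=np.quantile(curves, 0.025, axis=0),
        upper=np.quantile(curves, 0.975, axis=0),
        n_mc=n_mc, scenario=scenario, t=float(t), warnings=warnings_list,
    )


def predict_table(model, subject, scenarios, t, u_grid, n_mc=2000,
                  seed=None) -> pd.DataFrame:
    """One row per (scenario, u): median and 95% band."""
    frames = []
    for k, sc in enumerate(scenarios):
        pred = predict_survival(model, subject, t, u_grid, sc, n_mc=n_mc,
                                seed=None if seed is None else seed + k)
        frames.append(pred.to_frame())
    if not frames:
        return pd.DataFrame(
            columns=["scenario", "t", "u", "median", "lower", "upper"])
    return pd.concat(frames, ignore_index=True)
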