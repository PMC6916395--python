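"""Estimators: the joint model, the extrapolation comparator, and the
time-varying-covariate Cox comparator.

All three follow the scikit-learn estimator protocol (`fit` on a
:class:`~jmie.data.StudyData`, fitted attributes with trailing underscores,
`get_params`/`set_params`), so they compose with sklearn tooling; the
module-level functions at the bottom are thin functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import StudyData, SubjectData, validate_study
from .hazard import AssociationSpec, BSplineLogBaseline, WeibullBaseline
from .longitudinal import LongitudinalSpec
from .mcmc import (JointSampler, MCMCControls, Priors,
                   build_longitudinal_design, build_survival_design)
from .posterior import PosteriorDraws

logger = logging.getLogger(__name__)

__all__ = [
    "JointModel",
    "ExtrapolationJointModel",
    "TimeDependentCox",
    "fit_joint_model",
    "fit_extrapolation_model",
    "fit_timedep_cox",
    "log_joint_posterior",
]


class JointModel(BaseEstimator):
    """Bayesian joint longitudinal-survival model with an intermediate event.

    Parameters
    ----------
    longitudinal : LongitudinalSpec, default drop-and-slope linear trajectory.
    association : AssociationSpec, default current-value association.
    baseline : "weibull" or "bspline" (log-baseline B-spline with an RW1
        shrinkage prior; interior knots at observed event-time quantiles).
    baseline_knots : number of interior knots for the "bspline" baseline.
    priors : Priors hyperparameters.
    n_chains, n_warmup, n_draws, thin, seed : MCMC controls.

    Fitted attributes
    -----------------
    posterior_ : PosteriorDraws
    summary_ : posterior summary DataFrame (mean, sd, 2.5/97.5%, Rhat, ESS)
    converged_ : bool, split-Rhat < 1.05 on all reported parameters
    """

    _fits_pre_event_only = False

    def __init__(self, longitudinal=None, association=None,
                 baseline="weibull", baseline_knots=5, priors=None,
                 n_chains=2, n_warmup=1500, n_draws=1500, thin=1, seed=0):
        self.longitudinal = longitudinal
        self.association = association
        self.baseline = baseline
        self.baseline_knots = baseline_knots
        self.priors = priors
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.thin = thin
        self.seed = seed

    # -- spec resolution ----------------------------------------------------
    def _resolve_specs(self, data: StudyData):
        lspec = self.longitudinal or LongitudinalSpec()
        assoc = self.association or AssociationSpec()
        return lspec, assoc

    def _baseline_setup(self, data: StudyData):
        if self.baseline == "weibull":
            return "weibull", 1, None, None
        if self.baseline != "bspline":
            raise ValueError(f"unknown baseline kind {self.baseline!r}")
        times = np.array([s.T_obs for s in data.subjects])
        events = np.array([s.delta for s in data.subjects], bool)
        ref = times[events] if events.any() else times
        qs = np.linspace(0, 1, self.baseline_knots + 2)[1:-1]
        interior = tuple(np.unique(np.quantile(ref, qs)))
        boundary = (0.0, float(times.max()) * 1.001)
        return "bspline", len(interior) + 4, interior, boundary

    # -- fitting ------------------------------------------------------------
    def fit(self, data: StudyData, y=None):
        report = validate_study(data)
        if not report.ok:
            raise ValueError("invalid study data: " + "; ".join(report.violations))
        lspec, assoc = self._resolve_specs(data)
        kind, n_base, knots, boundary = self._baseline_setup(data)
        priors = self.priors or Priors()
        controls = MCMCControls(self.n_chains, self.n_warmup, self.n_draws,
                                self.thin, self.seed)
        ld = build_longitudinal_design(data.subjects, lspec,
                                       self._fits_pre_event_only)
        dropped = int((ld.counts == 0).sum())
        if dropped:
            logger.warning(
                "%d subject(s) contribute no longitudinal rows", dropped)
        # with a constant survival covariate the Weibull level can be
        # absorbed, making the whole survival block linear (better sampler)
        absorb = None
        if kind == "weibull" and data.subjects[0].w_baseline.size:
            W = np.vstack([np.atleast_1d(s.w_baseline)
                           for s in data.subjects])
            const = [j for j in range(W.shape[1])
                     if np.all(W[:, j] == 1.0)]
            if const:
                absorb, kind, n_base = const[0], "weibull_linear", 2
        sd = build_survival_design(data.subjects, lspec, assoc, kind,
                                   knots, boundary, drop_w_col=absorb)
        sampler = JointSampler(ld, sd, lspec.n_random, priors, kind, n_base)
        seeds = np.random.SeedSequence(self.seed).spawn(controls.n_chains)
        chains = [
            sampler.run_chain(controls, np.random.default_rng(s))
            for s in seeds
        ]
        self._assemble(chains, lspec, assoc, kind, n_base, knots, boundary,
                       data, absorb)
        self.sampler_ = sampler
        return self

    def _assemble(self, chains, lspec, assoc, kind, n_base, knots, boundary,
                  data, absorb=None):
        stack = lambda key: np.stack([c[key] for c in chains])
        phi = stack("phi")
        dw = data.subjects[0].w_baseline.size
        params = {
            "beta": stack("beta"),
            "sigma": stack("sigma"),
            "D": stack("D"),
        }
        if kind == "weibull":
            params["xi"] = np.exp(phi[:, :, 0])
            gamma = phi[:, :, n_base:n_base + dw] if dw else None
        elif kind == "weibull_linear":
            xi = 1.0 + phi[:, :, 1]
            params["xi"] = xi
            gamma_rest = phi[:, :, n_base:n_base + dw - 1]
            gamma = np.empty(phi.shape[:2] + (dw,))
            rest_cols = [j for j in range(dw) if j != absorb]
            gamma[:, :, absorb] = phi[:, :, 0] - np.log(xi)
            for k, j in enumerate(rest_cols):
                gamma[:, :, j] = gamma_rest[:, :, k]
            kind = "weibull"  # user-facing parameterization
        else:
            params["baseline_coefs"] = phi[:, :, :n_base]
            gamma = phi[:, :, n_base:n_base + dw] if dw else None
        if gamma is not None:
            params["gamma"] = gamma
        n_gamma_cols = (dw - 1 if absorb is not None else dw)
        params["zeta"] = phi[:, :, n_base + n_gamma_cols]
        params["alpha"] = phi[:, :, n_base + n_gamma_cols + 1:]
        w_names = data.meta.get("w_covariates") or [
            f"w{j+1}" for j in range(dw)]
        names = {
            "beta": [f"beta:{n}" for n in lspec.fixed_names],
            "sigma": ["sigma"],
            "xi": ["xi"],
            "zeta": ["zeta"],
            "gamma": [f"gamma:{n}" for n in w_names],
            "alpha": [f"alpha:{n}" for n in assoc.features],
        }
        acceptance = {
            k: float(np.mean([c["acceptance"][k] for c in chains]))
            for k in chains[0]["acceptance"]
        }
        self.posterior_ = PosteriorDraws(
            params=params, b=stack("b"), param_names=names,
            acceptance=acceptance, seed=self.seed)
        self.lspec_ = lspec
        self.assoc_ = assoc
        self.baseline_kind_ = kind
        self.bsp_knots_ = knots
        self.bsp_boundary_ = boundary
        self.subject_ids_ = data.ids()
        self.summary_ = self.posterior_.summary()
        # a frozen block (constant draws) fools ESS/Rhat: flag it explicitly
        stuck = bool((self.summary_["sd"] == 0.0).any())
        self.converged_ = bool(
            (self.summary_["rhat"].fillna(0.0) < 1.05).all()) and not stuck
        if stuck:
            logger.warning("one or more parameter chains never moved; "
                           "treat this fit as failed")
        if not self.converged_:
            logger.warning("joint model fit flagged as possibly non-converged")

    # -- posterior access used by the prediction machinery ------------------
    def posterior_arrays(self) -> dict:
        po = self.posterior_
        out = {k: po.stacked(k) for k in po.params}
        out["b"] = po.stacked_b()
        return out

    def baseline_from_draw(self, arrays, idx):
        if self.baseline_kind_ == "weibull":
            return WeibullBaseline(float(arrays["xi"][idx]))
        return BSplineLogBaseline(tuple(arrays["baseline_coefs"][idx]),
                                  self.bsp_knots_, self.bsp_boundary_)

    def predict_survival(self, subject: SubjectData, t, u_grid, scenario,
                         n_mc=2000, seed=None, mh_steps=5):
        """Scenario-adaptive dynamic survival prediction for a new subject."""
        from .prediction import predict_survival

        return predict_survival(self, subject, t, u_grid, scenario,
                                n_mc=n_mc, seed=seed, mh_steps=mh_steps)


class ExtrapolationJointModel(JointModel):
    """Comparator: biomarker modeled only up to the intermediate event.

    Longitudinal records taken at or after rho are omitted and the design has
    no post-event terms, so the pre-event trajectory is carried forward
    (extrapolated) past the event; the survival submodel is unchanged and
    keeps the direct effect zeta of the event status.
    """

    _fits_pre_event_only = True

    def _resolve_specs(self, data: StudyData):
        lspec, assoc = super()._resolve_specs(data)
        if lspec.post_form != "none":
            lspec = replace(lspec, post_form="none")
        return lspec, assoc


class TimeDependentCox(BaseEstimator):
    """Cox model with the intermediate-event status as its only time-varying
    covariate (no longitudinal submodel): start-stop episodes split at rho."""

    def __init__(self, penalizer=0.0):
        self.penalizer = penalizer

    @staticmethod
    def episodes(data: StudyData) -> pd.DataFrame:
        rows = []
        for s in data.subjects:
            w = {f"w{j+1}": v for j, v in enumerate(np.atleast_1d(s.w_baseline))}
            if s.rho is not None and s.rho < s.T_obs:
                rows.append({"id": s.id, "start": 0.0, "stop": s.rho,
                             "event": 0, "R": 0, **w})
                rows.append({"id": s.id, "start": s.rho, "stop": s.T_obs,
                             "event": s.delta, "R": 1, **w})
            else:
                rows.append({"id": s.id, "start": 0.0, "stop": s.T_obs,
                             "event": s.delta, "R": 0, **w})
        return pd.DataFrame(rows)

    def fit(self, data: StudyData, y=None):
        from lifelines import CoxTimeVaryingFitter, NelsonAalenFitter

        eps = self.episodes(data)
        if eps["event"].sum() == 0:
            raise ValueError("no events observed; cannot fit a hazard model")
        self.zeta_identified_ = bool(eps["R"].any())
        covs = [c for c in eps.columns
                if c not in ("id", "start", "stop", "event")
                and eps[c].nunique() > 1]  # constants are absorbed by h0
        if not self.zeta_identified_:
            if "R" in covs:
                covs.remove("R")
            logger.warning("no intermediate events in the data: "
                           "zeta is unidentified and omitted")
        self.covariates_ = covs
        if covs:
            ctv = CoxTimeVaryingFitter(penalizer=self.penalizer)
            ctv.fit(eps[["id", "start", "stop", "event"] + covs],
                    id_col="id", start_col="start", stop_col="stop",
                    event_col="event")
            self.model_ = ctv
            self.params_ = ctv.params_.copy()
            bch = ctv.baseline_cumulative_hazard_
            self._H0_times = bch.index.to_numpy(float)
            self._H0_vals = bch.iloc[:, 0].to_numpy(float)
        else:
            naf = NelsonAalenFitter()
            naf.fit(eps["stop"], event_observed=eps["event"])
            self.model_ = naf
            self.params_ = pd.Series(dtype=float)
            ch = naf.cumulative_hazard_
            self._H0_times = ch.index.to_numpy(float)
            self._H0_vals = ch.iloc[:, 0].to_numpy(float)
        return self

    def H0(self, t):
        """Breslow baseline cumulative hazard (right-continuous step)."""
        t = np.asarray(t, float)
        idx = np.searchsorted(self._H0_times, t, side="right") - 1
        vals = np.where(idx >= 0, self._H0_vals[np.maximum(idx, 0)], 0.0)
        return vals if t.ndim else float(vals)

    def predict_survival(self, subject: SubjectData, t, u, scenario_rho=None):
        """pi(u | t) under a fixed intermediate-event time (None = never)."""
        zeta = float(self.params_.get("R", 0.0))
        gamma = np.array([self.params_.get(f"w{j+1}", 0.0)
                          for j in range(np.atleast_1d(subject.w_baseline).size)])
        lp = float(gamma @ np.atleast_1d(subject.w_baseline)) if gamma.size else 0.0
        rho = scenario_rho
        H = 0.0
        if rho is None or rho >= u:
            H = (self.H0(u) - self.H0(t)) * np.exp(lp)
        else:
            split = max(t, rho)
            H = (self.H0(split) - self.H0(t)) * np.exp(lp)
            H += (self.H0(u) - self.H0(split)) * np.exp(lp + zeta)
        return float(np.exp(-H))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_joint_model(data: StudyData, **kwargs) -> JointModel:
    return JointModel(**kwargs).fit(data)


def fit_extrapolation_model(data: StudyData, **kwargs) -> ExtrapolationJointModel:
    return ExtrapolationJointModel(**kwargs).fit(data)


def fit_timedep_cox(data: StudyData, **kwargs) -> TimeDependentCox:
    return TimeDependentCox(**kwargs).fit(data)


def log_joint_posterior(data: StudyData, theta: dict, b: np.ndarray,
                        longitudinal=None, association=None,
                        baseline="weibull", priors=None) -> float:
    """Unnormalized log joint posterior density at (theta, {b_i}).

    ``theta`` must carry beta, sigma, D, zeta, alpha, and either xi (Weibull
    baseline) or baseline_coefs, plus gamma when survival covariates exist.
    Out-of-support parameter values return -inf rather than raising.
    """
    lspec = longitudinal or LongitudinalSpec()
    assoc = association or AssociationSpec()
    sigma = float(theta["sigma"])
    if sigma <= 0:
        return -np.inf
    D = np.atleast_2d(np.asarray(theta["D"], float))
    if np.any(np.linalg.eigvalsh(D) <= 0):
        return -np.inf
    model = JointModel(longitudinal=lspec, association=assoc,
                       baseline=baseline, priors=priors)
    kind, n_base, knots, boundary = model._baseline_setup(data)
    ld = build_longitudinal_design(data.subjects, lspec)
    sd = build_survival_design(data.subjects, lspec, assoc, kind, knots,
                               boundary)
    sampler = JointSampler(ld, sd, lspec.n_random, priors or Priors(), kind,
                           n_base)
    dw = data.subjects[0].w_baseline.size
    if kind == "weibull":
        base = [np.log(float(theta["xi"]))]
    else:
        base = list(np.asarray(theta["baseline_coefs"], float))
    gamma = list(np.atleast_1d(theta.get("gamma", np.zeros(dw))))
    phi = np.array(base + gamma + [float(theta["zeta"])]
                   + list(np.atleast_1d(theta["alpha"])))
    return sampler.log_joint(np.asarray(theta["beta"], float),
                             np.asarray(b, float), sigma**2, D, phi,
                             tau=float(theta.get("tau", 1.0)))
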