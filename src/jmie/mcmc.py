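"""MCMC engine for the joint model.

Sampling scheme (Metropolis-within-Gibbs over theta and the per-subject
random effects):

* ``b_i`` — independence Metropolis-Hastings.  The exact full conditional
  under the longitudinal likelihood and the N(0, D) prior is Gaussian and is
  used as the proposal; the acceptance ratio then reduces to the change in
  the subject's survival log likelihood.  All subjects update in parallel.
* ``beta`` — the same trick at the population level: propose from the
  Gaussian conditional given {b_i} (longitudinal likelihood x prior), accept
  with the total survival log-likelihood ratio.
* ``sigma^2`` — conjugate inverse-gamma Gibbs draw.
* ``D`` — conjugate inverse-Wishart Gibbs draw.
* survival block (baseline parameters, gamma, zeta, alpha) — adaptive
  random-walk Metropolis with empirical-covariance proposals (Haario-style),
  scale tuned to a 0.234 acceptance target during warmup.

The survival integral inside the sampler uses fixed (non-adaptive)
Gauss-Legendre abscissae per subject, with the integration range split at the
subject's intermediate-event time; the association features are linear maps
of (beta, b), so every likelihood evaluation is dense-array arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import invwishart

from .data import StudyData, event_indicator
from .hazard import AssociationSpec
from .longitudinal import LongitudinalSpec

__all__ = ["Priors", "MCMCControls", "LongitudinalDesign", "SurvivalDesign",
           "build_longitudinal_design", "build_survival_design", "JointSampler"]


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters (the package's own defaults; data dominate).

    coef_sd        Normal(0, coef_sd^2) on beta, gamma, zeta, alpha
    sigma2_shape/rate  inverse-gamma on the residual variance
    d_scale        inverse-Wishart IW(q + 2, d_scale * I_q) on D
    log_shape_sd   Normal(0, log_shape_sd^2) on log xi (Weibull baseline)
    bspline_tau_shape/rate  Gamma on the RW1 smoothing precision of the
                   log-baseline B-spline coefficients
    """

    coef_sd: float = 10.0
    sigma2_shape: float = 0.01
    sigma2_rate: float = 0.01
    d_scale: float = 1.0
    log_shape_sd: float = 3.0
    bspline_tau_shape: float = 1.0
    bspline_tau_rate: float = 0.005


@dataclass(frozen=True)
class MCMCControls:
    n_chains: int = 2
    n_warmup: int = 750
    n_draws: int = 750
    thin: int = 1
    seed: int = 0
    n_phi_updates: int = 3  # survival-block refreshes per sweep

    def __post_init__(self):
        if min(self.n_chains, self.n_warmup, self.n_draws, self.thin) < 1:
            raise ValueError("MCMC controls must all be positive")


@dataclass
class LongitudinalDesign:
    """Stacked longitudinal design with per-subject cross-products."""

    y: np.ndarray          # (N,)
    X: np.ndarray          # (N, p)
    Z: np.ndarray          # (N, q)
    subj: np.ndarray       # (N,) subject index
    n: int
    ZtZ: np.ndarray        # (n, q, q)
    ZtX: np.ndarray        # (n, q, p)
    Zty: np.ndarray        # (n, q)
    XtX: np.ndarray        # (p, p)
    Xty: np.ndarray        # (p,)
    counts: np.ndarray     # (n,) rows per subject


@dataclass
class SurvivalDesign:
    """Fixed-node quadrature structures for the survival log likelihood.

    Association features are linear in (beta, b): the folded designs FX/FZ
    already include the pre/post activity mask and the feature scale, so
    alpha' f(s) = sum_f alpha_f (FX[f] beta + FZ[f] b).
    """

    T: np.ndarray              # (n,) observed times
    delta: np.ndarray          # (n,)
    W: np.ndarray              # (n, dw) survival covariates
    s_nodes: np.ndarray        # (n, K) quadrature abscissae (padded with 1.0)
    w_nodes: np.ndarray        # (n, K) weights (0 on padding)
    log_s_nodes: np.ndarray    # (n, K)
    R_nodes: np.ndarray        # (n, K)
    FX_nodes: np.ndarray       # (f, n, K, p)
    FZ_nodes: np.ndarray       # (f, n, K, q)
    log_s_T: np.ndarray        # (n,)
    R_T: np.ndarray            # (n,)
    FX_T: np.ndarray           # (f, n, p)
    FZ_T: np.ndarray           # (f, n, q)
    baseline_kind: str = "weibull"
    bsp_nodes: np.ndarray | None = None   # (n, K, nb) basis at nodes
    bsp_T: np.ndarray | None = None       # (n, nb)
    rw1: np.ndarray | None = None         # (nb-1, nb) first-difference matrix

    @property
    def n_features(self) -> int:
        return self.FX_nodes.shape[0]

    def log_h0(self, base_params):
        if self.baseline_kind == "weibull":
            log_xi = float(base_params[0])
            xi = np.exp(log_xi)
            return (log_xi + (xi - 1.0) * self.log_s_nodes,
                    log_xi + (xi - 1.0) * self.log_s_T)
        if self.baseline_kind == "weibull_linear":
            # lam0 + lam1 log t == gamma0 + log xi + (xi - 1) log t
            lam0, lam1 = float(base_params[0]), float(base_params[1])
            return (lam0 + lam1 * self.log_s_nodes,
                    lam0 + lam1 * self.log_s_T)
        coefs = np.asarray(base_params, float)
        return self.bsp_nodes @ coefs, self.bsp_T @ coefs

    def loglik(self, beta, b, gamma, zeta, alpha, base_params):
        """Per-subject delta_i log h_i(T_i) - int_0^{T_i} h_i."""
        logh0_nodes, logh0_T = self.log_h0(base_params)
        wg = self.W @ gamma if gamma.size else 0.0
        fx = np.einsum("fnkp,p->fnk", self.FX_nodes, beta)
        fx += np.einsum("fnkq,nq->fnk", self.FZ_nodes, b)
        lp = logh0_nodes + np.einsum("f,fnk->nk", alpha, fx)
        lp += zeta * self.R_nodes
        if np.ndim(wg):
            lp += wg[:, None]
        H = np.einsum("nk,nk->n", self.w_nodes, np.exp(lp))
        fxT = np.einsum("fnp,p->fn", self.FX_T, beta)
        fxT += np.einsum("fnq,nq->fn", self.FZ_T, b)
        lpT = logh0_T + alpha @ fxT + zeta * self.R_T + wg
        return self.delta * lpT - H


def build_longitudinal_design(subjects, lspec: LongitudinalSpec,
                              pre_event_only=False) -> LongitudinalDesign:
    """Stack per-visit design rows; optionally keep only pre-event visits."""
    p, q, n = lspec.n_fixed, lspec.n_random, len(subjects)
    rows_X, rows_Z, rows_y, rows_s = [], [], [], []
    for i, s in enumerate(subjects):
        times, yvals = s.obs_times, s.y
        if pre_event_only and s.rho is not None:
            keep = times < s.rho
            times, yvals = times[keep], yvals[keep]
        if times.size == 0:
            continue
        X, Z = lspec.design_matrices(s.clock, times, s.x_baseline)
        rows_X.append(X)
        rows_Z.append(Z)
        rows_y.append(yvals)
        rows_s.append(np.full(times.size, i, dtype=int))
    X = np.vstack(rows_X) if rows_X else np.zeros((0, p))
    Z = np.vstack(rows_Z) if rows_Z else np.zeros((0, q))
    y = np.concatenate(rows_y) if rows_y else np.zeros(0)
    subj = np.concatenate(rows_s) if rows_s else np.zeros(0, int)
    ZtZ = np.zeros((n, q, q))
    ZtX = np.zeros((n, q, p))
    Zty = np.zeros((n, q))
    counts = np.zeros(n)
    np.add.at(ZtZ, subj, Z[:, :, None] * Z[:, None, :])
    np.add.at(ZtX, subj, Z[:, :, None] * X[:, None, :])
    np.add.at(Zty, subj, Z * y[:, None])
    np.add.at(counts, subj, 1.0)
    return LongitudinalDesign(y=y, X=X, Z=Z, subj=subj, n=n, ZtZ=ZtZ, ZtX=ZtX,
                              Zty=Zty, XtX=X.T @ X, Xty=X.T @ y, counts=counts)


_GL15 = leggauss(15)


def _quad_segments(t_end, rho):
    segs = [(0.0, t_end)]
    if rho is not None and 0.0 < rho < t_end:
        segs = [(0.0, rho), (rho, t_end)]
    return segs


def _feature_designs(lspec, assoc, clock, times, x_baseline):
    """Folded (activity- and scale-weighted) feature designs at `times`."""
    times = np.asarray(times, float)
    R = np.asarray(event_indicator(clock, times), float)
    out_X, out_Z = [], []
    cache = {}

    def designs(kind):
        if kind not in cache:
            if kind == "value":
                cache[kind] = lspec.design_matrices(clock, times, x_baseline)
            elif kind == "slope":
                cache[kind] = lspec.design_matrices(clock, times, x_baseline,
                                                    deriv=1)
            else:
                cache[kind] = lspec.area_design_matrices(clock, times,
                                                         x_baseline)
        return cache[kind]

    for f in assoc.features:
        kind = "slope" if f == "slope_x_R" else f
        X, Z = designs(kind)
        if f == "slope_x_R":
            active = R
        else:
            active = np.where(R > 0, float(f in assoc.post_features),
                              float(f in assoc.pre_features))
        scale = assoc.scale_of(f)
        out_X.append(X * (active / scale)[:, None])
        out_Z.append(Z * (active / scale)[:, None])
    return np.stack(out_X), np.stack(out_Z)


def build_survival_design(subjects, lspec: LongitudinalSpec,
                          assoc: AssociationSpec, baseline_kind="weibull",
                          bsp_knots=None, bsp_boundary=None,
                          drop_w_col=None) -> SurvivalDesign:
    from .longitudinal import _bspline_basis, _bspline_knots_full

    n = len(subjects)
    p, q, nf = lspec.n_fixed, lspec.n_random, assoc.n_alpha
    nodes15, wts15 = _GL15
    seg_lists = [_quad_segments(s.T_obs, s.rho) for s in subjects]
    K = 15 * max(len(sl) for sl in seg_lists)
    s_nodes = np.ones((n, K))
    w_nodes = np.zeros((n, K))
    R_nodes = np.zeros((n, K))
    FXn = np.zeros((nf, n, K, p))
    FZn = np.zeros((nf, n, K, q))
    FXT = np.zeros((nf, n, p))
    FZT = np.zeros((nf, n, q))
    R_T = np.zeros(n)
    for i, (subj, segs) in enumerate(zip(subjects, seg_lists)):
        offset = 0
        clock = subj.clock
        for a, bnd in segs:
            mid, half = (a + bnd) / 2.0, (bnd - a) / 2.0
            sl = slice(offset, offset + 15)
            s_nodes[i, sl] = mid + half * nodes15
            w_nodes[i, sl] = half * wts15
            offset += 15
        tt = s_nodes[i, :offset]
        R_nodes[i, :offset] = event_indicator(clock, tt)
        fX, fZ = _feature_designs(lspec, assoc, clock, tt, subj.x_baseline)
        FXn[:, i, :offset, :] = fX
        FZn[:, i, :offset, :] = fZ
        fXT, fZT = _feature_designs(lspec, assoc, clock,
                                    np.array([subj.T_obs]), subj.x_baseline)
        FXT[:, i, :] = fXT[:, 0, :]
        FZT[:, i, :] = fZT[:, 0, :]
        R_T[i] = event_indicator(clock, subj.T_obs)
    W = (np.vstack([np.atleast_1d(s.w_baseline) for s in subjects])
         if subjects[0].w_baseline.size else np.zeros((n, 0)))
    if drop_w_col is not None:
        W = np.delete(W, drop_w_col, axis=1)
    sd = SurvivalDesign(
        T=np.array([s.T_obs for s in subjects]),
        delta=np.array([float(s.delta) for s in subjects]),
        W=W,
        s_nodes=s_nodes, w_nodes=w_nodes, log_s_nodes=np.log(s_nodes),
        R_nodes=R_nodes, FX_nodes=FXn, FZ_nodes=FZn,
        log_s_T=np.log(np.array([s.T_obs for s in subjects])),
        R_T=R_T, FX_T=FXT, FZ_T=FZT, baseline_kind=baseline_kind,
    )
    if baseline_kind == "bspline":
        full = _bspline_knots_full(bsp_knots, bsp_boundary)
        nb = len(full) - 4
        flat = np.clip(s_nodes.ravel(), bsp_boundary[0], bsp_boundary[1])
        sd.bsp_nodes = _bspline_basis(flat, full).reshape(n, K, nb)
        sd.bsp_T = _bspline_basis(np.clip(sd.T, *bsp_boundary), full)
        sd.rw1 = np.diff(np.eye(nb), axis=0)
    return sd


@dataclass
class _PhiAdapt:
    """Haario-style adaptive random-walk state for the survival block."""

    dim: int
    log_scale: float = 0.0
    mean: np.ndarray = None
    cov: np.ndarray = None
    count: int = 0

    def __post_init__(self):
        self.mean = np.zeros(self.dim)
        self.cov = np.eye(self.dim) * 0.01

    def propose(self, phi, rng):
        scale = np.exp(self.log_scale) * 2.38 / np.sqrt(self.dim)
        chol = np.linalg.cholesky(self.cov + 1e-8 * np.eye(self.dim))
        return phi + scale * (chol @ rng.standard_normal(self.dim))

    def update(self, phi, accepted, warmup):
        self.count += 1
        lr = min(1.0, 5.0 / np.sqrt(self.count))
        if warmup:
            self.log_scale += lr * ((1.0 if accepted else 0.0) - 0.234)
            d = phi - self.mean
            self.mean += d / (self.count + 1)
            self.cov += lr * (np.outer(d, d) - self.cov)


class JointSampler:
    """Metropolis-within-Gibbs sampler for one chain of the joint model."""

    def __init__(self, long_design: LongitudinalDesign,
                 surv_design: SurvivalDesign, q: int, priors: Priors,
                 baseline_kind="weibull", n_baseline=1):
        self.ld = long_design
        self.sd = surv_design
        self.q = q
        self.priors = priors
        self.baseline_kind = baseline_kind
        self.n_baseline = n_baseline
        self.p = long_design.X.shape[1]
        self.dw = surv_design.W.shape[1]
        self.nf = surv_design.n_features
        self.n = long_design.n
        self.dim_phi = n_baseline + self.dw + 1 + self.nf
        self.accept = {"b": 0.0, "beta": 0.0, "phi": 0.0}
        self._tries = {"b": 0, "beta": 0, "phi": 0}
        # with a free baseline level the survival block is linear in phi:
        # its conditional is a log-concave Poisson-process likelihood, so a
        # Laplace (Newton) Gaussian works as an independence-MH proposal
        self.linear_phi = baseline_kind in ("weibull_linear", "bspline")
        if self.linear_phi:
            sd = self.sd
            n, K = sd.s_nodes.shape
            if baseline_kind == "weibull_linear":
                base_n = np.stack([np.ones((n, K)), sd.log_s_nodes], axis=2)
                base_T = np.column_stack([np.ones(n), sd.log_s_T])
            else:
                base_n, base_T = sd.bsp_nodes, sd.bsp_T
            Wn = np.broadcast_to(sd.W[:, None, :], (n, K, self.dw))
            self._xs_nodes = np.concatenate(
                [base_n, Wn, sd.R_nodes[:, :, None]], axis=2)
            self._xs_T = np.column_stack([base_T, sd.W, sd.R_T])

    def _phi_design(self, beta, b):
        """Full per-node design for the survival block at current (beta, b)."""
        f_n = np.einsum("fnkp,p->fnk", self.sd.FX_nodes, beta) \
            + np.einsum("fnkq,nq->fnk", self.sd.FZ_nodes, b)
        f_T = np.einsum("fnp,p->fn", self.sd.FX_T, beta) \
            + np.einsum("fnq,nq->fn", self.sd.FZ_T, b)
        x_nodes = np.concatenate(
            [self._xs_nodes, np.moveaxis(f_n, 0, 2)], axis=2)
        x_T = np.column_stack([self._xs_T, f_T.T]) if self.nf \
            else self._xs_T
        return x_nodes, x_T

    # -- phi packing: [baseline | gamma | zeta | alpha] ---------------------
    def unpack_phi(self, phi):
        nb, dw = self.n_baseline, self.dw
        return (phi[:nb], phi[nb:nb + dw], float(phi[nb + dw]),
                phi[nb + dw + 1:])

    def surv_loglik(self, beta, b, phi):
        base, gamma, zeta, alpha = self.unpack_phi(phi)
        return self.sd.loglik(beta, b, gamma, zeta, alpha, base)

    def log_prior_phi(self, phi, tau=None):
        base, gamma, zeta, alpha = self.unpack_phi(phi)
        pr = self.priors
        out = -0.5 * (np.sum(gamma**2) + zeta**2 + np.sum(alpha**2)) \
            / pr.coef_sd**2
        if self.baseline_kind == "weibull":
            out += -0.5 * float(base[0]) ** 2 / pr.log_shape_sd**2
        elif self.baseline_kind == "weibull_linear":
            # independent normals on (gamma0, log xi) mapped through
            # lam0 = gamma0 + log xi, lam1 = xi - 1 (Jacobian 1/xi)
            lam1 = float(base[1])
            if lam1 <= -1.0 + 1e-10:
                return -np.inf
            log_xi = np.log1p(lam1)
            gamma0 = float(base[0]) - log_xi
            out += -0.5 * gamma0**2 / pr.coef_sd**2 \
                - 0.5 * log_xi**2 / pr.log_shape_sd**2 - log_xi
        else:
            diffs = self.sd.rw1 @ base
            out += 0.5 * (len(base) - 1) * np.log(tau) \
                - 0.5 * tau * float(diffs @ diffs) \
                - 0.5 * float(base[0]) ** 2 / pr.coef_sd**2
        return float(out)

    # -- initial state ------------------------------------------------------
    def init_state(self, rng):
        ld = self.ld
        ridge = np.eye(self.p) * 1e-6
        beta = np.linalg.solve(ld.XtX + ridge, ld.Xty)
        resid = ld.y - ld.X @ beta
        sigma2 = max(float(resid @ resid) / max(len(ld.y) - self.p, 1), 1e-4)
        # method-of-moments start for D from per-subject ridge solves, so the
        # chain does not start deep in the small-variance pinch
        resid_b = ld.Zty - np.einsum("nqp,p->nq", ld.ZtX, beta)
        ridge_b = np.linalg.solve(
            ld.ZtZ + 0.5 * np.eye(self.q)[None, :, :],
            resid_b[:, :, None])[:, :, 0]
        informative = ld.counts >= 2
        if informative.sum() >= 5:
            D0 = np.cov(ridge_b[informative].T) + 0.25 * np.eye(self.q)
        else:
            D0 = np.eye(self.q) * max(sigma2, 1.0)
        state = {
            "beta": beta + 0.1 * rng.standard_normal(self.p),
            "sigma2": sigma2 * float(np.exp(0.2 * rng.standard_normal())),
            "D": np.atleast_2d(D0) * float(np.exp(0.3 * rng.standard_normal())),
            # start b at the ridge estimates: with b = 0 the association
            # coefficients are unidentified at initialization and their
            # conditional mode can be arbitrarily extreme
            "b": ridge_b,
            "tau": 1.0,
        }
        phi = np.zeros(self.dim_phi)
        # crude exponential-rate start for the baseline level; log xi = 0
        rate = max(self.sd.delta.sum(), 0.5) / self.sd.T.sum()
        if self.baseline_kind == "weibull":
            if self.dw:
                phi[self.n_baseline] = np.log(rate)
        elif self.baseline_kind == "weibull_linear":
            phi[0] = np.log(rate)
        else:
            phi[:self.n_baseline] = np.log(rate)
        state["phi"] = phi + 0.05 * rng.standard_normal(self.dim_phi)
        if self.linear_phi:
            # start the survival block at its conditional mode given the
            # initial (beta, b): chains must not begin in the proposal's tail.
            # The association coefficients are pinned near zero here — the
            # joint conditional has a spurious high-|alpha| basin (huge alpha
            # offset by the baseline level) that chains initialized inside it
            # do not leave
            x_nodes, x_T = self._phi_design(state["beta"], state["b"])
            P = self._phi_prior_precision(state["tau"]).copy()
            if self.nf:
                P[-self.nf:, -self.nf:] += np.eye(self.nf) * 1e4
            phi_hat, prec = self._laplace_fit(x_nodes, x_T, P, state["phi"])
            if np.all(np.isfinite(phi_hat)) and np.isfinite(
                    self.log_prior_phi(phi_hat, state["tau"])):
                jit = np.linalg.solve(np.linalg.cholesky(prec).T,
                                      rng.standard_normal(self.dim_phi))
                state["phi"] = phi_hat + jit
        state["surv_ll"] = self.surv_loglik(state["beta"], state["b"],
                                            state["phi"])
        return state

    # -- updates ------------------------------------------------------------
    def update_b(self, state, rng):
        ld, q = self.ld, self.q
        sigma2 = state["sigma2"]
        Dinv = np.linalg.inv(state["D"])
        prec = ld.ZtZ / sigma2 + Dinv[None, :, :]
        cov = np.linalg.inv(prec)
        r = (ld.Zty - np.einsum("nqp,p->nq", ld.ZtX, state["beta"])) / sigma2
        mean = np.einsum("nqr,nr->nq", cov, r)
        chol = np.linalg.cholesky(cov)
        prop = mean + np.einsum("nqr,nr->nq", chol,
                                rng.standard_normal((self.n, q)))
        ll_prop = self.surv_loglik(state["beta"], prop, state["phi"])
        log_acc = ll_prop - state["surv_ll"]
        acc = np.log(rng.uniform(size=self.n)) < log_acc
        state["b"] = np.where(acc[:, None], prop, state["b"])
        state["surv_ll"] = np.where(acc, ll_prop, state["surv_ll"])
        self.accept["b"] += acc.mean()
        self._tries["b"] += 1

    def update_beta(self, state, rng):
        ld = self.ld
        sigma2 = state["sigma2"]
        prior_prec = np.eye(self.p) / self.priors.coef_sd**2
        prec = ld.XtX / sigma2 + prior_prec
        cov = np.linalg.inv(prec)
        xtzb = np.einsum("nqp,nq->p", ld.ZtX, state["b"])
        mean = cov @ ((ld.Xty - xtzb) / sigma2)
        chol = np.linalg.cholesky(cov)
        prop = mean + chol @ rng.standard_normal(self.p)
        ll_prop = self.surv_loglik(prop, state["b"], state["phi"])
        if np.log(rng.uniform()) < ll_prop.sum() - state["surv_ll"].sum():
            state["beta"] = prop
            state["surv_ll"] = ll_prop
            self.accept["beta"] += 1
        else:
            # local random-walk fallback so beta can still creep when the
            # survival term makes the independence proposal all-or-nothing
            step = 0.1 * (chol @ rng.standard_normal(self.p))
            prop = state["beta"] + step
            ll_prop = self.surv_loglik(prop, state["b"], state["phi"])
            resid = ld.y - np.einsum("nq,nq->n", ld.Z, state["b"][ld.subj])
            d_long = (-0.5 * float((resid - ld.X @ prop)
                                   @ (resid - ld.X @ prop))
                      + 0.5 * float((resid - ld.X @ state["beta"])
                                    @ (resid - ld.X @ state["beta"]))) / sigma2
            d_prior = -0.5 * (float(prop @ prop)
                              - float(state["beta"] @ state["beta"])) \
                / self.priors.coef_sd**2
            if np.log(rng.uniform()) < (ll_prop.sum()
                                        - state["surv_ll"].sum()
                                        + d_long + d_prior):
                state["beta"] = prop
                state["surv_ll"] = ll_prop
        self._tries["beta"] += 1

    def update_b_scales(self, state, rng):
        """Joint rescale of one random-effect column (funnel escape move).

        The per-subject Gibbs/MH updates mix slowly in the global spread of a
        weakly identified random-effect component versus its variance in D;
        a multiplicative ensemble move traverses that ridge directly.
        """
        ld = self.ld
        nu0 = self.q + 2

        def log_iw(D):
            sign, logdet = np.linalg.slogdet(D)
            if sign <= 0:
                return -np.inf
            return -0.5 * (nu0 + self.q + 1) * logdet \
                - 0.5 * self.priors.d_scale * float(
                    np.trace(np.linalg.inv(D)))

        resid0 = ld.y - ld.X @ state["beta"] \
            - np.einsum("nq,nq->n", ld.Z, state["b"][ld.subj])
        sse0 = float(resid0 @ resid0)
        for j in list(range(self.q)) * 2:
            c = float(np.exp(0.4 * rng.standard_normal()))
            b_new = state["b"].copy()
            b_new[:, j] *= c
            scale_vec = np.ones(self.q)
            scale_vec[j] = c
            D_new = state["D"] * np.outer(scale_vec, scale_vec)
            resid_new = ld.y - ld.X @ state["beta"] \
                - np.einsum("nq,nq->n", ld.Z, b_new[ld.subj])
            sse_new = float(resid_new @ resid_new)
            d_long = -0.5 * (sse_new - sse0) / state["sigma2"]
            # b' = S b, D' = S D S: the N(0, D) quadratic form is invariant,
            # its normalization contributes -n log c, and the map's Jacobian
            # is c^(n+q+1); the net factor is (q+1) log c
            d_iw = log_iw(D_new) - log_iw(state["D"])
            ll_new = self.surv_loglik(state["beta"], b_new, state["phi"])
            d_surv = float(ll_new.sum() - state["surv_ll"].sum())
            jac = (self.q + 1) * np.log(c)
            if np.log(rng.uniform()) < d_long + d_iw + d_surv + jac:
                state["b"] = b_new
                state["D"] = D_new
                state["surv_ll"] = ll_new
                sse0 = sse_new

    def update_sigma2(self, state, rng):
        ld = self.ld
        resid = ld.y - ld.X @ state["beta"] \
            - np.einsum("nq,nq->n", ld.Z, state["b"][ld.subj])
        a = self.priors.sigma2_shape + 0.5 * len(ld.y)
        rate = self.priors.sigma2_rate + 0.5 * float(resid @ resid)
        state["sigma2"] = rate / max(rng.gamma(a), 1e-290)

    def update_D(self, state, rng):
        nu0 = self.q + 2
        scale = self.priors.d_scale * np.eye(self.q) \
            + state["b"].T @ state["b"]
        state["D"] = invwishart.rvs(df=nu0 + self.n, scale=scale,
                                    random_state=rng)
        state["D"] = np.atleast_2d(state["D"])

    def update_tau(self, state, rng):
        if self.baseline_kind != "bspline":
            return
        base = state["phi"][:self.n_baseline]
        diffs = self.sd.rw1 @ base
        a = self.priors.bspline_tau_shape + 0.5 * (len(base) - 1)
        rate = self.priors.bspline_tau_rate + 0.5 * float(diffs @ diffs)
        state["tau"] = rng.gamma(a) / rate

    def _phi_prior_precision(self, tau):
        pr = self.priors
        diag = np.full(self.dim_phi, 1.0 / pr.coef_sd**2)
        P = np.diag(diag)
        if self.baseline_kind == "bspline":
            nb = self.n_baseline
            P[:nb, :nb] = tau * (self.sd.rw1.T @ self.sd.rw1)
            P[0, 0] += 1.0 / pr.coef_sd**2
        return P

    def _laplace_fit(self, x_nodes, x_T, P, phi_start, n_newton=8):
        """Newton mode and precision of the survival-block conditional."""
        w, delta = self.sd.w_nodes, self.sd.delta
        grad_const = np.einsum("n,np->p", delta, x_T)
        eye = np.eye(self.dim_phi)
        phi_hat = phi_start.copy()
        for _ in range(n_newton):
            # the +-60 clip keeps a single runaway node from collapsing the
            # Hessian to a numerically rank-one matrix after an overshoot
            lp = np.clip(x_nodes @ phi_hat, -60, 60)
            mu = w * np.exp(lp)
            grad = grad_const - np.einsum("nk,nkp->p", mu, x_nodes) \
                - P @ phi_hat
            hess = np.einsum("nk,nkp,nkq->pq", mu, x_nodes, x_nodes) + P
            ridge = 1e-8 * max(1.0, float(np.trace(hess)) / self.dim_phi)
            try:
                step = np.linalg.solve(hess + ridge * eye, grad)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            phi_hat = phi_hat + np.clip(step, -5.0, 5.0)
        lp = np.clip(x_nodes @ phi_hat, -60, 60)
        mu = w * np.exp(lp)
        prec = np.einsum("nk,nkp,nkq->pq", mu, x_nodes, x_nodes) + P
        prec = prec + 1e-8 * max(1.0, float(np.trace(prec)) / self.dim_phi) \
            * eye
        return phi_hat, prec

    _T_DF = 7.0  # proposal degrees of freedom

    def update_phi_laplace(self, state, rng):
        """Independence MH for the log-concave survival-block conditional.

        The proposal is a multivariate t (df 7) centered at the Newton mode
        with the Laplace precision: heavier tails than the Gaussian, so the
        chain cannot freeze when the target's exponential-family tail is
        flatter than quadratic (the classic independence-MH trap).
        """
        x_nodes, x_T = self._phi_design(state["beta"], state["b"])
        w, delta = self.sd.w_nodes, self.sd.delta
        P = self._phi_prior_precision(state["tau"])
        phi_hat, prec = self._laplace_fit(x_nodes, x_T, P, state["phi"])
        chol = np.linalg.cholesky(prec)
        df, d = self._T_DF, self.dim_phi
        z = rng.standard_normal(d) / np.sqrt(rng.chisquare(df) / df)
        prop = phi_hat + np.linalg.solve(chol.T, z)

        def log_q(phi):
            u = chol.T @ (phi - phi_hat)
            return -0.5 * (df + d) * np.log1p(float(u @ u) / df)

        def lik(phi):
            lp = np.clip(x_nodes @ phi, -500, 500)
            return float(delta @ (x_T @ phi)
                         - np.einsum("nk,nk->", w, np.exp(lp)))

        def log_target(phi):
            pr = self.log_prior_phi(phi, state["tau"])
            if not np.isfinite(pr):
                return -np.inf
            return lik(phi) + pr

        num = log_target(prop) + log_q(state["phi"])
        den = log_target(state["phi"]) + log_q(prop)
        if np.log(rng.uniform()) < num - den:
            state["phi"] = prop
            state["surv_ll"] = self.surv_loglik(state["beta"], state["b"],
                                                prop)
            self.accept["phi"] += 1
        self._tries["phi"] += 1

    def update_phi(self, state, rng, adapt: _PhiAdapt, warmup):
        phi = state["phi"]
        prop = adapt.propose(phi, rng)
        ll_prop = self.surv_loglik(state["beta"], state["b"], prop)
        num = ll_prop.sum() + self.log_prior_phi(prop, state["tau"])
        den = state["surv_ll"].sum() + self.log_prior_phi(phi, state["tau"])
        accepted = np.log(rng.uniform()) < num - den
        if accepted:
            state["phi"] = prop
            state["surv_ll"] = ll_prop
            self.accept["phi"] += 1
        self._tries["phi"] += 1
        adapt.update(state["phi"], accepted, warmup)

    # -- chain driver -------------------------------------------------------
    def run_chain(self, controls: MCMCControls, rng,
                  n_phi_updates=None) -> dict:
        n_phi = n_phi_updates or controls.n_phi_updates
        state = self.init_state(rng)
        adapt = _PhiAdapt(self.dim_phi)
        keep = {"beta": [], "sigma": [], "D": [], "phi": [], "b": []}
        total = controls.n_warmup + controls.n_draws * controls.thin
        for it in range(total):
            warmup = it < controls.n_warmup
            self.update_b(state, rng)
            self.update_b_scales(state, rng)
            self.update_beta(state, rng)
            self.update_sigma2(state, rng)
            self.update_D(state, rng)
            self.update_tau(state, rng)
            if self.linear_phi:
                self.update_phi_laplace(state, rng)
            else:
                for _ in range(n_phi):
                    self.update_phi(state, rng, adapt, warmup)
            if not warmup and (it - controls.n_warmup) % controls.thin == 0:
                keep["beta"].append(state["beta"].copy())
                keep["sigma"].append(np.sqrt(state["sigma2"]))
                keep["D"].append(state["D"].copy())
                keep["phi"].append(state["phi"].copy())
                keep["b"].append(state["b"].copy())
        out = {k: np.asarray(v) for k, v in keep.items()}
        out["acceptance"] = {
            k: self.accept[k] / max(self._tries[k], 1) for k in self.accept
        }
        return out

    # -- full joint density (for tests and diagnostics) ---------------------
    def log_joint(self, beta, b, sigma2, D, phi, tau=1.0):
        ld = self.ld
        N = len(ld.y)
        resid = ld.y - ld.X @ beta - np.einsum("nq,nq->n", ld.Z, b[ld.subj])
        out = -0.5 * N * np.log(2 * np.pi * sigma2) \
            - 0.5 * float(resid @ resid) / sigma2
        out += float(self.surv_loglik(beta, b, phi).sum())
        sign, logdet = np.linalg.slogdet(D)
        if sign <= 0:
            return -np.inf
        Dinv = np.linalg.inv(D)
        out += -0.5 * self.n * (self.q * np.log(2 * np.pi) + logdet) \
            - 0.5 * float(np.einsum("nq,qr,nr->", b, Dinv, b))
        pr = self.priors
        out += -0.5 * float(beta @ beta) / pr.coef_sd**2
        out += self.log_prior_phi(phi, tau)
        # inverse-gamma log density for sigma2 (unnormalized constants kept)
        out += -(pr.sigma2_shape + 1) * np.log(sigma2) \
            - pr.sigma2_rate / sigma2
        nu0 = self.q + 2
        out += -0.5 * (nu0 + self.q + 1) * logdet \
            - 0.5 * pr.d_scale * float(np.trace(Dinv))
        return float(out)
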