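"""Mixed-effects trajectory submodel with an intermediate-event regime change.

The true biomarker level is

    eta_i(t) = x_i(t)' beta + z_i(t)' b_i                          t <  rho_i
    eta_i(t) = x_i(t)' beta + z_i(t)' b_i
               + x~_i(t)' beta~ + z~_i(t)' b~_i                    t >= rho_i

where the post-event design x~ is a function of the event status R(t) and the
post-event clock t+ = max(0, t - rho).  Two post-event forms are supported:

``drop_and_slope``
    x~(t) = [R(t), t+]: an instantaneous level change ("drop") at the event
    plus a change in slope thereafter (pulmonary-gradient-style profiles).
``post_spline``
    a cubic B-spline basis in t+ (smooth post-event reshaping, systolic-blood-
    pressure-style profiles); no separate R(t) column is needed because the
    basis itself carries the post-event change.
``none``
    no post-event terms at all: the pre-event trajectory is extrapolated.

The pre-event time trend is linear or a natural cubic spline.  All design
builders return plain numpy rows so that the trajectory, its slope and its
running integral are linear maps of (beta, b): this is what makes both the
MCMC and the prediction machinery cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

from .data import EventClock, event_indicator, relative_time

__all__ = [
    "LongitudinalSpec",
    "TrajectoryParams",
    "build_design_row",
    "eta",
    "eta_slope",
    "eta_area",
]


def _ns_knots_full(interior, boundary):
    ks = [boundary[0], *interior, boundary[1]]
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError(f"knots must be strictly increasing, got {ks}")
    return np.asarray(ks, float)


def _ns_basis(t, knots, deriv=0):
    """Natural cubic spline basis (no intercept), linear beyond the boundary.

    With K knots (boundary included) the basis has K - 1 columns; the first is
    the identity t.  Truncated-power construction with the standard linearity
    constraints beyond the boundary knots.
    """
    t = np.asarray(t, float)
    K = len(knots)
    cols = [np.ones_like(t) if deriv == 1 else (np.zeros_like(t) if deriv > 1 else t)]

    def d(j):
        # ((t-k_j)_+^3 - (t-k_K)_+^3) / (k_K - k_j), differentiated `deriv` times
        c = {0: 1.0, 1: 3.0, 2: 6.0}[deriv]
        p = 3 - deriv
        num = c * (
            np.maximum(t - knots[j], 0.0) ** p - np.maximum(t - knots[-1], 0.0) ** p
        )
        return num / (knots[-1] - knots[j])

    dK1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK1)
    return np.column_stack(cols)


def _bspline_knots_full(interior, boundary, degree=3):
    ks = [boundary[0], *interior, boundary[1]]
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError(f"knots must be strictly increasing, got {ks}")
    return np.concatenate(
        [np.repeat(boundary[0], degree), ks, np.repeat(boundary[1], degree)]
    )


def _bspline_basis(x, knots_full, degree=3, deriv=0):
    x = np.asarray(x, float)
    lo, hi = knots_full[degree], knots_full[-degree - 1]
    if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
        raise ValueError(
            f"post-event time outside the spline support [{lo}, {hi}]; "
            "no silent extrapolation"
        )
    n_basis = len(knots_full) - degree - 1
    spl = BSpline(knots_full, np.eye(n_basis), degree, extrapolate=False)
    out = spl(np.clip(x, lo, hi), nu=deriv)
    return np.nan_to_num(np.asarray(out, float))


@dataclass(frozen=True)
class LongitudinalSpec:
    """Design recipe for the trajectory submodel.

    Parameters
    ----------
    covariates : names of baseline covariates entering the fixed part.
    time_basis : "linear" or "ns" (natural cubic spline in study time).
    ns_knots, ns_boundary : interior knots / boundary of the "ns" basis.
    post_form : "drop_and_slope", "post_spline" or "none".
    post_knots, post_boundary : interior knots / boundary for "post_spline",
        on the post-event clock t+.
    random_post : whether the post-event columns also carry random effects
        (the random-effects vector is the concatenation (b_i, b~_i) with one
        joint covariance matrix D).
    """

    covariates: tuple = ()
    time_basis: str = "linear"
    ns_knots: tuple = ()
    ns_boundary: tuple = (0.0, 30.0)
    post_form: str = "drop_and_slope"
    post_knots: tuple = ()
    post_boundary: tuple = (0.0, 30.0)
    random_post: bool = True

    def __post_init__(self):
        if self.time_basis not in ("linear", "ns"):
            raise ValueError(f"unknown time_basis {self.time_basis!r}")
        if self.post_form not in ("drop_and_slope", "post_spline", "none"):
            raise ValueError(f"unknown post_form {self.post_form!r}")
        if self.time_basis == "ns":
            _ns_knots_full(self.ns_knots, self.ns_boundary)
        if self.post_form == "post_spline":
            _bspline_knots_full(self.post_knots, self.post_boundary)

    # -- column bookkeeping -------------------------------------------------
    @property
    def n_time_cols(self) -> int:
        if self.time_basis == "linear":
            return 1
        return len(self.ns_knots) + 1

    @property
    def n_post_cols(self) -> int:
        if self.post_form == "drop_and_slope":
            return 2
        if self.post_form == "post_spline":
            return len(self.post_knots) + 4  # cubic: interior + degree + 1
        return 0

    @property
    def n_fixed(self) -> int:
        return 1 + self.n_time_cols + len(self.covariates) + self.n_post_cols

    @property
    def n_random(self) -> int:
        q = 1 + self.n_time_cols
        if self.random_post:
            q += self.n_post_cols
        return q

    @property
    def fixed_names(self) -> list[str]:
        names = ["intercept"]
        if self.time_basis == "linear":
            names.append("time")
        else:
            names += [f"time_ns{j+1}" for j in range(self.n_time_cols)]
        names += list(self.covariates)
        if self.post_form == "drop_and_slope":
            names += ["drop", "post_slope"]
        elif self.post_form == "post_spline":
            names += [f"post_bs{j+1}" for j in range(self.n_post_cols)]
        return names

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "time_basis": self.time_basis,
            "ns_knots": list(self.ns_knots),
            "ns_boundary": list(self.ns_boundary),
            "post_form": self.post_form,
            "post_knots": list(self.post_knots),
            "post_boundary": list(self.post_boundary),
            "random_post": self.random_post,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LongitudinalSpec":
        d = dict(d)
        for key in ("covariates", "ns_knots", "ns_boundary", "post_knots",
                    "post_boundary"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    # -- design builders ----------------------------------------------------
    def _time_cols(self, t, deriv=0):
        t = np.asarray(t, float)
        if self.time_basis == "linear":
            if deriv == 0:
                return t[:, None]
            return (np.ones_like(t) if deriv == 1 else np.zeros_like(t))[:, None]
        return _ns_basis(t, _ns_knots_full(self.ns_knots, self.ns_boundary), deriv)

    def _post_cols(self, clock: EventClock, t, deriv=0, at_rho_post=True):
        """Post-event columns; zero rows wherever t < rho.

        ``at_rho_post`` keeps the closed-at-rho convention for derivative
        columns: slope features evaluated exactly at rho use the post side.
        """
        t = np.asarray(t, float)
        n = t.size
        if self.post_form == "none" or self.n_post_cols == 0:
            return np.zeros((n, 0))
        R = np.asarray(event_indicator(clock, t), float).reshape(n)
        tp = np.asarray(relative_time(clock, t), float).reshape(n)
        if self.post_form == "drop_and_slope":
            if deriv == 0:
                cols = np.column_stack([R, tp])
            elif deriv == 1:
                cols = np.column_stack([np.zeros(n), R if at_rho_post else (tp > 0)])
            else:
                cols = np.zeros((n, 2))
            return cols
        knots = _bspline_knots_full(self.post_knots, self.post_boundary)
        basis = _bspline_basis(tp, knots, deriv=deriv)
        return basis * R[:, None]

    def design_matrices(self, clock: EventClock, times, x_baseline=None, deriv=0):
        """Fixed and random design matrices (X, Z) at the given times.

        ``deriv=1`` gives the time-derivative designs (baseline covariates
        drop out).  Pre-event rows have exact zeros in every post column.
        """
        times = np.atleast_1d(np.asarray(times, float))
        n = times.size
        x_baseline = np.atleast_1d(np.asarray(
            np.zeros(len(self.covariates)) if x_baseline is None else x_baseline,
            float,
        ))
        if x_baseline.size != len(self.covariates):
            raise ValueError(
                f"expected {len(self.covariates)} baseline covariate value(s), "
                f"got {x_baseline.size}"
            )
        icol = (np.ones(n) if deriv == 0 else np.zeros(n))[:, None]
        tcols = self._time_cols(times, deriv)
        ccols = (
            np.repeat(x_baseline[None, :], n, axis=0)
            if deriv == 0
            else np.zeros((n, x_baseline.size))
        )
        pcols = self._post_cols(clock, times, deriv)
        X = np.column_stack([icol, tcols, ccols, pcols])
        Z = np.column_stack([icol, tcols] + ([pcols] if self.random_post else []))
        return X, Z

    def area_design_matrices(self, clock: EventClock, times, x_baseline=None):
        """Designs for the running integral: int_0^t of each design column.

        Closed form for the linear drop-and-slope case; Gauss-Legendre
        segment quadrature (split at rho and at every knot, so piecewise
        polynomials are integrated exactly) otherwise.
        """
        times = np.atleast_1d(np.asarray(times, float))
        if self.time_basis == "linear" and self.post_form in ("drop_and_slope", "none"):
            n = times.size
            x_baseline = np.atleast_1d(np.asarray(
                np.zeros(len(self.covariates)) if x_baseline is None else x_baseline,
                float,
            ))
            tp = np.asarray(relative_time(clock, times), float).reshape(n)
            cols = [times, times**2 / 2.0]
            cols += [np.full(n, c) * times for c in x_baseline]
            if self.post_form == "drop_and_slope":
                cols += [tp, tp**2 / 2.0]
            X = np.column_stack(cols)
            zcols = [times, times**2 / 2.0]
            if self.random_post and self.post_form == "drop_and_slope":
                zcols += [tp, tp**2 / 2.0]
            return X, np.column_stack(zcols)
        return self._area_by_quadrature(clock, times, x_baseline)

    def _area_by_quadrature(self, clock, times, x_baseline):
        nodes, wts = leggauss(10)
        breaks = set()
        if clock.rho is not None:
            breaks.add(float(clock.rho))
        if self.time_basis == "ns":
            breaks.update(float(k) for k in self.ns_knots)
        if self.post_form == "post_spline" and clock.rho is not None:
            breaks.update(float(clock.rho) + float(k) for k in self.post_knots)
        Xs, Zs = [], []
        for t in times:
            pts = sorted({0.0, float(t)} | {b for b in breaks if 0.0 < b < t})
            Xa = Za = None
            for a, b in zip(pts, pts[1:]):
                mid, half = (a + b) / 2.0, (b - a) / 2.0
                s = mid + half * nodes
                X, Z = self.design_matrices(clock, s, x_baseline)
                wx = half * wts
                Xa = wx @ X if Xa is None else Xa + wx @ X
                Za = wx @ Z if Za is None else Za + wx @ Z
            if Xa is None:  # t == 0: empty integral
                X0, Z0 = self.design_matrices(clock, [0.0], x_baseline)
                Xa, Za = np.zeros(X0.shape[1]), np.zeros(Z0.shape[1])
            Xs.append(Xa)
            Zs.append(Za)
        return np.asarray(Xs), np.asarray(Zs)


@dataclass
class TrajectoryParams:
    """Concrete trajectory parameters: fixed effects, random effects, sigma."""

    beta: np.ndarray
    b: np.ndarray
    sigma: float = 1.0

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        self.b = np.atleast_1d(np.asarray(self.b, float))
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def _check_dims(spec: LongitudinalSpec, params: TrajectoryParams) -> None:
    if params.beta.size != spec.n_fixed:
        raise ValueError(
            f"beta has length {params.beta.size}, design expects {spec.n_fixed}"
        )
    if params.b.size != spec.n_random:
        raise ValueError(
            f"b has length {params.b.size}, design expects {spec.n_random}"
        )


def build_design_row(spec: LongitudinalSpec, clock: EventClock, t, x_baseline=None):
    """(fixed row, random row) at a single time point."""
    X, Z = spec.design_matrices(clock, [t], x_baseline)
    return X[0], Z[0]


def eta(spec, params, clock, t, x_baseline=None):
    """True biomarker level eta(t); discontinuous at rho under drop_and_slope."""
    _check_dims(spec, params)
    t_arr = np.atleast_1d(np.asarray(t, float))
    X, Z = spec.design_matrices(clock, t_arr, x_baseline)
    out = X @ params.beta + Z @ params.b
    return out if np.ndim(t) else float(out[0])


def eta_slope(spec, params, clock, t, x_baseline=None, side=None):
    """d/dt eta(t).

    Under ``drop_and_slope`` the trajectory jumps at rho, so the derivative is
    undefined there: evaluation at t == rho is rejected unless a one-sided
    ``side`` ("-" or "+") is requested.  Association features at rho use the
    post-event side, consistent with R(rho) = 1.
    """
    _check_dims(spec, params)
    t_arr = np.atleast_1d(np.asarray(t, float))
    if (
        clock.rho is not None
        and spec.post_form == "drop_and_slope"
        and side is None
        and np.any(np.isclose(t_arr, clock.rho))
    ):
        raise ValueError(
            "slope is undefined at the intermediate-event time; pass side='-' "
            "or side='+' for a one-sided derivative"
        )
    use_clock = clock
    if side == "-" and clock.rho is not None:
        use_clock = EventClock(None) if np.all(t_arr <= clock.rho) else clock
    X, Z = spec.design_matrices(use_clock, t_arr, x_baseline, deriv=1)
    out = X @ params.beta + Z @ params.b
    return out if np.ndim(t) else float(out[0])


def eta_area(spec, params, clock, t, x_baseline=None):
    """Running integral int_0^t eta(s) ds, additive over [0, rho] and [rho, t]."""
    _check_dims(spec, params)
    t_arr = np.atleast_1d(np.asarray(t, float))
    X, Z = spec.area_design_matrices(clock, t_arr, x_baseline)
    out = X @ params.beta + Z @ params.b
    return out if np.ndim(t) else float(out[0])
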