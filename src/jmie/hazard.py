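"""Relative-risk submodel with trajectory association and event-status switching.

The hazard for subject i is

    h_i(t) = h0(t) exp{ gamma' w_i + R_i(t) zeta + alpha' f(t) }

where R_i(t) = I(t >= rho_i) is the intermediate-event status, zeta is its
direct log hazard ratio, and f(t) collects association features of the
trajectory eta_i — its current value, current slope d/dt eta, and cumulative
area int_0^t eta(s) ds — with possibly different feature sets before and
after rho (and optionally an extra R(t) x slope interaction feature).

The baseline h0 is either Weibull, h0(t) = xi t^(xi-1), or exp(B-spline) in t.

Cumulative hazards are computed with an adaptive 15-point Gauss-Kronrod rule
(7-point Gauss embedded) with bisection; the integration interval is always
split at rho because zeta and the feature switch make the integrand jump
there.  The integrand is evaluated vectorized over all nodes of a panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import EventClock, event_indicator
from .longitudinal import LongitudinalSpec, TrajectoryParams, _bspline_basis, \
    _bspline_knots_full

__all__ = [
    "AssociationSpec",
    "WeibullBaseline",
    "BSplineLogBaseline",
    "HazardParams",
    "baseline_log_hazard",
    "log_hazard",
    "cumulative_hazard",
    "survival_interval",
]

_FEATURES = ("value", "slope", "area")


@dataclass(frozen=True)
class AssociationSpec:
    """Which trajectory features drive the hazard, before and after the event.

    ``scales`` divides each feature before it meets its coefficient, so alpha
    can be reported per clinically meaningful unit (e.g. per 20 mmHg).
    """

    pre_features: tuple = ("value",)
    post_features: tuple = ("value",)
    slope_interaction: bool = False
    scales: dict = field(default_factory=dict)

    def __post_init__(self):
        for f in (*self.pre_features, *self.post_features):
            if f not in _FEATURES:
                raise ValueError(f"unknown association feature {f!r}")
        if not (self.pre_features or self.post_features or self.slope_interaction):
            raise ValueError("association needs at least one feature")
        if self.slope_interaction and "slope" not in self.post_features:
            # M9-style form: R(t) x slope rides on top of a slope main effect
            object.__setattr__(
                self, "post_features", tuple(self.post_features) + ("slope",)
            )

    @property
    def features(self) -> list[str]:
        """Ordered union of features; alpha aligns with this list."""
        union = [f for f in _FEATURES
                 if f in self.pre_features or f in self.post_features]
        if self.slope_interaction:
            union.append("slope_x_R")
        return union

    @property
    def n_alpha(self) -> int:
        return len(self.features)

    def scale_of(self, feature: str) -> float:
        return float(self.scales.get(feature, 1.0))

    def to_dict(self) -> dict:
        return {
            "pre_features": list(self.pre_features),
            "post_features": list(self.post_features),
            "slope_interaction": self.slope_interaction,
            "scales": dict(self.scales),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssociationSpec":
        d = dict(d)
        for key in ("pre_features", "post_features"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class WeibullBaseline:
    """h0(t) = xi * t^(xi - 1)."""

    shape: float = 1.0

    def __post_init__(self):
        if not self.shape > 0:
            raise ValueError(f"Weibull shape must be > 0, got {self.shape}")

    def log_h0(self, t):
        t = np.asarray(t, float)
        if np.any(t <= 0):
            raise ValueError("baseline hazard requires t > 0")
        return np.log(self.shape) + (self.shape - 1.0) * np.log(t)


@dataclass(frozen=True)
class BSplineLogBaseline:
    """log h0(t) expanded in a cubic B-spline basis."""

    coefs: tuple
    knots: tuple = ()
    boundary: tuple = (0.0, 30.0)

    def __post_init__(self):
        full = _bspline_knots_full(self.knots, self.boundary)
        n_basis = len(full) - 4
        if len(self.coefs) != n_basis:
            raise ValueError(
                f"baseline needs {n_basis} coefficients, got {len(self.coefs)}"
            )

    def log_h0(self, t):
        t = np.asarray(t, float)
        if np.any(t <= 0):
            raise ValueError("baseline hazard requires t > 0")
        full = _bspline_knots_full(self.knots, self.boundary)
        basis = _bspline_basis(np.clip(t, *self.boundary), full)
        return basis @ np.asarray(self.coefs, float)


@dataclass
class HazardParams:
    """gamma, zeta, alpha and the baseline-hazard parameters."""

    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    zeta: float = 0.0
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(1))
    baseline: object = field(default_factory=WeibullBaseline)

    def __post_init__(self):
        self.gamma = np.atleast_1d(np.asarray(self.gamma, float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, float))


def baseline_log_hazard(params, t):
    """log h0(t) for a HazardParams or a bare baseline object."""
    baseline = params.baseline if isinstance(params, HazardParams) else params
    out = baseline.log_h0(t)
    return out if np.ndim(t) else float(out)


def _association_term(assoc, lspec, tparams, clock, t, x_baseline, alpha):
    """alpha' f(t) with pre/post switching, vectorized over t."""
    t = np.atleast_1d(np.asarray(t, float))
    feats = assoc.features
    if alpha.size != len(feats):
        raise ValueError(
            f"alpha has length {alpha.size} but association defines "
            f"{len(feats)} feature(s): {feats}"
        )
    R = np.asarray(event_indicator(clock, t), float).reshape(t.size)
    need = set(feats)
    vals = {}
    if "value" in need:
        X, Z = lspec.design_matrices(clock, t, x_baseline)
        vals["value"] = X @ tparams.beta + Z @ tparams.b
    if "slope" in need or "slope_x_R" in need:
        X1, Z1 = lspec.design_matrices(clock, t, x_baseline, deriv=1)
        vals["slope"] = X1 @ tparams.beta + Z1 @ tparams.b
        vals["slope_x_R"] = vals["slope"] * R
    if "area" in need:
        Xa, Za = lspec.area_design_matrices(clock, t, x_baseline)
        vals["area"] = Xa @ tparams.beta + Za @ tparams.b
    total = np.zeros(t.size)
    for a_k, f in zip(alpha, feats):
        if f == "slope_x_R":
            active = np.ones(t.size)  # carries R already; zero pre-event anyway
        else:
            active = np.where(R > 0, float(f in assoc.post_features),
                              float(f in assoc.pre_features))
        total += a_k * (vals[f] / assoc.scale_of(f)) * active
    return total


def log_hazard(params, assoc, lspec, tparams, clock, t, w_baseline=None,
               x_baseline=None):
    """log h_i(t) = log h0(t) + gamma'w + R(t) zeta + alpha' f(t)."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    w = np.atleast_1d(np.asarray(
        np.zeros(params.gamma.size) if w_baseline is None else w_baseline, float))
    if w.size != params.gamma.size:
        raise ValueError(
            f"gamma has length {params.gamma.size}, got {w.size} covariate(s)")
    out = baseline_log_hazard(params.baseline, t_arr)
    out = out + float(params.gamma @ w)
    out = out + params.zeta * np.asarray(event_indicator(clock, t_arr), float)
    out = out + _association_term(assoc, lspec, tparams, clock, t_arr,
                                  x_baseline, params.alpha)
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# Adaptive Gauss-Kronrod (QUADPACK 15-point Kronrod / 7-point Gauss pair).
# ---------------------------------------------------------------------------

_XGK = np.array([
    -0.991455371120813, -0.949107912342759, -0.864864423359769,
    -0.741531185599394, -0.586087235467691, -0.405845151377397,
    -0.207784955007898, 0.0, 0.207784955007898, 0.405845151377397,
    0.586087235467691, 0.741531185599394, 0.864864423359769,
    0.949107912342759, 0.991455371120813,
])
_WGK = np.array([
    0.022935322010529, 0.063092092629979, 0.104790010322250,
    0.140653259715525, 0.169004726639267, 0.190350578064785,
    0.204432940075298, 0.209482141084728, 0.204432940075298,
    0.190350578064785, 0.169004726639267, 0.140653259715525,
    0.104790010322250, 0.063092092629979, 0.022935322010529,
])
_WG = np.array([
    0.129484966168870, 0.279705391489277, 0.381830050505119,
    0.417959183673469, 0.381830050505119, 0.279705391489277,
    0.129484966168870,
])
_GAUSS_IDX = np.arange(1, 15, 2)


def gauss_kronrod(f, a, b, rtol=1e-8, atol=1e-12, max_depth=30):
    """Adaptive G7-K15 quadrature of a vectorized integrand on [a, b]."""
    if b <= a:
        return 0.0
    total, stack = 0.0, [(float(a), float(b), 0)]
    while stack:
        lo, hi, depth = stack.pop()
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        fx = np.asarray(f(mid + half * _XGK), float)
        if not np.all(np.isfinite(fx)):
            raise ValueError(
                f"nonfinite integrand on subinterval [{lo:g}, {hi:g}]")
        k15 = half * float(_WGK @ fx)
        g7 = half * float(_WG @ fx[_GAUSS_IDX])
        err = abs(k15 - g7)
        if err <= max(atol, rtol * abs(k15)) or depth >= max_depth:
            total += k15
        else:
            stack.append((lo, mid, depth + 1))
            stack.append((mid, hi, depth + 1))
    return total


def cumulative_hazard(params, assoc, lspec, tparams, clock, t0, t1,
                      w_baseline=None, x_baseline=None, rtol=1e-8, atol=1e-12):
    """int_{t0}^{t1} h_i(s) ds, with the interval split at rho.

    The split keeps the Gauss-Kronrod error estimate honest: the integrand
    jumps at rho whenever zeta != 0 or the feature set switches.
    """
    if not 0 <= t0 <= t1:
        raise ValueError(f"need 0 <= t0 <= t1, got ({t0}, {t1})")
    if t0 == t1:
        return 0.0

    def integrand(s):
        return np.exp(log_hazard(params, assoc, lspec, tparams, clock, s,
                                 w_baseline, x_baseline))

    pieces = [t0, t1]
    if clock.rho is not None and t0 < clock.rho < t1:
        pieces = [t0, float(clock.rho), t1]
    return sum(
        gauss_kronrod(integrand, a, b, rtol=rtol, atol=atol)
        for a, b in zip(pieces, pieces[1:])
    )


def survival_interval(params, assoc, lspec, tparams, clock, t, u,
                      w_baseline=None, x_baseline=None, rtol=1e-8):
    """Pr(T* >= u | T* > t) = exp(-int_t^u h(s) ds) at fixed parameters."""
    if u < t:
        raise ValueError(f"need u >= t, got t={t}, u={u}")
    H = cumulative_hazard(params, assoc, lspec, tparams, clock, t, u,
                          w_baseline, x_baseline, rtol=rtol)
    return float(np.exp(-H))
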