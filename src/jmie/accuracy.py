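"""Predictive-accuracy estimators that respect intermediate-event strata.

At a landmark t with horizon dt, every subject still at risk is assigned to
stratum A (intermediate event not yet occurred, t < rho) or stratum B
(occurred, t >= rho), and the dynamic prediction pi_hat(t+dt | t) is computed
under the subject's observed status.  Discrimination and calibration are then
measured within strata:

AUC(t, dt) decomposes over four ordered-pair classes formed WITHIN a stratum:
  1. i has the event in (t, t+dt] (observed), j survives past t+dt;
  2. i censored in the window, j survives past t+dt;
  3. i has the event in the window, j censored inside the window after T_i;
  4. i censored in the window, j censored inside the window after T_i.
Class 1 pairs count 1 each; classes 2-4 are weighted by the probability the
pair would have been comparable: nu2 = 1 - pi_i(t+dt | T_i),
nu3 = pi_j(t+dt | T_j), nu4 = nu2 * nu3.  A pair is concordant when
pi_i < pi_j (strict; ties contribute nothing and are counted separately).
The headline AUC pools numerators and denominators over strata and pair
classes, which keeps it in [0, 1]; per-stratum and per-class ratios are also
reported.

PE(u | t) is a Brier-type expected squared loss with the Henderson-style
decomposition for subjects censored inside the window: survivors contribute
(1 - pi)^2, observed events pi^2, and a subject censored at T_i in (t, u)
contributes pi_i(u|T_i) (1-pi)^2 + (1 - pi_i(u|T_i)) pi^2, i.e. its loss is
averaged over the two outcomes using its own predicted survival from T_i.
Per-stratum means are reported, pooled with at-risk-count weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import StudyData

__all__ = ["AccuracyReport", "classify_pairs", "auc_dynamic", "pe_dynamic"]

_STRATA = ("A", "B")


@dataclass
class AccuracyReport:
    """AUC and/or PE results at one (landmark, horizon)."""

    t: float
    dt: float
    auc: float | None = None
    auc_components: dict = field(default_factory=dict)   # (stratum, m) -> ratio
    pair_counts: dict = field(default_factory=dict)      # (stratum, m) -> int
    auc_strata: dict = field(default_factory=dict)       # stratum -> pooled ratio
    n_ties: int = 0
    pe: float | None = None
    pe_strata: dict = field(default_factory=dict)
    n_at_risk: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def u(self) -> float:
        return self.t + self.dt

    def to_frame(self) -> pd.DataFrame:
        rows = [{"measure": "auc", "stratum": "pooled", "value": self.auc},
                {"measure": "pe", "stratum": "pooled", "value": self.pe}]
        for st in _STRATA:
            rows.append({"measure": "auc", "stratum": st,
                         "value": self.auc_strata.get(st)})
            rows.append({"measure": "pe", "stratum": st,
                         "value": self.pe_strata.get(st)})
        df = pd.DataFrame(rows)
        df.insert(0, "t", self.t)
        df.insert(1, "dt", self.dt)
        return df


def _prediction_table(predictions) -> pd.DataFrame:
    """Normalize predictions to a frame indexed by id.

    Expected columns: ``pi_window`` = pi_hat(t+dt | t) for every at-risk
    subject, and ``pi_cens`` = pi_hat(t+dt | T_i) for subjects censored
    inside the window (NaN elsewhere).
    """
    df = pd.DataFrame(predictions)
    if "id" in df.columns:
        df = df.set_index("id")
    if "pi_window" not in df.columns:
        raise ValueError("predictions need a 'pi_window' column")
    if "pi_cens" not in df.columns:
        df = df.assign(pi_cens=np.nan)
    return df


def _strata(data: StudyData, t: float):
    at_risk = [s for s in data.subjects if s.T_obs > t]
    A = [s for s in at_risk if s.rho is None or t < s.rho]
    B = [s for s in at_risk if s.rho is not None and t >= s.rho]
    return A, B


def _pair_class(si, sj, t, u):
    """Ordered-pair class 1-4 within a stratum, or None."""
    in_window_i = (t < si.T_obs <= u)
    if not in_window_i:
        return None
    if sj.T_obs > u:
        return 1 if si.delta == 1 else 2
    if (si.T_obs < sj.T_obs <= u) and sj.delta == 0:
        return 3 if si.delta == 1 else 4
    return None


def classify_pairs(data: StudyData, predictions, t, dt):
    """Ordered pairs (i, j) per stratum and class, with missing-prediction
    checks for every subject that enters any pair."""
    u = t + dt
    preds = _prediction_table(predictions)
    A, B = _strata(data, t)
    out = {("A", m): [] for m in (1, 2, 3, 4)}
    out.update({("B", m): [] for m in (1, 2, 3, 4)})
    missing = set()
    for name, group in (("A", A), ("B", B)):
        for si in group:
            for sj in group:
                if si.id == sj.id:
                    continue
                m = _pair_class(si, sj, t, u)
                if m is None:
                    continue
                for s in (si, sj):
                    if s.id not in preds.index or \
                            not np.isfinite(preds.at[s.id, "pi_window"]):
                        missing.add(s.id)
                out[(name, m)].append((si.id, sj.id))
    if missing:
        raise ValueError(
            "subjects missing predictions: " + ", ".join(map(str, sorted(missing))))
    return out


def auc_dynamic(data: StudyData, predictions, t, dt) -> AccuracyReport:
    """Stratified time-dependent AUC with censoring-weighted pair classes."""
    u = t + dt
    preds = _prediction_table(predictions)
    pairs = classify_pairs(data, predictions, t, dt)
    report = AccuracyReport(t=float(t), dt=float(dt))

    def pi_w(i):
        return float(preds.at[i, "pi_window"])

    def pi_c(i):
        v = preds.at[i, "pi_cens"] if i in preds.index else np.nan
        if not np.isfinite(v):
            raise ValueError(
                f"subject {i} is censored inside the window and needs a "
                "'pi_cens' prediction from its own censoring time")
        return float(v)

    num_total = den_total = 0.0
    n_ties = 0
    stratum_num = {st: 0.0 for st in _STRATA}
    stratum_den = {st: 0.0 for st in _STRATA}
    for (st, m), plist in pairs.items():
        num = den = 0.0
        for i, j in plist:
            if m == 1:
                w = 1.0
            elif m == 2:
                w = 1.0 - pi_c(i)
            elif m == 3:
                w = pi_c(j)
            else:
                w = (1.0 - pi_c(i)) * pi_c(j)
            if pi_w(i) == pi_w(j):
                n_ties += 1
            conc = 1.0 if pi_w(i) < pi_w(j) else 0.0
            num += w * conc
            den += w
        report.pair_counts[(st, m)] = len(plist)
        report.auc_components[(st, m)] = num / den if den > 0 else np.nan
        stratum_num[st] += num
        stratum_den[st] += den
        num_total += num
        den_total += den
    for st in _STRATA:
        report.auc_strata[st] = (stratum_num[st] / stratum_den[st]
                                 if stratum_den[st] > 0 else np.nan)
    report.n_ties = n_ties
    if den_total > 0:
        report.auc = num_total / den_total
    else:
        report.auc = np.nan
        report.flags.append(f"AUC({t}, {dt}) undefined: no comparable mass")
    return report


def pe_dynamic(data: StudyData, predictions, t, u) -> AccuracyReport:
    """Brier-type expected prediction error at u given t, per stratum."""
    if not u > t:
        raise ValueError(f"need u > t, got t={t}, u={u}")
    preds = _prediction_table(predictions)
    A, B = _strata(data, t)
    report = AccuracyReport(t=float(t), dt=float(u - t))

    def loss(s):
        pi = preds.at[s.id, "pi_window"] if s.id in preds.index else np.nan
        if not np.isfinite(pi):
            raise ValueError(f"subject {s.id} is missing a 'pi_window' prediction")
        pi = float(pi)
        if s.T_obs >= u:
            return (1.0 - pi) ** 2
        if s.delta == 1:
            return pi**2
        pc = preds.at[s.id, "pi_cens"] if s.id in preds.index else np.nan
        if not np.isfinite(pc):
            raise ValueError(
                f"subject {s.id} is censored inside the window and needs a "
                "'pi_cens' prediction from its own censoring time")
        pc = float(pc)
        return pc * (1.0 - pi) ** 2 + (1.0 - pc) * pi**2

    pooled_num = pooled_den = 0.0
    for st, group in zip(_STRATA, (A, B)):
        report.n_at_risk[st] = len(group)
        if not group:
            report.pe_strata[st] = np.nan
            continue
        val = float(np.mean([loss(s) for s in group]))
        report.pe_strata[st] = val
        pooled_num += val * len(group)
        pooled_den += len(group)
    if pooled_den > 0:
        report.pe = pooled_num / pooled_den
    else:
        report.pe = np.nan
        report.flags.append(f"PE({u} | {t}) undefined: nobody at risk")
    return report
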