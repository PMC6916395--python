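"""Independent brute-force oracles used by the accuracy tests.

Deliberately written as direct transcriptions of the estimator definitions —
explicit loops over ordered subject pairs and per-subject loss branches —
with no code shared with the package implementation.
"""

import numpy as np

from jmie.data import StudyData, SubjectData


def random_instance(rng, n_max=12):
    """A random tiny study plus a prediction table, arbitrary censoring."""
    n = int(rng.integers(3, n_max + 1))
    subjects, preds = [], {}
    for i in range(n):
        T = float(rng.uniform(0.5, 40.0))
        delta = int(rng.uniform() < 0.6)
        rho = float(rng.uniform(0.0, T)) if rng.uniform() < 0.5 else None
        subjects.append(SubjectData(
            id=i, obs_times=np.array([min(0.1, T / 2)]),
            y=np.array([0.0]), T_obs=T, delta=delta, rho=rho))
        preds[i] = {"pi_window": float(rng.uniform()),
                    "pi_cens": float(rng.uniform())}
    import pandas as pd
    table = pd.DataFrame(
        [{"id": i, **v} for i, v in preds.items()])
    return StudyData(subjects=subjects), table


def _stratum(s, t):
    if s.T_obs <= t:
        return None
    return "B" if (s.rho is not None and t >= s.rho) else "A"


def brute_auc(data, preds, t, dt):
    """Direct pair enumeration of the stratified, censoring-weighted AUC."""
    u = t + dt
    p = {row.id: (row.pi_window, row.pi_cens) for row in preds.itertuples()}
    num = {("A", m): 0.0 for m in (1, 2, 3, 4)}
    num.update({("B", m): 0.0 for m in (1, 2, 3, 4)})
    den = dict(num)
    for si in data.subjects:
        for sj in data.subjects:
            if si.id == sj.id:
                continue
            st_i, st_j = _stratum(si, t), _stratum(sj, t)
            if st_i is None or st_i != st_j:
                continue
            st = st_i
            m = None
            if t < si.T_obs <= u and si.delta == 1 and sj.T_obs > u:
                m = 1
            elif t < si.T_obs <= u and si.delta == 0 and sj.T_obs > u:
                m = 2
            elif (t < si.T_obs <= u and si.delta == 1
                  and si.T_obs < sj.T_obs <= u and sj.delta == 0):
                m = 3
            elif (t < si.T_obs <= u and si.delta == 0
                  and si.T_obs < sj.T_obs <= u and sj.delta == 0):
                m = 4
            if m is None:
                continue
            if m == 1:
                w = 1.0
            elif m == 2:
                w = 1.0 - p[si.id][1]
            elif m == 3:
                w = p[sj.id][1]
            else:
                w = (1.0 - p[si.id][1]) * p[sj.id][1]
            conc = 1.0 if p[si.id][0] < p[sj.id][0] else 0.0
            num[(st, m)] += w * conc
            den[(st, m)] += w
    total_num = sum(num.values())
    total_den = sum(den.values())
    auc = total_num / total_den if total_den > 0 else np.nan
    comp = {k: (num[k] / den[k] if den[k] > 0 else np.nan) for k in num}
    return auc, comp


def brute_pe(data, preds, t, u):
    """Direct per-subject evaluation of the Henderson-style adapted PE."""
    p = {row.id: (row.pi_window, row.pi_cens) for row in preds.itertuples()}
    out = {}
    pooled_num = pooled_den = 0.0
    for st in ("A", "B"):
        losses = []
        for s in data.subjects:
            if _stratum(s, t) != st:
                continue
            pi = p[s.id][0]
            if s.T_obs >= u:
                losses.append((1 - pi) ** 2)
            elif s.delta == 1:
                losses.append((0 - pi) ** 2)
            else:
                pc = p[s.id][1]
                losses.append(pc * (1 - pi) ** 2 + (1 - pc) * (0 - pi) ** 2)
        out[st] = float(np.mean(losses)) if losses else np.nan
        if losses:
            pooled_num += np.sum(losses)
            pooled_den += len(losses)
    pooled = pooled_num / pooled_den if pooled_den else np.nan
    return pooled, out
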