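import numpy as np
import pandas as pd
import pytest

from helpers import brute_auc, brute_pe, random_instance
from jmie import StudyData, SubjectData, auc_dynamic, classify_pairs, \
    pe_dynamic


def _subj(i, T, delta, rho=None):
    return SubjectData(id=i, obs_times=[0.5], y=[0.0], T_obs=T, delta=delta,
                       rho=rho)


def _preds(d):
    return pd.DataFrame([
        {"id": k, "pi_window": v[0],
         "pi_cens": v[1] if len(v) > 1 else np.nan}
        for k, v in d.items()
    ])


def test_pair_classification_three_subjects():
    """One event in the window, one survivor, one censored inside it."""
    data = StudyData(subjects=[
        _subj("e", 11.0, 1), _subj("s", 20.0, 0), _subj("c", 11.5, 0)])
    preds = _preds({"e": (0.2, 0.1), "s": (0.9,), "c": (0.5, 0.6)})
    pairs = classify_pairs(data, preds, t=10.0, dt=2.0)
    assert pairs[("A", 1)] == [("e", "s")]
    assert pairs[("A", 2)] == [("c", "s")]
    assert pairs[("A", 3)] == [("e", "c")]
    assert pairs[("A", 4)] == []
    assert all(not pairs[("B", m)] for m in (1, 2, 3, 4))


def test_all_censored_before_t_gives_empty_sets():
    data = StudyData(subjects=[_subj(1, 5.0, 0), _subj(2, 8.0, 0)])
    pairs = classify_pairs(data, _preds({1: (0.5,), 2: (0.5,)}), 10.0, 2.0)
    assert all(not v for v in pairs.values())


def test_cross_stratum_pairs_excluded():
    data = StudyData(subjects=[
        _subj(1, 11.0, 1, rho=None), _subj(2, 20.0, 0, rho=3.0)])
    pairs = classify_pairs(data, _preds({1: (0.2,), 2: (0.9,)}), 10.0, 2.0)
    assert all(not v for v in pairs.values())


def test_missing_predictions_rejected_with_ids():
    data = StudyData(subjects=[_subj(1, 11.0, 1), _subj(2, 20.0, 0)])
    with pytest.raises(ValueError, match="2"):
        classify_pairs(data, _preds({1: (0.2,)}), 10.0, 2.0)


def test_auc1_hand_example():
    """Event pi = 0.2 vs survivors 0.9 and 0.1: one concordant of two."""
    data = StudyData(subjects=[
        _subj("e", 11.0, 1), _subj("s1", 20.0, 0), _subj("s2", 19.0, 0)])
    preds = _preds({"e": (0.2,), "s1": (0.9,), "s2": (0.1,)})
    rep = auc_dynamic(data, preds, 10.0, 2.0)
    assert rep.auc_components[("A", 1)] == pytest.approx(0.5)
    assert rep.auc == pytest.approx(0.5)


def test_perfect_ranking_gives_one():
    data = StudyData(subjects=[
        _subj("e1", 10.5, 1), _subj("e2", 11.0, 1),
        _subj("s1", 20.0, 0), _subj("s2", 25.0, 0)])
    preds = _preds({"e1": (0.1,), "e2": (0.2,), "s1": (0.8,), "s2": (0.9,)})
    assert auc_dynamic(data, preds, 10.0, 2.0).auc == 1.0


def test_weighted_pair_hand_example():
    """A single censored-in-window pair contributes nu * I(concordant) over
    nu; with pi_cens = 0.6 the weight is 1 - 0.6 = 0.4."""
    data = StudyData(subjects=[_subj("c", 11.0, 0), _subj("s", 20.0, 0)])
    preds = _preds({"c": (0.3, 0.6), "s": (0.8,)})
    rep = auc_dynamic(data, preds, 10.0, 2.0)
    assert rep.pair_counts[("A", 2)] == 1
    assert rep.auc_components[("A", 2)] == pytest.approx(1.0)  # 0.4*1 / 0.4
    assert rep.auc == pytest.approx(1.0)


def test_no_comparable_mass_flagged():
    data = StudyData(subjects=[_subj(1, 30.0, 0), _subj(2, 28.0, 0)])
    rep = auc_dynamic(data, _preds({1: (0.5,), 2: (0.5,)}), 10.0, 2.0)
    assert np.isnan(rep.auc)
    assert rep.flags


def test_auc_invariant_to_monotone_transform(rng):
    data, preds = random_instance(rng, 12)
    base = auc_dynamic(data, preds, 8.0, 4.0)
    warped = preds.copy()
    warped["pi_window"] = warped["pi_window"] ** 3  # strictly increasing
    again = auc_dynamic(data, warped, 8.0, 4.0)
    if not np.isnan(base.auc):
        assert again.auc == pytest.approx(base.auc, abs=1e-12)


def test_label_swap_symmetry():
    """Negating the ranking maps AUC1 to 1 - AUC1 on censoring-free data."""
    rng = np.random.default_rng(3)
    subjects, rows = [], []
    for i in range(10):
        T = float(rng.uniform(5, 30))
        subjects.append(_subj(i, T, 1))
        rows.append({"id": i, "pi_window": float(rng.uniform()),
                     "pi_cens": np.nan})
    data = StudyData(subjects=subjects)
    preds = pd.DataFrame(rows)
    a = auc_dynamic(data, preds, 8.0, 10.0)
    flipped = preds.assign(pi_window=1.0 - preds["pi_window"])
    b = auc_dynamic(data, flipped, 8.0, 10.0)
    assert a.auc + b.auc == pytest.approx(1.0)  # no ties drawn


def test_censoring_free_reductions(rng):
    """Without censored-in-window subjects the weighted classes vanish and
    the total equals AUC1; the PE keeps only its two uncensored branches."""
    subjects, rows = [], []
    for i in range(12):
        T = float(rng.uniform(5, 30))
        subjects.append(_subj(i, T, 1, rho=7.0 if i % 3 == 0 else None))
        rows.append({"id": i, "pi_window": float(rng.uniform()),
                     "pi_cens": np.nan})
    data = StudyData(subjects=subjects)
    preds = pd.DataFrame(rows)
    rep = auc_dynamic(data, preds, 8.0, 4.0)
    for st in ("A", "B"):
        for m in (2, 3, 4):
            assert rep.pair_counts[(st, m)] == 0
    num = den = 0.0
    for st in ("A", "B"):
        if rep.pair_counts[(st, 1)]:
            num += rep.auc_components[(st, 1)] * rep.pair_counts[(st, 1)]
            den += rep.pair_counts[(st, 1)]
    if den:
        assert rep.auc == pytest.approx(num / den)


def test_pe_trivial_values():
    data = StudyData(subjects=[_subj(1, 30.0, 0), _subj(2, 11.0, 1)])
    perfect = _preds({1: (1.0,), 2: (0.0,)})
    assert pe_dynamic(data, perfect, 10.0, 12.0).pe == 0.0
    half = _preds({1: (0.5,), 2: (0.5,)})
    data2 = StudyData(subjects=[_subj(1, 30.0, 0), _subj(2, 28.0, 0)])
    assert pe_dynamic(data2, half, 10.0, 12.0).pe == pytest.approx(0.25)


def test_pe_three_branch_hand_example():
    """Survivor 0.8, event 0.4, censored inside with pi(u|T)=0.5, pi=0.6:
    PE = (0.04 + 0.16 + 0.5*0.16 + 0.5*0.36) / 3."""
    data = StudyData(subjects=[
        _subj("s", 30.0, 0), _subj("e", 11.0, 1), _subj("c", 11.5, 0)])
    preds = _preds({"s": (0.8,), "e": (0.4,), "c": (0.6, 0.5)})
    rep = pe_dynamic(data, preds, 10.0, 12.0)
    assert rep.pe == pytest.approx((0.04 + 0.16 + 0.5 * 0.16 + 0.5 * 0.36) / 3)


def test_pe_nobody_at_risk_flagged():
    data = StudyData(subjects=[_subj(1, 5.0, 1)])
    rep = pe_dynamic(data, _preds({1: (0.5,)}), 10.0, 12.0)
    assert np.isnan(rep.pe) and rep.flags


def test_pe_requires_u_after_t():
    data = StudyData(subjects=[_subj(1, 30.0, 0)])
    with pytest.raises(ValueError):
        pe_dynamic(data, _preds({1: (0.5,)}), 10.0, 10.0)


@pytest.mark.parametrize("seed", range(40))
def test_brute_force_equivalence(seed):
    """On random tiny instances the implementation must equal a direct
    enumeration of ordered pairs and loss branches to near machine precision."""
    rng = np.random.default_rng(seed)
    data, preds = random_instance(rng, 12)
    t, dt = 8.0, 4.0
    rep = auc_dynamic(data, preds, t, dt)
    auc_b, comp_b = brute_auc(data, preds, t, dt)
    if np.isnan(auc_b):
        assert np.isnan(rep.auc)
    else:
        assert rep.auc == pytest.approx(auc_b, abs=1e-12)
    for key, val in comp_b.items():
        got = rep.auc_components[key]
        assert (np.isnan(val) and np.isnan(got)) or \
            got == pytest.approx(val, abs=1e-12)
    pe = pe_dynamic(data, preds, t, t + dt)
    pe_b, strata_b = brute_pe(data, preds, t, t + dt)
    if np.isnan(pe_b):
        assert np.isnan(pe.pe)
    else:
        assert pe.pe == pytest.approx(pe_b, abs=1e-12)
    for st in ("A", "B"):
        got, want = pe.pe_strata[st], strata_b[st]
        assert (np.isnan(want) and np.isnan(got)) or \
            got == pytest.approx(want, abs=1e-12)
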