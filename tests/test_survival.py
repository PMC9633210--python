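"""Survival metric correctness against hand computations and oracles."""

import numpy as np
import pandas as pd
import pytest

from omiprog.containers import OmiprogError, SurvivalTable
from omiprog.survival import (
    brier_score,
    concordance_counts,
    concordance_index,
    cox_fit,
    cox_score_test,
    evaluate_subgroups,
    kaplan_meier,
    logrank_test,
)

from conftest import random_survival


def _surv(time, event):
    return SurvivalTable(pd.DataFrame(
        {"time": time, "event": event}, index=[f"s{i}" for i in range(len(time))]))


# -- Kaplan-Meier -----------------------------------------------------------

def test_km_no_events_constant_one():
    surv = _surv([5.0, 7.0, 9.0], [0, 0, 0])
    curve = kaplan_meier(surv)[0]
    assert (curve["survival"] == 1.0).all()


def test_km_closed_form_no_censoring():
    surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    curve = kaplan_meier(surv)[0].set_index("time")["survival"]
    assert curve.loc[0.0] == 1.0
    assert curve.loc[[1.0, 2.0, 3.0, 4.0]].tolist() == pytest.approx(
        [0.75, 0.5, 0.25, 0.0])


def test_km_hand_computed_with_censoring(toy_survival):
    # events at 1, 3, 4, 6; censored at 2 and 5:
    # S(1)=5/6, S(3)=5/6*3/4, S(4)=5/8, S(6)=0
    curve = kaplan_meier(toy_survival)[0].set_index("time")["survival"]
    assert curve.loc[1.0] == pytest.approx(5 / 6)
    assert curve.loc[3.0] == pytest.approx(5 / 6 * 3 / 4)
    assert curve.loc[4.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
    assert curve.loc[6.0] == pytest.approx(0.0)


# -- log-rank ---------------------------------------------------------------

def test_logrank_identical_groups_null():
    surv = _surv([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [1, 1, 1, 1, 1, 1])
    chi2, p = logrank_test(surv, [0, 0, 0, 1, 1, 1])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def _logrank_oracle(time, event, group):
    """Direct O-E / hypergeometric-variance summation for two groups."""
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_matches_hand_summation():
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.ones(6, dtype=int)
    group = np.array([0, 0, 0, 1, 1, 1])
    chi2, _ = logrank_test(_surv(time, event), group)
    assert chi2 == pytest.approx(_logrank_oracle(time, event, group), rel=1e-10)


def test_logrank_null_permutation_calibration():
    rng = np.random.default_rng(0)
    n = 40
    surv = random_survival(rng, n, censor=0.3)
    pvals = []
    for _ in range(300):
        labels = rng.permutation(np.repeat([0, 1], n // 2))
        _, p = logrank_test(surv, labels)
        pvals.append(p)
    # under the null the p distribution should not be anti-conservative
    assert np.mean(np.asarray(pvals) < 0.05) < 0.10


def test_logrank_relabeling_invariance(toy_survival):
    chi2a, _ = logrank_test(toy_survival, [0, 1, 0, 1, 0, 1])
    chi2b, _ = logrank_test(toy_survival, [1, 0, 1, 0, 1, 0])
    assert chi2a == pytest.approx(chi2b)


# -- Cox --------------------------------------------------------------------

def test_cox_null_covariate():
    time = [1.0, 2.0, 3.0, 4.0] * 2
    event = [1, 1, 0, 1] * 2
    surv = _surv(time, event)
    cov = pd.Series([0.0] * 4 + [1.0] * 4, index=surv.sample_ids, name="g")
    res = cox_fit(surv, cov)
    assert res.summary.loc["g", "hr"] == pytest.approx(1.0, abs=0.05)
    assert res.summary.loc["g", "p"] > 0.9


def test_cox_ci_is_symmetric_wald_interval():
    rng = np.random.default_rng(1)
    n = 150
    x = rng.normal(size=n)
    time = rng.exponential(1.0 / (0.01 * np.exp(0.5 * x)))
    surv = _surv(time, np.ones(n, dtype=int))
    res = cox_fit(surv, pd.Series(x, index=surv.sample_ids, name="x"))
    row = res.summary.loc["x"]
    assert row["ci_lower"] <= row["hr"] <= row["ci_upper"]
    assert (np.log(row["ci_upper"]) - np.log(row["hr"])
            == pytest.approx(np.log(row["hr"]) - np.log(row["ci_lower"]), abs=1e-9))


def test_cox_score_test_equals_logrank_for_binary_covariate():
    rng = np.random.default_rng(2)
    n = 80
    g = np.repeat([0.0, 1.0], n // 2)
    time = rng.exponential(1.0 / (0.01 * np.exp(0.7 * g)))
    event = (rng.random(n) > 0.2).astype(int)
    surv = _surv(time, event)
    _, logrank_p = logrank_test(surv, g.astype(int))
    score_p = cox_score_test(surv, pd.DataFrame({"g": g}, index=surv.sample_ids))
    assert score_p == pytest.approx(logrank_p, rel=1e-6)


def test_cox_univariate_mode_one_model_per_covariate():
    rng = np.random.default_rng(3)
    n = 100
    surv = random_survival(rng, n)
    covs = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)},
                        index=surv.sample_ids)
    uni = cox_fit(surv, covs, mode="univariate")
    for name in ("a", "b"):
        alone = cox_fit(surv, covs[[name]])
        assert uni.summary.loc[name, "hr"] == pytest.approx(
            alone.summary.loc[name, "hr"])


# -- concordance ------------------------------------------------------------

def _cindex_oracle(risk, time, event, ties):
    conc = disc = tied = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0)
            if not usable:
                continue
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] < risk[j]:
                disc += 1
            else:
                tied += 1
    if ties == "half":
        return (conc + 0.5 * tied) / (conc + disc + tied)
    return conc / (conc + disc) if conc + disc else 0.5


def test_cindex_all_ties_is_half():
    rng = np.random.default_rng(4)
    surv = random_survival(rng, 20, censor=0.2)
    assert concordance_index(np.ones(20), surv) == pytest.approx(0.5)


def test_cindex_perfect_ordering():
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    surv = _surv(time, np.ones(5, dtype=int))
    assert concordance_index(-time, surv) == pytest.approx(1.0)
    assert concordance_index(time, surv) == pytest.approx(0.0)


@pytest.mark.parametrize("ties", ["half", "exclude"])
def test_cindex_matches_bruteforce(ties):
    rng = np.random.default_rng(5)
    for _ in range(5):
        n = 30
        surv = random_survival(rng, n, censor=0.4)
        risk = rng.choice([0.0, 1.0, 2.0], size=n)  # many score ties
        expected = _cindex_oracle(risk, surv.time.to_numpy(),
                                  surv.event.to_numpy(), ties)
        assert concordance_index(risk, surv, ties=ties) == pytest.approx(expected)


def test_cindex_antisymmetric_without_ties():
    rng = np.random.default_rng(6)
    surv = random_survival(rng, 40, censor=0.3)
    risk = rng.normal(size=40)
    c1 = concordance_index(risk, surv)
    c2 = concordance_index(-risk, surv)
    assert c1 + c2 == pytest.approx(1.0)


def test_cindex_half_matches_lifelines():
    from lifelines.utils import concordance_index as lifelines_cindex

    rng = np.random.default_rng(7)
    surv = random_survival(rng, 60, censor=0.3)
    risk = rng.normal(size=60)
    mine = concordance_index(risk, surv)
    ref = lifelines_cindex(surv.time, -risk, surv.event)
    assert mine == pytest.approx(ref, abs=1e-12)


# -- Brier score ------------------------------------------------------------

def test_brier_perfect_predictions_no_censoring():
    time = np.array([1.0, 2.0, 8.0, 9.0])
    surv = _surv(time, np.ones(4, dtype=int))
    pred = np.array([0.0, 0.0, 1.0, 1.0])  # correct status at t=5
    assert brier_score(pred, surv, t=5.0) == pytest.approx(0.0)
    assert brier_score(np.full(4, 0.5), surv, t=5.0) == pytest.approx(0.25)


def test_brier_hand_computed_ipcw():
    # 8 subjects; censoring KM: drops at t=4 (1 of 6 at risk) and t=7 (1 of 2)
    time = np.array([1.0, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
    event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    surv = _surv(time, event)
    pred = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
    t = 6.5
    g4 = 5 / 6          # G(t) for t in [4, 7)
    # events before t: times 1, 2 (G(t-)=1), 5, 6 (G(t-)=5/6); at risk: 7, 8, 9
    expected = (pred[0]**2 / 1 + pred[1]**2 / 1 + pred[3]**2 / g4 + pred[4]**2 / g4
                + (1 - pred[5])**2 / g4 + (1 - pred[6])**2 / g4
                + (1 - pred[7])**2 / g4) / 8
    assert brier_score(pred, surv, t=t) == pytest.approx(expected, rel=1e-12)


def test_brier_matches_scikit_survival():
    from sksurv.metrics import brier_score as sksurv_brier

    rng = np.random.default_rng(8)
    n = 100
    surv = random_survival(rng, n, censor=0.3)
    pred = rng.random(n)
    t = float(np.quantile(surv.time, 0.5))
    y = np.array([(bool(e), t_) for e, t_ in zip(surv.event, surv.time)],
                 dtype=[("event", "?"), ("time", "<f8")])
    _, ref = sksurv_brier(y, y, pred[None, :].T @ np.ones((1, 1)), [t])
    assert brier_score(pred, surv, t=t) == pytest.approx(float(ref[0]), rel=1e-9)


def test_integrated_brier_constant_half_is_quarter():
    from omiprog.survival import integrated_brier_score

    rng = np.random.default_rng(9)
    surv = random_survival(rng, 50, censor=0.3)
    v = integrated_brier_score(lambda t: np.full(50, 0.5), surv)
    assert v == pytest.approx(0.25, abs=1e-9)


def test_brier_zero_censoring_survival_errors():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([1, 1, 1, 0])
    surv = _surv(time, event)
    with pytest.raises(OmiprogError, match="horizon"):
        brier_score(np.full(4, 0.5), surv, t=4.0)


# -- evaluation bundle ------------------------------------------------------

def test_evaluate_subgroups_bundle(small_cohort):
    _, cohort = small_cohort
    ev = evaluate_subgroups(cohort.survival, cohort.true_labels.to_numpy())
    assert 0 <= ev.c_index <= 1
    assert 0 <= ev.brier_score <= 1
    assert 0 < ev.logrank_p <= 1
    assert set(ev.km_curves) == {0, 1}
    # strong simulated hazard contrast must separate
    assert ev.logrank_p < 0.01
    assert ev.c_index > 0.6


def test_km_plot_written(tmp_path, small_cohort):
    from omiprog.survival import plot_km

    _, cohort = small_cohort
    curves = kaplan_meier(cohort.survival, cohort.true_labels.to_numpy())
    out = tmp_path / "km.svg"
    plot_km(curves, path=out, title="simulated subgroups")
    assert out.exists() and out.stat().st_size > 0
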