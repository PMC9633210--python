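"""Survival evaluation: Kaplan–Meier, log-rank, Cox PH, C-index, Brier score.

Kaplan–Meier estimation, log-rank testing and Cox partial-likelihood fits
are delegated to lifelines (Efron tie handling); the model-level score test
at beta = 0 and the IPCW Brier score are implemented here directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .containers import OmiprogError, SurvivalTable

__all__ = [
    "CoxResult",
    "SurvivalEvaluation",
    "kaplan_meier",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "concordance_index",
    "brier_score",
    "integrated_brier_score",
    "evaluate_subgroups",
]


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald inference and model-level tests."""

    summary: pd.DataFrame  # index covariate; columns hr, ci_lower, ci_upper, z, p
    score_p: float
    n: int
    events: int
    model: CoxPHFitter | None = None

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


@dataclass
class SurvivalEvaluation:
    """Bundle of survival separation metrics for one subgroup assignment."""

    logrank_chi2: float
    logrank_p: float
    c_index: float
    brier_score: float
    brier_time: float
    km_curves: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "c_index": self.c_index,
            "brier_score": self.brier_score,
            "brier_time": self.brier_time,
        }


def _labels_series(surv: SurvivalTable, labels) -> pd.Series:
    s = pd.Series(np.asarray(labels), index=surv.sample_ids)
    return s


def kaplan_meier(surv: SurvivalTable, labels=None) -> dict:
    """Product-limit survival curve per group (all samples if labels is None).

    Returns a dict label -> DataFrame with columns (time, survival); the
    curve is right-continuous and starts at S(0) = 1.
    """
    if labels is None:
        labels = np.zeros(len(surv), dtype=int)
    s = _labels_series(surv, labels)
    curves = {}
    for g, idx in s.groupby(s).groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time.loc[idx], surv.event.loc[idx])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                                  "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
    return curves


def logrank_test(surv: SurvivalTable, labels) -> tuple[float, float]:
    """Unweighted log-rank chi-square (K-1 df) and p-value."""
    s = _labels_series(surv, labels)
    counts = s.value_counts()
    if len(counts) < 2:
        raise OmiprogError("log-rank test needs at least two groups")
    if (counts == 0).any():
        raise OmiprogError("a group has zero subjects")
    if surv.event.sum() == 0:
        raise OmiprogError("log-rank test needs at least one event")
    res = multivariate_logrank_test(surv.time, s, surv.event)
    return float(res.test_statistic), float(res.p_value)


def _design_matrix(covariates: pd.DataFrame, references: dict | None = None) -> pd.DataFrame:
    """Numeric columns pass through; categoricals become treatment dummies."""
    references = references or {}
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float))
        else:
            cats = list(pd.unique(col.astype(str)))
            ref = references.get(name, sorted(cats)[0])
            for level in sorted(c for c in cats if c != ref):
                cols.append((col.astype(str) == level).astype(float).rename(f"{name}[{level}]"))
    return pd.concat(cols, axis=1)


def cox_fit(surv: SurvivalTable, covariates, mode: str = "multivariate",
            references: dict | None = None) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald inference.

    ``mode="univariate"`` fits one single-covariate model per column and
    concatenates the rows; ``"multivariate"`` fits one joint model.  The
    model-level p is the score test at beta = 0.
    """
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    covariates = covariates.loc[surv.sample_ids]
    X = _design_matrix(covariates, references)
    if mode == "univariate" and X.shape[1] > 1:
        parts = []
        for name in covariates.columns:
            sub = covariates[[name]]
            res = cox_fit(surv, sub, mode="multivariate", references=references)
            parts.append(res.summary)
        # model-level score p of the joint design, for reference
        score_p = cox_score_test(surv, X)
        return CoxResult(pd.concat(parts), score_p, len(surv), int(surv.event.sum()))

    df = X.copy()
    df["time"] = surv.time.to_numpy()
    df["event"] = surv.event.to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise OmiprogError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame({
        "hr": np.exp(summ["coef"]),
        "ci_lower": np.exp(summ["coef"] - 1.959963984540054 * summ["se(coef)"]),
        "ci_upper": np.exp(summ["coef"] + 1.959963984540054 * summ["se(coef)"]),
        "z": summ["z"],
        "p": summ["p"],
    })
    big = out["hr"][(out["hr"] > 1e4) | (out["hr"] < 1e-4)]
    if len(big):
        warnings.warn(f"extreme hazard ratios (possible separation): {list(big.index)}")
    score_p = cox_score_test(surv, X)
    return CoxResult(out, score_p, len(surv), int(surv.event.sum()), model=cph)


def cox_score_test(surv: SurvivalTable, X: pd.DataFrame) -> float:
    """Score (log-rank-type) test of the Cox model at beta = 0, Efron ties."""
    x = X.to_numpy(dtype=float)
    t = surv.time.to_numpy(dtype=float)
    e = surv.event.to_numpy(dtype=int)
    p = x.shape[1]
    U = np.zeros(p)
    V = np.zeros((p, p))
    order = np.argsort(t)
    t, e, x = t[order], e[order], x[order]
    event_times = np.unique(t[e == 1])
    for tj in event_times:
        at_risk = t >= tj
        deaths = (t == tj) & (e == 1)
        d = int(deaths.sum())
        nj = int(at_risk.sum())
        S = x[at_risk].sum(axis=0)
        D = x[deaths].sum(axis=0)
        Q = x[at_risk].T @ x[at_risk]
        QD = x[deaths].T @ x[deaths]
        for l in range(d):
            denom = nj - l
            mu = (S - (l / d) * D) / denom
            U_part = (Q - (l / d) * QD) / denom
            V += U_part - np.outer(mu, mu)
        U += D - sum((S - (l / d) * D) / (nj - l) for l in range(d))
    try:
        stat = float(U @ np.linalg.solve(V, U))
    except np.linalg.LinAlgError:
        stat = float(U @ np.linalg.pinv(V) @ U)
    return float(stats.chi2.sf(stat, df=p))


def concordance_counts(risk_score, surv: SurvivalTable) -> dict:
    """Count concordant / discordant / score-tied usable pairs.

    A pair is usable when its survival ordering is observable: the earlier
    time is an event (a censored subject at the same time as an event is
    taken to outlive it; two events at the same time are not orderable).
    """
    risk = np.asarray(risk_score, dtype=float)
    t = surv.time.to_numpy(dtype=float)
    e = surv.event.to_numpy(dtype=int)
    if risk.shape[0] != len(surv):
        raise OmiprogError("risk score length does not match survival table")
    # usable[i, j]: subject i observably failed before subject j
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    tied_time = (t[:, None] == t[None, :]) & (e[:, None] == 1) & (e[None, :] == 0)
    usable = earlier | tied_time
    gt = risk[:, None] > risk[None, :]
    lt = risk[:, None] < risk[None, :]
    conc = int(np.sum(usable & gt))
    disc = int(np.sum(usable & lt))
    tied = int(np.sum(usable) - conc - disc)
    return {"concordant": conc, "discordant": disc, "tied": tied,
            "usable": conc + disc + tied}


def concordance_index(risk_score, surv: SurvivalTable, ties: str = "half") -> float:
    """Harrell's C for a per-sample risk score (higher = higher risk).

    ``ties="half"`` counts score-tied usable pairs as 1/2 (Harrell's
    classic definition); ``ties="exclude"`` drops them from both numerator
    and denominator (the convention of survcomp-style implementations,
    relevant when the score is a group label and within-group pairs are
    all ties).
    """
    if surv.event.sum() == 0:
        raise OmiprogError("no events: no usable pairs for the C-index")
    c = concordance_counts(risk_score, surv)
    if c["usable"] == 0:
        raise OmiprogError("no usable pairs for the C-index")
    if ties == "half":
        return (c["concordant"] + 0.5 * c["tied"]) / c["usable"]
    if ties == "exclude":
        denom = c["concordant"] + c["discordant"]
        if denom == 0:
            return 0.5  # all usable pairs tied: no information
        return c["concordant"] / denom
    raise OmiprogError(f"unknown ties convention {ties!r}")


def _censoring_survival(surv: SurvivalTable) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, 1 - surv.event.to_numpy())
    return kmf


def _km_left(kmf: KaplanMeierFitter, times: np.ndarray) -> np.ndarray:
    """Left-continuous value G(t-) of a fitted KM step function."""
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    idx = np.searchsorted(grid, times, side="left") - 1
    out = np.where(idx >= 0, vals[np.clip(idx, 0, len(vals) - 1)], 1.0)
    return out


def brier_score(pred_survival_prob, surv: SurvivalTable, t: float | None = None) -> float:
    """IPCW Brier score at horizon ``t`` (default: median observed follow-up).

    ``pred_survival_prob`` is each sample's predicted probability of being
    event-free at ``t``.  Weights use the Kaplan–Meier estimate of the
    censoring distribution: G(T_i-) for events before t, G(t) for subjects
    still at risk.
    """
    pred = np.asarray(pred_survival_prob, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise OmiprogError("predicted survival probabilities must lie in [0, 1]")
    time = surv.time.to_numpy(dtype=float)
    event = surv.event.to_numpy(dtype=int)
    if t is None:
        t = float(np.median(time))
    if t <= 0 or t > time.max():
        raise OmiprogError(f"horizon t={t} outside follow-up range (0, {time.max()}]")
    kmf = _censoring_survival(surv)
    g_t = float(kmf.predict(t))
    if g_t <= 0:
        raise OmiprogError(
            f"censoring survival is zero at t={t}; choose a smaller horizon")
    g_left = _km_left(kmf, time)
    had_event = (time <= t) & (event == 1)
    at_risk = time > t
    contrib = np.zeros_like(pred)
    with np.errstate(divide="ignore"):
        contrib[had_event] = (pred[had_event] ** 2) / g_left[had_event]
    contrib[at_risk] = ((1.0 - pred[at_risk]) ** 2) / g_t
    return float(contrib.mean())


def integrated_brier_score(pred_fn, surv: SurvivalTable, t_max: float | None = None,
                           n_grid: int = 50) -> float:
    """Integrated IPCW Brier score over (0, t_max]; ``pred_fn(t)`` returns
    per-sample survival probabilities at ``t``."""
    time = surv.time.to_numpy(dtype=float)
    if t_max is None:
        t_max = float(np.quantile(time, 0.8))
    grid = np.linspace(time.min(), t_max, n_grid)
    scores = [brier_score(pred_fn(u), surv, u) for u in grid]
    return float(np.trapezoid(scores, grid) / (grid[-1] - grid[0]))


def group_survival_at(surv: SurvivalTable, labels, t: float) -> np.ndarray:
    """Per-sample predicted survival at ``t``: the KM value of the sample's group."""
    s = _labels_series(surv, labels)
    pred = np.empty(len(surv), dtype=float)
    for g, idx in s.groupby(s).groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time.loc[idx], surv.event.loc[idx])
        pred[s.index.get_indexer(idx)] = float(kmf.predict(t))
    return np.clip(pred, 0.0, 1.0)


def plot_km(km_curves: dict, path=None, title: str | None = None):
    """Step plot of per-group Kaplan-Meier curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, curve in sorted(km_curves.items(), key=lambda kv: str(kv[0])):
        ax.step(curve["time"], curve["survival"], where="post", label=str(g))
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="subgroup")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def evaluate_subgroups(surv: SurvivalTable, labels, horizon: float | None = None) -> SurvivalEvaluation:
    """Full survival separation bundle for a subgroup assignment.

    The C-index risk score is the Cox linear predictor of the subgroup
    indicator(s); Brier predictions are per-group Kaplan–Meier survival at
    the horizon (default: median observed follow-up time).
    """
    s = _labels_series(surv, labels)
    chi2, p = logrank_test(surv, s)
    onehot = pd.get_dummies(s.astype(str), prefix="grp", drop_first=True).astype(float)
    res = cox_fit(surv, onehot)
    lp = (onehot.to_numpy() @ np.log(res.summary["hr"].to_numpy())).ravel()
    # group labels make every within-group pair a score tie; excluding ties
    # measures the between-group ordering, the convention under which a
    # hazard ratio r maps to C ~ r/(1+r)
    c = concordance_index(lp, surv, ties="exclude")
    t = float(np.median(surv.time)) if horizon is None else float(horizon)
    pred = group_survival_at(surv, s, t)
    bs = brier_score(pred, surv, t)
    return SurvivalEvaluation(
        logrank_chi2=chi2, logrank_p=p, c_index=c, brier_score=bs,
        brier_time=t, km_curves=kaplan_meier(surv, s))
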