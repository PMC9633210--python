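"""Survival subgroup discovery on latent representation features.

Bottleneck features are screened one at a time with univariate Cox PH
models (keep p <= alpha, default 0.10); k-means is run on the surviving
features with the cluster number chosen by silhouette index (ties broken by
Calinski-Harabasz, then smaller K); clusters are finally oriented into
low/high risk by their fitted hazards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .containers import OmiprogError, SurvivalTable, check_aligned
from .survival import cox_fit

__all__ = [
    "FeatureScreenResult",
    "ClusterSelectionReport",
    "SubgroupAssignment",
    "screen_features_cox",
    "select_k",
    "kmeans_cluster",
    "orient_risk_labels",
    "discover_subgroups",
    "RiskSubgroupModel",
]


@dataclass
class FeatureScreenResult:
    pvalues: pd.Series  # per-feature univariate Cox Wald p
    kept: pd.Index
    alpha: float
    dropped_uninformative: list = field(default_factory=list)


@dataclass
class ClusterSelectionReport:
    candidates: list
    silhouette: dict
    calinski_harabasz: dict
    chosen_k: int


@dataclass
class SubgroupAssignment:
    labels: pd.Series  # per-sample risk label ("low"/"high", or "risk1".. for K>2)
    report: ClusterSelectionReport | None
    seed: int | None
    cluster_to_label: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def high_mask(self) -> np.ndarray:
        """Indicator of the highest-risk label."""
        order = _risk_order(sorted(self.labels.unique()))
        return (self.labels == order[-1]).to_numpy()


def _risk_order(names) -> list:
    rank = {"low": 0, "high": 10**6}
    return sorted(names, key=lambda s: rank.get(s, int(str(s).replace("risk", "") or 0)))


def _frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    arr = np.asarray(features, dtype=float)
    return pd.DataFrame(arr, columns=[f"f{j}" for j in range(arr.shape[1])])


def screen_features_cox(features, surv: SurvivalTable, alpha: float = 0.10) -> FeatureScreenResult:
    """Univariate Cox screen: keep features with Wald p <= alpha."""
    df = _frame(features)
    if df.shape[0] != len(surv):
        raise OmiprogError("features and survival table have different sample counts")
    if surv.event.sum() < 1:
        raise OmiprogError("need at least one event for Cox screening")
    time = surv.time.to_numpy()
    event = surv.event.to_numpy()
    pvals, dropped = {}, []
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            dropped.append(col)
            continue
        fit_df = pd.DataFrame({"x": (x - x.mean()) / x.std(),
                               "time": time, "event": event})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(fit_df, duration_col="time", event_col="event")
            pvals[col] = float(cph.summary.loc["x", "p"])
        except Exception:
            dropped.append(col)
    if dropped:
        warnings.warn(f"{len(dropped)} features dropped during Cox screening "
                      "(constant or non-convergent)")
    pser = pd.Series(pvals)
    kept = pser.index[pser <= alpha]
    if len(kept) == 0:
        raise OmiprogError(
            f"no feature passed the Cox screen at alpha={alpha}; consider a larger alpha")
    return FeatureScreenResult(pvalues=pser, kept=pd.Index(kept), alpha=alpha,
                               dropped_uninformative=dropped)


def kmeans_cluster(features, k: int, seed: int | None = None,
                   n_restarts: int = 20) -> np.ndarray:
    """Best-of-restarts k-means labels (lowest within-cluster sum of squares)."""
    df = _frame(features)
    if k < 2:
        raise OmiprogError("k must be >= 2")
    if k > df.shape[0]:
        raise OmiprogError(f"k={k} exceeds the number of samples ({df.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(df.to_numpy(dtype=float))


def select_k(features, k_candidates=range(2, 7), seed: int | None = None,
             n_restarts: int = 20) -> ClusterSelectionReport:
    """Scan candidate cluster numbers; choose by silhouette, ties by CH then smaller K."""
    df = _frame(features)
    arr = df.to_numpy(dtype=float)
    if np.all(arr == arr[0]):
        raise OmiprogError("all samples identical; clustering is degenerate")
    candidates = [k for k in k_candidates if k + 1 <= df.shape[0]]
    if not candidates:
        raise OmiprogError("too few samples for any candidate K")
    sil, ch = {}, {}
    for k in candidates:
        labels = kmeans_cluster(arr, k, seed=seed, n_restarts=n_restarts)
        if len(np.unique(labels)) < 2:
            sil[k], ch[k] = -1.0, 0.0
            continue
        sil[k] = float(silhouette_score(arr, labels))
        ch[k] = float(calinski_harabasz_score(arr, labels))
    chosen = sorted(candidates, key=lambda k: (-sil[k], -ch[k], k))[0]
    return ClusterSelectionReport(candidates=candidates, silhouette=sil,
                                  calinski_harabasz=ch, chosen_k=chosen)


def orient_risk_labels(labels, surv: SurvivalTable, report=None,
                       seed: int | None = None) -> SubgroupAssignment:
    """Name clusters by observed hazard: 'low'/'high' for K=2, 'risk1..K' otherwise.

    Hazard ordering comes from a Cox fit on the cluster indicators; clusters
    without events fall back to ordering by median observed time (shorter
    median = higher risk).
    """
    s = pd.Series(np.asarray(labels), index=surv.sample_ids)
    clusters = sorted(s.unique())
    k = len(clusters)
    events_per = {g: int(surv.event[s == g].sum()) for g in clusters}
    order = None
    if all(v >= 1 for v in events_per.values()) and k >= 2:
        try:
            onehot = pd.get_dummies(s, drop_first=True).astype(float)
            onehot.columns = [f"c{g}" for g in clusters[1:]]
            res = cox_fit(surv, onehot)
            loghr = {clusters[0]: 0.0}
            for g in clusters[1:]:
                loghr[g] = float(np.log(res.summary.loc[f"c{g}", "hr"]))
            order = sorted(clusters, key=lambda g: loghr[g])
        except OmiprogError:
            order = None
    if order is None:
        med = {g: float(surv.time[s == g].median()) for g in clusters}
        order = sorted(clusters, key=lambda g: -med[g])  # longer median = lower risk
    if k == 2:
        names = ["low", "high"]
    else:
        names = [f"risk{i + 1}" for i in range(k)]
    mapping = {g: names[i] for i, g in enumerate(order)}
    return SubgroupAssignment(labels=s.map(mapping), report=report, seed=seed,
                              cluster_to_label=mapping)


def discover_subgroups(features, surv: SurvivalTable, alpha: float = 0.10,
                       k_candidates=range(2, 7), seed: int | None = None,
                       n_restarts: int = 20) -> tuple[SubgroupAssignment, FeatureScreenResult]:
    """Screen -> select K -> cluster -> orient, the full subgroup stage."""
    df = _frame(features)
    screen = screen_features_cox(df, surv, alpha=alpha)
    kept = df[screen.kept]
    report = select_k(kept, k_candidates=k_candidates, seed=seed, n_restarts=n_restarts)
    labels = kmeans_cluster(kept, report.chosen_k, seed=seed, n_restarts=n_restarts)
    assignment = orient_risk_labels(labels, surv, report=report, seed=seed)
    return assignment, screen


class RiskSubgroupModel(ClusterMixin, BaseEstimator):
    """Estimator wrapper around the subgroup discovery stage.

    ``fit(X, y)`` expects the latent feature matrix and a
    :class:`~omiprog.containers.SurvivalTable` (or a 2-column (time, event)
    array) as ``y``.  Fitted attributes: ``labels_`` (risk names),
    ``assignment_``, ``screen_``, ``report_``.
    """

    def __init__(self, alpha: float = 0.10, k_candidates=tuple(range(2, 7)),
                 n_restarts: int = 20, random_state: int | None = None):
        self.alpha = alpha
        self.k_candidates = k_candidates
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _surv(y, X) -> SurvivalTable:
        if isinstance(y, SurvivalTable):
            return y
        arr = np.asarray(y, dtype=float)
        idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(arr.shape[0])
        return SurvivalTable(pd.DataFrame({"time": arr[:, 0], "event": arr[:, 1]},
                                          index=idx))

    def fit(self, X, y):
        surv = self._surv(y, X)
        if isinstance(X, pd.DataFrame):
            check_aligned(X, surv)
        assignment, screen = discover_subgroups(
            X, surv, alpha=self.alpha, k_candidates=self.k_candidates,
            seed=self.random_state, n_restarts=self.n_restarts)
        self.assignment_ = assignment
        self.screen_ = screen
        self.report_ = assignment.report
        self.labels_ = assignment.labels.to_numpy()
        self.n_features_in_ = _frame(X).shape[1]
        return self

    def fit_predict(self, X, y):
        return self.fit(X, y).labels_
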