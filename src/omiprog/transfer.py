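"""Supervised label transfer: internal CV-like validation and external cohorts.

The internal validation splits samples into 5 folds and uses all 10 choices
of 2 test folds vs 3 training folds.  Per combination, the unsupervised
discovery stage (autoencoder -> Cox screen -> k-means) is re-run on the
training split, ANOVA-ranked features (top 50 mRNA / 30 miRNA / 50
methylation) feed an RBF SVM which transfers the subgroup labels to the
test folds, and survival separation of the transferred labels is measured.

For external expression-only cohorts the SVM is trained on the full
discovery cohort restricted to the common genes.  Scalers are fitted
independently on each set (train, test, external) because cross-platform
location/scale differ; a train-fit/test-apply mode is available via
``fit_scalers_on_train``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import f_classif
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .autoencoder import Autoencoder
from .containers import OmicsMatrix, OmiprogError, SurvivalTable
from .preprocess import MedianScaler, TrimmedScaler, UnitFeatureScaler, unit_scale_samples, stack_omics
from .subgroup import discover_subgroups
from .survival import (
    SurvivalEvaluation,
    brier_score,
    evaluate_subgroups,
    group_survival_at,
)

__all__ = [
    "CVPlan",
    "ValidationSummary",
    "make_cv_plan",
    "anova_select",
    "scale_for_classifier",
    "fit_svm",
    "SubgroupClassifier",
    "run_internal_validation",
    "run_external_validation",
    "DEFAULT_TOP_N",
]

DEFAULT_TOP_N = {
    "mrna_counts": 50,
    "mirna_counts": 30,
    "methylation_promoter": 50,
    "methylation_beta": 50,
    "expression_intensity": 50,
}

DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 6))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-7, 4))


@dataclass
class CVPlan:
    """5 folds and the 10 (3 train folds, 2 test folds) combinations."""

    fold_of: pd.Series  # sample id -> fold index
    combos: list  # list of (train_folds tuple, test_folds tuple)
    seed: int | None

    @property
    def n_folds(self) -> int:
        return int(self.fold_of.max()) + 1

    def split(self, i: int) -> tuple[pd.Index, pd.Index]:
        train_folds, test_folds = self.combos[i]
        train = self.fold_of.index[self.fold_of.isin(train_folds)]
        test = self.fold_of.index[self.fold_of.isin(test_folds)]
        return train, test


def make_cv_plan(sample_ids, seed: int | None = None, n_folds: int = 5,
                 n_test_folds: int = 2) -> CVPlan:
    """Random near-equal 5-fold partition with all C(5,2)=10 test-fold pairs."""
    ids = pd.Index(sample_ids)
    if len(ids) < 10:
        raise OmiprogError("need at least 10 samples for the CV-like plan")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    combos = []
    for test in itertools.combinations(range(n_folds), n_test_folds):
        train = tuple(f for f in range(n_folds) if f not in test)
        combos.append((train, test))
    return CVPlan(fold_of=pd.Series(folds, index=ids), combos=combos, seed=seed)


def anova_select(m, labels, top_n: int) -> list:
    """Top features by one-way ANOVA p across labels (ties: larger F, then id)."""
    df = m.values if isinstance(m, OmicsMatrix) else m
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise OmiprogError("ANOVA selection needs at least two label classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = f_classif(df.to_numpy(dtype=float), y)
    F = np.nan_to_num(F, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    if top_n > df.shape[1]:
        warnings.warn(f"top_n={top_n} exceeds feature count {df.shape[1]}; returning all")
        top_n = df.shape[1]
    order = sorted(range(df.shape[1]), key=lambda j: (p[j], -F[j], str(df.columns[j])))
    return [df.columns[j] for j in order[:top_n]]


def scale_for_classifier(m: OmicsMatrix) -> OmicsMatrix:
    """Per-omics scaling recipe used before the SVM.

    mRNA / methylation / intensity: median-MAD scaling followed by trimmed
    ("robust") scaling.  miRNA: median-MAD scaling followed by per-feature
    unit (l2) scaling.  Parameters are fitted on the given set.
    """
    if m.kind in ("mrna_counts", "methylation_promoter", "methylation_beta",
                  "expression_intensity"):
        step1 = MedianScaler().fit_transform(m.values)
        out = TrimmedScaler().fit_transform(step1)
    elif m.kind == "mirna_counts":
        step1 = MedianScaler().fit_transform(m.values)
        out = UnitFeatureScaler().fit_transform(step1)
    else:
        raise OmiprogError(f"no classifier scaling recipe for kind {m.kind!r}")
    return OmicsMatrix(out, "latent")


def fit_svm(X, labels, c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
            cv: int = 5, seed: int | None = None) -> GridSearchCV:
    """RBF SVM with 5-fold CV grid search over (C, gamma); refit on all data."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise OmiprogError("cannot fit an SVM on single-class labels")
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    n_per_class = min(np.bincount(pd.factorize(y)[0]))
    folds = min(cv, n_per_class)
    gs = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(c_grid), "gamma": list(gamma_grid)},
        cv=StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed),
        scoring="accuracy", n_jobs=None)
    gs.fit(arr, y)
    return gs


class SubgroupClassifier(ClassifierMixin, BaseEstimator):
    """ANOVA feature selection + per-omics scaling + RBF SVM label transfer.

    ``fit`` takes a list of :class:`OmicsMatrix` (same samples) and the
    per-sample subgroup labels; ``predict`` takes matrices of the same kinds
    and returns transferred labels.  By default the scalers are re-fitted on
    each set passed to ``predict`` (cross-platform transfer); set
    ``fit_scalers_on_train=True`` to reuse the training scalers instead.
    """

    def __init__(self, top_n: dict | None = None, c_grid=DEFAULT_C_GRID,
                 gamma_grid=DEFAULT_GAMMA_GRID, cv: int = 5,
                 fit_scalers_on_train: bool = False, random_state: int | None = None):
        self.top_n = top_n
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.fit_scalers_on_train = fit_scalers_on_train
        self.random_state = random_state

    def _scale(self, m: OmicsMatrix, stored=None):
        if stored is not None:
            step1 = stored[0].transform(m.values)
            return stored[1].transform(step1)
        return scale_for_classifier(m).values

    def fit(self, omics_list, y):
        if isinstance(omics_list, OmicsMatrix):
            omics_list = [omics_list]
        top_n = dict(DEFAULT_TOP_N, **(self.top_n or {}))
        self.kinds_ = [m.kind for m in omics_list]
        self.selected_ = []
        self.scalers_ = []
        blocks = []
        for m in omics_list:
            if self.fit_scalers_on_train:
                s1 = MedianScaler().fit(m.values)
                step1 = s1.transform(m.values)
                s2 = (UnitFeatureScaler() if m.kind == "mirna_counts"
                      else TrimmedScaler()).fit(step1)
                scaled = s2.transform(step1)
                self.scalers_.append((s1, s2))
            else:
                scaled = scale_for_classifier(m).values
                self.scalers_.append(None)
            sel = anova_select(scaled, y, top_n.get(m.kind, 50))
            self.selected_.append(sel)
            blocks.append(scaled[sel])
        X = pd.concat(blocks, axis=1)
        self.svm_ = fit_svm(X, y, self.c_grid, self.gamma_grid, self.cv,
                            seed=self.random_state)
        self.best_params_ = self.svm_.best_params_
        self.classes_ = self.svm_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, omics_list):
        if isinstance(omics_list, OmicsMatrix):
            omics_list = [omics_list]
        blocks = []
        for m, sel, stored in zip(omics_list, self.selected_, self.scalers_):
            missing = [f for f in sel if f not in set(m.feature_ids)]
            if missing:
                raise OmiprogError(
                    f"matrix of kind {m.kind} lacks selected features, e.g. {missing[:5]}")
            scaled = (self._scale(m, stored) if stored is not None
                      else scale_for_classifier(m).values)
            blocks.append(scaled[sel])
        X = pd.concat(blocks, axis=1)
        return self.svm_.predict(X.to_numpy(dtype=float))


def _evaluate_transferred(surv: SurvivalTable, labels) -> SurvivalEvaluation:
    """Evaluation for transferred labels; a single-class transfer means no
    separation (chi2 = 0, p = 1, C = 1/2, Brier of the marginal KM)."""
    labels = np.asarray(labels)
    if len(pd.unique(labels)) >= 2:
        return evaluate_subgroups(surv, labels)
    t = float(np.median(surv.time))
    pred = group_survival_at(surv, np.zeros(len(surv), dtype=int), t)
    return SurvivalEvaluation(logrank_chi2=0.0, logrank_p=1.0, c_index=0.5,
                              brier_score=brier_score(pred, surv, t),
                              brier_time=t, km_curves={})


# ---------------------------------------------------------------------------
# validation drivers

@dataclass
class ValidationSummary:
    """Per-combination survival evaluations plus the aggregate statistics."""

    entries: list  # one dict per combo: {"combo", "train": {...}, "test": {...}}
    skipped: list = field(default_factory=list)

    def _collect(self, split: str, which: str, metric: str) -> np.ndarray:
        vals = []
        for ent in self.entries:
            ev = ent[split].get(which)
            if ev is not None:
                vals.append(getattr(ev, metric))
        return np.asarray(vals, dtype=float)

    def geometric_mean_p(self, split: str = "test", which: str = "multi") -> float:
        p = self._collect(split, which, "logrank_p")
        return float(np.exp(np.mean(np.log(np.maximum(p, 1e-300)))))

    def metric_mean_sd(self, metric: str, split: str = "test",
                       which: str = "multi") -> tuple[float, float]:
        v = self._collect(split, which, metric)
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def table(self) -> pd.DataFrame:
        rows = []
        for split in ("train", "test"):
            for which in sorted({w for e in self.entries for w in e[split]}):
                c_mean, c_sd = self.metric_mean_sd("c_index", split, which)
                b_mean, b_sd = self.metric_mean_sd("brier_score", split, which)
                rows.append({
                    "dataset": split, "omics": which,
                    "logrank_p_geomean": self.geometric_mean_p(split, which),
                    "c_index_mean": c_mean, "c_index_sd": c_sd,
                    "brier_mean": b_mean, "brier_sd": b_sd,
                })
        return pd.DataFrame(rows)


def _discovery_on(omics: dict, surv: SurvivalTable, sample_ids, ae_params: dict,
                  alpha: float, k_candidates, seed: int):
    scaled = [unit_scale_samples(m.with_values(m.values.loc[sample_ids]))
              for m in omics.values()]
    stacked = stack_omics(scaled)
    ae = Autoencoder(random_state=seed, **ae_params)
    bottleneck = ae.fit_transform(stacked.values)
    bottleneck = pd.DataFrame(bottleneck, index=stacked.sample_ids)
    sub_surv = surv.loc(stacked.sample_ids)
    assignment, _ = discover_subgroups(bottleneck, sub_surv, alpha=alpha,
                                       k_candidates=k_candidates, seed=seed)
    return assignment


def run_internal_validation(
    omics: dict,
    surv: SurvivalTable,
    ae_params: dict | None = None,
    seed: int = 0,
    alpha: float = 0.10,
    k_candidates=range(2, 7),
    top_n: dict | None = None,
    per_omics: bool = False,
    svm_kwargs: dict | None = None,
) -> ValidationSummary:
    """CV-like internal validation of the discovery pipeline.

    ``omics`` maps names to preprocessed (filtered/aggregated/imputed, not
    yet scaled) :class:`OmicsMatrix` layers sharing the sample universe.
    Per combination the discovery stage is retrained on the 3 training
    folds (autoencoder seed = ``seed + 1 + combo``), labels are transferred
    to the 2 test folds by the SVM, and log-rank/C-index/Brier are computed
    on both splits.  ``per_omics=True`` additionally fits one SVM per
    single omics layer.
    """
    ae_params = ae_params or {}
    svm_kwargs = svm_kwargs or {}
    ids = next(iter(omics.values())).sample_ids
    plan = make_cv_plan(ids, seed=seed)
    entries, skipped = [], []
    for i in range(len(plan.combos)):
        train_ids, test_ids = plan.split(i)
        try:
            assignment = _discovery_on(omics, surv, train_ids, ae_params,
                                       alpha, k_candidates, seed=seed + 1 + i)
        except OmiprogError as exc:
            warnings.warn(f"combo {i}: discovery failed ({exc}); skipped")
            skipped.append(i)
            continue
        train_labels = assignment.labels
        if train_labels.nunique() < 2:
            warnings.warn(f"combo {i}: single-class training labels; skipped")
            skipped.append(i)
            continue
        train_mats = {k: m.with_values(m.values.loc[train_labels.index])
                      for k, m in omics.items()}
        test_mats = {k: m.with_values(m.values.loc[test_ids])
                     for k, m in omics.items()}
        sets = {"multi": list(omics.keys())}
        if per_omics:
            sets.update({k: [k] for k in omics.keys()})
        ent = {"combo": plan.combos[i], "train": {}, "test": {}}
        for which, keys in sets.items():
            clf = SubgroupClassifier(top_n=top_n, random_state=seed + 1 + i,
                                     **svm_kwargs)
            clf.fit([train_mats[k] for k in keys], train_labels.to_numpy())
            pred_test = clf.predict([test_mats[k] for k in keys])
            try:
                ent["train"][which] = _evaluate_transferred(
                    surv.loc(train_labels.index), train_labels.to_numpy())
                ent["test"][which] = _evaluate_transferred(surv.loc(test_ids), pred_test)
            except OmiprogError as exc:
                warnings.warn(f"combo {i} ({which}): evaluation failed ({exc})")
                ent["train"].setdefault(which, None)
                ent["test"].setdefault(which, None)
        entries.append(ent)
    return ValidationSummary(entries=entries, skipped=skipped)


def run_external_validation(
    discovery_mrna: OmicsMatrix,
    discovery_labels,
    external_expr: OmicsMatrix,
    external_surv: SurvivalTable,
    top_n: int = 50,
    seed: int = 0,
    svm_kwargs: dict | None = None,
) -> tuple[SurvivalEvaluation, pd.Series]:
    """Transfer discovery subgroup labels to an expression-only cohort.

    Both cohorts are restricted to their common genes; the top ``top_n``
    ANOVA features are chosen on the full discovery cohort against its
    discovered labels, the SVM is trained on discovery and applied to the
    external cohort, and survival separation of the transferred labels is
    evaluated.  Returns (evaluation, predicted labels).
    """
    svm_kwargs = svm_kwargs or {}
    common = [g for g in discovery_mrna.feature_ids if g in set(external_expr.feature_ids)]
    if not common:
        raise OmiprogError("empty gene intersection between cohorts")
    if len(common) < top_n:
        warnings.warn(f"only {len(common)} common genes (< top_n={top_n}); using all")
    disc = discovery_mrna.with_values(discovery_mrna.values[common])
    ext = external_expr.with_values(external_expr.values[common])
    clf = SubgroupClassifier(top_n={disc.kind: top_n}, random_state=seed, **svm_kwargs)
    clf.fit([disc], np.asarray(discovery_labels))
    # selected gene names carry over: the external matrix shares the gene
    # universe and the intensity kind maps to the same scaling recipe
    pred = clf.predict([ext])
    pred_s = pd.Series(pred, index=ext.sample_ids, name="subgroup")
    evaluation = _evaluate_transferred(external_surv, pred_s.to_numpy())
    return evaluation, pred_s
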