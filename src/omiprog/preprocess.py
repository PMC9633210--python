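"""Preprocessing: filtering, promoter aggregation, imputation, normalization.

Count layers are filtered by zero fraction (features first, then samples);
CpG methylation is averaged over strand-aware promoter windows (1500 bp
upstream of the TSS) into per-gene values, filtered by missing fraction and
KNN-imputed.  Three normalizations are provided, both as plain functions and
as scikit-learn transformers:

* per-sample unit (l2) scaling — applied to every layer before stacking,
* per-feature median/MAD scaling,
* per-feature "robust" scaling by the mean and sd of the interquartile slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer
from sklearn.utils.validation import check_is_fitted

from .containers import (
    COUNT_KINDS,
    CpGAnnotation,
    GeneAnnotation,
    OmicsMatrix,
    OmiprogError,
)

__all__ = [
    "ScalerParams",
    "StackedMatrix",
    "filter_zero_features",
    "filter_zero_samples",
    "filter_missing",
    "aggregate_promoter_methylation",
    "knn_impute",
    "unit_scale_samples",
    "median_scale",
    "robust_scale",
    "collapse_probes_to_genes",
    "stack_omics",
    "UnitSampleScaler",
    "MedianScaler",
    "TrimmedScaler",
    "UnitFeatureScaler",
]


@dataclass
class ScalerParams:
    """Per-feature location/scale statistics fitted by the scalers."""

    median: pd.Series | None = None
    mad: pd.Series | None = None
    trimmed_mean: pd.Series | None = None
    trimmed_sd: pd.Series | None = None
    degenerate: pd.Index | None = None  # features with zero scale (divided by 1)


@dataclass
class StackedMatrix(OmicsMatrix):
    """Stacked multiomics matrix retaining per-layer column provenance."""

    blocks: dict = field(default_factory=dict)  # prefix -> list of stacked column names


# ---------------------------------------------------------------------------
# filtering

def filter_zero_features(m: OmicsMatrix, max_zero_frac: float = 0.2) -> OmicsMatrix:
    """Drop features whose zero fraction exceeds ``max_zero_frac``."""
    if m.kind not in COUNT_KINDS:
        raise OmiprogError(f"zero filtering applies to count layers, not {m.kind}")
    frac = (m.values == 0).mean(axis=0)
    keep = frac <= max_zero_frac
    if not keep.any():
        raise OmiprogError(
            f"all features exceed the zero-fraction threshold {max_zero_frac}")
    return m.with_values(m.values.loc[:, keep])


def filter_zero_samples(m: OmicsMatrix, max_zero_frac: float = 0.2) -> OmicsMatrix:
    """Drop samples whose zero fraction exceeds ``max_zero_frac`` (after feature filtering)."""
    if m.kind not in COUNT_KINDS:
        raise OmiprogError(f"zero filtering applies to count layers, not {m.kind}")
    frac = (m.values == 0).mean(axis=1)
    keep = frac <= max_zero_frac
    if not keep.any():
        raise OmiprogError(
            f"all samples exceed the zero-fraction threshold {max_zero_frac}")
    return m.with_values(m.values.loc[keep, :])


def filter_missing(m: OmicsMatrix, max_missing_frac: float = 0.2,
                   axis: str = "both") -> OmicsMatrix:
    """Drop entries whose missing fraction exceeds the threshold.

    ``axis`` is "features", "samples", or "both" (features first, then
    samples — the standard order for this pipeline).
    """
    if axis not in ("features", "samples", "both"):
        raise OmiprogError(f"axis must be 'features', 'samples' or 'both', got {axis!r}")
    vals = m.values
    if axis in ("features", "both"):
        keep_f = vals.isna().mean(axis=0) <= max_missing_frac
        if not keep_f.any():
            raise OmiprogError(
                f"all features exceed the missing-fraction threshold {max_missing_frac}")
        vals = vals.loc[:, keep_f]
    if axis in ("samples", "both"):
        keep_s = vals.isna().mean(axis=1) <= max_missing_frac
        if not keep_s.any():
            raise OmiprogError(
                f"all samples exceed the missing-fraction threshold {max_missing_frac}")
        vals = vals.loc[keep_s, :]
    return m.with_values(vals)


# ---------------------------------------------------------------------------
# promoter aggregation

def promoter_window(tss: int, strand: str, window_bp: int = 1500) -> tuple[int, int]:
    """Inclusive 1-based promoter interval upstream of the TSS, strand-aware."""
    if strand == "+":
        return max(1, tss - window_bp), tss
    return tss, tss + window_bp


def aggregate_promoter_methylation(
    cpg: OmicsMatrix,
    cpg_ann: CpGAnnotation,
    gene_ann: GeneAnnotation,
    window_bp: int = 1500,
) -> OmicsMatrix:
    """Average CpG beta values within each gene's promoter window.

    A gene cell is missing only when all of its in-window CpGs are missing;
    genes with no in-window CpG are dropped.
    """
    if cpg.kind != "methylation_beta":
        raise OmiprogError(f"expected methylation_beta, got {cpg.kind}")
    if len(gene_ann.table) == 0 or len(cpg_ann.table) == 0:
        raise OmiprogError("empty annotation")

    probes = cpg_ann.table[cpg_ann.table["probe_id"].isin(cpg.feature_ids)]
    probes = probes.set_index("probe_id")
    out = {}
    by_chrom = {c: g.sort_values("position") for c, g in probes.groupby("chromosome")}
    for row in gene_ann.table.itertuples(index=False):
        chrom_probes = by_chrom.get(row.chromosome)
        if chrom_probes is None:
            continue
        lo, hi = promoter_window(int(row.tss), row.strand, window_bp)
        pos = chrom_probes["position"].to_numpy()
        sel = chrom_probes.index[(pos >= lo) & (pos <= hi)]
        if len(sel) == 0:
            continue
        out[row.gene_id] = cpg.values[sel].mean(axis=1, skipna=True)
    if not out:
        raise OmiprogError("no gene promoter contains a CpG probe")
    df = pd.DataFrame(out, index=cpg.sample_ids)
    return OmicsMatrix(df, "methylation_promoter")


# ---------------------------------------------------------------------------
# imputation

def knn_impute(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing cells from the ``k`` nearest *features*.

    Distances between features are Euclidean over co-observed samples; the
    imputed value is the mean of the neighbours' values in that sample (the
    convention of nearest-neighbour imputation for omics matrices).
    """
    if not m.values.isna().any().any():
        return m
    fully_missing = m.values.isna().all(axis=0)
    if fully_missing.any():
        warnings.warn(
            f"{int(fully_missing.sum())} features have no observed values; "
            "falling back to the per-sample mean for them")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputed_t = imputer.fit_transform(m.values.to_numpy(dtype=float).T)
    vals = pd.DataFrame(imputed_t.T, index=m.sample_ids, columns=m.feature_ids)
    if m.kind.startswith("methylation"):
        vals = vals.clip(0.0, 1.0)
    return m.with_values(vals)


# ---------------------------------------------------------------------------
# scalers (scikit-learn estimators)

class UnitSampleScaler(TransformerMixin, BaseEstimator):
    """Scale each sample (row) to unit Euclidean norm.

    ``squared=True`` divides by the squared norm instead (an alternative
    convention occasionally seen in print); the default produces genuine
    unit vectors.  Zero rows are left unchanged with a warning.
    """

    def __init__(self, squared: bool = False):
        self.squared = squared

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X, dtype=float).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        norms = np.linalg.norm(X, axis=1)
        zero = norms == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero rows left unscaled")
        denom = norms**2 if self.squared else norms
        denom = np.where(zero, 1.0, denom)
        return X / denom[:, None]


def _feature_frame(X):
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class MedianScaler(TransformerMixin, BaseEstimator):
    """Per-feature (x - median) / MAD scaling.

    The MAD is the raw median absolute deviation (no consistency constant).
    Features with MAD 0 are divided by 1 and flagged in ``degenerate_``.
    """

    def fit(self, X, y=None):
        df = _feature_frame(X)
        self.median_ = df.median(axis=0)
        self.mad_ = (df - self.median_).abs().median(axis=0)
        self.degenerate_ = df.columns[self.mad_ == 0]
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "median_")
        df = _feature_frame(X)
        scale = self.mad_.where(self.mad_ > 0, 1.0)
        out = (df - self.median_) / scale
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()


class TrimmedScaler(TransformerMixin, BaseEstimator):
    """Per-feature scaling by mean and sd of the interquartile slice.

    Each feature is centered by the mean of its values lying within
    [Q1, Q3] (inclusive) and divided by the standard deviation of that same
    trimmed set.  Features whose trimmed sd is 0 are divided by 1 and
    flagged.  If fewer than 2 values fall in the slice, the full mean/sd is
    used with a warning.
    """

    def fit(self, X, y=None):
        df = _feature_frame(X)
        means, sds, degenerate = {}, {}, []
        for col in df.columns:
            x = df[col].to_numpy(dtype=float)
            q1, q3 = np.percentile(x, [25, 75])
            trimmed = x[(x >= q1) & (x <= q3)]
            if trimmed.size < 2:
                warnings.warn(f"feature {col}: fewer than 2 values in [Q1, Q3]; "
                              "using full mean/sd")
                trimmed = x
            mu = trimmed.mean()
            sd = trimmed.std(ddof=1) if trimmed.size > 1 else 0.0
            if sd == 0:
                degenerate.append(col)
                sd = 1.0
            means[col], sds[col] = mu, sd
        self.trimmed_mean_ = pd.Series(means)
        self.trimmed_sd_ = pd.Series(sds)
        self.degenerate_ = pd.Index(degenerate)
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "trimmed_mean_")
        df = _feature_frame(X)
        out = (df - self.trimmed_mean_) / self.trimmed_sd_
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()


class UnitFeatureScaler(TransformerMixin, BaseEstimator):
    """Scale each feature (column) vector to unit Euclidean norm."""

    def fit(self, X, y=None):
        df = _feature_frame(X)
        norms = np.linalg.norm(df.to_numpy(dtype=float), axis=0)
        self.norms_ = pd.Series(np.where(norms == 0, 1.0, norms), index=df.columns)
        self.degenerate_ = df.columns[norms == 0]
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "norms_")
        df = _feature_frame(X)
        out = df / self.norms_
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()


# function wrappers over the estimators --------------------------------------

def unit_scale_samples(m: OmicsMatrix, squared: bool = False) -> OmicsMatrix:
    scaled = UnitSampleScaler(squared=squared).fit_transform(m.to_numpy())
    return m.with_values(pd.DataFrame(scaled, index=m.sample_ids, columns=m.feature_ids),
                         kind="latent" if m.kind == "latent" else m.kind)


def median_scale(m: OmicsMatrix) -> tuple[OmicsMatrix, ScalerParams]:
    sc = MedianScaler().fit(m.values)
    out = m.with_values(sc.transform(m.values), kind="latent")
    return out, ScalerParams(median=sc.median_, mad=sc.mad_, degenerate=sc.degenerate_)


def robust_scale(m: OmicsMatrix) -> tuple[OmicsMatrix, ScalerParams]:
    sc = TrimmedScaler().fit(m.values)
    out = m.with_values(sc.transform(m.values), kind="latent")
    return out, ScalerParams(trimmed_mean=sc.trimmed_mean_, trimmed_sd=sc.trimmed_sd_,
                             degenerate=sc.degenerate_)


# ---------------------------------------------------------------------------
# probe collapsing and stacking

def collapse_probes_to_genes(m: OmicsMatrix, probe_to_gene: dict) -> OmicsMatrix:
    """Average expression probes mapping to the same gene symbol."""
    if not probe_to_gene:
        raise OmiprogError("empty probe-to-gene mapping")
    mapped = [p for p in m.feature_ids if p in probe_to_gene]
    if not mapped:
        raise OmiprogError("no probe maps to a gene symbol")
    sub = m.values[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped])
    collapsed = sub.T.groupby(genes).mean().T
    return m.with_values(collapsed)


_PREFIX = {
    "mrna_counts": "mrna",
    "mirna_counts": "mirna",
    "methylation_beta": "meth",
    "methylation_promoter": "meth",
    "expression_intensity": "expr",
    "latent": "latent",
    "stacked": "stacked",
}


def stack_omics(ms: list[OmicsMatrix]) -> StackedMatrix:
    """Inner-join layers on sample ids and concatenate features.

    Row order follows the first matrix restricted to the common samples.
    Column names get an omics prefix; per-layer provenance is kept in
    ``blocks``.
    """
    if not ms:
        raise OmiprogError("no matrices to stack")
    common = ms[0].sample_ids
    for m in ms[1:]:
        common = common.intersection(m.sample_ids)
    common = pd.Index([s for s in ms[0].sample_ids if s in set(common)])
    if len(common) == 0:
        raise OmiprogError("empty sample intersection")

    frames, blocks = [], {}
    seen = {}
    for m in ms:
        prefix = _PREFIX[m.kind]
        seen[prefix] = seen.get(prefix, 0) + 1
        tag = prefix if seen[prefix] == 1 else f"{prefix}{seen[prefix]}"
        cols = [f"{tag}:{c}" for c in m.feature_ids]
        df = m.values.loc[common]
        df.columns = cols
        frames.append(df)
        blocks[tag] = cols
    stacked = pd.concat(frames, axis=1)
    return StackedMatrix(values=stacked, kind="stacked", blocks=blocks)
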