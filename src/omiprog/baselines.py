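"""Alternative integration approaches: PCA and similarity network fusion.

The PCA baseline swaps the autoencoder bottleneck for principal-component
scores and reuses the identical downstream path (Cox screen, k-means, risk
orientation, survival evaluation).  The SNF baseline builds one sample
affinity network per omics layer from correlation distances, fuses them by
iterative cross-diffusion, and clusters the fused network spectrally with
the cluster number picked by the largest Laplacian eigengap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA

from .containers import OmicsMatrix, OmiprogError, SurvivalTable
from .subgroup import SubgroupAssignment, discover_subgroups, orient_risk_labels
from .survival import SurvivalEvaluation, evaluate_subgroups

__all__ = [
    "SNFConfig",
    "pca_reduce",
    "run_pca_baseline",
    "snf_affinity",
    "snf_fuse",
    "spectral_cluster",
    "run_snf_baseline",
]

_EPS = np.finfo(float).eps


@dataclass
class SNFConfig:
    """SNF hyperparameters: neighbourhood size K, kernel bandwidth sigma,
    diffusion iterations T, and the cluster count (None = eigengap choice)."""

    k_neighbors: int = 14
    sigma: float = 0.3
    t_iterations: int = 27
    n_clusters: int | None = None
    correlation: str = "pearson"

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise OmiprogError("k_neighbors must be >= 1")
        if self.sigma <= 0:
            raise OmiprogError("sigma must be positive")
        if self.t_iterations < 1:
            raise OmiprogError("t_iterations must be >= 1")


# ---------------------------------------------------------------------------
# PCA baseline

def pca_reduce(m, n_components: int = 500):
    """Centered PCA scores ordered by decreasing explained variance.

    ``n_components`` is clamped (with a warning) to min(n_samples - 1,
    n_features) when the matrix cannot support it.
    """
    df = m.values if isinstance(m, OmicsMatrix) else pd.DataFrame(np.asarray(m, float))
    arr = df.to_numpy(dtype=float)
    if np.allclose(arr, arr[0]):
        raise OmiprogError("constant matrix: PCA undefined")
    max_rank = min(arr.shape[0] - 1, arr.shape[1])
    if n_components > max_rank:
        warnings.warn(f"n_components={n_components} clamped to rank limit {max_rank}")
        n_components = max_rank
    scores = PCA(n_components=n_components, svd_solver="auto").fit_transform(arr)
    return pd.DataFrame(scores, index=df.index,
                        columns=[f"pc{j + 1:03d}" for j in range(scores.shape[1])])


def run_pca_baseline(stacked: OmicsMatrix, surv: SurvivalTable,
                     n_components: int = 500, alpha: float = 0.10,
                     k_candidates=range(2, 7), seed: int | None = None
                     ) -> tuple[SubgroupAssignment, SurvivalEvaluation]:
    """PCA scores -> Cox screen -> k-means -> orientation -> evaluation."""
    scores = pca_reduce(stacked, n_components=n_components)
    sub_surv = surv.loc(scores.index)
    assignment, _ = discover_subgroups(scores, sub_surv, alpha=alpha,
                                       k_candidates=k_candidates, seed=seed)
    evaluation = evaluate_subgroups(sub_surv, assignment.labels.to_numpy())
    return assignment, evaluation


# ---------------------------------------------------------------------------
# SNF

def _correlation_distance(arr: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        from scipy.stats import rankdata
        arr = np.apply_along_axis(rankdata, 1, arr)
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0])
        raise OmiprogError(f"zero-variance samples (rows {bad[:5]}): "
                           "correlation distance undefined")
    corr = np.corrcoef(arr)
    return 1.0 - corr


def snf_affinity(m, config: SNFConfig | None = None) -> np.ndarray:
    """Scaled-exponential-kernel affinity from pairwise correlation distance.

    Local bandwidths follow the SNF construction: eps_ij is the average of
    the mean distances of i and j to their K nearest neighbours and d_ij,
    and the kernel is the normal density with sd sigma * eps_ij.
    """
    config = config or SNFConfig()
    config.validate()
    df = m.values if isinstance(m, OmicsMatrix) else pd.DataFrame(np.asarray(m, float))
    arr = df.to_numpy(dtype=float)
    n = arr.shape[0]
    if n < config.k_neighbors + 2:
        raise OmiprogError("need at least K+2 samples for the SNF affinity")
    d = _correlation_distance(arr, config.correlation)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    sorted_d = np.sort(d, axis=1)
    mu = sorted_d[:, 1:config.k_neighbors + 1].mean(axis=1) + _EPS
    eps = (mu[:, None] + mu[None, :]) / 3.0 + d / 3.0 + _EPS
    eps = np.maximum(eps, _EPS)
    sd = config.sigma * eps
    dens = np.exp(-(d**2) / (2.0 * sd**2)) / (np.sqrt(2 * np.pi) * sd)
    return (dens + dens.T) / 2.0


def _normalize_p(w: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix with the stabilising 1/2 on the diagonal."""
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    rs = off.sum(axis=1)
    rs[rs == 0] = 1.0
    p = off / (2.0 * rs[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _knn_kernel(w: np.ndarray, k: int) -> np.ndarray:
    """Keep each row's K largest off-diagonal entries, row-normalized."""
    n = w.shape[0]
    s = np.zeros_like(w)
    off = w.copy()
    np.fill_diagonal(off, -np.inf)
    idx = np.argsort(off, axis=1)[:, ::-1][:, :k]
    rows = np.repeat(np.arange(n), k)
    s[rows, idx.ravel()] = w[rows, idx.ravel()]
    rs = s.sum(axis=1)
    rs[rs == 0] = 1.0
    return s / rs[:, None]


def snf_fuse(affinities: list, config: SNFConfig | None = None) -> np.ndarray:
    """Fuse per-omics affinity matrices by iterative cross-diffusion.

    Each view's transition matrix is diffused through its K-NN kernel
    against the average of the other views for T iterations; the fused
    network is the symmetrized average.  A single input view diffuses
    against itself (degenerate but well defined).
    """
    config = config or SNFConfig()
    config.validate()
    mats = [np.asarray(a, dtype=float) for a in affinities]
    if not mats:
        raise OmiprogError("no affinity matrices to fuse")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise OmiprogError("affinity matrices have mismatching shapes")
    p = [_normalize_p(m) for m in mats]
    s = [_knn_kernel(m, config.k_neighbors) for m in mats]
    v = len(mats)
    for _ in range(config.t_iterations):
        new = []
        for i in range(v):
            if v == 1:
                other = p[0]
            else:
                other = sum(p[j] for j in range(v) if j != i) / (v - 1)
            pi = s[i] @ other @ s[i].T
            pi = _normalize_p(pi)
            new.append((pi + pi.T) / 2.0)
        p = new
    fused = sum(p) / v
    fused = _normalize_p(fused)
    return (fused + fused.T + np.eye(shape[0])) / 2.0


def eigengap_k(affinity: np.ndarray, k_candidates=range(2, 7)) -> int:
    """Cluster number with the largest normalized-Laplacian eigengap."""
    w = np.asarray(affinity, dtype=float)
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(w.shape[0]) - d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    evals = np.sort(np.linalg.eigvalsh(lap))
    gaps = {k: evals[k] - evals[k - 1] for k in k_candidates if k < len(evals)}
    if not gaps:
        raise OmiprogError("too few samples for the candidate cluster numbers")
    return max(gaps, key=gaps.get)


def spectral_cluster(fused: np.ndarray, n_clusters: int | None = None,
                     k_candidates=range(2, 7), seed: int | None = None) -> np.ndarray:
    """Normalized-Laplacian spectral clustering of a fused affinity matrix."""
    w = np.asarray(fused, dtype=float)
    if not np.allclose(w, w.T, atol=1e-8):
        raise OmiprogError("fused matrix must be symmetric")
    if np.any(w < -1e-12):
        raise OmiprogError("fused matrix must be nonnegative")
    if n_clusters is None:
        n_clusters = eigengap_k(w, k_candidates)
    n_comp, comp_labels = connected_components(w > 1e-12, directed=False)
    if n_comp > n_clusters:
        warnings.warn(f"graph has {n_comp} components > {n_clusters} clusters; "
                      "labelling by connected component")
        return comp_labels
    sc = SpectralClustering(n_clusters=n_clusters, affinity="precomputed",
                            random_state=seed, assign_labels="kmeans", n_init=20)
    return sc.fit_predict(w)


def run_snf_baseline(omics_list: list, surv: SurvivalTable,
                     config: SNFConfig | None = None, seed: int | None = None
                     ) -> tuple[SubgroupAssignment, SurvivalEvaluation]:
    """Per-omics affinities -> fusion -> spectral clustering -> evaluation."""
    config = config or SNFConfig()
    ids = omics_list[0].sample_ids
    affinities = [snf_affinity(m, config) for m in omics_list]
    fused = snf_fuse(affinities, config)
    labels = spectral_cluster(fused, n_clusters=config.n_clusters, seed=seed)
    sub_surv = surv.loc(ids)
    assignment = orient_risk_labels(labels, sub_surv, seed=seed)
    evaluation = evaluate_subgroups(sub_surv, assignment.labels.to_numpy())
    return assignment, evaluation
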