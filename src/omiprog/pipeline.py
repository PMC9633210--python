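"""End-to-end orchestration: preprocess -> integrate -> subgroup -> evaluate.

``run_discovery`` executes the full unsupervised discovery path on a
multiomics cohort; ``run_compare`` reruns the downstream stages with the
PCA and SNF alternatives so the three methods are comparable on the shared
evaluation bundle.  A manifest records the configuration, stage seeds and
content digests of the main outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .autoencoder import Autoencoder
from .baselines import SNFConfig, run_pca_baseline, run_snf_baseline
from .containers import OmicsMatrix, OmiprogError, SurvivalTable, SyntheticCohort
from .preprocess import (
    aggregate_promoter_methylation,
    filter_missing,
    filter_zero_features,
    filter_zero_samples,
    knn_impute,
    stack_omics,
    unit_scale_samples,
)
from .subgroup import FeatureScreenResult, SubgroupAssignment, discover_subgroups
from .survival import SurvivalEvaluation, evaluate_subgroups

__all__ = ["PipelineConfig", "DiscoveryResult", "RunManifest", "preprocess_cohort",
           "run_discovery", "run_compare"]

# fixed offsets fanning the global seed out to the stages
_SEED_OFFSETS = {"autoencoder": 11, "cluster": 23, "pca": 31, "snf": 41, "cv": 53}


@dataclass
class PipelineConfig:
    """All tunable parameters of the discovery pipeline (defaults are the
    standard operating point: 20% zero/missing filters, screening alpha
    0.10, K scanned over 2..6, SNF at K=14/sigma=0.3/T=27)."""

    max_zero_frac: float = 0.2
    max_missing_frac: float = 0.2
    knn_k: int = 10
    promoter_window_bp: int = 1500
    ae: dict = field(default_factory=lambda: {
        "hidden_sizes": (2000, 500, 2000), "activation": "tanh", "epochs": 32,
        "batch_size": 16, "learning_rate": 1e-3, "batch_norm": True})
    alpha: float = 0.10
    k_candidates: tuple = tuple(range(2, 7))
    n_restarts: int = 20
    snf: SNFConfig = field(default_factory=SNFConfig)
    pca_components: int | None = None  # None = bottleneck size
    de_lfc_threshold: float = 1.0
    de_fdr_threshold: float = 0.05
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seeds: dict
    digests: dict
    started: float
    finished: float | None = None

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        return json.dumps(asdict(self), indent=2, default=default)


@dataclass
class DiscoveryResult:
    assignment: SubgroupAssignment
    evaluation: SurvivalEvaluation
    screen: FeatureScreenResult
    bottleneck: pd.DataFrame
    stacked: OmicsMatrix
    omics: dict           # preprocessed, unscaled layers
    scaled_omics: dict    # unit-sample-scaled layers (SNF input)
    survival: SurvivalTable
    manifest: RunManifest


def _digest(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes())
    h.update(",".join(map(str, df.columns)).encode())
    h.update(",".join(map(str, df.index)).encode())
    return h.hexdigest()[:16]


def preprocess_cohort(cohort: SyntheticCohort, config: PipelineConfig
                      ) -> tuple[dict, SurvivalTable]:
    """Filter counts, aggregate/ impute methylation, align samples.

    Returns the preprocessed (unscaled) layers keyed by name and the
    survival table restricted to the common samples.
    """
    mrna = filter_zero_samples(filter_zero_features(cohort.mrna, config.max_zero_frac),
                               config.max_zero_frac)
    mirna = filter_zero_samples(filter_zero_features(cohort.mirna, config.max_zero_frac),
                                config.max_zero_frac)
    prom = aggregate_promoter_methylation(cohort.methylation_cpg, cohort.cpg_annotation,
                                          cohort.gene_annotation,
                                          window_bp=config.promoter_window_bp)
    prom = knn_impute(filter_missing(prom, config.max_missing_frac), k=config.knn_k)
    common = [s for s in mrna.sample_ids
              if s in set(mirna.sample_ids) and s in set(prom.sample_ids)]
    if not common:
        raise OmiprogError("no common samples across omics layers after filtering")
    omics = {
        "mrna": mrna.with_values(mrna.values.loc[common]),
        "mirna": mirna.with_values(mirna.values.loc[common]),
        "methylation": prom.with_values(prom.values.loc[common]),
    }
    return omics, cohort.survival.loc(common)


def run_discovery(cohort: SyntheticCohort, config: PipelineConfig | None = None
                  ) -> DiscoveryResult:
    """Preprocess -> stack -> autoencoder -> Cox screen -> k-means -> evaluate."""
    config = config or PipelineConfig()
    started = time.time()
    omics, surv = preprocess_cohort(cohort, config)
    scaled = {k: unit_scale_samples(m) for k, m in omics.items()}
    stacked = stack_omics(list(scaled.values()))
    ae_seed = config.seed + _SEED_OFFSETS["autoencoder"]
    ae = Autoencoder(random_state=ae_seed, **config.ae)
    bottleneck = pd.DataFrame(ae.fit_transform(stacked.values),
                              index=stacked.sample_ids,
                              columns=[f"ae{j:03d}" for j in range(ae.bottleneck_size_)])
    cluster_seed = config.seed + _SEED_OFFSETS["cluster"]
    assignment, screen = discover_subgroups(
        bottleneck, surv, alpha=config.alpha, k_candidates=config.k_candidates,
        seed=cluster_seed, n_restarts=config.n_restarts)
    evaluation = evaluate_subgroups(surv, assignment.labels.to_numpy())
    manifest = RunManifest(
        config={**asdict(config), "snf": asdict(config.snf)},
        version=__version__,
        stage_seeds={"autoencoder": ae_seed, "cluster": cluster_seed},
        digests={
            "stacked": _digest(stacked.values),
            "bottleneck": _digest(bottleneck),
            "labels": hashlib.sha256(
                ",".join(assignment.labels).encode()).hexdigest()[:16],
        },
        started=started,
        finished=time.time(),
    )
    return DiscoveryResult(assignment=assignment, evaluation=evaluation, screen=screen,
                           bottleneck=bottleneck, stacked=stacked, omics=omics,
                           scaled_omics=scaled, survival=surv, manifest=manifest)


def run_compare(result: DiscoveryResult, config: PipelineConfig | None = None
                ) -> pd.DataFrame:
    """One row per integration method with the shared survival metrics."""
    config = config or PipelineConfig()
    n_comp = config.pca_components or result.bottleneck.shape[1]
    _, pca_eval = run_pca_baseline(
        result.stacked, result.survival, n_components=n_comp, alpha=config.alpha,
        k_candidates=config.k_candidates, seed=config.seed + _SEED_OFFSETS["pca"])
    _, snf_eval = run_snf_baseline(
        list(result.scaled_omics.values()), result.survival, config=config.snf,
        seed=config.seed + _SEED_OFFSETS["snf"])
    rows = []
    for method, ev in (("autoencoder", result.evaluation), ("pca", pca_eval),
                       ("snf", snf_eval)):
        rows.append({"method": method, "logrank_p": ev.logrank_p,
                     "c_index": ev.c_index, "brier_score": ev.brier_score})
    return pd.DataFrame(rows).set_index("method")
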