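# omiprog

Unsupervised multiomics integration for cancer prognosis: an autoencoder
compresses stacked mRNA expression, miRNA expression and promoter DNA
methylation into a low-dimensional bottleneck; bottleneck features associated
with overall survival (univariate Cox PH, keep p ≤ 0.10) are clustered with
k-means (cluster number chosen by silhouette index, ties broken by
Calinski–Harabasz) to split patients into **low-** and **high-risk**
subgroups. The package was built around the stomach-adenocarcinoma use case —
a TCGA-style discovery cohort with expression-only microarray validation
cohorts — but every stage is a reusable, tested component.

It provides:

- a **synthetic cohort generator** (`omiprog.simulate`) producing
  negative-binomial counts, logit-normal CpG methylation on an annotated
  synthetic genome, group-dependent exponential survival with tunable
  censoring, clinical covariates, and platform-shifted expression-only
  external cohorts — with known ground-truth subgroups, so the whole pipeline
  is testable without any download;
- **preprocessing** (`omiprog.preprocess`): zero/missing-fraction filters,
  strand-aware promoter aggregation of CpG β-values (1500 bp upstream of the
  TSS), nearest-feature KNN imputation, and three normalizations — per-sample
  unit (l2) scaling `v / ‖v‖₂`, per-feature median scaling
  `(x − median(x)) / mad(x)`, and "robust" scaling by the mean/sd of the
  interquartile slice — as scikit-learn transformers;
- a NumPy **autoencoder** (`omiprog.Autoencoder`): dense → tanh → batch-norm
  hidden blocks (default 2000/500/2000), linear output, MSE loss, Adam, fixed
  32 epochs, fully seed-deterministic; `transform` returns the bottleneck;
- **subgroup discovery** (`omiprog.subgroup`) and **survival evaluation**
  (`omiprog.survival`): Kaplan–Meier, log-rank, Cox PH with Wald and score
  tests (via lifelines, Efron ties), Harrell's C-index with both tie
  conventions, and the IPCW Brier score;
- **validation** (`omiprog.transfer`): the CV-like scheme (5 folds, all 10
  choices of 2 test folds), per-fold re-training of the unsupervised stage,
  ANOVA selection of the top 50 mRNA / 30 miRNA / 50 methylation features and
  an RBF-SVM label transfer; plus external-cohort transfer on common genes;
- **baselines** (`omiprog.baselines`): PCA + the identical downstream path,
  and similarity network fusion (correlation-distance affinities, scaled
  exponential kernel, cross-diffusion, spectral clustering with eigengap K);
- **differential analysis** (`omiprog.diffexpr`): median-of-ratios size
  factors + Welch t on log2 counts (|log2FC| > 1, BH FDR < 0.05) and an
  empirical-Bayes moderated t on methylation M values
  (M = log2(β/(1−β)), |ΔM| > 1, FDR < 0.05).

## Worked example

```python
import numpy as np
from omiprog import SimulationConfig, simulate_cohort, PipelineConfig, run_discovery

cfg = SimulationConfig(n_samples=200, n_mrna=2000, n_mirna=300, n_cpg=6000,
                       n_genes_annotated=2000, signal_fraction=0.05,
                       effect_size=1.0, true_log_hr=np.log(3), seed=111)
cohort = simulate_cohort(cfg)

pc = PipelineConfig(seed=11)
pc.ae["hidden_sizes"] = (512, 64, 512)   # reduced net for a 4300-feature input
res = run_discovery(cohort, pc)
ev = res.evaluation
print(f"K={res.assignment.report.chosen_k}  log-rank p={ev.logrank_p:.2e}  "
      f"C-index={ev.c_index:.3f}  Brier={ev.brier_score:.3f}")
```

Output:

```
K=2  log-rank p=1.35e-06  C-index=0.727  Brier=0.167
```

The pipeline chose two clusters, and the recovered low/high-risk split
separates survival strongly (log-rank p ≈ 1e−06): the high-risk group's
hazard dominates (the simulated hazard ratio is 3), between-group pairs are
ordered correctly about 73% of the time here (C-index; seed-dependent,
typically 0.65–0.85 under these conditions), and the squared error of the
group-wise Kaplan–Meier prediction at the median follow-up is 0.167 (Brier;
0.25 would be uninformative). `run_compare(res, pc)` appends the same three
metrics for the PCA and SNF alternatives; `omiprog simulate / discover /
compare / de` expose the same steps on the command line.

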