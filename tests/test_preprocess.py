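"""Filtering, promoter aggregation, imputation and scaling contracts."""

import numpy as np
import pandas as pd
import pytest

from omiprog.containers import CpGAnnotation, GeneAnnotation, OmicsMatrix, OmiprogError
from omiprog.preprocess import (
    MedianScaler,
    TrimmedScaler,
    aggregate_promoter_methylation,
    collapse_probes_to_genes,
    filter_missing,
    filter_zero_features,
    filter_zero_samples,
    knn_impute,
    median_scale,
    promoter_window,
    robust_scale,
    stack_omics,
    unit_scale_samples,
)


def _counts(arr, samples=None, features=None, kind="mrna_counts"):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    features = features or [f"g{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(pd.DataFrame(arr, index=samples, columns=features), kind)


# -- zero / missing filters -------------------------------------------------

def test_filter_zero_features_hand_counts():
    # per-feature zero counts 0,1,1,2,3,4 over 4 samples -> fracs 0,.25,.25,.5,.75,1
    cols = []
    for nzero in (0, 1, 1, 2, 3, 4):
        col = np.ones(4)
        col[:nzero] = 0
        cols.append(col)
    m = _counts(np.column_stack(cols))
    out = filter_zero_features(m, 0.2)
    assert list(out.feature_ids) == ["g0"]
    assert filter_zero_features(m, 1.0).shape == m.shape
    # idempotence
    assert filter_zero_features(out, 0.2).shape == out.shape


def test_filter_zero_features_all_removed_errors():
    m = _counts(np.zeros((3, 2)))
    with pytest.raises(OmiprogError, match="0.2"):
        filter_zero_features(m, 0.2)


def test_filter_zero_samples_hand_counts():
    rows = []
    for nzero in (0, 1, 2, 3, 0, 5):
        row = np.ones(10)
        row[:nzero] = 0
        rows.append(row)
    m = _counts(np.vstack(rows))
    out = filter_zero_samples(m, 0.2)
    assert list(out.sample_ids) == ["s0", "s1", "s2", "s4"]
    clean = _counts(np.ones((3, 3)))
    assert filter_zero_samples(clean, 0.2).shape == clean.shape


def test_filter_missing_features_then_samples():
    vals = np.full((5, 5), 0.5)
    for j, nmiss in enumerate((0, 1, 1, 2, 3)):
        vals[:nmiss, j] = np.nan
    m = OmicsMatrix(pd.DataFrame(vals, index=[f"s{i}" for i in range(5)],
                                 columns=[f"g{j}" for j in range(5)]),
                    "methylation_promoter")
    out = filter_missing(m, 0.2)
    assert list(out.feature_ids) == ["g0", "g1", "g2"]
    only_features = filter_missing(m, 0.2, axis="features")
    assert list(only_features.sample_ids) == list(m.sample_ids)
    with pytest.raises(OmiprogError, match="axis"):
        filter_missing(m, 0.2, axis="rows")
    # no-missing input unchanged
    clean = OmicsMatrix(pd.DataFrame(np.full((4, 4), 0.5)), "methylation_promoter")
    assert filter_missing(clean, 0.2).shape == (4, 4)


# -- promoter aggregation ---------------------------------------------------

def _meth(vals, probes, samples=None):
    samples = samples or [f"s{i}" for i in range(np.asarray(vals).shape[0])]
    return OmicsMatrix(pd.DataFrame(vals, index=samples, columns=probes),
                       "methylation_beta")


def test_promoter_mean_plus_strand():
    cpg = _meth([[0.2, 0.4]], ["cgA", "cgB"])
    cpg_ann = CpGAnnotation(pd.DataFrame({
        "probe_id": ["cgA", "cgB"], "chromosome": ["chr1"] * 2,
        "position": [8700, 9900]}))
    gene_ann = GeneAnnotation(pd.DataFrame({
        "gene_id": ["G1"], "chromosome": ["chr1"], "tss": [10000], "strand": ["+"]}))
    out = aggregate_promoter_methylation(cpg, cpg_ann, gene_ann)
    assert out.values.loc["s0", "G1"] == pytest.approx(0.3)


def test_promoter_strand_reflection():
    cpg = _meth([[0.8, 0.1]], ["cg_down", "cg_up"])
    cpg_ann = CpGAnnotation(pd.DataFrame({
        "probe_id": ["cg_down", "cg_up"], "chromosome": ["chr1"] * 2,
        "position": [11400, 8700]}))
    gene_ann = GeneAnnotation(pd.DataFrame({
        "gene_id": ["G1"], "chromosome": ["chr1"], "tss": [10000], "strand": ["-"]}))
    out = aggregate_promoter_methylation(cpg, cpg_ann, gene_ann)
    # on the minus strand upstream means larger coordinates
    assert out.values.loc["s0", "G1"] == pytest.approx(0.8)


def test_promoter_aggregation_matches_bruteforce_scan(small_cohort):
    _, cohort = small_cohort
    out = aggregate_promoter_methylation(cohort.methylation_cpg,
                                         cohort.cpg_annotation,
                                         cohort.gene_annotation)
    # independent oracle: scan every CpG position for every emitted gene
    cpg_pos = cohort.cpg_annotation.table.set_index("probe_id")
    genes = cohort.gene_annotation.table.set_index("gene_id")
    rng = np.random.default_rng(0)
    for gene in rng.choice(out.feature_ids, size=25, replace=False):
        lo, hi = promoter_window(int(genes.loc[gene, "tss"]), genes.loc[gene, "strand"])
        in_window = [p for p in cpg_pos.index
                     if genes.loc[gene, "chromosome"] == cpg_pos.loc[p, "chromosome"]
                     and lo <= cpg_pos.loc[p, "position"] <= hi]
        expected = cohort.methylation_cpg.values[in_window].mean(axis=1, skipna=True)
        pd.testing.assert_series_equal(out.values[gene], expected, check_names=False)


# -- imputation -------------------------------------------------------------

def test_knn_impute_no_missing_is_identity():
    m = OmicsMatrix(pd.DataFrame(np.random.default_rng(0).random((6, 5))),
                    "methylation_promoter")
    pd.testing.assert_frame_equal(knn_impute(m).values, m.values)


def test_knn_impute_duplicate_feature_exact():
    vals = np.tile(np.linspace(0.1, 0.9, 9)[:, None], (1, 3))
    vals[:, 2] = np.linspace(0.9, 0.1, 9)  # a decoy far from the duplicate pair
    vals[4, 0] = np.nan
    m = OmicsMatrix(pd.DataFrame(vals, columns=["a", "dup", "decoy"]),
                    "methylation_promoter")
    out = knn_impute(m, k=1)
    assert out.values.loc[4, "a"] == pytest.approx(vals[4, 1])


def test_knn_impute_beats_column_mean():
    rng = np.random.default_rng(1)
    base = rng.random((40, 30))
    # correlated features so neighbours are informative
    full = np.clip(np.repeat(base[:, :10], 3, axis=1) + rng.normal(0, 0.03, (40, 30)),
                   0, 1)
    mask = rng.random(full.shape) < 0.05
    masked = full.copy()
    masked[mask] = np.nan
    m = OmicsMatrix(pd.DataFrame(masked), "methylation_promoter")
    imputed = knn_impute(m, k=5).values.to_numpy()
    col_mean = pd.DataFrame(masked).fillna(pd.DataFrame(masked).mean()).to_numpy()
    rmse_knn = np.sqrt(np.mean((imputed[mask] - full[mask]) ** 2))
    rmse_mean = np.sqrt(np.mean((col_mean[mask] - full[mask]) ** 2))
    assert rmse_knn < rmse_mean


# -- scaling ----------------------------------------------------------------

def test_unit_scale_rows():
    m = _counts([[3.0, 4.0], [1.0, 0.0]])
    out = unit_scale_samples(m)
    assert out.values.iloc[0].tolist() == pytest.approx([0.6, 0.8])
    norms = np.linalg.norm(out.to_numpy(), axis=1)
    assert norms == pytest.approx([1.0, 1.0], abs=1e-12)


def test_unit_scale_squared_flag_and_zero_rows():
    m = _counts([[2.0, 0.0], [0.0, 0.0]])
    with pytest.warns(UserWarning, match="zero rows"):
        out = unit_scale_samples(m, squared=True)
    assert out.values.iloc[0, 0] == pytest.approx(0.5)  # 2 / 2^2
    assert (out.values.iloc[1] == 0).all()


def test_median_scale_examples():
    m = _counts(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
    out, params = median_scale(m)
    assert out.values.iloc[:, 0].tolist() == pytest.approx([-1.0, 0.0, 1.0])
    assert (out.values.iloc[:, 1] == 0).all()
    assert "g1" in params.degenerate


def test_median_scale_output_statistics():
    rng = np.random.default_rng(3)
    m = _counts(rng.normal(10, 4, size=(51, 4)))
    out, _ = median_scale(m)
    arr = out.to_numpy()
    med = np.median(arr, axis=0)
    mad = np.median(np.abs(arr - med), axis=0)
    assert med == pytest.approx(np.zeros(4), abs=1e-12)
    assert mad == pytest.approx(np.ones(4), abs=1e-12)


def test_robust_scale_outlier_resistance():
    m = _counts(np.array([[1.0], [2.0], [3.0], [4.0], [100.0]]))
    out, _ = robust_scale(m)
    assert out.values.iloc[4, 0] > 10  # outlier maps far out, positive
    sym = _counts(np.array([[-1.0], [0.0], [1.0]]))
    out2, _ = robust_scale(sym)
    assert out2.values.iloc[1, 0] == pytest.approx(0.0)


def test_robust_scale_matches_bruteforce():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 3, size=40)
    m = _counts(x[:, None])
    out, _ = robust_scale(m)
    q1, q3 = np.percentile(x, [25, 75])
    trimmed = x[(x >= q1) & (x <= q3)]
    expected = (x - trimmed.mean()) / trimmed.std(ddof=1)
    assert out.values.iloc[:, 0].to_numpy() == pytest.approx(expected)


def test_scalers_location_scale_equivariance():
    rng = np.random.default_rng(11)
    x = rng.normal(5, 2, size=(30, 3))
    for scaler in (MedianScaler, TrimmedScaler):
        a = scaler().fit_transform(pd.DataFrame(x))
        b = scaler().fit_transform(pd.DataFrame(3.5 * x))
        pd.testing.assert_frame_equal(a, b, rtol=1e-10)


# -- probe collapsing and stacking ------------------------------------------

def test_collapse_probes_mean_and_identity():
    m = _counts([[2.0, 4.0, 7.0]], features=["p1", "p2", "p3"],
                kind="expression_intensity")
    out = collapse_probes_to_genes(m, {"p1": "G", "p2": "G", "p3": "H"})
    assert out.values.loc["s0", "G"] == pytest.approx(3.0)
    assert out.values.loc["s0", "H"] == pytest.approx(7.0)
    one2one = collapse_probes_to_genes(m, {"p1": "A", "p2": "B", "p3": "C"})
    assert one2one.values.to_numpy().tolist() == m.values.to_numpy().tolist()
    with pytest.raises(OmiprogError):
        collapse_probes_to_genes(m, {})


def test_collapse_probes_matches_groupby_oracle():
    rng = np.random.default_rng(5)
    m = _counts(rng.random((8, 20)), features=[f"p{j}" for j in range(20)],
                kind="expression_intensity")
    mapping = {f"p{j}": f"G{j % 6}" for j in range(20)}
    out = collapse_probes_to_genes(m, mapping)
    for g in sorted(set(mapping.values())):
        probes = [p for p, gg in mapping.items() if gg == g]
        expected = m.values[probes].mean(axis=1)
        pd.testing.assert_series_equal(out.values[g], expected, check_names=False)


def test_stack_concats_features_and_aligns_samples():
    a = _counts(np.ones((3, 3)), samples=["s0", "s1", "s2"])
    b = _counts(np.arange(6, dtype=float).reshape(3, 2),
                samples=["s2", "s0", "s1"], kind="mirna_counts")
    st = stack_omics([a, b])
    assert st.shape == (3, 5)
    assert list(st.blocks) == ["mrna", "mirna"]
    # alignment: stacked row for s2 carries b's s2 row (0, 1)
    assert st.values.loc["s2", st.blocks["mirna"]].tolist() == [0.0, 1.0]
    assert st.values.loc["s0", st.blocks["mirna"]].tolist() == [2.0, 3.0]


def test_stack_disjoint_samples_errors():
    a = _counts(np.ones((2, 2)), samples=["x0", "x1"])
    b = _counts(np.ones((2, 2)), samples=["y0", "y1"], kind="mirna_counts")
    with pytest.raises(OmiprogError):
        stack_omics([a, b])
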