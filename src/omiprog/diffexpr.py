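"""Differential analysis between risk subgroups.

Counts (mRNA/miRNA) are normalized with median-of-ratios size factors and
tested per gene with a Welch t-test on the log2(x+1) scale — a deliberately
simple, documented approximation of a negative-binomial GLM analysis; the
significance thresholds (|log2FC| > 1 and BH FDR < 0.05) are applied
exactly.  Methylation betas are mapped to M values, M = log2(beta/(1-beta)),
and tested with an empirical-Bayes moderated t-test (closed-form variance
shrinkage with the prior estimated by moment matching) under the
|M difference| > 1, FDR < 0.05 rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix, OmiprogError

__all__ = [
    "size_factors",
    "de_counts",
    "beta_to_m",
    "m_to_beta",
    "moderated_t",
    "bh_fdr",
    "estimate_variance_prior",
]


def _counts_frame(counts) -> pd.DataFrame:
    df = counts.values if isinstance(counts, OmicsMatrix) else pd.DataFrame(counts)
    arr = df.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise OmiprogError("counts must be nonnegative")
    return df


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (samples in rows).

    Each sample's factor is the median, over genes positive in every
    sample, of that sample's count divided by the gene's geometric mean.
    """
    df = _counts_frame(counts)
    arr = df.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=0)
    if not all_positive.any():
        raise OmiprogError("no gene is positive in all samples; "
                           "size factors need a pseudo-reference")
    ref = arr[:, all_positive]
    geo_mean = np.exp(np.log(ref).mean(axis=0))
    factors = np.median(ref / geo_mean, axis=1)
    return pd.Series(factors, index=df.index, name="size_factor")


def _two_groups(labels) -> tuple[np.ndarray, list]:
    y = np.asarray(labels)
    groups = sorted(pd.unique(y).tolist(), key=str)
    if len(groups) != 2:
        raise OmiprogError(f"differential analysis needs exactly 2 groups, got {len(groups)}")
    return y, groups


def de_counts(counts, labels, lfc_threshold: float = 1.0,
              fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t-test on size-factor-normalized log2(x+1) counts.

    ``effect`` is log2FC = mean(group2) - mean(group1) on that scale, with
    groups in sorted label order.  ``significant`` applies
    |log2FC| > ``lfc_threshold`` and BH FDR < ``fdr_threshold``.
    """
    df = _counts_frame(counts)
    y, groups = _two_groups(labels)
    for g in groups:
        if (y == g).sum() < 2:
            raise OmiprogError(f"group {g!r} has fewer than 2 samples")
    sf = size_factors(df)
    norm = df.to_numpy(dtype=float) / sf.to_numpy()[:, None]
    logged = np.log2(norm + 1.0)
    a = logged[y == groups[0]]
    b = logged[y == groups[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(b, a, axis=0, equal_var=False)
    effect = b.mean(axis=0) - a.mean(axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    stat = np.where(np.isfinite(stat), stat, 0.0)
    fdr = bh_fdr(p)
    out = pd.DataFrame({
        "feature": df.columns,
        "effect": effect,
        "stat": stat,
        "p": p,
        "fdr": fdr,
        "significant": (np.abs(effect) > lfc_threshold) & (fdr < fdr_threshold),
    }).set_index("feature")
    return out.sort_values("p")


def beta_to_m(beta, eps: float = 1e-6):
    """Methylation beta -> M value: log2(beta / (1 - beta)), beta clipped to
    [eps, 1 - eps]."""
    if isinstance(beta, OmicsMatrix):
        beta = beta.values
    arr = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + 2.0 ** (-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    return beta


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior for residual variances.

    Assuming s^2 ~ s0^2 * F(df_resid, d0), the log variances satisfy
    E[log s^2] = log s0^2 + psi(d/2) - psi(d0/2) + log(d0/d) and
    Var[log s^2] = psi'(d/2) + psi'(d0/2).  Returns (d0, s0_squared);
    d0 = inf when the observed spread is no larger than expected by chance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    d = float(df_resid)
    e_var = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2))
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(z) - special.digamma(d / 2) + np.log(d / 2)))
        return d0, s0_2
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(np.mean(z) - special.digamma(d / 2)
                        + special.digamma(d0 / 2) - np.log(d0 / d)))
    return d0, s0_2


def moderated_t(m_values, labels, m_threshold: float = 1.0,
                fdr_threshold: float = 0.05,
                prior_df: float | None = None) -> pd.DataFrame:
    """Two-group moderated t-test with empirical-Bayes variance shrinkage.

    Per feature, the pooled residual variance s^2 (df = n1 + n2 - 2) is
    shrunk towards the prior: s~^2 = (d0 s0^2 + d s^2) / (d0 + d), and the
    moderated t uses d0 + d degrees of freedom.  ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary t-test; inf gives full shrinkage).
    """
    df = m_values.values if isinstance(m_values, OmicsMatrix) else pd.DataFrame(m_values)
    y, groups = _two_groups(labels)
    a = df.to_numpy(dtype=float)[y == groups[0]]
    b = df.to_numpy(dtype=float)[y == groups[1]]
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise OmiprogError("each group needs at least 2 samples")
    d = n1 + n2 - 2
    if d <= 0:
        raise OmiprogError("zero residual degrees of freedom")
    diff = b.mean(axis=0) - a.mean(axis=0)
    s2 = (a.var(axis=0, ddof=1) * (n1 - 1) + b.var(axis=0, ddof=1) * (n2 - 1)) / d
    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2, d) if d0 > 0 else (0.0, 0.0)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = float(d0 + d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    fdr = bh_fdr(p)
    out = pd.DataFrame({
        "feature": df.columns,
        "effect": diff,
        "stat": t,
        "p": p,
        "fdr": fdr,
        "significant": (np.abs(diff) > m_threshold) & (fdr < fdr_threshold),
    }).set_index("feature")
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    return out.sort_values("p")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise OmiprogError("p-values must be finite and in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
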