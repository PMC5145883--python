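"""Minimal negative-binomial differential-expression engine.

A deliberately small, analytically checkable stand-in for the classic
count-based DE workflow: median-of-ratios size factors, a pooled
method-of-moments dispersion per gene, a Wald test on the log2 ratio of
group mean normalized counts for each treatment versus control, and
Benjamini-Hochberg adjustment within each contrast.  No dispersion
shrinkage across genes, no independent filtering, and no |log2FC|
threshold: a DEG is a gene with adjusted p < alpha, nothing more.

The negative-binomial parameterization throughout is
``var = mu + phi * mu**2`` with dispersion phi >= 0 (phi = 0 is Poisson).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import CONTROL, CountMatrix, Design
from .errors import NormalizationError, ValidationError

DE_COLUMNS = ("log2fc", "se", "pvalue", "qvalue", "significant", "direction")


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each gene expressed in every sample, the ratio of its count to
    its geometric mean across samples is formed; a sample's factor is
    the median of those ratios.  Requires at least one gene with nonzero
    counts in all samples.
    """
    mat = counts.counts.to_numpy(dtype=float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; filter empty samples "
            "or provide size factors explicitly"
        )
    logs = np.log(mat[expressed])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalized_counts(counts: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    return counts.counts / size_factors.reindex(counts.sample_ids)


def estimate_dispersion(
    counts: CountMatrix,
    size_factors: pd.Series,
    design: Design,
    floor: float = 1e-8,
) -> pd.Series:
    """Pooled within-condition method-of-moments dispersion per gene.

    On normalized counts, each condition contributes its sample mean m_c
    and variance v_c; the estimate pools the moment identity
    ``v = m + phi * m**2`` across conditions weighted by degrees of
    freedom::

        phi = max(floor, sum_c (n_c - 1)(v_c - m_c) / sum_c (n_c - 1) m_c**2)

    Every condition used must have >= 2 replicates.
    """
    norm = normalized_counts(counts, size_factors)
    num = np.zeros(len(norm))
    den = np.zeros(len(norm))
    for cond in design.conditions:
        samples = design.samples(cond)
        if len(samples) < 2:
            raise ValidationError(f"condition {cond!r} has fewer than 2 replicates")
        block = norm[samples].to_numpy()
        n_c = block.shape[1]
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        num += (n_c - 1) * (v - m)
        den += (n_c - 1) * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    phi = np.maximum(phi, floor)
    return pd.Series(phi, index=counts.gene_ids, name="dispersion")


def test_contrast(
    counts: CountMatrix,
    design: Design,
    treatment: str,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of one treatment against the CK control.

    The effect is ``L = log2((m_t + c) / (m_0 + c))`` where m_t, m_0 are
    group means of normalized counts and c is a pseudo-count.  The
    standard error comes from the delta method under NB variance on the
    normalized scale: the variance of a normalized observation in sample
    j is approximated by ``m / s_j + phi * m**2``, so

        Var(m_g) = n_g^{-2} * sum_j (m_g / s_j + phi m_g^2)
        SE(L)^2  = [Var(m_t)/(m_t + c)^2 + Var(m_0)/(m_0 + c)^2] / ln(2)^2

    Two-sided normal p-values are BH-adjusted across all genes within
    the contrast; a gene is significant when q < alpha, with direction
    up/down by the sign of L (none when not significant).  Genes with
    zero counts in both groups get L = 0 and p = 1.
    """
    from scipy import stats

    if treatment == CONTROL:
        raise ValidationError("treatment contrast must differ from the CK control")
    if treatment not in design.conditions:
        raise ValidationError(f"condition {treatment!r} absent from design")
    for cond in (CONTROL, treatment):
        if len(design.samples(cond)) < 2:
            raise ValidationError(f"condition {cond!r} has fewer than 2 replicates")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, size_factors, design)

    norm = normalized_counts(counts, size_factors)
    phi = dispersions.reindex(counts.gene_ids).to_numpy()

    def group_stats(cond):
        samples = design.samples(cond)
        block = norm[samples].to_numpy()
        m = block.mean(axis=1)
        s = size_factors[samples].to_numpy()
        var_mean = (m[:, None] / s[None, :] + phi[:, None] * m[:, None] ** 2).sum(axis=1)
        var_mean /= len(samples) ** 2
        return m, var_mean

    m_t, v_t = group_stats(treatment)
    m_0, v_0 = group_stats(CONTROL)

    c = pseudocount
    log2fc = np.log2((m_t + c) / (m_0 + c))
    ln2 = np.log(2.0)
    se = np.sqrt(v_t / (m_t + c) ** 2 + v_0 / (m_0 + c) ** 2) / ln2

    both_zero = (m_t == 0) & (m_0 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(both_zero | (se == 0), 1.0, pvalue)
    log2fc = np.where(both_zero, 0.0, log2fc)
    pvalue = np.clip(pvalue, 0.0, 1.0)

    qvalue = adjust_bh(pvalue)
    significant = qvalue < alpha
    direction = np.where(
        significant, np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")), "none"
    )
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "qvalue": qvalue,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    return out


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), clipped to 1.  Ties share the
    adjusted value (joint adjustment under a stable sort).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("adjust_bh expects a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
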