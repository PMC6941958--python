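"""Differential phenotype analysis: DEG and DMR calling.

Expression counts are upper-quartile normalized between samples, then
differential expression is tested per gene with a two-sided Welch t on
log2(normalized + 1); methylation beta values are tested with a
two-sided rank-sum test.  Both analyses apply Benjamini-Hochberg
correction over exactly the tested features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConsistencyError,
    DegenerateSampleError,
    InsufficientReplicationError,
    ParameterError,
)
from .formats_io import ExpressionMatrix

log = logging.getLogger(__name__)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_upper_quartile(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Upper-quartile between-sample normalization of a count matrix.

    Each sample is rescaled so that the 75th percentile of its positive
    counts equals the geometric mean of all samples' upper quartiles.
    Within-sample (e.g. GC-content) correction is not applied.
    """
    if not expr.counts:
        raise ParameterError("upper-quartile normalization expects a count matrix")
    arr = expr.values.to_numpy(dtype=float)
    uq = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        positive = arr[:, j][arr[:, j] > 0]
        if positive.size == 0:
            raise DegenerateSampleError(
                f"sample {expr.sample_ids[j]!r} has no positive counts"
            )
        uq[j] = np.percentile(positive, 75)
    target = np.exp(np.mean(np.log(uq)))
    scaled = arr * (target / uq)[None, :]
    out = pd.DataFrame(scaled, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, dict(expr.condition_map), counts=True)


def _group_columns(expr: ExpressionMatrix, label: str, min_n: int) -> list[str]:
    samples = expr.samples_in(label)
    if not samples:
        raise ConsistencyError(f"unknown condition label {label!r}")
    if len(samples) < min_n:
        raise InsufficientReplicationError(
            f"condition {label!r} has {len(samples)} samples; need >= {min_n}"
        )
    return samples


def call_degs(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    logfc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
    normalize: bool = True,
) -> pd.DataFrame:
    """Call differentially expressed genes between two conditions.

    Returns a DataFrame indexed by gene with columns ``logFC`` (mean
    log2(normalized + 1) difference, B minus A), ``p_raw`` (two-sided
    Welch t), ``fdr`` (BH over all tested genes) and ``is_deg``
    (|logFC| > ``logfc_threshold`` and fdr < ``fdr_threshold``).  Genes
    with zero counts in every sample are dropped before testing.
    """
    a_cols = _group_columns(expr, group_a, 2)
    b_cols = _group_columns(expr, group_b, 2)
    if normalize and expr.counts:
        expr = normalize_upper_quartile(expr)
    values = expr.values
    all_zero = (values[a_cols + b_cols].to_numpy() == 0).all(axis=1)
    if all_zero.any():
        log.info("dropping %d genes with zero counts in all samples", int(all_zero.sum()))
        values = values.loc[~all_zero]
    logged = np.log2(values.to_numpy(dtype=float) + 1.0)
    cols = list(values.columns)
    ai = [cols.index(s) for s in a_cols]
    bi = [cols.index(s) for s in b_cols]
    a, b = logged[:, ai], logged[:, bi]
    logfc = b.mean(axis=1) - a.mean(axis=1)
    t = scipy.stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)  # zero-variance ties
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "p_raw": p,
            "fdr": fdr,
            "is_deg": (np.abs(logfc) > logfc_threshold) & (fdr < fdr_threshold),
        },
        index=values.index,
    )
    out.index.name = "gene"
    return out


def call_dmrs(
    beta: ExpressionMatrix,
    group_a: str,
    group_b: str,
    delta_threshold: float = 0.2,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Call differentially methylated regions from beta values.

    Per region, a two-sided rank-sum test on non-missing betas plus the
    mean beta difference (B minus A).  A region is a DMR when
    |delta_beta| >= ``delta_threshold`` and BH FDR < ``fdr_threshold``.
    Regions with fewer than 2 usable values in either group are excluded
    (logged), not fatal.
    """
    a_cols = _group_columns(beta, group_a, 2)
    b_cols = _group_columns(beta, group_b, 2)
    rows = []
    index = []
    for region, row in beta.values.iterrows():
        a = row[a_cols].to_numpy(dtype=float)
        b = row[b_cols].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            log.info("region %r excluded: fewer than 2 usable betas in a group", region)
            continue
        delta = float(b.mean() - a.mean())
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(scipy.stats.mannwhitneyu(b, a, alternative="two-sided").pvalue)
        rows.append((delta, p))
        index.append(region)
    if not rows:
        return pd.DataFrame(
            columns=["delta_beta", "p_raw", "fdr", "is_dmr", "direction"]
        )
    delta_beta = np.array([r[0] for r in rows])
    p_raw = np.array([r[1] for r in rows])
    fdr = bh_adjust(p_raw)
    out = pd.DataFrame(
        {
            "delta_beta": delta_beta,
            "p_raw": p_raw,
            "fdr": fdr,
            "is_dmr": (np.abs(delta_beta) >= delta_threshold) & (fdr < fdr_threshold),
            "direction": np.where(delta_beta > 0, "hyper", "hypo"),
        },
        index=pd.Index(index, name="region"),
    )
    return out
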