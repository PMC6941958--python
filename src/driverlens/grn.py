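"""Gene regulatory network inference by kNN mutual information.

Each differentially expressed gene (DEG) is treated as a candidate
regulator.  Its MI with every other gene is estimated on tumor-condition
samples with the Kraskov k-nearest-neighbor estimator (k = 3 by
default), and edges are kept when they beat a per-regulator permutation
null (nboot permutations of the regulator vector, each scored against
up to n_genes_perm randomly drawn genes) at raw empirical p <= alpha.
The retained targets of a regulator form its regulon.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.special

from ._mi import ksg_mi_many, ksg_mi_pair, ksg_null_block
from .errors import ParameterError
from .formats_io import ExpressionMatrix, RegulatoryNetwork

log = logging.getLogger(__name__)

_JITTER_REL = 1e-10  # relative tie-breaking jitter amplitude


def _psi_table(n: int) -> np.ndarray:
    """psi[m] = digamma(m) for m in 1..n+1 (index 0 unused)."""
    tbl = np.zeros(n + 2)
    tbl[1:] = scipy.special.digamma(np.arange(1, n + 2).astype(float))
    return tbl


def _jitter(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Break exact ties (integer counts) without moving real distances."""
    span = float(np.ptp(v))
    if span == 0.0:
        return v.astype(float)
    return v + rng.uniform(-_JITTER_REL * span, _JITTER_REL * span, size=v.shape)


def mi_knn(x, y, k: int = 3, jitter_seed: int = 0) -> float:
    """Kraskov kNN mutual information (nats) between two sample vectors.

    Symmetric in its arguments; small negative values are possible and
    are not clipped.  A constant vector yields 0.0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < k + 2:
        raise ParameterError(f"need n >= k + 2 samples (got n={n}, k={k})")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector; MI undefined, returning 0.0")
        return 0.0
    rng = np.random.default_rng(jitter_seed)
    xj = _jitter(x, rng)
    yj = _jitter(y, rng)
    return float(ksg_mi_pair(xj, yj, int(k), _psi_table(n)))


def permutation_null(
    regulator_values,
    candidate_pool: ExpressionMatrix | np.ndarray,
    nboot: int = 100,
    n_genes_perm: int = 1000,
    k: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Null MI sample for one regulator.

    For each of ``nboot`` iterations the regulator vector is permuted and
    its MI computed against min(``n_genes_perm``, pool size) genes drawn
    without replacement from the pool; all values are pooled into one
    flat null sample.
    """
    if nboot < 1:
        raise ParameterError("nboot must be >= 1")
    x = np.asarray(regulator_values, dtype=float)
    pool = (
        candidate_pool.values.to_numpy(dtype=float)
        if isinstance(candidate_pool, ExpressionMatrix)
        else np.asarray(candidate_pool, dtype=float)
    )
    if pool.ndim != 2 or pool.shape[0] < 1:
        raise ParameterError("candidate pool must be a nonempty gene x sample matrix")
    if pool.shape[1] != x.size:
        raise ParameterError("pool sample count must match the regulator vector")
    rng = np.random.default_rng(seed)
    n_pool = pool.shape[0]
    m = min(int(n_genes_perm), n_pool)
    pool_j = np.empty_like(pool)
    for g in range(n_pool):
        pool_j[g] = _jitter(pool[g], rng)
    x_perms = np.empty((nboot, x.size))
    draws = np.empty((nboot, m), dtype=np.int64)
    for b in range(nboot):
        x_perms[b] = _jitter(rng.permutation(x), rng)
        draws[b] = rng.choice(n_pool, size=m, replace=False)
    return ksg_null_block(x_perms, pool_j, draws, int(k), _psi_table(x.size))


def edge_pvalue(mi_observed: float, null: np.ndarray) -> float:
    """Empirical permutation p with the add-one rule (never exactly 0)."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ParameterError("null sample must be nonempty")
    return float((1 + np.count_nonzero(null >= mi_observed)) / (1 + null.size))


def build_network(
    expr_tumor: ExpressionMatrix,
    degs: pd.DataFrame,
    alpha: float = 0.05,
    k: int = 3,
    nboot: int = 100,
    n_genes_perm: int = 1000,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Infer each DEG's regulon from tumor-condition expression.

    MI is computed between every DEG and every other gene in the matrix;
    edges whose per-regulator permutation p is <= ``alpha`` are kept.
    Per-regulator randomness derives from ``seed`` by matrix row order,
    so results do not depend on gene naming.
    """
    params = dict(alpha=alpha, k=k, nboot=nboot, n_genes_perm=n_genes_perm, seed=seed)
    genes = expr_tumor.gene_ids
    deg_genes = [g for g in genes if g in degs.index and bool(degs.loc[g, "is_deg"])]
    columns = ["regulator", "target", "mi", "p_perm"]
    if not deg_genes:
        warnings.warn("no DEGs: returning an empty network")
        return RegulatoryNetwork(pd.DataFrame(columns=columns), params)
    arr = np.log2(expr_tumor.values.to_numpy(dtype=float) + 1.0) if expr_tumor.counts \
        else expr_tumor.values.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < k + 2:
        raise ParameterError(f"need >= k + 2 samples (got {n})")
    psi = _psi_table(n)
    gene_pos = {g: i for i, g in enumerate(genes)}
    children = np.random.SeedSequence(seed).spawn(len(genes))
    rows = []
    for g in deg_genes:
        i = gene_pos[g]
        rng = np.random.default_rng(children[i])
        x = _jitter(arr[i], rng)
        other_idx = np.array([j for j in range(len(genes)) if j != i], dtype=np.int64)
        ys = np.empty((other_idx.size, n))
        for t, j in enumerate(other_idx):
            ys[t] = _jitter(arr[j], rng)
        mi = ksg_mi_many(x, ys, int(k), psi)
        null = _null_from_jittered(x, ys, nboot, n_genes_perm, int(k), psi, rng)
        thresh_count = np.array(
            [1 + np.count_nonzero(null >= m_) for m_ in mi], dtype=float
        )
        p = thresh_count / (1 + null.size)
        keep = p <= alpha
        for t in np.flatnonzero(keep):
            rows.append((g, genes[int(other_idx[t])], float(mi[t]), float(p[t])))
    log.info("network: %d regulators, %d retained edges", len(deg_genes), len(rows))
    edges = pd.DataFrame(rows, columns=columns)
    return RegulatoryNetwork(edges, params)


def _null_from_jittered(x, ys, nboot, n_genes_perm, k, psi, rng):
    """Permutation null reusing already-jittered vectors."""
    m = min(int(n_genes_perm), ys.shape[0])
    x_perms = np.empty((nboot, x.size))
    draws = np.empty((nboot, m), dtype=np.int64)
    for b in range(nboot):
        x_perms[b] = rng.permutation(x)
        draws[b] = rng.choice(ys.shape[0], size=m, replace=False)
    return ksg_null_block(x_perms, ys, draws, k, psi)
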