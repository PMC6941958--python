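"""Functional enrichment and upstream-regulator scoring.

Two statistics link differential expression to curated process
knowledge:

* the **gene Z-score** ``z_ij = sum_k y_kj / sqrt(n)``, summed over the
  regulon ``S_i`` of regulator *i*, where ``y_kj`` scores the agreement
  between target *k*'s literature direction for process *j* and the
  sign of its observed log fold change, and *n* counts the targets with
  directional (Increased/Decreased) support;
* the **process Z-score**, the same construction evaluated over the
  DEGs annotated to a process, which signs the enrichment results.

Enrichment itself is a one-sided Fisher exact (hypergeometric
over-representation) test of the overlap between DEGs and the genes
annotated to each process, BH-corrected across processes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .dpa import bh_adjust
from .errors import ConsistencyError, ParameterError, VocabularyError
from .formats_io import DIRECTIONS, GeneZMatrix, ProcessKnowledge, RegulatoryNetwork


def y_score(direction: str, logfc: float) -> int:
    """Agreement score in {-1, 0, +1} between a literature direction and
    an observed log fold change.

    +1 when the literature says Increased and the gene goes up, or
    Decreased and the gene goes down; -1 for the two mismatches; 0 for
    an Affected (direction-free) annotation or a zero fold change.
    """
    if direction not in DIRECTIONS:
        raise VocabularyError(
            f"unknown direction {direction!r}; allowed: {sorted(DIRECTIONS)}"
        )
    if direction == "Affected" or logfc == 0:
        return 0
    up = logfc > 0
    if direction == "Increased":
        return 1 if up else -1
    return -1 if up else 1


def gene_z(
    targets_logfc: pd.Series | dict,
    process: str,
    knowledge: ProcessKnowledge,
) -> tuple[float, int]:
    """Gene Z-score of one regulator for one process.

    ``targets_logfc`` maps each regulon target to its log fold change.
    Returns ``(z, n_support)``; ``z`` is NaN when no target has
    directional support (n_support = 0).
    """
    targets_logfc = pd.Series(targets_logfc, dtype=float)
    if targets_logfc.empty:
        raise ParameterError("regulon must be nonempty")
    if targets_logfc.isna().any():
        missing = targets_logfc.index[targets_logfc.isna()].tolist()
        raise ConsistencyError(f"targets lacking a logFC: {missing[:5]}")
    directions = knowledge.directions_for(process)
    total = 0.0
    n_support = 0
    for gene, logfc in targets_logfc.items():
        d = directions.get(gene)
        if d is None:
            continue
        if d in ("Increased", "Decreased"):
            n_support += 1
        total += y_score(d, float(logfc))
    if n_support == 0:
        return float("nan"), 0
    return total / np.sqrt(n_support), n_support


def ura_matrix(
    network: RegulatoryNetwork,
    degs: pd.DataFrame,
    knowledge: ProcessKnowledge,
    processes: list[str] | None = None,
) -> GeneZMatrix:
    """Gene Z-score of every regulator for every process.

    Rows are the network's regulators (all must appear in the DEG
    table, which supplies target log fold changes), columns the
    requested processes (default: all in the knowledge base).
    """
    if processes is None:
        processes = knowledge.processes
    if not processes:
        raise ParameterError("process set must be nonempty")
    regulators = network.regulators
    missing = [r for r in regulators if r not in degs.index]
    if missing:
        raise ConsistencyError(f"regulators absent from the DEG table: {missing[:5]}")
    z = np.full((len(regulators), len(processes)), np.nan)
    n_support = np.zeros((len(regulators), len(processes)), dtype=int)
    for i, reg in enumerate(regulators):
        regulon = network.regulon(reg)
        targets = regulon["target"].tolist()
        absent = [t for t in targets if t not in degs.index]
        if absent:
            raise ConsistencyError(
                f"regulon targets of {reg!r} lack a logFC: {absent[:5]}"
            )
        logfcs = degs.loc[targets, "logFC"]
        for j, proc in enumerate(processes):
            zij, nij = gene_z(logfcs, proc, knowledge)
            z[i, j] = zij
            n_support[i, j] = nij
    idx = pd.Index(regulators, name="gene")
    return GeneZMatrix(
        pd.DataFrame(z, index=idx, columns=processes),
        pd.DataFrame(n_support, index=idx, columns=processes),
    )


def enrichment_pvalue(
    n_overlap: int, n_universe: int, n_annotated: int, n_deg: int
) -> float:
    """One-sided over-representation p: P(X >= n_overlap) for
    X ~ Hypergeometric(N=n_universe, K=n_annotated, n=n_deg)."""
    if not (0 <= n_overlap <= min(n_annotated, n_deg)):
        raise ParameterError("overlap outside its feasible range")
    return float(scipy.stats.hypergeom.sf(n_overlap - 1, n_universe, n_annotated, n_deg))


def fea(
    degs: pd.DataFrame,
    knowledge: ProcessKnowledge,
    universe: set[str] | None = None,
    z_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Process over-representation among DEGs with signed Z-scores.

    For each process: a one-sided hypergeometric p for the overlap of
    the DEG set with the process's annotated genes (both intersected
    with the universe), BH across processes, plus the process Z-score
    computed over annotated DEGs.  ``significant`` requires
    |process_z| >= ``z_threshold`` and fdr <= ``fdr_threshold``.
    The universe defaults to all genes in the DEG table (the genes that
    were eligible to be called).
    """
    if universe is None:
        universe = set(degs.index)
    universe = set(universe)
    if not universe:
        raise ParameterError("universe must be nonempty")
    deg_set = set(degs.index[degs["is_deg"]]) & universe
    rows = []
    for proc in knowledge.processes:
        annotated = knowledge.genes_for(proc) & universe
        overlap = annotated & deg_set
        n_ann, n_ov = len(annotated), len(overlap)
        p = enrichment_pvalue(n_ov, len(universe), n_ann, len(deg_set))
        if overlap:
            pz, ns = gene_z(degs.loc[sorted(overlap), "logFC"], proc, knowledge)
        else:
            pz, ns = float("nan"), 0
        rows.append((proc, n_ann, n_ov, p, pz, ns))
    out = pd.DataFrame(
        rows,
        columns=["process", "n_annotated", "n_overlap", "p_fisher", "process_z", "n_support"],
    ).set_index("process")
    out["fdr"] = bh_adjust(out["p_fisher"].to_numpy())
    with np.errstate(invalid="ignore"):
        out["significant"] = (np.abs(out["process_z"]) >= z_threshold) & (
            out["fdr"] <= fdr_threshold
        )
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out
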