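"""Pattern recognition analysis: role calls, dual-role genes, evidence.

A gene is called an oncogene (OCG) when its regulon concurrently
increases the growth-like process and decreases the death-like process
(z_growth > t and z_death < -t), a tumor suppressor (TSG) for the
inverse pattern, and unclassified otherwise.  Genes called OCG in one
condition and TSG in another are dual-role.  Secondary evidence
(methylation, copy number, cell-line expression, prognosis) promotes
calls to "critical" by adding flags; it never changes a role.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ParameterError
from .formats_io import (
    CRITICALITY_FLAGS,
    DriverCallSet,
    EvidenceTable,
    ExpressionMatrix,
    GeneZMatrix,
)

log = logging.getLogger(__name__)

# evidence kind -> {role: concordant value} -> flag name
_EVIDENCE_RULES = {
    "methylation": ("critical_epigenetic", {"TSG": "hyper", "OCG": "hypo"}),
    "copy_number": ("critical_copy_number", {"OCG": "amplified", "TSG": "deleted"}),
    "cellline_expression": ("cellline_concordant", {"OCG": "high", "TSG": "low"}),
    "prognosis": ("prognosis_concordant", {"OCG": "poor", "TSG": "good"}),
}


def classify_roles(
    zmat: GeneZMatrix,
    growth_process: str,
    death_process: str,
    threshold: float = 0.0,
    condition: str = "tumor_vs_normal",
) -> DriverCallSet:
    """Call TSG/OCG roles from the gene Z-score matrix for one condition.

    Genes with a missing Z for either process are unclassified.
    ``threshold`` >= 0 tightens the pattern (|z| must exceed it with the
    right signs on both processes).
    """
    if growth_process == death_process:
        raise ParameterError("growth and death processes must differ")
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    for proc in (growth_process, death_process):
        if proc not in zmat.z.columns:
            raise ParameterError(f"process {proc!r} absent from the Z matrix")
    zg = zmat.z[growth_process].to_numpy(dtype=float)
    zd = zmat.z[death_process].to_numpy(dtype=float)
    ok = np.isfinite(zg) & np.isfinite(zd)
    role = np.full(len(zg), "unclassified", dtype=object)
    role[ok & (zg > threshold) & (zd < -threshold)] = "OCG"
    role[ok & (zg < -threshold) & (zd > threshold)] = "TSG"
    calls = pd.DataFrame(
        {
            "gene": zmat.genes,
            "condition": condition,
            "role": role,
            "z_growth": zg,
            "z_death": zd,
            "dual_role": False,
        }
    )
    return DriverCallSet(calls, growth_process=growth_process, death_process=death_process)


def combine_conditions(call_sets: list[DriverCallSet]) -> DriverCallSet:
    """Stack per-condition call sets into one table."""
    if not call_sets:
        raise ParameterError("need at least one call set")
    growth = call_sets[0].growth_process
    death = call_sets[0].death_process
    calls = pd.concat([c.calls for c in call_sets], ignore_index=True)
    return DriverCallSet(calls, growth_process=growth, death_process=death)


def detect_dual(calls: DriverCallSet) -> pd.DataFrame:
    """Genes called OCG in one condition and TSG in another.

    Returns one row per dual gene with the witnessing condition pairs,
    and sets the ``dual_role`` flag on the call table in place.
    """
    if len(calls.conditions) < 2:
        raise ParameterError("dual-role detection needs >= 2 conditions")
    df = calls.calls
    rows = []
    for gene, sub in df.groupby("gene"):
        ocg_conds = sorted(sub.loc[sub["role"] == "OCG", "condition"])
        tsg_conds = sorted(sub.loc[sub["role"] == "TSG", "condition"])
        if ocg_conds and tsg_conds:
            pairs = [(o, t) for o in ocg_conds for t in tsg_conds]
            rows.append((gene, pairs))
            df.loc[df["gene"] == gene, "dual_role"] = True
    return pd.DataFrame(rows, columns=["gene", "witness_pairs"])


def integrate_evidence(calls: DriverCallSet, evidence: EvidenceTable) -> DriverCallSet:
    """Accrue criticality flags from secondary evidence.

    A flag is set when the evidence direction is concordant with the
    called role (e.g. TSG + hypermethylation, OCG + amplification).
    Roles never change; evidence for (gene, condition) pairs absent from
    the calls is logged and skipped.  Idempotent.
    """
    df = calls.calls.copy()
    idx = {(g, c): i for i, (g, c) in enumerate(zip(df["gene"], df["condition"]))}
    for row in evidence.rows.itertuples(index=False):
        key = (row.gene, row.condition)
        if key not in idx:
            log.info("evidence for absent call %r skipped", key)
            continue
        i = idx[key]
        role = df.at[i, "role"]
        flag, concordant = _EVIDENCE_RULES[row.evidence_kind]
        if concordant.get(role) == row.evidence_value:
            df.at[i, flag] = True
    return DriverCallSet(df, growth_process=calls.growth_process, death_process=calls.death_process)


def classify_cellline_expression(
    cellline_expr: ExpressionMatrix,
    genes: set[str],
    condition: str = "tumor_vs_normal",
) -> EvidenceTable:
    """Label genes low/high expressed against the pooled distribution.

    A gene is ``low`` when its mean across cell lines falls below the
    25th percentile of the pooled (all genes x all lines) expression
    distribution, ``high`` above the 75th; in-between genes get no row.
    Percentiles use linear interpolation.
    """
    if cellline_expr.values.shape[1] < 4:
        raise ParameterError("need >= 4 cell lines")
    pooled = cellline_expr.values.to_numpy(dtype=float).ravel()
    q25, q75 = np.percentile(pooled, [25, 75])
    rows = []
    for gene in sorted(genes):
        if gene not in cellline_expr.values.index:
            log.info("gene %r absent from the cell-line matrix; skipped", gene)
            continue
        mean = float(cellline_expr.values.loc[gene].mean())
        if mean < q25:
            rows.append((gene, condition, "cellline_expression", "low"))
        elif mean > q75:
            rows.append((gene, condition, "cellline_expression", "high"))
    return EvidenceTable(
        pd.DataFrame(rows, columns=["gene", "condition", "evidence_kind", "evidence_value"])
    )
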