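"""Data containers and file I/O for every pipeline artifact.

All stages exchange data through the types defined here.  On disk the
canonical dialect is tab-delimited UTF-8 text with ``.`` as the decimal
separator and no thousands separators; sparse expression may instead be
stored as a Matrix Market ``.mtx`` file with sidecar row/column index
files.  Gene identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ConsistencyError, FormatError, VocabularyError

DIRECTIONS = frozenset({"Increased", "Decreased", "Affected"})
PROCESS_EFFECTS = frozenset({"promotes_cancer", "reduces_cancer"})
ROLES = ("TSG", "OCG", "unclassified")
EVIDENCE_VOCAB: dict[str, frozenset[str]] = {
    "methylation": frozenset({"hyper", "hypo"}),
    "copy_number": frozenset({"amplified", "deleted"}),
    "cellline_expression": frozenset({"high", "low"}),
    "prognosis": frozenset({"good", "poor"}),
}
CRITICALITY_FLAGS = (
    "critical_epigenetic",
    "critical_copy_number",
    "cellline_concordant",
    "prognosis_concordant",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with a sample-to-condition map.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); index are gene identifiers,
        columns are sample identifiers.  Counts or normalized intensities.
    condition_map
        Mapping from every sample identifier to a condition label.
    counts
        True when ``values`` are raw (non-negative) counts.
    allow_missing
        True for methylation beta matrices, where masked probes appear
        as NaN; expression matrices must be fully observed.
    """

    values: pd.DataFrame
    condition_map: dict[str, str]
    counts: bool = True
    allow_missing: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        missing = [s for s in v.columns if s not in self.condition_map]
        if missing:
            raise ConsistencyError(
                f"samples missing from the condition map: {missing[:5]}"
            )
        arr = v.to_numpy()
        if not self.allow_missing and not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if self.counts and np.nanmin(arr, initial=0.0) < 0:
            raise FormatError("counts mode implies values >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        """Sample identifiers carrying the given condition label."""
        out = [s for s in self.values.columns if self.condition_map[s] == condition]
        return out

    def restrict(self, condition: str) -> "ExpressionMatrix":
        """Sub-matrix of the samples in one condition."""
        samples = self.samples_in(condition)
        if not samples:
            raise ConsistencyError(f"no samples with condition {condition!r}")
        return ExpressionMatrix(
            self.values[samples].copy(),
            {s: condition for s in samples},
            counts=self.counts,
            allow_missing=self.allow_missing,
        )


@dataclass
class ProcessKnowledge:
    """Curated gene/biological-process literature directions.

    ``entries`` has one row per (gene, process) with the literature
    direction (Increased / Decreased / Affected) and the supporting
    publication count; ``process_effect`` says whether activating the
    process promotes or reduces cancer.
    """

    entries: pd.DataFrame  # columns: gene, process, direction, publication_count
    process_effect: dict[str, str]

    def __post_init__(self) -> None:
        e = self.entries
        required = ["gene", "process", "direction", "publication_count"]
        if list(e.columns[:4]) != required:
            e = e[required]
            self.entries = e
        bad = set(e["direction"]) - DIRECTIONS
        if bad:
            raise VocabularyError(
                f"unknown direction token(s): {sorted(bad)}; allowed: {sorted(DIRECTIONS)}"
            )
        dup = e.duplicated(subset=["gene", "process"])
        if dup.any():
            pairs = e.loc[dup, ["gene", "process"]].itertuples(index=False)
            raise FormatError(
                "duplicate (gene, process) entries: " + str([tuple(p) for p in pairs][:5])
            )
        if (e["publication_count"] < 0).any():
            raise FormatError("publication_count must be >= 0")
        orphans = set(e["process"]) - set(self.process_effect)
        if orphans:
            raise ConsistencyError(
                f"processes without an effect record: {sorted(orphans)[:5]}"
            )
        bad_eff = set(self.process_effect.values()) - PROCESS_EFFECTS
        if bad_eff:
            raise VocabularyError(f"unknown process effect(s): {sorted(bad_eff)}")

    @property
    def processes(self) -> list[str]:
        return sorted(self.process_effect)

    def directions_for(self, process: str) -> pd.Series:
        """gene -> direction for one process."""
        sub = self.entries[self.entries["process"] == process]
        return pd.Series(sub["direction"].to_numpy(), index=sub["gene"].to_numpy())

    def genes_for(self, process: str) -> set[str]:
        return set(self.entries.loc[self.entries["process"] == process, "gene"])

    def processes_by_effect(self, effect: str) -> list[str]:
        return sorted(p for p, e in self.process_effect.items() if e == effect)


@dataclass
class EvidenceTable:
    """Secondary evidence rows: (gene, condition, kind, value)."""

    rows: pd.DataFrame  # columns: gene, condition, evidence_kind, evidence_value

    def __post_init__(self) -> None:
        r = self.rows
        for _, row in r.iterrows():
            kind, value = row["evidence_kind"], row["evidence_value"]
            if kind not in EVIDENCE_VOCAB:
                raise VocabularyError(f"unknown evidence kind {kind!r}")
            if value not in EVIDENCE_VOCAB[kind]:
                raise VocabularyError(
                    f"value {value!r} invalid for kind {kind!r}; "
                    f"allowed: {sorted(EVIDENCE_VOCAB[kind])}"
                )
        if r.duplicated(subset=["gene", "condition", "evidence_kind"]).any():
            raise FormatError("(gene, condition, evidence_kind) rows must be unique")


@dataclass
class GoldStandardLists:
    """Driver-gene lists from two independent sources."""

    source_a_ocg: set[str]
    source_a_tsg: set[str]
    source_a_dual: set[str]
    source_b_ocg: set[str]
    source_b_tsg: set[str]

    def __post_init__(self) -> None:
        a_sets = [self.source_a_ocg, self.source_a_tsg, self.source_a_dual]
        for i in range(len(a_sets)):
            for j in range(i + 1, len(a_sets)):
                common = a_sets[i] & a_sets[j]
                if common:
                    raise ConsistencyError(
                        f"source A OCG/TSG/dual sets overlap: {sorted(common)[:5]}"
                    )
        common_b = self.source_b_ocg & self.source_b_tsg
        if common_b:
            raise ConsistencyError(
                f"source B OCG/TSG sets overlap: {sorted(common_b)[:5]}"
            )


@dataclass
class RegulatoryNetwork:
    """Per-regulator regulons inferred by mutual information.

    ``edges`` holds one row per retained regulator->target edge with the
    MI estimate (nats) and its empirical permutation p-value.
    """

    edges: pd.DataFrame  # columns: regulator, target, mi, p_perm
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) and (e["regulator"] == e["target"]).any():
            raise ConsistencyError("a regulator may not appear in its own regulon")
        if len(e) and not np.isfinite(e["mi"].to_numpy()).all():
            raise FormatError("MI values must be finite")

    @property
    def regulators(self) -> list[str]:
        return sorted(self.edges["regulator"].unique()) if len(self.edges) else []

    def regulon(self, regulator: str) -> pd.DataFrame:
        """Targets of one regulator with their MI and permutation p."""
        return self.edges[self.edges["regulator"] == regulator]

    def to_networkx(self):
        """Directed regulator->target graph with mi/p_perm edge data."""
        import networkx as nx

        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.regulator, row.target, mi=row.mi, p_perm=row.p_perm)
        return g


@dataclass
class GeneZMatrix:
    """Gene x process Z-scores with their support counts.

    ``z[i, j]`` summarizes, over regulon targets of gene i with
    directional literature support for process j, the agreement between
    the literature direction and the observed expression change;
    ``n_support[i, j]`` is the number of supporting targets.  Entries
    with zero support are NaN.
    """

    z: pd.DataFrame
    n_support: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.z.index.equals(self.n_support.index) or not self.z.columns.equals(
            self.n_support.columns
        ):
            raise ConsistencyError("z and n_support must share index and columns")

    def validate(self) -> None:
        """Check |z| <= sqrt(n_support) and NaN exactly where support is 0."""
        z = self.z.to_numpy(dtype=float)
        n = self.n_support.to_numpy(dtype=float)
        pos = n > 0
        if not np.all(np.isnan(z[~pos])):
            raise ConsistencyError("z must be missing where n_support == 0")
        if np.any(np.abs(z[pos]) > np.sqrt(n[pos]) + 1e-9):
            raise ConsistencyError("|z| exceeds sqrt(n_support)")

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)

    @property
    def process_ids(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class DriverCallSet:
    """Role calls per (gene, condition) with dual-role and criticality flags."""

    calls: pd.DataFrame
    growth_process: str = "proliferation"
    death_process: str = "apoptosis"

    COLUMNS = (
        "gene",
        "condition",
        "role",
        "z_growth",
        "z_death",
        "dual_role",
    ) + CRITICALITY_FLAGS

    def __post_init__(self) -> None:
        c = self.calls
        for col in self.COLUMNS:
            if col not in c.columns:
                if col == "dual_role" or col in CRITICALITY_FLAGS:
                    c[col] = False
                else:
                    raise FormatError(f"driver call table lacks column {col!r}")
        self.calls = c[list(self.COLUMNS)].reset_index(drop=True)
        bad = set(self.calls["role"]) - set(ROLES)
        if bad:
            raise VocabularyError(f"unknown role token(s): {sorted(bad)}")
        if self.calls.duplicated(subset=["gene", "condition"]).any():
            raise FormatError("(gene, condition) must be unique in driver calls")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.calls["condition"].unique())

    def roles_in(self, condition: str) -> pd.Series:
        sub = self.calls[self.calls["condition"] == condition]
        return pd.Series(sub["role"].to_numpy(), index=sub["gene"].to_numpy())

    def summary(self) -> dict:
        """Role counts per condition, JSON-ready."""
        out: dict[str, dict[str, int]] = {}
        for cond in self.conditions:
            sub = self.calls[self.calls["condition"] == cond]
            out[cond] = {
                role: int((sub["role"] == role).sum()) for role in ("OCG", "TSG")
            }
            out[cond]["unclassified"] = int((sub["role"] == "unclassified").sum())
            out[cond]["dual_role"] = int(sub["dual_role"].sum())
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_condition_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "condition"]:
        raise FormatError(
            f"condition file must have columns 'sample', 'condition'; got {list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"duplicate sample ids in condition file: {dups[:5]}")
    return dict(zip(df["sample"], df["condition"]))


def _parse_numeric_frame(path: str | Path, allow_missing: bool) -> pd.DataFrame:
    header = Path(path).open().readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate sample identifiers in header: {dups[:5]}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = np.empty(raw.shape)
    # cell-by-cell float(): correctly rounded, and errors carry coordinates
    for j, col in enumerate(raw.columns):
        for i, tok in enumerate(raw[col].to_numpy()):
            if tok == "":
                if not allow_missing:
                    raise FormatError(
                        f"missing value at row {raw.index[i]!r}, column {col!r}"
                    )
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise FormatError(
                    f"non-numeric cell {tok!r} at row {raw.index[i]!r}, "
                    f"column {col!r} (row {i + 1}, column {j + 1})"
                ) from None
    return pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))


def _read_mtx_triplet(path: Path) -> pd.DataFrame:
    rows_path = path.with_suffix(".rows.txt")
    cols_path = path.with_suffix(".cols.txt")
    for p in (rows_path, cols_path):
        if not p.exists():
            raise FormatError(f"MTX sidecar index file missing: {p}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = [line.strip() for line in rows_path.read_text().splitlines() if line.strip()]
    samples = [line.strip() for line in cols_path.read_text().splitlines() if line.strip()]
    if mat.shape != (len(genes), len(samples)):
        raise FormatError(
            f"MTX shape {mat.shape} does not match index files "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    return pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=samples)


def read_expression(
    path: str | Path,
    condition_path: str | Path,
    counts: bool = True,
) -> ExpressionMatrix:
    """Read a gene x sample expression matrix plus its condition map.

    ``path`` is tab-delimited text (genes as rows, header of sample ids)
    or a Matrix Market ``.mtx`` file with ``.rows.txt`` / ``.cols.txt``
    sidecars.  Row and column order are preserved from the file.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        values = _read_mtx_triplet(path)
    else:
        values = _parse_numeric_frame(path, allow_missing=False)
    cmap = _read_condition_map(condition_path)
    return ExpressionMatrix(values, cmap, counts=counts)


def read_methylation(path: str | Path, condition_path: str | Path) -> ExpressionMatrix:
    """Read a region x sample beta matrix; empty fields become NaN."""
    values = _parse_numeric_frame(path, allow_missing=True)
    arr = values.to_numpy()
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise FormatError("beta values must lie in [0, 1]")
    cmap = _read_condition_map(condition_path)
    return ExpressionMatrix(values, cmap, counts=False, allow_missing=True)


def write_expression(expr: ExpressionMatrix, path: str | Path, condition_path: str | Path | None = None) -> None:
    """Write the canonical tab-delimited dialect (value round-trip exact)."""
    expr.values.to_csv(path, sep="\t", index_label="gene")
    if condition_path is not None:
        pd.DataFrame(
            {"sample": expr.sample_ids, "condition": [expr.condition_map[s] for s in expr.sample_ids]}
        ).to_csv(condition_path, sep="\t", index=False)


def read_knowledge(entries_path: str | Path, effects_path: str | Path) -> ProcessKnowledge:
    """Read the (gene, process, direction, publication_count) entries and
    the (process, effect) table."""
    entries = pd.read_csv(entries_path, sep="\t", dtype={"gene": str, "process": str, "direction": str})
    required = {"gene", "process", "direction", "publication_count"}
    if not required.issubset(entries.columns):
        raise FormatError(
            f"knowledge entries need columns {sorted(required)}; got {list(entries.columns)}"
        )
    effects = pd.read_csv(effects_path, sep="\t", dtype=str)
    if not {"process", "effect"}.issubset(effects.columns):
        raise FormatError("effects file needs columns 'process', 'effect'")
    if effects["process"].duplicated().any():
        raise FormatError("duplicate process in effects file")
    return ProcessKnowledge(entries, dict(zip(effects["process"], effects["effect"])))


def write_knowledge(knowledge: ProcessKnowledge, entries_path: str | Path, effects_path: str | Path) -> None:
    knowledge.entries.to_csv(entries_path, sep="\t", index=False)
    pd.DataFrame(
        sorted(knowledge.process_effect.items()), columns=["process", "effect"]
    ).to_csv(effects_path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """One identifier per line; blank lines ignored."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def read_evidence(path: str | Path) -> EvidenceTable:
    rows = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "condition", "evidence_kind", "evidence_value"}
    if not required.issubset(rows.columns):
        raise FormatError(f"evidence table needs columns {sorted(required)}")
    return EvidenceTable(rows[sorted(required)].reindex(
        columns=["gene", "condition", "evidence_kind", "evidence_value"]))


def write_evidence(table: EvidenceTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df["is_deg"] = df["is_deg"].astype(bool)
    return df


def write_deg_table(degs: pd.DataFrame, path: str | Path) -> None:
    degs.to_csv(path, sep="\t", index_label="gene")


def read_network(path: str | Path) -> RegulatoryNetwork:
    edges = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    params_path = Path(path).with_suffix(".params.json")
    params = json.loads(params_path.read_text()) if params_path.exists() else {}
    return RegulatoryNetwork(edges, params)


def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)
    Path(path).with_suffix(".params.json").write_text(
        json.dumps(network.params, indent=2, sort_keys=True) + "\n"
    )


def read_zmatrix(path: str | Path) -> GeneZMatrix:
    z = pd.read_csv(path, sep="\t", index_col=0)
    ns_path = Path(path).with_suffix(".nsupport.tsv")
    n_support = pd.read_csv(ns_path, sep="\t", index_col=0).astype(int)
    z.index = z.index.astype(str)
    n_support.index = n_support.index.astype(str)
    return GeneZMatrix(z, n_support)


def write_zmatrix(zmat: GeneZMatrix, path: str | Path) -> None:
    """Z matrix as TSV (missing entries as empty fields) + n_support sidecar."""
    zmat.z.to_csv(path, sep="\t", index_label="gene")
    zmat.n_support.to_csv(Path(path).with_suffix(".nsupport.tsv"), sep="\t", index_label="gene")


def write_driver_calls(calls: DriverCallSet, path: str | Path) -> None:
    """Write the per-(gene, condition) call table plus a JSON summary.

    The summary (role counts per condition) lands next to ``path`` with a
    ``.summary.json`` suffix.
    """
    df = calls.calls.copy()
    df = df.rename(columns={"z_growth": f"z_{calls.growth_process}", "z_death": f"z_{calls.death_process}"})
    df.to_csv(path, sep="\t", index=False)
    summary = {
        "growth_process": calls.growth_process,
        "death_process": calls.death_process,
        "counts": calls.summary(),
    }
    Path(path).with_suffix(".summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )


def read_driver_calls(path: str | Path) -> DriverCallSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str, "role": str})
    summary_path = Path(path).with_suffix(".summary.json")
    growth, death = "proliferation", "apoptosis"
    if summary_path.exists():
        meta = json.loads(summary_path.read_text())
        growth, death = meta["growth_process"], meta["death_process"]
    df = df.rename(columns={f"z_{growth}": "z_growth", f"z_{death}": "z_death"})
    for col in ("dual_role",) + CRITICALITY_FLAGS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return DriverCallSet(df, growth_process=growth, death_process=death)
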