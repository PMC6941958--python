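"""Config-driven orchestration of the full pipeline.

Stages run in order (simulate | load) -> dpa -> grn -> scoring -> pra
[-> ml], each seeded deterministically from the one global seed, with
all outputs written to the configured directory and a manifest
recording parameters, derived stage seeds, and output digests so any
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dpa, formats_io, grn, pra, role_ml, scoring, simulate
from .errors import DriverlensError, ParameterError
from .formats_io import DriverCallSet

log = logging.getLogger(__name__)

_SCHEMA: dict[str, dict] = {
    "seed": None,
    "outdir": None,
    "simulate": {
        "enabled": None,
        "n_genes": None,
        "n_samples_per_group": None,
        "n_ocg": None,
        "n_tsg": None,
        "targets_per_regulator": None,
        "effect_logfc": None,
        "dependence_strength": None,
        "noise_sd": None,
    },
    "inputs": {
        "expression": None,
        "conditions": None,
        "knowledge_entries": None,
        "knowledge_effects": None,
        "evidence": None,
    },
    "dpa": {"group_a": None, "group_b": None, "logfc_threshold": None, "fdr_threshold": None},
    "grn": {"alpha": None, "k": None, "nboot": None, "n_genes_perm": None, "use_condition": None},
    "scoring": {"run_fea": None, "z_threshold": None, "fdr_threshold": None},
    "pra": {"growth_process": None, "death_process": None, "threshold": None, "condition_label": None},
    "ml": {"enabled": None, "labels": None, "repetitions": None, "n_estimators": None},
}

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "driverlens_out",
    "simulate": {"enabled": True},
    "inputs": {},
    "dpa": {"group_a": "normal", "group_b": "tumor", "logfc_threshold": 1.0, "fdr_threshold": 0.01},
    "grn": {"alpha": 0.05, "k": 3, "nboot": 100, "n_genes_perm": 1000, "use_condition": "tumor"},
    "scoring": {"run_fea": True, "z_threshold": 1.0, "fdr_threshold": 0.01},
    "pra": {
        "growth_process": None,
        "death_process": None,
        "threshold": 0.0,
        "condition_label": "tumor_vs_normal",
    },
    "ml": {"enabled": False, "repetitions": 10, "n_estimators": 500},
}


def validate_config(config: dict) -> dict:
    """Merge over defaults, rejecting unknown keys at every level."""
    out = json.loads(json.dumps(DEFAULTS))
    for key, value in config.items():
        if key not in _SCHEMA:
            raise ParameterError(f"unknown config key {key!r}")
        if isinstance(_SCHEMA[key], dict):
            if not isinstance(value, dict):
                raise ParameterError(f"config section {key!r} must be a mapping")
            for sub in value:
                if sub not in _SCHEMA[key]:
                    raise ParameterError(f"unknown config key {key}.{sub}")
            out.setdefault(key, {}).update(value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> dict:
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed and the stage name."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> tuple[DriverCallSet, dict]:
    """Execute all enabled stages; returns the driver calls and manifest.

    Any stage failure is re-raised annotated with the stage name, after
    a ``FAILED`` marker naming the stage is written next to whatever
    partial outputs exist.
    """
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stage_seeds": {}, "outputs": {}}
    current = "setup"
    try:
        # --- inputs ---------------------------------------------------
        if cfg["simulate"]["enabled"]:
            current = "simulate"
            seed = stage_seed(cfg["seed"], "simulate")
            manifest["stage_seeds"]["simulate"] = seed
            sim_kwargs = {
                k: v for k, v in cfg["simulate"].items() if k != "enabled" and v is not None
            }
            expr, knowledge, truth = simulate.simulate_dataset(seed=seed, **sim_kwargs)
            formats_io.write_expression(
                expr, outdir / "expression.tsv", outdir / "conditions.tsv"
            )
            formats_io.write_knowledge(
                knowledge, outdir / "knowledge_entries.tsv", outdir / "knowledge_effects.tsv"
            )
            (outdir / "truth.json").write_text(
                json.dumps(
                    {
                        "planted_degs": truth.planted_degs,
                        "planted_modules": truth.planted_modules,
                        "planted_roles": truth.planted_roles,
                        "params": truth.params,
                    },
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
        else:
            current = "load"
            inp = cfg["inputs"]
            expr = formats_io.read_expression(inp["expression"], inp["conditions"])
            knowledge = formats_io.read_knowledge(
                inp["knowledge_entries"], inp["knowledge_effects"]
            )
            truth = None

        # --- dpa ------------------------------------------------------
        current = "dpa"
        d = cfg["dpa"]
        degs = dpa.call_degs(
            expr,
            d["group_a"],
            d["group_b"],
            logfc_threshold=d["logfc_threshold"],
            fdr_threshold=d["fdr_threshold"],
        )
        formats_io.write_deg_table(degs, outdir / "degs.tsv")

        # --- grn ------------------------------------------------------
        current = "grn"
        g = cfg["grn"]
        seed = stage_seed(cfg["seed"], "grn")
        manifest["stage_seeds"]["grn"] = seed
        network = grn.build_network(
            expr.restrict(g["use_condition"]),
            degs,
            alpha=g["alpha"],
            k=g["k"],
            nboot=g["nboot"],
            n_genes_perm=g["n_genes_perm"],
            seed=seed,
        )
        formats_io.write_network(network, outdir / "network.tsv")

        # --- scoring --------------------------------------------------
        current = "scoring"
        s = cfg["scoring"]
        zmat = scoring.ura_matrix(network, degs, knowledge)
        formats_io.write_zmatrix(zmat, outdir / "zmatrix.tsv")
        if s["run_fea"]:
            fea_table = scoring.fea(
                degs,
                knowledge,
                z_threshold=s["z_threshold"],
                fdr_threshold=s["fdr_threshold"],
            )
            fea_table.to_csv(outdir / "fea.tsv", sep="\t")

        # --- pra ------------------------------------------------------
        current = "pra"
        p = cfg["pra"]
        growth = p["growth_process"] or _default_process(knowledge, "promotes_cancer")
        death = p["death_process"] or _default_process(knowledge, "reduces_cancer")
        calls = pra.classify_roles(
            zmat,
            growth_process=growth,
            death_process=death,
            threshold=p["threshold"],
            condition=p["condition_label"],
        )
        evidence_path = cfg["inputs"].get("evidence")
        if evidence_path:
            calls = pra.integrate_evidence(calls, formats_io.read_evidence(evidence_path))
        formats_io.write_driver_calls(calls, outdir / "driver_calls.tsv")

        # --- ml (optional) --------------------------------------------
        if cfg["ml"]["enabled"]:
            current = "ml"
            seed = stage_seed(cfg["seed"], "ml")
            manifest["stage_seeds"]["ml"] = seed
            labels = _ml_labels(cfg, truth)
            result = role_ml.loo_evaluate(
                zmat,
                labels,
                repetitions=cfg["ml"]["repetitions"],
                seed=seed,
                n_estimators=cfg["ml"]["n_estimators"],
            )
            (outdir / "ml_evaluation.json").write_text(
                json.dumps(
                    {
                        "logloss": result.logloss,
                        "auc": result.auc,
                        "logloss_per_rep": result.logloss_per_rep,
                        "auc_per_rep": result.auc_per_rep,
                        "params": result.params,
                    },
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        raise DriverlensError(f"pipeline failed in stage {current!r}: {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _digest(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return calls, manifest


def _default_process(knowledge, effect: str) -> str:
    procs = knowledge.processes_by_effect(effect)
    if not procs:
        raise ParameterError(f"knowledge base has no process with effect {effect!r}")
    return procs[0]


def _ml_labels(cfg: dict, truth) -> role_ml.RoleLabels:
    labels_path = cfg["ml"].get("labels")
    if labels_path:
        df = pd.read_csv(labels_path, sep="\t", dtype=str)
        return role_ml.RoleLabels(pd.Series(df["class"].to_numpy(), index=df["gene"].to_numpy()))
    if truth is not None:
        return role_ml.RoleLabels(pd.Series(truth.planted_roles))
    raise ParameterError("ml stage needs a labels file when not simulating")


def rerun_from_manifest(manifest_path: str | Path) -> tuple[DriverCallSet, dict]:
    """Reproduce a previous run from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    return run_pipeline(manifest["config"])
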