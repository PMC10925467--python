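"""End-to-end pipeline orchestration: simulate -> filter -> normalize -> screen ->
differential abundance -> LSEA -> network -> classification/integration, with a
provenance manifest recording parameters, seed, and output hashes."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import diff, integrate, lsea, network, preprocess, simulate
from .preprocess import DriftParams, FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {"enabled": True},
    "filter": {"snr_min": 3.0, "quality_min": 0.6, "grades": ["A", "B", "C"]},
    "normalize": {"n_predictors": 10, "n_trees": 100, "max_missing": 0.2},
    "screen": {"covariates": ["age", "sex_female", "pmi", "education"], "alpha": 0.05},
    "diff": {"posthoc": "tukey", "fdr_display_threshold": 0.7},
    "lsea": {"n_permutations": 1000, "min_set_size": 3, "weight_exponent": 1.0},
    "network": {
        "cut_height": 0.97, "deep_split": 3, "min_module_size": 2,
        "scale_free_target_r2": 0.9, "outlier_z": 3.0,
    },
    "integrate": {"relevance_cutoff": 0.7, "ncomp": 2},
    "traits": [
        "cognition", "gpath", "amyloid", "tangles", "braak", "cerad",
        "reagan_inverted", "diagnosis_code",
    ],
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides or {})


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str, traits_path: Optional[str] = None,
                 table_prefix: Optional[str] = None) -> dict:
    """Execute the stages in order, writing CSV outputs and a provenance manifest.

    Either simulation is enabled in the config, or ``traits_path`` (CSV) and
    ``table_prefix`` (feature-table CSV trio) point at existing inputs; missing
    inputs abort before any compute.
    """
    seed = int(config["seed"])
    use_sim = config.get("simulate", {}).get("enabled", True)
    if not use_sim:
        if traits_path is None or not os.path.exists(traits_path):
            raise FileNotFoundError(f"traits file not found: {traits_path}")
        for suffix in ("_abundance.csv", "_features.csv", "_samples.csv"):
            if table_prefix is None or not os.path.exists(table_prefix + suffix):
                raise FileNotFoundError(f"feature table file not found: {table_prefix}{suffix}")
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"seed": seed, "config": config, "stages": {}, "outputs": {}}
    t0 = time.time()

    if use_sim:
        sim_params = dict(config.get("simulate", {}).get("params", {}))
        if "modules" in sim_params:
            sim_params["modules"] = [simulate.ModuleSpec(**m) for m in sim_params["modules"]]
        if "couplings" in sim_params:
            sim_params["couplings"] = [
                simulate.CouplingSpec(**c) for c in sim_params["couplings"]
            ]
        sim_cfg = simulate.SimConfig(seed=seed, **sim_params)
        sim = simulate.simulate_all(sim_cfg)
        cohort, table, proteins = sim.cohort, sim.lipidome, sim.protein_modules
        sim.ground_truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    else:
        from .io import read_feature_table

        cohort = pd.read_csv(traits_path, index_col=0)
        table = read_feature_table(table_prefix)
        proteins = None
    cohort.to_csv(os.path.join(out_dir, "traits.csv"))
    manifest["stages"]["ingest"] = {"n_samples": int(table.abundance.shape[0]),
                                    "n_features": int(table.abundance.shape[1])}

    fcfg = config["filter"]
    filt = preprocess.filter_features(
        table, fcfg["snr_min"], fcfg["quality_min"], frozenset(fcfg["grades"])
    )
    manifest["stages"]["filter"] = {"n_input": filt.n_input, "n_retained": filt.n_retained}

    ncfg = config["normalize"]
    clean = preprocess.handle_missing(filt.table, ncfg["max_missing"])
    corrected, report = preprocess.qc_drift_correct(
        clean, DriftParams(n_predictors=ncfg["n_predictors"], n_trees=ncfg["n_trees"], seed=seed)
    )
    with open(os.path.join(out_dir, "normalization_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    manifest["stages"]["normalize"] = report.to_dict()

    log_table = preprocess.log2_transform(corrected)
    log_table = log_table.loc[[s for s in cohort.index if s in log_table.index]]
    log_table.to_csv(os.path.join(out_dir, "log2_normalized.csv"))

    scfg = config["screen"]
    covs = cohort.loc[log_table.index, scfg["covariates"]]
    screen_p = preprocess.covariate_screen(log_table, covs, alpha=scfg["alpha"])
    screen_p.to_csv(os.path.join(out_dir, "covariate_screen.csv"))
    manifest["stages"]["screen"] = screen_p.to_dict()

    groups = cohort.loc[log_table.index, "diagnosis"]
    kw = diff.kruskal_fdr(log_table, groups, config["diff"]["fdr_display_threshold"])
    kw.to_csv(os.path.join(out_dir, "kruskal_fdr.csv"))
    fc_tables = {}
    for a, b in [("SAD", "Control"), ("AAD", "Control"), ("SAD", "AAD")]:
        fc = diff.fold_change_table(log_table, groups, a, b, moderation="empirical_bayes")
        fc.to_csv(os.path.join(out_dir, f"foldchange_{a}_vs_{b}.csv"))
        fc_tables[(a, b)] = fc
    manifest["stages"]["diff"] = {"n_kw_flagged": int(kw["flagged"].sum())}

    lcfg = config["lsea"]
    sets = lsea.build_lipid_sets(list(log_table.columns), min_set_size=lcfg["min_set_size"])
    enr = lsea.lsea_test(
        log_table, groups, ("SAD", "Control"), sets,
        n_permutations=lcfg["n_permutations"],
        weight_exponent=lcfg["weight_exponent"], seed=seed,
    )
    enr.to_csv(os.path.join(out_dir, "lsea_SAD_vs_Control.csv"))
    manifest["stages"]["lsea"] = {"n_sets": len(sets),
                                  "n_significant": int((enr["p"] < 0.05).sum())}

    wcfg = config["network"]
    retained, outlier_report = network.remove_outlier_samples(log_table, wcfg["outlier_z"])
    net_table = log_table.loc[retained]
    net_config = network.NetworkConfig(
        cut_height=wcfg["cut_height"], deep_split=wcfg["deep_split"],
        min_module_size=wcfg["min_module_size"],
        scale_free_target_r2=wcfg["scale_free_target_r2"],
    )
    powers_table, beta = network.pick_soft_threshold(net_table, config=net_config)
    net_config.power = beta
    diss = network.build_tom(net_table, net_config)
    labels = network.detect_modules(diss, net_config)
    modules = network.eigenlipids(net_table, labels)
    labels.to_csv(os.path.join(out_dir, "module_labels.csv"))
    modules.eigenlipids.to_csv(os.path.join(out_dir, "eigenlipids.csv"))
    modules.kme.to_csv(os.path.join(out_dir, "kme.csv"))
    trait_cols = [t for t in config["traits"] if t != "diagnosis_code"]
    traits_num = cohort.loc[retained, trait_cols].astype(float)
    traits_num["diagnosis_code"] = (
        cohort.loc[retained, "diagnosis"].map({"Control": 0, "AAD": 1, "SAD": 2}).astype(float)
    )
    assoc = network.module_trait_assoc(modules.eigenlipids, traits_num)
    assoc.to_csv(os.path.join(out_dir, "module_trait.csv"), index=False)
    manifest["stages"]["network"] = {
        "power": int(beta), "n_modules": int(labels.max()),
        "n_outliers_removed": int(len(log_table) - len(retained)),
    }

    icfg = config["integrate"]
    y = groups.loc[retained]
    model = integrate.splsda_fit(net_table, list(y), ncomp=icfg["ncomp"])
    scores, _ = integrate.splsda_predict(model, net_table)
    aucs = {}
    for cls in model.classes:
        auc, p = integrate.roc_auc(scores[str(cls)].to_numpy(), (y == cls).astype(int).to_numpy())
        aucs[str(cls)] = {"auc": auc, "p": p}
    if proteins is not None:
        common = [s for s in proteins.index if s in modules.eigenlipids.index]
        rel = integrate.relevance_network(
            {
                "lipid_module": modules.eigenlipids.loc[common],
                "protein_module": proteins.loc[common],
                "clinical": traits_num.loc[common],
            },
            cutoff=icfg["relevance_cutoff"],
        )
        rel.edges.to_csv(os.path.join(out_dir, "relevance_edges.tsv"), sep="\t", index=False)
        manifest["stages"]["integrate"] = {"auc_one_vs_rest": aucs,
                                           "n_relevance_edges": len(rel.edges)}
    else:
        manifest["stages"]["integrate"] = {"auc_one_vs_rest": aucs}

    manifest["runtime_s"] = round(time.time() - t0, 2)
    for fn in sorted(os.listdir(out_dir)):
        path = os.path.join(out_dir, fn)
        if os.path.isfile(path) and fn != "manifest.json":
            manifest["outputs"][fn] = _hash_file(path)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
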