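"""End-to-end orchestration: synthetic data -> qHTS -> SOM -> enrichment ->
endpoint calls -> toxicity models.

A single config dict (YAML-friendly) drives every stage; each stage reads
its inputs from files written by the previous one, writes its outputs with
a seed header, and the run manifest records per-stage outputs (sha256),
row counts and timings.  Re-running an unchanged config reproduces
identical output checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import endpoints as ep
from . import io as tio
from . import models as mdl
from . import qhts, som
from .synthetic import (
    EndpointSpec,
    generate_endpoints,
    generate_library,
    generate_plate_set,
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "rundir",
    "stages": {
        "synth": True,
        "qhts": True,
        "som": True,
        "enrichment": True,
        "endpoints": True,
        "models": True,
    },
    "synth": {
        "n_compounds": 500,
        "n_classes": 4,
        "n_assays": 8,
        "n_bits": 128,
        "signal_strength": 0.8,
        "annotation_coverage": 0.6,
        "endpoint_specs": [
            {"name": "acute_oral", "endpoint_type": "dose",
             "class_probs": [0.8, 0.2, 0.8, 0.2],
             "replicate_rate": 0.3, "replicate_noise": 0.05},
            {"name": "acute_dermal", "endpoint_type": "dose",
             "class_probs": [0.7, 0.3, 0.2, 0.8],
             "replicate_rate": 0.3, "replicate_noise": 0.05},
            {"name": "repro_tdlo", "endpoint_type": "score",
             "class_probs": [0.8, 0.1, 0.5, 0.5],
             "replicate_rate": 0.3, "replicate_noise": 0.05},
            {"name": "acute_composite", "endpoint_type": "composite",
             "components": ["acute_oral", "acute_dermal"]},
        ],
        "n_plate_compounds": 8,
        "n_plate_assays": 2,
        "plate_noise_sd": 5.0,
    },
    "qhts": {"efficacy_threshold": 30.0, "active_cutoff": 3},
    "som": {
        "activity_grid": [8, 8],
        "structure_grid": [10, 10],
        "schedule": {},
    },
    "enrichment": {"fdr": False},
    "endpoints": {},
    "models": {"n_repeats": 25, "missing_policy": "neutral"},
}


class ConfigError(ValueError):
    """Raised before any stage runs when the config cannot be satisfied."""


def make_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _paths(cfg: dict) -> dict[str, Path]:
    out = Path(cfg["outdir"])
    return {
        "profiles": out / "profiles.csv",
        "fingerprints": out / "fingerprints.csv",
        "annotations": out / "annotations.tsv",
        "classes": out / "latent_classes.csv",
        "endpoints": out / "endpoints.csv",
        "endpoint_meta": out / "endpoint_meta.yaml",
        "plates": out / "plates.csv",
        "fits": out / "fits.csv",
        "repro": out / "repro.csv",
        "som_activity": out / "som_activity.json",
        "som_structure": out / "som_structure.json",
        "clusters_activity": out / "clusters_activity.tsv",
        "clusters_structure": out / "clusters_structure.tsv",
        "clusters_consensus": out / "clusters_consensus.tsv",
        "enrichment": out / "enrichment.csv",
        "cluster_labels": out / "cluster_labels.csv",
        "calls": out / "calls.csv",
        "endpoint_summary": out / "endpoint_summary.csv",
        "evaluations": out / "evaluations.csv",
        "auc_per_split": out / "auc_per_split.csv",
        "single_assay": out / "single_assay_auc.csv",
        "manifest": out / "manifest.json",
    }


# inputs each stage needs on disk when it starts (produced upstream or
# supplied by the user when the upstream stage is disabled)
_STAGE_INPUTS = {
    "synth": [],
    "qhts": ["plates"],
    "som": ["profiles", "fingerprints"],
    "enrichment": ["clusters_activity", "annotations"],
    "endpoints": ["endpoints", "endpoint_meta"],
    "models": ["calls", "clusters_activity", "clusters_structure",
               "clusters_consensus", "profiles"],
}

_STAGE_ORDER = ["synth", "qhts", "som", "enrichment", "endpoints", "models"]


def validate_config(cfg: dict) -> None:
    """Check schema and that every enabled stage's inputs will exist."""
    stages = cfg.get("stages", {})
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    paths = _paths(cfg)
    produced: set[str] = set()
    for stage in _STAGE_ORDER:
        if not stages.get(stage, False):
            continue
        for key in _STAGE_INPUTS[stage]:
            if key in produced:
                continue
            if not paths[key].exists():
                raise ConfigError(
                    f"stage {stage!r} requires missing input file: {paths[key]}"
                )
        produced.update(_produces(stage))


def _produces(stage: str) -> list[str]:
    return {
        "synth": ["profiles", "fingerprints", "annotations", "classes",
                  "endpoints", "endpoint_meta", "plates"],
        "qhts": ["fits", "repro"],
        "som": ["som_activity", "som_structure", "clusters_activity",
                "clusters_structure", "clusters_consensus"],
        "enrichment": ["enrichment", "cluster_labels"],
        "endpoints": ["calls", "endpoint_summary"],
        "models": ["evaluations", "auc_per_split", "single_assay"],
    }[stage]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | None = None, log=None) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    cfg = make_config(config)
    validate_config(cfg)
    paths = _paths(cfg)
    Path(cfg["outdir"]).mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stages": {},
    }

    def _log(stage: str, **info) -> None:
        if log is not None:
            log(json.dumps({"stage": stage, "seed": seed, **info}))

    runners = {
        "synth": _run_synth,
        "qhts": _run_qhts,
        "som": _run_som,
        "enrichment": _run_enrichment,
        "endpoints": _run_endpoints,
        "models": _run_models,
    }
    try:
        for stage in _STAGE_ORDER:
            if not cfg["stages"].get(stage, False):
                continue
            t0 = time.perf_counter()
            info = runners[stage](cfg, paths)
            elapsed = time.perf_counter() - t0
            outputs = {
                key: _sha256(paths[key])
                for key in _produces(stage)
                if paths[key].exists()
            }
            manifest["stages"][stage] = {
                "outputs": {str(paths[k]): v for k, v in outputs.items()},
                "seconds": round(elapsed, 3),
                **info,
            }
            _log(stage, seconds=round(elapsed, 3), **info)
    finally:
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


def _specs_from_config(spec_dicts: list[dict]) -> list[EndpointSpec]:
    specs = []
    for d in spec_dicts:
        probs = {i: p for i, p in enumerate(d.get("class_probs", []))}
        specs.append(
            EndpointSpec(
                name=d["name"],
                endpoint_type=d["endpoint_type"],
                class_toxicity_prob=probs,
                replicate_rate=float(d.get("replicate_rate", 0.0)),
                replicate_noise=float(d.get("replicate_noise", 0.0)),
                components=tuple(d.get("components", ())),
            )
        )
    return specs


def _run_synth(cfg: dict, paths: dict) -> dict:
    p = cfg["synth"]
    seed = int(cfg["seed"])
    lib = generate_library(
        n_compounds=int(p["n_compounds"]),
        n_classes=int(p["n_classes"]),
        n_assays=int(p["n_assays"]),
        n_bits=int(p["n_bits"]),
        signal_strength=float(p["signal_strength"]),
        annotation_coverage=float(p["annotation_coverage"]),
        seed=seed,
    )
    tio.write_matrix(lib.profiles, paths["profiles"], seed=seed)
    tio.write_matrix(lib.fingerprints, paths["fingerprints"], seed=seed)
    tio.write_annotations(lib.annotations, paths["annotations"], seed=seed)
    classes = pd.DataFrame(
        sorted(lib.latent_class.items()), columns=["compound_id", "latent_class"]
    )
    tio._write_csv(classes, paths["classes"], seed=seed)
    table = generate_endpoints(lib, _specs_from_config(p["endpoint_specs"]),
                               seed=seed)
    tio.write_endpoint_table(table, paths["endpoints"],
                             paths["endpoint_meta"], seed=seed)
    _write_plates(lib, cfg, paths["plates"])
    return {"n_compounds": len(lib.compounds),
            "n_endpoints": len(table.meta)}


def _write_plates(lib, cfg: dict, path: Path) -> None:
    """Simulate triplicate raw plates for a subset of compounds/assays."""
    p = cfg["synth"]
    seed = int(cfg["seed"])
    n_cpds = min(int(p["n_plate_compounds"]), len(lib.compounds))
    assays = list(lib.profiles.columns[: int(p["n_plate_assays"])])
    noise = float(p["plate_noise_sd"])
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    rows = []
    for a_idx, assay in enumerate(assays):
        for cpd_i, cid in enumerate(lib.compounds[:n_cpds]):
            rank = int(lib.profiles.at[cid, assay])
            # active compounds get a real Hill curve scaled by their rank
            eff = float(np.sign(rank)) * min(abs(rank) / 8.0, 1.0) * 90.0
            ac50 = float(10.0 ** rng.uniform(-7.0, -5.0))
            reps = generate_plate_set(
                true_ac50=ac50, true_efficacy=eff, hill_slope=1.0,
                n_conc=15, noise_sd=noise, n_replicates=3,
                seed=seed + 1000 * a_idx + cpd_i, compound_id=cid,
            )
            for r_idx, tit in enumerate(reps, start=1):
                plate = f"{assay}_r{r_idx}"
                for w, (conc, raw) in enumerate(
                    zip(tit.concentrations, tit.raw_reads)
                ):
                    rows.append(
                        (plate, f"{cid}_w{w:02d}", "compound", cid, assay,
                         r_idx, conc, raw)
                    )
                rows.append((plate, f"{cid}_pos", "pos", cid, assay, r_idx,
                             "", tit.pos_control_median))
                rows.append((plate, f"{cid}_dmso", "dmso", cid, assay, r_idx,
                             "", tit.dmso_median))
    df = pd.DataFrame(
        rows,
        columns=["plate_id", "well", "role", "compound_id", "assay",
                 "replicate", "concentration_M", "raw_signal"],
    )
    tio._write_csv(df, path, seed=seed)


def _run_qhts(cfg: dict, paths: dict) -> dict:
    p = cfg["qhts"]
    seed = int(cfg["seed"])
    plates = tio._read_csv(paths["plates"])
    fit_rows = []
    ranks: dict[tuple[str, str], dict[int, int]] = {}
    grouped = plates.groupby(["compound_id", "assay", "replicate"], sort=True)
    for (cid, assay, rep), grp in grouped:
        cpd = grp[grp["role"] == "compound"].sort_values("concentration_M")
        pos = grp[grp["role"] == "pos"]["raw_signal"].median()
        dmso = grp[grp["role"] == "dmso"]["raw_signal"].median()
        tit = qhts.RawTitration(
            compound_id=str(cid),
            concentrations=cpd["concentration_M"].astype(float).to_numpy(),
            raw_reads=cpd["raw_signal"].astype(float).to_numpy(),
            pos_control_median=float(pos),
            dmso_median=float(dmso),
        )
        fit = qhts.fit_titration(tit, efficacy_threshold=float(
            p["efficacy_threshold"]))
        fit_rows.append(
            (cid, assay, rep, fit.ac50, fit.efficacy, fit.hill_slope,
             fit.r2, fit.curve_class, fit.curve_rank)
        )
        ranks.setdefault((str(cid), str(assay)), {})[int(rep)] = int(
            fit.curve_rank)
    fits = pd.DataFrame(
        fit_rows,
        columns=["compound_id", "assay", "replicate", "ac50_M",
                 "efficacy_pct", "hill_slope", "r2", "curve_class",
                 "curve_rank"],
    )
    tio._write_csv(fits, paths["fits"], seed=seed)

    cutoff = int(p["active_cutoff"])
    by_assay: dict[str, list] = {}
    for (cid, assay), reps in ranks.items():
        if len(reps) == 3:
            call = qhts.call_reproducibility(
                [reps[i] for i in sorted(reps)], active_cutoff=cutoff,
                compound_id=cid,
            )
            by_assay.setdefault(assay, []).append(call)
    rep_rows = []
    for assay in sorted(by_assay):
        summary = qhts.summarize_assay_repro(by_assay[assay])
        rep_rows.append(
            (assay, summary.pct_active_match, summary.pct_inactive_match,
             summary.pct_inconclusive, summary.pct_mismatch, summary.score,
             summary.grade)
        )
    repro = pd.DataFrame(
        rep_rows,
        columns=["assay", "pct_active_match", "pct_inactive_match",
                 "pct_inconclusive", "pct_mismatch", "score", "grade"],
    )
    tio._write_csv(repro, paths["repro"], seed=seed)
    return {"n_fits": len(fits), "n_assays": len(rep_rows)}


def _run_som(cfg: dict, paths: dict) -> dict:
    p = cfg["som"]
    seed = int(cfg["seed"])
    profiles = tio.read_matrix(paths["profiles"])
    fps = tio.read_matrix(paths["fingerprints"])
    ar, ac = p["activity_grid"]
    sr, sc = p["structure_grid"]
    m_act = som.train_som(profiles, int(ar), int(ac),
                          schedule=p.get("schedule") or None, seed=seed)
    m_str = som.train_som(fps, int(sr), int(sc),
                          schedule=p.get("schedule") or None, seed=seed + 1)
    m_act.to_json(paths["som_activity"])
    m_str.to_json(paths["som_structure"])
    a_assign = som.assign_clusters(m_act, profiles, map_kind="activity")
    s_assign = som.assign_clusters(m_str, fps, map_kind="structure")
    consensus = som.consensus_clusters(a_assign, s_assign)
    tio.write_assignment(a_assign, paths["clusters_activity"], seed=seed)
    tio.write_assignment(s_assign, paths["clusters_structure"], seed=seed)
    tio.write_assignment(consensus, paths["clusters_consensus"], seed=seed)
    return {
        "activity_clusters": a_assign.n_clusters(),
        "structure_clusters": s_assign.n_clusters(),
        "consensus_clusters": consensus.n_clusters(),
    }


def _run_enrichment(cfg: dict, paths: dict) -> dict:
    from . import enrichment as enr

    seed = int(cfg["seed"])
    assignment = tio.read_assignment(paths["clusters_activity"])
    annotations = tio.read_annotations(paths["annotations"])
    results = enr.enrich_clusters(
        assignment.clusters(), annotations, fdr=bool(cfg["enrichment"]["fdr"])
    )
    tio._write_csv(enr.results_frame(results), paths["enrichment"], seed=seed)
    labels = enr.label_clusters(results, assignment.clusters())
    frame = pd.DataFrame(
        [(c, t, pv) for c, (t, pv) in sorted(labels.items())],
        columns=["cluster", "best_term", "p_value"],
    )
    tio._write_csv(frame, paths["cluster_labels"], seed=seed)
    return {"n_tests": len(results), "n_labelled": len(labels)}


def _run_endpoints(cfg: dict, paths: dict) -> dict:
    seed = int(cfg["seed"])
    table = tio.read_endpoint_table(paths["endpoints"], paths["endpoint_meta"])
    calls = ep.build_calls(table)
    tio.write_calls(calls.calls, paths["calls"], seed=seed)
    summary = ep.summarize_endpoints(table, calls)
    tio._write_csv(summary, paths["endpoint_summary"], seed=seed)
    return {"n_endpoints": summary.shape[0],
            "n_retained": int(summary["retained"].sum())}


def _run_models(cfg: dict, paths: dict) -> dict:
    p = cfg["models"]
    seed = int(cfg["seed"])
    calls_df = tio.read_calls(paths["calls"])
    calls = ep.ToxCalls(calls=calls_df)
    calls.retained = ep.filter_endpoints(calls)
    assignments = {
        "activity": tio.read_assignment(paths["clusters_activity"]),
        "structure": tio.read_assignment(paths["clusters_structure"]),
        "combined": tio.read_assignment(paths["clusters_consensus"]),
    }
    by_endpoint = {epname: calls.endpoint_calls(epname)
                   for epname in calls.retained}
    evals = mdl.evaluate_models(
        by_endpoint, assignments, n_repeats=int(p["n_repeats"]), seed=seed
    )
    tio._write_csv(mdl.evaluations_frame(evals), paths["evaluations"],
                   seed=seed)
    long_rows = [
        (e.endpoint, e.model_kind, i, auc)
        for e in evals
        for i, auc in enumerate(e.auc_per_split)
    ]
    tio._write_csv(
        pd.DataFrame(long_rows,
                     columns=["endpoint", "model_kind", "split", "auc"]),
        paths["auc_per_split"], seed=seed,
    )
    profiles = tio.read_matrix(paths["profiles"])
    sa_rows = []
    for epname in calls.retained:
        sa = mdl.single_assay_auc(profiles, by_endpoint[epname])
        sa.insert(0, "endpoint", epname)
        sa_rows.append(sa)
    sa_all = (pd.concat(sa_rows, ignore_index=True) if sa_rows
              else pd.DataFrame(columns=["endpoint", "assay", "auc",
                                         "predictive"]))
    tio._write_csv(sa_all, paths["single_assay"], seed=seed)
    return {"n_models": len(evals), "n_endpoints": len(by_endpoint)}
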