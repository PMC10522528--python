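"""End-to-end orchestration: simulate → connectome → encode → train →
importance → report, under one seeded configuration.

Every stage draws its randomness from a named child of the global seed
(via :class:`numpy.random.SeedSequence` spawning), so a run is reproducible
from the (config, seed) pair alone.  Each stage writes its artifacts under
the output directory and the run ends with a manifest listing every artifact
with a SHA-256 checksum; identical config + seed reproduces identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import connectome as conn
from . import encoder as enc
from . import importance as imp
from . import survival as surv
from . import synthetic as syn
from .errors import ConfigurationError, GbmsurvError

log = logging.getLogger("gbmsurv")

#: stage order; each stage gets a dedicated child seed in this order
STAGES = ("simulate", "connectome", "encode", "train", "importance", "report")


@dataclasses.dataclass
class RunConfig:
    sim: syn.SimConfig = dataclasses.field(default_factory=syn.SimConfig)
    autoencoder: enc.AutoencoderConfig = dataclasses.field(default_factory=enc.AutoencoderConfig)
    classifier: clf.ClassifierConfig = dataclasses.field(default_factory=clf.ClassifierConfig)
    within_method: str = "set"
    importance_repeats: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        try:
            sim = syn.SimConfig(**raw.get("sim", {}))
            ae = enc.AutoencoderConfig(**raw.get("autoencoder", {}))
            cl = clf.ClassifierConfig(**raw.get("classifier", {}))
            for key in ("hidden_layers", "alpha_grid"):
                if isinstance(getattr(cl, key), list):
                    setattr(cl, key, tuple(getattr(cl, key)))
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        return cls(
            sim=sim, autoencoder=ae, classifier=cl,
            within_method=raw.get("within_method", "set"),
            importance_repeats=int(raw.get("importance_repeats", 20)),
            seed=int(raw.get("seed", 0)),
        )


def stage_seeds(global_seed: int) -> dict[str, int]:
    """One deterministic 31-bit child seed per stage."""
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {name: int(ss.generate_state(1)[0] % (2**31 - 1))
            for name, ss in zip(STAGES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict[str, Any] = {"seed": config.seed, "stage_seeds": seeds,
                                "stages": {}, "artifacts": {}}
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        t0 = time.perf_counter()
        sim_cfg = dataclasses.replace(config.sim, seed=seeds["simulate"])
        cohort = syn.generate_cohort(sim_cfg)
        cohort_df = cohort.to_frame()
        cohort_path = out / "cohort.csv"
        cohort_df.to_csv(cohort_path, index=False)
        artifacts["cohort"] = cohort_path
        maps = syn.generate_probability_maps(sim_cfg)
        artifacts["probability_maps"] = Path(syn.save_probability_maps(maps, out))
        manifest["stages"]["simulate"] = {"n_subjects": len(cohort.subjects),
                                          "seconds": time.perf_counter() - t0}
        log.info("simulate: %d subjects", len(cohort.subjects))

        # --- connectome ---------------------------------------------------
        stage = "connectome"
        t0 = time.perf_counter()
        networks = sim_cfg.networks
        conn_df = conn.connectome_table(cohort.timeseries, networks=networks,
                                        within_method=config.within_method)
        conn_path = out / "connectomes.csv"
        conn_df.to_csv(conn_path)
        artifacts["connectomes"] = conn_path
        manifest["stages"]["connectome"] = {"n_features": conn_df.shape[1],
                                            "seconds": time.perf_counter() - t0}
        log.info("connectome: %d features", conn_df.shape[1])

        # --- encode -------------------------------------------------------
        stage = "encode"
        t0 = time.perf_counter()
        model = enc.fit_autoencoder(conn_df.to_numpy(float), config.autoencoder,
                                    rng=seeds["encode"])
        model = enc.prune_sparse_features_with_tol(
            model, conn_df.to_numpy(float), config.autoencoder.sparsity_tol_ratio)
        model_dir = out / "autoencoder"
        enc.save_model(model, model_dir)
        artifacts["autoencoder"] = model_dir / "autoencoder.json"
        X, y = clf.assemble_features(cohort_df, conn_df, model)
        feats_path = out / "features.csv"
        pd.concat([X, y], axis=1).to_csv(feats_path)
        artifacts["features"] = feats_path
        manifest["stages"]["encode"] = {"kept_features": len(model.kept_features or ()),
                                        "best_epoch": model.best_epoch,
                                        "seconds": time.perf_counter() - t0}
        log.info("encode: kept %d of %d code units",
                 len(model.kept_features or ()), model.hidden_dim)

        # --- train --------------------------------------------------------
        stage = "train"
        t0 = time.perf_counter()
        ensemble = clf.train_nested_cv(X, y, config.classifier, rng=seeds["train"])
        report = clf.evaluate(ensemble, X, y)
        pred_path = out / "predictions.csv"
        _write_predictions(ensemble, X, y, pred_path)
        artifacts["predictions"] = pred_path
        acc_path = out / "report.json"
        acc_path.write_text(json.dumps({
            "cv_accuracy": report.cv_accuracy,
            "holdout_accuracy": report.holdout_accuracy,
            "combined_accuracy": report.combined_accuracy,
            "ensemble_accuracy": report.ensemble_accuracy,
            "n_cv": report.n_cv,
            "n_holdout": report.n_holdout,
            "confusion": {k: v.tolist() for k, v in report.confusion.items()},
        }, indent=2))
        artifacts["report"] = acc_path
        manifest["stages"]["train"] = {"cv_accuracy": report.cv_accuracy,
                                       "combined_accuracy": report.combined_accuracy,
                                       "seconds": time.perf_counter() - t0}
        log.info("train: cv %.3f combined %.3f",
                 report.cv_accuracy, report.combined_accuracy)

        # --- importance ---------------------------------------------------
        stage = "importance"
        t0 = time.perf_counter()
        imp_report = imp.importance_report(
            ensemble, X, y, model, conn_df, maps=maps,
            repeats=config.importance_repeats, rng=seeds["importance"])
        imp_path = out / "importance.csv"
        imp_report.to_frame().to_csv(imp_path, index=False)
        artifacts["importance"] = imp_path
        voxel_path = out / "voxel_map.csv"
        np.savetxt(voxel_path, imp_report.voxel_map)
        (out / "voxel_map.json").write_text(json.dumps(
            {"grid_size": int(len(imp_report.voxel_map)),
             "networks": list(imp_report.per_network.index)}))
        artifacts["voxel_map"] = voxel_path
        manifest["stages"]["importance"] = {"seconds": time.perf_counter() - t0}

        # --- report -------------------------------------------------------
        stage = "report"
        t0 = time.perf_counter()
        cv_ids = ensemble.cv_predictions.index
        table = pd.DataFrame({
            "time": cohort_df.set_index("subject_id").loc[cv_ids, "survival_months"],
            "event": cohort_df.set_index("subject_id").loc[cv_ids, "event"],
            "group": ensemble.cv_predictions,
        })
        curves = surv.km_estimate(table)
        km_path = out / "km_curves.csv"
        surv.km_table(curves).to_csv(km_path, index=False)
        artifacts["km_curves"] = km_path
        chi2, df, p = surv.logrank_test(table)
        tests = surv.group_tests(cohort_df)
        tests_path = out / "tests.csv"
        tests.to_csv(tests_path, index=False)
        artifacts["tests"] = tests_path
        manifest["stages"]["report"] = {"logrank_chi2": chi2, "logrank_df": df,
                                        "logrank_p": p,
                                        "seconds": time.perf_counter() - t0}
        log.info("report: log-rank chi2=%.2f p=%.2g", chi2, p)
    except GbmsurvError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["artifacts"] = {name: {"path": str(p.relative_to(out)),
                                    "sha256": _sha256(p)}
                             for name, p in artifacts.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_predictions(ensemble, X, y, path: Path) -> None:
    rows = []
    for sid in ensemble.cv_predictions.index:
        rows.append({"subject_id": sid, "split": "cv",
                     "true_class": y.loc[sid],
                     "predicted_class": ensemble.cv_predictions.loc[sid]})
    if ensemble.holdout_ids:
        Xh = X.loc[list(ensemble.holdout_ids)]
        labels, scores = clf.predict(ensemble, Xh, mode="averaged")
        for i, sid in enumerate(ensemble.holdout_ids):
            row = {"subject_id": sid, "split": "holdout",
                   "true_class": y.loc[sid], "predicted_class": labels[i]}
            row.update({f"score_{c}": scores[i, j]
                        for j, c in enumerate(ensemble.classes)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
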