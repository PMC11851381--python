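"""End-to-end pipeline orchestration.

``run_pipeline`` wires the stages -- phantom cohort, preprocessing, defect
dataset, reconstruction-net training, inference, implant extraction and
evaluation -- under one validated configuration with a single root seed.
Every run writes the resolved config and tool version next to its outputs
so it can be re-run bit-compatibly on the same build.
"""

from __future__ import annotations

import logging
import os
import time

import numpy as np
import yaml

from . import __version__
from .models import ModelConfig, build_reconstruction_net, forward_reconstruct
from .defects import RegionAtlas, SHAPES, REGIONS, build_dataset, realize_case
from .errors import ConfigError, PipelineError
from .evaluate import edge_gap_report, evaluate_suite
from .implant import binarize, clean_implant, extract_implant
from .phantom import PhantomSpec, make_cohort
from .preprocess import PreprocessConfig, preprocess_pipeline
from .train import TrainConfig, train_network
from .volio import write_nrrd

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "out": "craniorec_run",
    "verbosity": 1,
    "phantom": {
        "n_train": 10,
        "n_test": 5,
        "dims": [32, 32, 16],
        "spacing": [4.0, 4.0, 4.0],
        "radii": [42.0, 52.0, 26.0],
        "thickness": 6.0,
        "jitter": 0.1,
        "artefact_plate": False,
        "noise_density": 0.0,
    },
    "preprocess": {
        "enabled": False,
        "threshold": 300.0,
        "median_kernel": 3,
        "skip_align": False,
        "target_dims": None,
    },
    "defects": {
        "shapes": list(SHAPES),
        "regions": list(REGIONS),
        "size_band": [0.15, 0.25],
    },
    "model": {
        "levels": 4,
        "base_channels": 8,
        "growth": 2,
        "enhancement_feature_channels": 16,
        "binarize_tau": 0.5,
    },
    "train": {
        "enabled": True,
        "learning_rate": 1e-3,
        "batch_size": 2,
        "epochs": 2,
        "validation_fraction": 0.1,
    },
    "implant": {"clean": True},
    "evaluate": {"hd_mode": "max", "edge_gap": True, "n_eval": 8},
    "io": {"write_volumes": False},
}


def _merge_validate(user: dict, defaults: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            out[key] = _merge_validate(user.get(key, {}) or {}, dval, f"{path}{key}.")
        else:
            out[key] = user.get(key, dval)
    unknown = [f"{path}{k}" for k in user if k not in defaults]
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return out


def resolve_config(user: dict | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    return _merge_validate(user or {}, DEFAULT_CONFIG)


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
    return result


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full pipeline; returns a summary dict of artifacts.

    Stage order: phantom -> (preprocess) -> defects -> train -> reconstruct
    -> implant -> evaluate.  Raises :class:`PipelineError` naming the first
    failing stage.
    """
    cfg = resolve_config(config)
    seed = int(cfg["seed"])
    out_dir = cfg["out"]
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump({"version": __version__, "config": cfg}, fh)

    pc = cfg["phantom"]
    base = PhantomSpec(
        dims=tuple(pc["dims"]), spacing=tuple(pc["spacing"]),
        radii=tuple(pc["radii"]), thickness=pc["thickness"],
        artefact_plate=pc["artefact_plate"], noise_density=pc["noise_density"],
    )
    n_total = pc["n_train"] + pc["n_test"]
    cohort = _stage("phantom", make_cohort, n_total, base, pc["jitter"], seed)

    if cfg["preprocess"]["enabled"]:
        pp = cfg["preprocess"]
        ppc = PreprocessConfig(
            threshold=pp["threshold"], median_kernel=pp["median_kernel"],
            skip_align=pp["skip_align"],
            target_dims=tuple(pp["target_dims"]) if pp["target_dims"] else None,
        )
        cohort = [_stage("preprocess", preprocess_pipeline, v, ppc) for v in cohort]

    train_skulls = {f"s{i:04d}": v for i, v in enumerate(cohort[: pc["n_train"]])}
    test_skulls = {
        f"s{i + pc['n_train']:04d}": v for i, v in enumerate(cohort[pc["n_train"]:])
    }
    atlas = RegionAtlas()
    dc = cfg["defects"]
    manifest = _stage(
        "defects", build_dataset, train_skulls, test_skulls, atlas,
        tuple(dc["shapes"]), seed, tuple(dc["regions"]),
    )
    skulls = {**train_skulls, **test_skulls}
    size_band = tuple(dc["size_band"])

    def realize(row):
        return realize_case(
            skulls[row.skull_id], row.region, row.shape, int(row.case_seed),
            atlas, size_band,
        )

    if cfg["io"]["write_volumes"]:
        for row in manifest.rows.itertuples():
            pairx = realize(row)
            for sub, vol in (
                (row.defected_path, pairx.defected),
                (row.implant_path, pairx.implant_gt),
            ):
                dest = os.path.join(out_dir, sub)
                os.makedirs(os.path.dirname(dest), exist_ok=True)
                write_nrrd(vol, dest)
        manifest.rows.to_csv(
            os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False
        )

    summary = {
        "out": out_dir,
        "n_train_pairs": manifest.n_train,
        "n_test_pairs": manifest.n_test,
    }

    mc = cfg["model"]
    model_cfg = ModelConfig(
        input_dims=tuple(pc["dims"]), levels=mc["levels"],
        base_channels=mc["base_channels"], growth=mc["growth"],
        enhancement_feature_channels=mc["enhancement_feature_channels"],
        binarize_tau=mc["binarize_tau"],
    )
    if cfg["train"]["enabled"]:
        tc = cfg["train"]
        handle = build_reconstruction_net(model_cfg, seed=seed)
        train_rows = manifest.rows[manifest.rows["split"] == "train"]
        pairs = []
        for row in train_rows.itertuples():
            p = realize(row)
            pairs.append((p.defected, p.healthy))
        tcfg = TrainConfig(
            learning_rate=tc["learning_rate"], batch_size=tc["batch_size"],
            epochs=tc["epochs"], seed=seed,
            validation_fraction=tc["validation_fraction"],
            checkpoint_path=os.path.join(out_dir, "reconstruction.ckpt.npz"),
        )
        handle, history = _stage("train", train_network, handle, pairs, tcfg)
        summary["final_train_loss"] = history.train_loss[-1]

        test_rows = manifest.rows[manifest.rows["split"] == "test"]
        n_eval = min(cfg["evaluate"]["n_eval"], len(test_rows))
        records, gap_overall = [], []
        for row in test_rows.head(n_eval).itertuples():
            p = realize(row)
            prob = _stage("reconstruct", forward_reconstruct, handle, p.defected)
            recon = binarize(prob, model_cfg.binarize_tau, like=p.defected)
            imp = _stage("implant", extract_implant, recon, p.defected)
            if cfg["implant"]["clean"] and imp.count() > 0:
                imp = clean_implant(imp)
            records.append({
                "region": row.region, "shape": row.shape,
                "pred": recon, "truth": p.healthy, "spacing": p.healthy.spacing,
            })
            if cfg["evaluate"]["edge_gap"] and imp.count() > 0:
                gap_overall.append(edge_gap_report(imp, p, seed=seed).overall)
        table = _stage("evaluate", evaluate_suite, records,
                       cfg["evaluate"]["hd_mode"])
        table.to_csv(os.path.join(out_dir, "metrics.tsv"), sep="\t", index=False)
        summary["metrics"] = table
        summary["mean_test_dsc"] = float(
            table.loc[table["region"] == "overall", "dsc"].iloc[0]
        )
        if gap_overall:
            summary["mean_edge_gap_mm"] = float(np.mean(gap_overall))
    return summary
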