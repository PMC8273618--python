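"""End-to-end orchestration: phantom → train → predict → postprocess →
thickness → validate, as one reproducible, self-describing run.

The histology-style chain is: 2D fold-ensemble prediction, probability
threshold, small-region removal, 2D median filter, 2D local thickness.
The micro-CT-style chain is: slice-wise plane-ensemble prediction,
threshold, largest-component sweep, 3D median filter, 3D local thickness.
Every run directory receives the resolved configuration, the global seed,
per-stage artifacts, and a machine-readable ``run.json``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import imgio
from .agreement import bland_altman, dice, pearson
from .grids import GridMetadata
from .inference import InferenceConfig, TileSpec, predict_2d, threshold_probability
from .model import LossConfig, ModelConfig
from .phantom import PhantomSpec, generate_phantom_2d, prescribed_mean_thickness_um
from .postprocess import postprocess_histology
from .thickness import local_thickness, summarize, summary_row
from .training import (
    AugmentationConfig,
    SampleRecord,
    TrainConfig,
    split_by_subject,
    train_cv,
)

log = logging.getLogger("ccmorph")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "modality": "histology",
    "stages": ["phantom", "train", "predict", "thickness", "validate"],
    "phantom": {
        "n_train": 8,
        "n_heldout": 4,
        "shape": [128, 192],
        # per-subject base thickness is drawn from this range (px), emulating
        # the anatomical variation in CC thickness between samples
        "base_thickness_range_px": [14.0, 30.0],
        "amplitude_px": 4.0,
        "spatial_period_px": 96.0,
        "noise_sd": 0.03,
        "void_density_per_1000px": 0.5,
    },
    "train": {
        "n_folds": 4,
        "epochs": 20,
        "batch_size": 4,
        "crops_per_image": 6,
        "learning_rate": 1e-3,
        "tile_shape": [64, 64],
        "model": {"encoder_depth": "small", "base_channels": 16, "normalization": "batch"},
    },
    "infer": {"threshold": 0.8, "window": [64, 64], "step": [32, 32]},
    "postprocess": {"min_region_px": 500, "median_radius_px": 12},
}

_SCHEMA = {
    "seed": int,
    "modality": str,
    "stages": list,
    "phantom": dict,
    "train": dict,
    "infer": dict,
    "postprocess": dict,
}


def validate_config(cfg: dict) -> dict:
    """Merge a user config over the defaults and type-check the top level."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (cfg or {}).items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key {key!r}; known: {sorted(_SCHEMA)}")
        if not isinstance(val, _SCHEMA[key]):
            raise ValueError(f"config key {key!r} must be {_SCHEMA[key].__name__}")
        if isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    unknown_stages = set(merged["stages"]) - {"phantom", "train", "predict", "thickness", "validate"}
    if unknown_stages:
        raise ValueError(f"unknown stages {sorted(unknown_stages)}")
    return merged


def _phantom_spec(cfg: dict, seed: int, shape, base_px: float) -> PhantomSpec:
    return PhantomSpec(
        shape=tuple(shape),
        base_thickness_px=base_px,
        amplitude_px=cfg["amplitude_px"],
        spatial_period_px=cfg["spatial_period_px"],
        noise_sd=cfg["noise_sd"],
        void_density_per_1000px=cfg["void_density_per_1000px"],
        seed=seed,
    )


def generate_phantom_set(cfg: dict, out_dir: Path, seed: int):
    """Write train and held-out phantom cohorts (one subject per phantom).

    Each subject's base band thickness is drawn from
    ``base_thickness_range_px`` so the cohort spans a realistic range of
    CC.Th, giving the recovery correlation something to explain.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(seed)
    n_total = cfg["n_train"] + cfg["n_heldout"]
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(n_total)]
    base_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    lo, hi = cfg["base_thickness_range_px"]
    bases = base_rng.uniform(lo, hi, size=n_total)
    records, heldout = [], []
    truth_rows = []
    meta = GridMetadata(modality_tag="histology")
    for i in range(n_total):
        spec = _phantom_spec(cfg, child_seeds[i], cfg["shape"], float(bases[i]))
        sample = generate_phantom_2d(spec, meta)
        sid = f"phantom{i:02d}"
        img_path = out_dir / f"{sid}_image.png"
        msk_path = out_dir / f"{sid}_mask.png"
        imgio.write_image(sample.image, img_path, bits=16)
        imgio.write_mask(sample.truth_mask, msk_path)
        rec = SampleRecord(sid, subject_id=f"subject{i:02d}", image_path=str(img_path), mask_path=str(msk_path))
        (records if i < cfg["n_train"] else heldout).append(rec)
        truth_rows.append(
            {"sample_id": sid, "prescribed_mean_um": prescribed_mean_thickness_um(sample, meta)}
        )
    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return records, heldout


def run_end_to_end(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stage sequence and return the run summary.

    ``config`` is a mapping or a path to a YAML file; unspecified keys take
    the documented defaults. Any stage error aborts the run with the stage
    name, leaving earlier artifacts in place.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(name)s %(message)s")

    run: dict = {"config": cfg, "seed": cfg["seed"], "stages": {}}
    (out_dir / "config.resolved.yaml").write_text(yaml.safe_dump(cfg))
    stage = "setup"
    t0 = time.time()
    try:
        state: dict = {}
        for stage in cfg["stages"]:
            ts = time.time()
            log.info("stage %s: start", stage)
            _STAGES[stage](cfg, out_dir, state)
            run["stages"][stage] = {"seconds": round(time.time() - ts, 2)}
            log.info("stage %s: done in %.1fs", stage, time.time() - ts)
    except Exception as exc:
        run["error"] = {"stage": stage, "message": str(exc)}
        (out_dir / "run.json").write_text(json.dumps(run, indent=2, default=str))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    run["elapsed_seconds"] = round(time.time() - t0, 2)
    run.update({k: v for k, v in state.items() if k.startswith("result_")})
    (out_dir / "run.json").write_text(json.dumps(run, indent=2, default=str))
    return run


# ---------------------------------------------------------------------------
# stages (each reads/writes the shared ``state`` dict)


def _stage_phantom(cfg, out_dir, state):
    records, heldout = generate_phantom_set(cfg["phantom"], out_dir / "phantoms", cfg["seed"])
    state["records"], state["heldout"] = records, heldout


def _stage_train(cfg, out_dir, state):
    tc = cfg["train"]
    train_cfg = TrainConfig(
        n_folds=tc["n_folds"],
        epochs=tc["epochs"],
        modality=cfg["modality"],
        batch_size=tc["batch_size"],
        learning_rate=tc["learning_rate"],
        seed=cfg["seed"],
        crops_per_image=tc["crops_per_image"],
        tile_shape=tuple(tc["tile_shape"]),
        model=ModelConfig(**tc["model"], seed=cfg["seed"]),
    )
    folds = split_by_subject(state["records"], train_cfg.n_folds, cfg["seed"])
    models, report = train_cv(state["records"], folds, train_cfg, out_dir / "checkpoints")
    state["models"] = list(models.values())
    state["result_cv_mean_dice"] = report["mean_dice"]


def _stage_predict(cfg, out_dir, state):
    ic = cfg["infer"]
    infer = InferenceConfig(tiles=TileSpec(tuple(ic["window"]), tuple(ic["step"])), threshold=ic["threshold"])
    pp = cfg["postprocess"]
    pred_dir = out_dir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    state["pred_masks"] = {}
    for rec in state["heldout"]:
        img = imgio.read_image(rec.image_path, GridMetadata(modality_tag="histology"))
        pmap = predict_2d(img, state["models"], infer)
        mask = threshold_probability(pmap, infer.threshold)
        mask = postprocess_histology(mask, pp["min_region_px"], pp["median_radius_px"])
        imgio.write_mask(mask, pred_dir / f"{rec.sample_id}_pred.png")
        np.save(pred_dir / f"{rec.sample_id}_prob.npy", pmap.values)
        state["pred_masks"][rec.sample_id] = mask


def _stage_thickness(cfg, out_dir, state):
    from .thickness import ThicknessSummary

    rows = []
    state["recovered_um"] = {}
    for sid, mask in state["pred_masks"].items():
        if mask.values.any():
            summ = summarize(local_thickness(mask))
        else:
            # an empty segmentation is a recordable failure, not a crash
            log.warning("sample %s: empty predicted mask, no thickness", sid)
            nan = float("nan")
            summ = ThicknessSummary(nan, nan, nan, nan, 0, mask.meta.pixel_size_um)
        rows.append(summary_row(summ, sid))
        state["recovered_um"][sid] = summ.mean_um
    imgio.write_summary_table(rows, out_dir / "thickness_summary.csv")


def _stage_validate(cfg, out_dir, state):
    import pandas as pd

    truth = pd.read_csv(out_dir / "phantoms" / "truth.csv").set_index("sample_id")
    dices, pres, recs = {}, [], []
    for rec in state["heldout"]:
        truth_mask = imgio.read_mask(rec.mask_path)
        dices[rec.sample_id] = dice(state["pred_masks"][rec.sample_id], truth_mask)
        pres.append(float(truth.loc[rec.sample_id, "prescribed_mean_um"]))
        recs.append(state["recovered_um"][rec.sample_id])
    report = {
        "heldout_dice": dices,
        "heldout_mean_dice": float(np.mean(list(dices.values()))),
        "prescribed_um": pres,
        "recovered_um": recs,
    }
    if len(pres) >= 3 and np.std(pres) > 0 and np.std(recs) > 0:
        r, p = pearson(pres, recs)
        ba = bland_altman(recs, pres)
        report.update({"pearson_r": r, "pearson_p": p, "bias_um": ba.bias, "sd_diff_um": ba.sd_diff})
    (out_dir / "validation.json").write_text(json.dumps(report, indent=2))
    state["result_validation"] = report


_STAGES = {
    "phantom": _stage_phantom,
    "train": _stage_train,
    "predict": _stage_predict,
    "thickness": _stage_thickness,
    "validate": _stage_validate,
}


# ---------------------------------------------------------------------------
# the scaled phantom recovery study


def run_phantom_recovery_study(seed: int, out_dir: str | Path, overrides: dict | None = None) -> dict:
    """Train on a phantom cohort and measure how well CC.Th is recovered.

    Generates the train + held-out cohorts, trains the fold models, then
    runs the full histology chain (ensemble prediction for held-out
    samples, out-of-fold prediction for training samples, threshold,
    small-region removal, median filter, 2D local thickness) and compares
    recovered against prescribed mean thickness for every phantom.

    Returns held-out Dice scores, per-phantom relative thickness errors,
    the Pearson correlation of prescribed vs recovered means over the whole
    cohort, and the corresponding Bland–Altman agreement.
    """
    cfg = validate_config({"seed": seed, **(overrides or {})})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records, heldout = generate_phantom_set(cfg["phantom"], out_dir / "phantoms", seed)

    tc = cfg["train"]
    train_cfg = TrainConfig(
        n_folds=tc["n_folds"],
        epochs=tc["epochs"],
        modality=cfg["modality"],
        batch_size=tc["batch_size"],
        learning_rate=tc["learning_rate"],
        seed=seed,
        crops_per_image=tc["crops_per_image"],
        tile_shape=tuple(tc["tile_shape"]),
        model=ModelConfig(**tc["model"], seed=seed),
    )
    folds = split_by_subject(records, train_cfg.n_folds, seed)
    models, cv_report = train_cv(records, folds, train_cfg, out_dir / "checkpoints")

    ic, pp = cfg["infer"], cfg["postprocess"]
    infer = InferenceConfig(tiles=TileSpec(tuple(ic["window"]), tuple(ic["step"])), threshold=ic["threshold"])

    import pandas as pd

    truth = pd.read_csv(out_dir / "phantoms" / "truth.csv").set_index("sample_id")

    def _predict_mask(rec, member_models):
        img = imgio.read_image(rec.image_path, GridMetadata(modality_tag="histology"))
        pmap = predict_2d(img, member_models, infer)
        mask = threshold_probability(pmap, infer.threshold)
        return postprocess_histology(mask, pp["min_region_px"], pp["median_radius_px"])

    prescribed, recovered, rel_err = {}, {}, {}
    heldout_dice = {}
    empty_predictions = []

    def _measure(sid, mask):
        prescribed[sid] = float(truth.loc[sid, "prescribed_mean_um"])
        if mask.values.any():
            recovered[sid] = summarize(local_thickness(mask)).mean_um
        else:
            # an empty segmentation is recorded, not silently dropped
            empty_predictions.append(sid)
            recovered[sid] = float("nan")

    for rec in heldout:  # held-out: full fold ensemble
        mask = _predict_mask(rec, list(models.values()))
        heldout_dice[rec.sample_id] = dice(mask, imgio.read_mask(rec.mask_path))
        _measure(rec.sample_id, mask)
    for rec in records:  # training cohort: out-of-fold model only
        k = folds.fold_of(rec.subject_id)
        _measure(rec.sample_id, _predict_mask(rec, [models[k]]))

    for sid in prescribed:
        rel_err[sid] = (recovered[sid] - prescribed[sid]) / prescribed[sid]

    sids = sorted(sid for sid in prescribed if sid not in empty_predictions)
    pres = [prescribed[s] for s in sids]
    recs = [recovered[s] for s in sids]
    r, p = pearson(pres, recs)
    ba = bland_altman(recs, pres)
    heldout_err = {s: rel_err[s] for s in heldout_dice}
    result = {
        "cv_mean_dice": cv_report["mean_dice"],
        "heldout_dice": heldout_dice,
        "heldout_mean_dice": float(np.mean(list(heldout_dice.values()))),
        "prescribed_um": dict(zip(sids, pres)),
        "recovered_um": dict(zip(sids, recs)),
        "rel_err": rel_err,
        "heldout_max_abs_rel_err": float(max(abs(e) for e in heldout_err.values())),
        "pearson_r": r,
        "pearson_p": p,
        "bias_um": ba.bias,
        "sd_diff_um": ba.sd_diff,
        "n_phantoms": len(sids),
        "empty_predictions": empty_predictions,
    }
    (out_dir / "recovery_study.json").write_text(json.dumps(result, indent=2))
    return result
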