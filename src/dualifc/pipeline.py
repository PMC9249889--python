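"""End-to-end pipeline: simulate -> preprocess -> extract -> bench -> cv-unet.

A YAML (or dict) configuration names the stages to run and their
parameters; every artifact a stage writes is listed in a manifest JSON that
also records the configuration hash and master seed, so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import bench as bench_mod
from . import features as features_mod
from . import preprocess as preprocess_mod
from .data import read_dataset, write_dataset
from .nn import TrainingConfig, cross_validate, desk_arch, desk_config
from .phantom import PRESETS, ClassParams, CohortDesign, generate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "extract", "bench", "cv-unet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def _design_from_config(cfg: dict, seed: int) -> CohortDesign:
    preset = cfg.get("preset", "default")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    params = {label: ClassParams(**{**vars(p), **cfg.get(label, {})})
              for label, p in PRESETS[preset].items()}
    return CohortDesign(
        cells_per_subject=int(cfg.get("cells_per_subject", 100)),
        n_subjects_per_class=int(cfg.get("n_subjects_per_class", 2)),
        cell_type=cfg.get("cell_type", "HSC"),
        class_params_map=params,
        seed=seed,
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    The config must contain ``stages`` (ordered subset of
    simulate/preprocess/extract/bench/cv-unet) and may contain a ``seed``
    plus one section per stage. Validation happens before any stage runs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages = config.get("stages")
    if not stages:
        raise PipelineError("config must name at least one stage under 'stages'")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in stages]
    if ordered != list(stages):
        raise PipelineError(f"stages must appear in pipeline order {STAGES}")
    # each stage needs its input stage (or an explicit input file)
    for stage, needs in (("preprocess", "simulate"), ("extract", "preprocess"),
                         ("cv-unet", "preprocess"), ("bench", "extract")):
        section = config.get(stage, {}) or {}
        if stage in stages and needs not in stages and "input" not in section:
            raise PipelineError(f"stage {stage!r} needs stage {needs!r} or an 'input' file")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": list(ordered),
        "artifacts": {},
    }
    dataset = None
    table = None

    for stage in ordered:
        cfg = config.get(stage, {}) or {}
        log.info("pipeline stage %s (seed=%d)", stage, seed)
        try:
            if stage == "simulate":
                design = _design_from_config(cfg, seed)
                dataset = generate_cohort(design)
                path = out_dir / "dataset.h5"
                write_dataset(dataset, path)
                manifest["artifacts"]["dataset"] = str(path)
            elif stage == "preprocess":
                if dataset is None:
                    dataset = read_dataset(cfg["input"])
                dataset = preprocess_mod.remove_background_dataset(
                    dataset, tau=float(cfg.get("tau", 0.05))
                )
                dataset = preprocess_mod.normalize_global(dataset)
                if "n_per_subject" in cfg:
                    dataset = preprocess_mod.balance_sample(
                        dataset, int(cfg["n_per_subject"]), seed
                    ).materialize()
                path = out_dir / "preprocessed.h5"
                write_dataset(dataset, path)
                manifest["artifacts"]["preprocessed"] = str(path)
            elif stage == "extract":
                if dataset is None:
                    dataset = read_dataset(cfg["input"])
                frame = features_mod.extract_table(
                    dataset, tau=float(cfg.get("tau", 0.05)),
                    transmission_is_absorbance=True,
                )
                table = features_mod.FeatureTable(frame=frame)
                path = out_dir / "features.csv"
                features_mod.write_features(table, path)
                manifest["artifacts"]["features"] = str(path)
            elif stage == "bench":
                if table is None:
                    table = features_mod.read_features(cfg["input"])
                folds = bench_mod.stratified_folds(
                    table.labels, k=int(cfg.get("k", 4)), seed=seed,
                    subjects=table.frame["subject_id"].to_numpy(),
                )
                results = bench_mod.benchmark(table, folds, seed=seed)
                path = out_dir / "bench.json"
                with open(path, "w") as f:
                    json.dump({name: r.to_dict() for name, r in results.items()}, f, indent=1)
                manifest["artifacts"]["bench"] = str(path)
            elif stage == "cv-unet":
                if dataset is None:
                    dataset = read_dataset(cfg["input"])
                tc = desk_config(seed=seed, epochs=int(cfg.get("epochs", 10)))
                if cfg.get("paper_schedule"):
                    tc = TrainingConfig(seed=seed)
                result, histories = cross_validate(
                    dataset, arch=desk_arch(), config=tc, k=int(cfg.get("k", 4))
                )
                path = out_dir / "cv_unet.json"
                with open(path, "w") as f:
                    json.dump({"result": result.to_dict(), "histories": histories}, f, indent=1)
                manifest["artifacts"]["cv_unet"] = str(path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=1)
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest
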