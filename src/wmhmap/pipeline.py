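"""End-to-end orchestration: simulate -> volumes -> models -> voxel maps -> association.

Stages communicate through files in a run directory (cohort CSV + NIfTI mask
trees), so each stage can also be run in isolation from the CLI.  Every run
writes a manifest recording each artifact with its SHA-256 checksum, the
configuration hash, and the per-stage seeds, which are derived from the
single global seed by hashing the stage name — rerunning any stage with the
same config reproduces its outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (build_change_features, encode_response,
                          fit_sgd_ridge, rescale_for_display)
from .cohort_stats import ModelSpec, derive_model_columns, fit_ancova, fit_linear
from .imaging import build_4d, read_cohort, read_mask, write_statmap, write_volume
from .synthetic import GeneratorConfig, generate_cohort
from .volumetrics import evolution_mask, summarize_by_location
from .voxel_stats import default_battery, run_contrast_battery

MASK_KINDS = ("wmh_baseline", "wmh_intense", "wmh_less_intense",
              "wmh_followup", "rssi", "old_lesion")


class DependencyError(RuntimeError):
    """A stage's required input artifact is missing."""


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_subjects: int = 118
    grid_dims: tuple[int, int, int] = (32, 32, 32)
    voxel_dims_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    input_dir: str | None = None      # use existing data instead of simulating
    min_overlap: int = 2
    alphas: tuple[float, ...] = (0.05, 0.01)
    lam: float = 1.0 / 47.0
    epsilon: float | None = None
    epochs: int = 50
    stages: tuple[str, ...] = ("simulate", "volumes", "stats", "voxelmap",
                               "associate", "report")

    def __post_init__(self) -> None:
        for a in self.alphas:
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha not in (0,1): {a}")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(f"input_dir does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_dims", "voxel_dims_mm", "alphas", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunData:
    """In-memory view of a run directory's inputs."""

    table: pd.DataFrame
    masks: dict          # kind -> {subject_id: LesionMask}
    voxel_dims_mm: tuple[float, float, float]


def load_inputs(data_dir: str | Path) -> RunData:
    data_dir = Path(data_dir)
    cohort_path = data_dir / "cohort.csv"
    if not cohort_path.exists():
        raise DependencyError(f"missing required artifact: {cohort_path}")
    table = read_cohort(cohort_path)
    masks: dict = {}
    vox = None
    for kind in MASK_KINDS:
        kind_dir = data_dir / "masks" / kind
        masks[kind] = {}
        if not kind_dir.exists():
            continue
        for p in sorted(kind_dir.glob("*.nii.gz")):
            m = read_mask(p)
            masks[kind][p.name.removesuffix(".nii.gz")] = m
            vox = m.voxel_dims_mm
    if not masks["wmh_baseline"]:
        raise DependencyError(
            f"missing required artifact: {data_dir / 'masks' / 'wmh_baseline'}"
        )
    return RunData(table=table, masks=masks, voxel_dims_mm=vox)


def stage_simulate(config: RunConfig) -> Path:
    gen = GeneratorConfig(
        n_subjects=config.n_subjects,
        grid_dims=config.grid_dims,
        voxel_dims_mm=config.voxel_dims_mm,
        seed=stage_seed(config.seed, "simulate"),
    )
    cohort = generate_cohort(gen)
    inputs = Path(config.out_dir) / "inputs"
    cohort.write(inputs)
    return inputs


def stage_volumes(data: RunData, outdir: Path) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for feature, name in (("RSSI", "volumes_rssi.csv"),
                          ("lacunes", "volumes_lacunes.csv")):
        table = summarize_by_location(data.table, feature)
        p = outdir / name
        table.to_csv(p, index=False)
        written.append(p)
    # per-subject evolution accounting for the followed-up subsample
    rows = []
    for sid, base in data.masks["wmh_baseline"].items():
        fu = data.masks["wmh_followup"].get(sid)
        if fu is None:
            continue
        emap = evolution_mask(base, fu)
        rows.append({
            "subject_id": sid,
            "regressed_ml": emap.volume_ml(1),
            "stable_ml": emap.volume_ml(2),
            "progressed_ml": emap.volume_ml(3),
            "change_ml": emap.volume_ml(3) - emap.volume_ml(1),
        })
    p = outdir / "evolution_volumes.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    written.append(p)
    return written


_MODEL_VARIANTS = {
    # the three stated covariate variants of the subject-level models
    "wmh_on_lacunes_age": ModelSpec(
        "wmh_pct_icv_baseline", ["lacune_count", "age"]),
    "wmh_on_lacunes_age_risks": ModelSpec(
        "wmh_pct_icv_baseline",
        ["lacune_count", "age", "diabetes", "hypertension", "hyperlipidemia",
         "smoker"]),
    "wmh_on_rssi_age_risks": ModelSpec(
        "wmh_pct_icv_baseline",
        ["rssi_pct_icv", "age", "lacune_count", "diabetes", "hypertension",
         "hyperlipidemia", "smoker"]),
    "change_on_rssi_age_lacunes": ModelSpec(
        "wmh_change_ml", ["rssi_volume_ml", "age", "lacune_count"]),
    "change_on_rssi_full": ModelSpec(
        "wmh_change_ml",
        ["rssi_volume_ml", "age", "lacune_count", "diabetes", "hypertension",
         "hyperlipidemia", "smoker", "old_pct_icv"]),
}


def stage_cohort_stats(data: RunData, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    df = derive_model_columns(data.table)
    frames = []
    for name, spec in _MODEL_VARIANTS.items():
        fit = (fit_ancova if name.startswith("change") else fit_linear)(df, spec)
        terms = fit.terms.copy()
        terms.insert(0, "model", name)
        terms["n_used"] = fit.n_used
        terms["r_squared"] = fit.r_squared
        frames.append(terms)
    p = outdir / "models.csv"
    pd.concat(frames, ignore_index=True).to_csv(p, index=False)
    return p


def stage_voxelmap(data: RunData, outdir: Path, min_overlap: int,
                   alphas: tuple[float, ...]) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    ids = list(data.masks["wmh_baseline"])
    stack = build_4d([data.masks["wmh_baseline"][s] for s in ids], ids)
    battery, maps = run_contrast_battery(
        stack, data.table, default_battery(), min_overlap=min_overlap,
        alphas=alphas,
    )
    p = outdir / "voxelwise_battery.csv"
    battery.to_csv(p, index=False)
    for label, statmap in maps.items():
        safe = label.replace("/", "-").replace(" ", "_")
        write_statmap(statmap, outdir / "maps" / safe)
    return p


def stage_associate(data: RunData, outdir: Path, lam: float,
                    epsilon: float | None, epochs: int, seed: int) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    followed = [sid for sid in data.masks["wmh_baseline"]
                if sid in data.masks["wmh_followup"]]
    if not followed:
        raise DependencyError("missing required artifact: masks/wmh_followup/*")
    emaps = {
        sid: evolution_mask(data.masks["wmh_baseline"][sid],
                            data.masks["wmh_followup"][sid])
        for sid in followed
    }
    union = np.zeros(emaps[followed[0]].grid_dims, dtype=bool)
    for emap in emaps.values():
        union |= emap.codes > 0
    features = build_change_features(emaps, union)
    sub = data.table.set_index("subject_id").loc[followed].reset_index()
    y = encode_response(sub, mode="location_code")
    age = sub["age"].to_numpy(dtype=float)
    amap = fit_sgd_ridge(features, y, covariates=age[:, None], lam=lam,
                         epsilon=epsilon, epochs=epochs, seed=seed)
    write_volume(amap.weights, amap.voxel_dims_mm, outdir / "association_weights.nii.gz")
    pos, neg, _ = rescale_for_display(amap)
    write_volume(pos, amap.voxel_dims_mm, outdir / "association_positive_display.nii.gz")
    write_volume(neg, amap.voxel_dims_mm, outdir / "association_negative_display.nii.gz")
    meta = outdir / "association_fit.json"
    meta.write_text(json.dumps({
        "n_subjects": len(followed),
        "n_voxels": features.n_voxels,
        "intercept": amap.intercept,
        "covariate_weights": amap.covariate_weights,
        "hyperparameters": amap.hyperparameters,
    }, indent=2))
    return meta


def stage_report(data: RunData, outdir: Path) -> Path:
    """Box-plot summary data (group, median, quartiles) per location/timepoint."""
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for feature in ("RSSI", "lacunes"):
        t = summarize_by_location(data.table, feature)
        frames.append(t[["feature", "region", "timepoint", "n",
                         "total_median_ml", "total_q1_ml", "total_q3_ml",
                         "descriptive_only"]])
    p = outdir / "boxplot_summaries.csv"
    pd.concat(frames, ignore_index=True).to_csv(p, index=False)
    return p


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order; write the manifest.

    A stage failure aborts the run with the failing stage named; artifacts of
    completed stages are retained and flagged in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "stages": {},
        "artifacts": [],
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, status: str) -> None:
        manifest["stages"][stage] = status

    data: RunData | None = None
    inputs_dir = Path(config.input_dir) if config.input_dir else out / "inputs"
    try:
        for stage in config.stages:
            if stage == "simulate":
                if config.input_dir is None:
                    inputs_dir = stage_simulate(config)
                record(stage, "ok")
                continue
            if data is None:
                data = load_inputs(inputs_dir)
            if stage == "volumes":
                stage_volumes(data, out / "tables")
            elif stage == "stats":
                stage_cohort_stats(data, out / "tables")
            elif stage == "voxelmap":
                stage_voxelmap(data, out / "voxelmap", config.min_overlap,
                               config.alphas)
            elif stage == "associate":
                stage_associate(data, out / "association", config.lam,
                                config.epsilon, config.epochs,
                                stage_seed(config.seed, "associate"))
            elif stage == "report":
                stage_report(data, out / "report")
            else:
                raise ValueError(f"unknown stage: {stage!r}")
            record(stage, "ok")
    except Exception as exc:
        record(stage, f"failed: {exc}")
        manifest["failed_stage"] = stage
        _finalize_manifest(manifest, out, manifest_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _finalize_manifest(manifest, out, manifest_path)
    return manifest_path


def _finalize_manifest(manifest: dict, out: Path, manifest_path: Path) -> None:
    artifacts = []
    for p in sorted(out.rglob("*")):
        if p.is_file() and p != manifest_path:
            artifacts.append({
                "path": str(p.relative_to(out)),
                "sha256": _sha256(p),
            })
    manifest["artifacts"] = artifacts
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
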