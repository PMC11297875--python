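"""Experiment orchestration: config, seeding, stage chaining, serialization.

An experiment is one YAML config executed as a chain of stages
(``generate -> train -> measure -> analyze -> ablate``) that communicate
only through files in per-stage subdirectories of the output directory.
Every stage's randomness is seeded deterministically from one master seed,
so re-running a config reproduces identical results; a manifest records the
config, seeds and a canonical checksum of every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ablation import ablate_cumulative, ablation_gap
from .attribution import measure_model, measures_frame, MeasurePoint
from .errors import CorruptionError, DependencyError, StageError, ValidationError
from .mode_analysis import powerlaw_fit, slope_curve
from .synthetic_data import (DatasetSpec, load_dataset, make_dataset,
                             save_dataset, save_label_manifest, subset)
from .training import (DecayInitScheme, TrainConfig, crossvalidate,
                       load_model, save_model)

logger = logging.getLogger("spikemode")

STAGES = ("generate", "train", "measure", "analyze", "ablate")


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-stage seed: first 8 hex digits of sha256('master:label')."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).hexdigest()
    return int(digest[:8], 16)


@dataclasses.dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment."""

    master_seed: int = 0
    dataset: DatasetSpec | None = None
    dataset_path: str | None = None
    n_steps: int = 100
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    decay: DecayInitScheme = dataclasses.field(
        default_factory=lambda: DecayInitScheme(mode="binned_uniform"))
    run_measures: bool = True
    run_slopes: bool = True
    run_powerlaw: bool = True
    run_ablation: bool = True
    measure_max_samples: int | None = 128
    test_fraction: float = 0.25

    def __post_init__(self):
        if (self.dataset is None) == (self.dataset_path is None):
            raise ValidationError(
                "config needs exactly one of a dataset spec or a dataset path")

    @classmethod
    def from_yaml(cls, path, master_seed: int | None = None) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls.from_dict(raw, master_seed=master_seed)

    @classmethod
    def from_dict(cls, raw: dict, master_seed: int | None = None):
        master = master_seed if master_seed is not None else raw.get("master_seed", 0)
        ds_raw = raw.get("dataset", {})
        spec = path = None
        if isinstance(ds_raw, str) or "path" in ds_raw:
            path = ds_raw if isinstance(ds_raw, str) else ds_raw["path"]
        else:
            ds_raw = dict(ds_raw)
            ds_raw.setdefault("seed", derive_seed(master, "data"))
            spec = DatasetSpec(**ds_raw)
        train_raw = dict(raw.get("train", {}))
        train_raw.setdefault("seed", derive_seed(master, "train"))
        train_raw.setdefault("n_steps", raw.get("encoding", {}).get("n_steps", 100))
        decay_raw = dict(raw.get("decay", {"mode": "binned_uniform"}))
        if "decay_range" in decay_raw:
            decay_raw["decay_range"] = tuple(decay_raw["decay_range"])
        analysis = raw.get("analysis", {})
        return cls(
            master_seed=master, dataset=spec, dataset_path=path,
            n_steps=train_raw["n_steps"],
            train=TrainConfig(**train_raw),
            decay=DecayInitScheme(**decay_raw),
            run_measures=analysis.get("measures", True),
            run_slopes=analysis.get("slopes", True),
            run_powerlaw=analysis.get("powerlaw", True),
            run_ablation=analysis.get("ablation", True),
            measure_max_samples=analysis.get("measure_max_samples", 128),
            test_fraction=raw.get("test_fraction", 0.25),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # plain types only


# ---------------------------------------------------------------------------
# Canonical checksums (content-based so HDF5 header noise is irrelevant)
# ---------------------------------------------------------------------------

def artifact_checksum(path) -> str:
    """Canonical sha256 of an artifact's content.

    CSV/JSON/YAML files hash their bytes; HDF5 files hash dataset names,
    values and sorted attributes, which is stable across h5py versions and
    independent of file-level metadata.
    """
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            def visit(name, obj):
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    h.update(np.ascontiguousarray(obj[...]).tobytes())
                for k in sorted(obj.attrs):
                    h.update(f"{k}={obj.attrs[k]!r}".encode())
            f.visititems(visit)
            for k in sorted(f.attrs):
                h.update(f"{k}={f.attrs[k]!r}".encode())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages (file-in, file-out)
# ---------------------------------------------------------------------------

def stage_generate(config: ExperimentConfig, out: Path) -> None:
    d = out / "data"
    d.mkdir(parents=True, exist_ok=True)
    if config.dataset_path:
        ds = load_dataset(config.dataset_path)
    else:
        ds = make_dataset(config.dataset)
    save_dataset(ds, d / "dataset.h5")
    save_label_manifest(ds, d / "labels.csv")


def _load_stage_dataset(out: Path):
    path = out / "data" / "dataset.h5"
    if not path.exists():
        raise DependencyError("generate", "run the generate stage first "
                              f"(missing {path})")
    return load_dataset(path)


def stage_train(config: ExperimentConfig, out: Path) -> None:
    ds = _load_stage_dataset(out)
    d = out / "models"
    d.mkdir(parents=True, exist_ok=True)
    results, summary = crossvalidate(ds, config.train, config.decay)
    rows, fold_rows = [], []
    for model, metrics, te_idx in results:
        save_model(model, d / f"fold_{model.fold_id}.json",
                   d / f"fold_{model.fold_id}.h5")
        rows.append({"fold": model.fold_id, **metrics.as_dict()})
        fold_rows.extend({"fold": model.fold_id, "sample": int(i)}
                         for i in te_idx)
    pd.DataFrame(rows).to_csv(d / "metrics.csv", index=False)
    pd.DataFrame(fold_rows).to_csv(d / "folds.csv", index=False)
    with open(d / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)


def _load_fold_models(config: ExperimentConfig, out: Path):
    d = out / "models"
    if not (d / "folds.csv").exists():
        raise DependencyError("train", "run the train stage first "
                              f"(missing {d / 'folds.csv'})")
    folds = pd.read_csv(d / "folds.csv")
    models = {}
    for fold in sorted(folds["fold"].unique()):
        models[int(fold)] = load_model(d / f"fold_{fold}.json",
                                       d / f"fold_{fold}.h5")
    return models, folds


def stage_measure(config: ExperimentConfig, out: Path) -> None:
    ds = _load_stage_dataset(out)
    models, folds = _load_fold_models(config, out)
    d = out / "measures"
    d.mkdir(parents=True, exist_ok=True)
    frames = []
    for fold, model in models.items():
        te_idx = folds.loc[folds["fold"] == fold, "sample"].to_numpy()
        pts = measure_model(model, subset(ds, te_idx),
                            seed=derive_seed(config.master_seed,
                                             f"measure:{fold}"),
                            max_samples=config.measure_max_samples,
                            fold_id=fold)
        frames.append(measures_frame(pts))
    pd.concat(frames, ignore_index=True).to_csv(d / "measures.csv", index=False)


def stage_analyze(config: ExperimentConfig, out: Path) -> None:
    path = out / "measures" / "measures.csv"
    if not path.exists():
        raise DependencyError("measure", f"missing {path}")
    df = pd.read_csv(path)
    points = [MeasurePoint(decay_time=r.decay_time_ms,
                           mean_n_contributing=r.mean_n_contributing,
                           mean_interval=r.mean_interval_ms,
                           neuron=int(r.neuron),
                           n_spikes_observed=int(r.n_spikes))
              for r in df.itertuples()]
    d = out / "analysis"
    d.mkdir(parents=True, exist_ok=True)
    curve = slope_curve(points)
    curve.frame().to_csv(d / "slopes.csv", index=False)
    if config.run_powerlaw:
        fit = powerlaw_fit(curve)
        with open(d / "powerlaw.json", "w") as f:
            json.dump(fit.as_dict(), f, indent=2, sort_keys=True)


def stage_ablate(config: ExperimentConfig, out: Path) -> None:
    ds = _load_stage_dataset(out)
    models, folds = _load_fold_models(config, out)
    d = out / "ablation"
    d.mkdir(parents=True, exist_ok=True)
    fold = min(models)
    model = models[fold]
    te_idx = folds.loc[folds["fold"] == fold, "sample"].to_numpy()
    test_ds = subset(ds, te_idx)
    seed = derive_seed(config.master_seed, "ablate")
    asc = ablate_cumulative(model, test_ds, "ascending", seed=seed)
    desc = ablate_cumulative(model, test_ds, "descending", seed=seed)
    pd.concat([asc.frame(), desc.frame()], ignore_index=True).to_csv(
        d / "ablation.csv", index=False)
    with open(d / "gap.json", "w") as f:
        json.dump({"gap": ablation_gap(asc, desc), "fold": fold},
                  f, indent=2, sort_keys=True)


def _enabled_stages(config: ExperimentConfig):
    stages = [("generate", stage_generate), ("train", stage_train)]
    if config.run_measures:
        stages.append(("measure", stage_measure))
    if config.run_slopes or config.run_powerlaw:
        stages.append(("analyze", stage_analyze))
    if config.run_ablation:
        stages.append(("ablate", stage_ablate))
    return stages


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Execute all enabled stages and write the manifest.

    Any stage failure halts the run, leaves partial outputs in place next
    to a ``FAILED`` marker naming the stage, and re-raises as
    :class:`StageError`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    for name, fn in _enabled_stages(config):
        t0 = time.monotonic()
        try:
            fn(config, out)
        except Exception as exc:
            failed_marker.write_text(f"stage: {name}\nerror: {exc}\n")
            if isinstance(exc, (StageError, DependencyError)):
                raise
            raise StageError(name, str(exc)) from exc
        logger.info("stage %s finished in %.2fs", name, time.monotonic() - t0)
    write_manifest(config, out)
    return out


def write_manifest(config: ExperimentConfig, out: Path) -> None:
    artifacts = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.suffix in (".csv", ".json", ".h5", ".hdf5") \
                and path.name != "manifest.json":
            artifacts[str(path.relative_to(out))] = artifact_checksum(path)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "derived_seeds": {label: derive_seed(config.master_seed, label)
                          for label in ("data", "train", "ablate")},
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)


def load_results(out_dir) -> dict:
    """Round-trip every recorded artifact, verifying canonical checksums.

    Returns a nested record keyed by relative path (DataFrames for CSV,
    dicts for JSON, arrays for HDF5 datasets). Missing optional stages are
    simply absent; a checksum mismatch raises :class:`CorruptionError`.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise DependencyError("manifest", f"no manifest at {manifest_path}")
    with open(manifest_path) as f:
        manifest = json.load(f)
    record = {"manifest": manifest}
    for rel, checksum in manifest["artifacts"].items():
        path = out / rel
        if not path.exists():
            raise CorruptionError(f"artifact {rel} recorded but missing")
        actual = artifact_checksum(path)
        if actual != checksum:
            raise CorruptionError(
                f"artifact {rel}: checksum {actual} != recorded {checksum}")
        if path.suffix == ".csv":
            record[rel] = pd.read_csv(path)
        elif path.suffix == ".json":
            with open(path) as f:
                record[rel] = json.load(f)
        else:
            with h5py.File(path, "r") as f:
                data = {}
                f.visititems(lambda name, obj: data.__setitem__(
                    name, obj[...]) if isinstance(obj, h5py.Dataset) else None)
                record[rel] = data
    return record
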