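"""Dataset loading, run configuration, model persistence, pipeline glue.

Datasets follow the ``class_XXXX/session_Y/sample_Z.png`` layout or carry
a ``manifest.csv`` with columns ``class_id,session,sample,path[,mask_path,
seed]``.  The single-sample split is always the same: the first sample of
session 1 enrolls a class, all later-session samples are probes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, UnidentifiedImageError

from veinsemble.ensemble import (
    EnsembleModel,
    TrainConfig,
    evaluate,
    featurize_samples,
    train_basic,
    train_full,
    train_shared,
)
from veinsemble.feature_maps import GaborBank, LbpParams
from veinsemble.similarity import (
    FsimParams,
    PhaseCongruencyParams,
    SimilarityMatrix,
    similarity_matrix_from_maps,
)
from veinsemble.synthetic_data import VeinSample, generate_dataset
from veinsemble.weak_classifier import load_classifier, save_classifier

__all__ = [
    "DatasetManifest",
    "RunConfig",
    "load_dataset",
    "load_ensemble",
    "run_pipeline",
    "save_ensemble",
]

logger = logging.getLogger("veinsemble")

_REGIMES = {"basic": train_basic, "shared": train_shared, "full": train_full}


@dataclass
class DatasetManifest:
    """Table of (class_id, session, sample, path) rows plus the split rule."""

    table: pd.DataFrame
    root: Path
    split_rule: str = "sspp: train = session-1 sample-1; test = sessions >= 2"


def _read_gray(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as img:
            return np.asarray(img.convert("L"))
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc


_DIR_PATTERN = re.compile(
    r"class_(\d+)/session_(\d+)/sample_(\d+)\.(png|bmp)$", re.IGNORECASE
)


def _scan_directory(root: Path) -> pd.DataFrame:
    rows = []
    for path in sorted(root.rglob("sample_*.png")) + sorted(root.rglob("sample_*.bmp")):
        rel = path.relative_to(root).as_posix()
        match = _DIR_PATTERN.search(rel)
        if match is None:
            continue
        rows.append(
            {
                "class_id": int(match.group(1)),
                "session": int(match.group(2)),
                "sample": int(match.group(3)),
                "path": rel,
                "mask_path": "",
                "seed": 0,
            }
        )
    if not rows:
        raise ValueError(
            f"no images found under {root}; expected "
            "class_XXXX/session_Y/sample_Z.png or a manifest.csv"
        )
    return pd.DataFrame(rows)


def load_dataset(
    path: str | Path,
) -> tuple[list[VeinSample], list[VeinSample], DatasetManifest]:
    """Load a dataset and apply the single-sample split.

    ``path`` is a dataset directory (with or without ``manifest.csv``) or
    a manifest CSV file.  Returns ``(train, test, manifest)`` with train
    sorted by class id.
    """
    path = Path(path)
    if path.is_file():
        manifest_path, root = path, path.parent
        table = pd.read_csv(manifest_path)
    elif (path / "manifest.csv").exists():
        root = path
        table = pd.read_csv(path / "manifest.csv")
    elif path.is_dir():
        root = path
        table = _scan_directory(root)
    else:
        raise FileNotFoundError(f"dataset path {path} does not exist")

    required = {"class_id", "session", "sample", "path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")

    ids = np.sort(table["class_id"].unique())
    remap = {int(c): i for i, c in enumerate(ids)}
    no_enroll = [
        int(c)
        for c in ids
        if not ((table["class_id"] == c) & (table["session"] == 1)).any()
    ]
    if no_enroll:
        raise ValueError(
            f"classes without a session-1 enrollment sample: {no_enroll}"
        )

    samples = []
    for row in table.itertuples(index=False):
        image = _read_gray(root / row.path)
        mask = None
        mask_rel = getattr(row, "mask_path", "")
        if isinstance(mask_rel, str) and mask_rel:
            mask = _read_gray(root / mask_rel) > 127
        samples.append(
            VeinSample(
                image=image,
                mask=mask if mask is not None else np.zeros_like(image, bool),
                class_id=remap[int(row.class_id)],
                session=int(row.session),
                sample_index=int(row.sample),
                seed=int(getattr(row, "seed", 0) or 0),
                path=str(row.path),
                mask_path=str(mask_rel) if isinstance(mask_rel, str) else None,
            )
        )

    by_key = sorted(samples, key=lambda s: (s.class_id, s.session, s.sample_index))
    train = {}
    for s in by_key:
        if s.session == 1 and s.class_id not in train:
            train[s.class_id] = s
    train_list = [train[c] for c in sorted(train)]
    test_list = [s for s in by_key if s.session >= 2]
    return train_list, test_list, DatasetManifest(table=table, root=root)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML round-trips losslessly."""

    data_dir: str = "data"
    out_dir: str = "run"
    regime: str = "full"
    k_steps: int = 4
    p_epochs: int = 8
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int | None = None
    seed: int = 0
    gate_threshold: float = 0.5
    input_shape: tuple[int, int] = (64, 128)
    synth: dict | None = None  # e.g. {"n_classes": 10, "sessions": 2, ...}
    lbp: LbpParams = field(default_factory=LbpParams)
    bank: GaborBank = field(default_factory=GaborBank)
    fsim_params: FsimParams = field(default_factory=FsimParams)
    pc_params: PhaseCongruencyParams = field(default_factory=PhaseCongruencyParams)

    def __post_init__(self) -> None:
        if self.regime not in _REGIMES:
            raise ValueError(
                f"unknown regime {self.regime!r}; choose from {sorted(_REGIMES)}"
            )
        self.input_shape = tuple(self.input_shape)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            k_steps=self.k_steps,
            p_epochs=self.p_epochs,
            lr=self.lr,
            momentum=self.momentum,
            batch_size=self.batch_size,
            seed=self.seed,
            gate_threshold=self.gate_threshold,
            input_shape=self.input_shape,
            lbp=self.lbp,
            bank=self.bank,
            fsim_params=self.fsim_params,
            pc_params=self.pc_params,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(_to_plain(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "lbp" in data and isinstance(data["lbp"], dict):
            data["lbp"] = LbpParams(**data["lbp"])
        if "bank" in data and isinstance(data["bank"], dict):
            b = dict(data["bank"])
            b["scales"] = tuple(b.get("scales", GaborBank().scales))
            b["orientations"] = tuple(
                b.get("orientations", GaborBank().orientations)
            )
            data["bank"] = GaborBank(**b)
        if "fsim_params" in data and isinstance(data["fsim_params"], dict):
            data["fsim_params"] = FsimParams(**data["fsim_params"])
        if "pc_params" in data and isinstance(data["pc_params"], dict):
            data["pc_params"] = PhaseCongruencyParams(**data["pc_params"])
        if "input_shape" in data:
            data["input_shape"] = tuple(data["input_shape"])
        return cls(**data)


# --------------------------------------------------------------------------
# Model persistence
# --------------------------------------------------------------------------

def save_ensemble(model: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for state in model.classifiers:
        save_classifier(state, directory / f"classifier_{state.classifier_index}")
    meta = {
        "regime": model.regime,
        "weights": model.weights.tolist(),
        "gate": model.gate.tolist(),
        "e_plus": model.e_plus.tolist(),
        "e_minus": model.e_minus.tolist(),
        "similarity": (
            model.similarity.values.tolist() if model.similarity else None
        ),
        "similarity_n": model.similarity.n if model.similarity else None,
        "ec_table": (
            {f"{i},{j}": ec for (i, j), ec in model.ec_table.items()}
            if model.ec_table
            else None
        ),
        "weight_history": model.weight_history,
        "config": _to_plain(model.config),
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))


def _train_config_from_dict(data: dict) -> TrainConfig:
    data = dict(data)
    data["lbp"] = LbpParams(**data["lbp"])
    b = dict(data["bank"])
    b["scales"] = tuple(b["scales"])
    b["orientations"] = tuple(b["orientations"])
    data["bank"] = GaborBank(**b)
    data["fsim_params"] = FsimParams(**data["fsim_params"])
    data["pc_params"] = PhaseCongruencyParams(**data["pc_params"])
    data["input_shape"] = tuple(data["input_shape"])
    return TrainConfig(**data)


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    classifiers = [
        load_classifier(directory / f"classifier_{i}") for i in range(1, 7)
    ]
    sim = None
    if meta["similarity"] is not None:
        sim = SimilarityMatrix(
            values=np.array(meta["similarity"]), n=meta["similarity_n"]
        )
    ec = None
    if meta["ec_table"] is not None:
        ec = {
            tuple(int(v) for v in key.split(",")): int(val)
            for key, val in meta["ec_table"].items()
        }
    return EnsembleModel(
        classifiers=classifiers,
        weights=np.array(meta["weights"]),
        gate=np.array(meta["gate"], dtype=bool),
        e_plus=np.array(meta["e_plus"]),
        e_minus=np.array(meta["e_minus"]),
        config=_train_config_from_dict(meta["config"]),
        regime=meta["regime"],
        similarity=sim,
        ec_table=ec,
        weight_history=meta["weight_history"],
    )


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute synth (optional) -> features -> similarity -> training ->
    evaluation, writing all artifacts under ``config.out_dir``.

    Returns a dict with the ensemble accuracy, per-classifier accuracies
    and the artifact paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = Path(config.data_dir)

    if config.synth is not None and not (data_dir / "manifest.csv").exists():
        logger.info("stage synth: generating dataset under %s", data_dir)
        synth = dict(config.synth)
        generate_dataset(
            n_classes=int(synth.get("n_classes", 10)),
            sessions=int(synth.get("sessions", 2)),
            samples_per_session=int(synth.get("samples_per_session", 6)),
            master_seed=int(synth.get("master_seed", config.seed)),
            out_dir=data_dir,
            canvas_size=tuple(synth.get("canvas_size", (64, 128))),
        )

    logger.info("stage load: %s", data_dir)
    train, test, manifest = load_dataset(data_dir)

    tc = config.train_config()
    logger.info("stage features: %d train / %d test images", len(train), len(test))
    train_data = featurize_samples(
        train, lbp=tc.lbp, bank=tc.bank, input_shape=tc.input_shape
    )
    test_data = featurize_samples(
        test, lbp=tc.lbp, bank=tc.bank, input_shape=tc.input_shape
    )

    logger.info("stage similarity: 6x6 feature-map matrix")
    sim = similarity_matrix_from_maps(
        train_data.map_sets, params=tc.fsim_params, pc_params=tc.pc_params
    )
    st_path = out / "st.csv"
    sim.to_dataframe().to_csv(st_path)

    logger.info("stage train: regime=%s", config.regime)
    model = _REGIMES[config.regime](train_data, tc)

    logger.info("stage evaluate: %d probes", len(test))
    result = evaluate(model, test_data)

    model_dir = out / "model"
    save_ensemble(model, model_dir)
    results_path = out / "results.csv"
    result.records.to_csv(results_path, index=False)
    log_path = out / "run_log.jsonl"
    with open(log_path, "w") as fh:
        for entry in model.run_log:
            fh.write(json.dumps(entry) + "\n")
    config_path = out / "config.yaml"
    config_path.write_text(config.to_yaml())

    return {
        "accuracy": result.accuracy,
        "per_classifier_accuracy": result.per_classifier_accuracy.tolist(),
        "weights": model.weights.tolist(),
        "gate": model.gate.tolist(),
        "artifacts": {
            "model_dir": str(model_dir),
            "st_csv": str(st_path),
            "results_csv": str(results_path),
            "run_log": str(log_path),
            "config": str(config_path),
        },
    }
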