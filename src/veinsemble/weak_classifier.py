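"""Per-feature-map CNN weak classifiers.

Two architectures are used: maps 1-2 get a five-conv-block network
(filters 64, 64, 64, 128, 256) and maps 3-6 a six-conv-block network
(filters 64, 64, 64, 128, 128, 256).  Every conv uses a 2x2 kernel with
stride 1 and is followed by 2x2/stride-2 max pooling; the head is
flatten -> ReLU -> dropout 0.5 -> softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from veinsemble._nn import Network, softmax

__all__ = [
    "ARCH_FILTERS",
    "ClassifierState",
    "arch_for_map",
    "build_cnn",
    "close_test",
    "cnn_arch_spec",
    "load_classifier",
    "save_classifier",
    "train_epochs",
    "training_loss",
]

ARCH_FILTERS: dict[str, tuple[int, ...]] = {
    "A": (64, 64, 64, 128, 256),
    "B": (64, 64, 64, 128, 128, 256),
}

DEFAULT_INPUT_SHAPE = (64, 128)
DEFAULT_LR = 0.01
DEFAULT_MOMENTUM = 0.9


def arch_for_map(map_index: int) -> str:
    """Architecture of the classifier fed by 1-based map ``map_index``."""
    if not 1 <= map_index <= 6:
        raise ValueError(f"map index must be in 1..6, got {map_index}")
    return "A" if map_index <= 2 else "B"


def cnn_arch_spec(arch: str) -> list[dict]:
    """Layer-by-layer description of an architecture (for introspection)."""
    if arch not in ARCH_FILTERS:
        raise ValueError(f"unknown architecture {arch!r}")
    layers: list[dict] = []
    for f in ARCH_FILTERS[arch]:
        layers.append(
            {
                "type": "conv",
                "n_filters": f,
                "kernel": (2, 2),
                "stride": (1, 1),
                "padding": (0, 0),
            }
        )
        layers.append(
            {
                "type": "maxpool",
                "n_filters": 1,
                "kernel": (2, 2),
                "stride": (2, 2),
                "padding": (0, 0),
            }
        )
    layers.append({"type": "relu-dropout", "dropout": 0.5})
    layers.append({"type": "softmax"})
    return layers


@dataclass
class ClassifierState:
    """One weak classifier plus its per-step training history.

    ``loss_history[u]``, ``score_history[u]`` and ``epochs_history[u]``
    record the loss, close-test score and executed own-map epochs of step
    ``u + 1``; they are appended by the ensemble orchestrator, one entry
    per completed step.
    """

    classifier_index: int
    arch: str
    input_shape: tuple[int, int]
    n_classes: int
    seed: int
    net: Network
    rng: np.random.Generator
    loss_history: list[float] = field(default_factory=list)
    score_history: list[float] = field(default_factory=list)
    epochs_history: list[int] = field(default_factory=list)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class-probability rows for a stack of maps (n, H, W) in [0, 1]."""
        x = _as_batch(images, self.input_shape)
        return self.net.predict_proba(x)


def _min_input(arch: str) -> int:
    return 2 ** len(ARCH_FILTERS[arch])


def _as_batch(images: np.ndarray, input_shape: tuple[int, int]) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1:] != tuple(input_shape):
        raise ValueError(
            f"images of shape {x.shape[1:]} do not match the classifier "
            f"input shape {tuple(input_shape)}"
        )
    # per-image standardization: the DC component of raw [0, 1] maps
    # badly conditions the linear conv trunk
    mean = x.mean(axis=(1, 2), keepdims=True)
    std = x.std(axis=(1, 2), keepdims=True) + np.float32(1e-6)
    return (x - mean) / std


def build_cnn(
    arch: str,
    input_shape: tuple[int, int] = DEFAULT_INPUT_SHAPE,
    n_classes: int = 2,
    seed: int = 0,
    classifier_index: int = 0,
) -> ClassifierState:
    """Build a deterministically initialized weak classifier."""
    if arch not in ARCH_FILTERS:
        raise ValueError(f"unknown architecture {arch!r}")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    min_side = _min_input(arch)
    h, w = input_shape
    if h < min_side or w < min_side:
        raise ValueError(
            f"input shape {input_shape} too small for architecture {arch}: "
            f"each side must be at least {min_side} pixels to survive "
            f"{len(ARCH_FILTERS[arch])} pooling stages"
        )
    rng = np.random.default_rng([int(seed), int(classifier_index)])
    net = Network(ARCH_FILTERS[arch], (h, w), n_classes, rng)
    return ClassifierState(
        classifier_index=classifier_index,
        arch=arch,
        input_shape=(h, w),
        n_classes=n_classes,
        seed=int(seed),
        net=net,
        rng=rng,
    )


def train_epochs(
    state: ClassifierState,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int,
    lr: float = DEFAULT_LR,
    momentum: float = DEFAULT_MOMENTUM,
    batch_size: int | None = None,
) -> ClassifierState:
    """Run full passes of mini-batch SGD; mutates and returns ``state``.

    Histories are not touched here — they are per training step and owned
    by the ensemble orchestrator.
    """
    if epochs < 1:
        raise ValueError(f"epochs must be >= 1, got {epochs}")
    x = _as_batch(images, state.input_shape)
    y = np.asarray(labels)
    if y.shape[0] != x.shape[0]:
        raise ValueError("images and labels disagree in length")
    if y.min() < 0 or y.max() >= state.n_classes:
        raise ValueError(
            f"labels must lie in [0, {state.n_classes}), got range "
            f"[{y.min()}, {y.max()}]"
        )
    n = x.shape[0]
    bs = batch_size if batch_size is not None else min(32, n)
    for _ in range(epochs):
        if bs >= n:
            state.net.train_batch(x, y, lr, momentum, state.rng)
            continue
        order = state.rng.permutation(n)
        for start in range(0, n, bs):
            sel = order[start : start + bs]
            state.net.train_batch(x[sel], y[sel], lr, momentum, state.rng)
    return state


def training_loss(state: ClassifierState, images: np.ndarray, labels: np.ndarray) -> float:
    """Cross-entropy on the given set with dropout disabled."""
    probs = state.predict_proba(images)
    y = np.asarray(labels)
    return float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())


def close_test(state: ClassifierState, images: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of samples whose argmax prediction matches the label."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("close test needs a nonempty set")
    probs = state.predict_proba(images)
    return float((probs.argmax(axis=1) == y).mean())


def save_classifier(state: ClassifierState, directory: str | Path) -> None:
    """Write parameters (npz) and a JSON sidecar with metadata/histories."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **state.net.parameters())
    sidecar = {
        "classifier_index": state.classifier_index,
        "arch": state.arch,
        "input_shape": list(state.input_shape),
        "n_classes": state.n_classes,
        "seed": state.seed,
        "loss_history": state.loss_history,
        "score_history": state.score_history,
        "epochs_history": state.epochs_history,
    }
    (directory / "classifier.json").write_text(json.dumps(sidecar, indent=2))


def load_classifier(directory: str | Path) -> ClassifierState:
    directory = Path(directory)
    meta = json.loads((directory / "classifier.json").read_text())
    state = build_cnn(
        meta["arch"],
        tuple(meta["input_shape"]),
        meta["n_classes"],
        meta["seed"],
        meta["classifier_index"],
    )
    with np.load(directory / "params.npz") as arrays:
        state.net.load_parameters(dict(arrays))
    state.loss_history = list(meta["loss_history"])
    state.score_history = list(meta["score_history"])
    state.epochs_history = list(meta["epochs_history"])
    return state
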