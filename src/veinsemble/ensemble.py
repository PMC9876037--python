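"""Training orchestration and the gated weighted ensemble.

Three regimes train the six weak classifiers over ``K`` steps of ``P``
epochs each:

* **basic** — each classifier sees only its own feature map;
* **shared** — after its own epochs in a step, a classifier is fine-tuned
  for ``Ec = max(0, 2 * floor(P/4 * St) - 1)`` epochs on every other map
  whose dataset-level similarity ``St`` makes ``Ec`` positive, most
  similar first;
* **full** — shared learning plus loss-driven speed adjustment: the
  own-map epoch count of step ``u`` is ``floor(sigmoid(L[u-1]) * P)``
  (at least 1), with the first step running all ``P`` epochs.

After every step the close-test scores and losses are folded into
normalized sigmoid weights ``E+``/``E-``; classifiers whose score exceeds
the gate threshold vote with weight proportional to ``|E+ - E-|``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from veinsemble.feature_maps import (
    FeatureMapSet,
    GaborBank,
    LbpParams,
    build_feature_maps,
)
from veinsemble.similarity import (
    FsimParams,
    PhaseCongruencyParams,
    SimilarityMatrix,
    similarity_matrix_from_maps,
)
from veinsemble.synthetic_data import VeinSample
from veinsemble.weak_classifier import (
    ClassifierState,
    arch_for_map,
    build_cnn,
    train_epochs,
)

__all__ = [
    "TrainConfig",
    "EnsembleModel",
    "EvaluationResult",
    "FeatureData",
    "featurize_samples",
    "shared_epochs",
    "speed_alpha",
    "step_epochs",
    "pos_weight",
    "neg_weight",
    "ensemble_weights",
    "train_basic",
    "train_shared",
    "train_full",
    "predict",
    "evaluate",
]


# --------------------------------------------------------------------------
# Scheduler arithmetic
# --------------------------------------------------------------------------

def shared_epochs(st: float, p_epochs: int) -> int:
    """Epochs of shared learning for one map pair.

    ``Ec = 2 * floor(P/4 * St) - 1``, clamped at 0: a pair whose raw
    value is negative is not similar enough and is skipped.
    """
    if not 0.0 < st <= 1.0:
        raise ValueError(f"St must lie in (0, 1], got {st}")
    if p_epochs < 1:
        raise ValueError(f"P must be >= 1, got {p_epochs}")
    raw = 2 * math.floor(p_epochs / 4.0 * st) - 1
    return max(0, raw)


def speed_alpha(loss_prev: float) -> float:
    """Learning-speed factor ``1 / (1 + exp(-L))`` of the previous loss."""
    if loss_prev < 0:
        raise ValueError(f"loss must be >= 0, got {loss_prev}")
    return float(1.0 / (1.0 + np.exp(-loss_prev)))


def step_epochs(alpha: float, p_epochs: int) -> int:
    """Own-map epochs of the next step: ``floor(alpha * P)``, minimum 1."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if p_epochs < 1:
        raise ValueError(f"P must be >= 1, got {p_epochs}")
    return max(1, math.floor(alpha * p_epochs))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def pos_weight(scores: Sequence[float]) -> np.ndarray:
    """Normalized sigmoid of close-test scores; sums to 1."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be nonempty")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    sig = _sigmoid(s)
    return sig / sig.sum()


def neg_weight(losses: Sequence[float]) -> np.ndarray:
    """Normalized sigmoid of losses; sums to 1."""
    l = np.asarray(losses, dtype=float)
    if l.size == 0:
        raise ValueError("losses must be nonempty")
    if l.min() < 0:
        raise ValueError("losses must be >= 0")
    sig = _sigmoid(l)
    return sig / sig.sum()


def ensemble_weights(
    e_plus: np.ndarray,
    e_minus: np.ndarray,
    scores: Sequence[float],
    gate_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Gated vote weights.

    A classifier joins the vote when its close-test score exceeds
    ``gate_threshold``; gated weights are ``|E+ - E-|`` renormalized over
    the gated set.  If no classifier passes the gate, the vote falls back
    to uniform weights over all classifiers (with a warning).
    """
    e_plus = np.asarray(e_plus, dtype=float)
    e_minus = np.asarray(e_minus, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not (e_plus.shape == e_minus.shape == s.shape):
        raise ValueError("e_plus, e_minus and scores must have equal length")
    k = s.size
    gate = s > gate_threshold
    if not gate.any():
        warnings.warn(
            "no classifier passed the close-test gate; falling back to "
            "uniform ensemble weights",
            stacklevel=2,
        )
        return np.full(k, 1.0 / k), gate
    raw = np.where(gate, np.abs(e_plus - e_minus), 0.0)
    total = raw.sum()
    if total <= 0:
        w = np.where(gate, 1.0 / gate.sum(), 0.0)
    else:
        w = raw / total
    return w, gate


# --------------------------------------------------------------------------
# Feature data
# --------------------------------------------------------------------------

@dataclass
class FeatureData:
    """Six-map stacks of a sample list, ready for the classifiers.

    ``stack[k - 1, i]`` is the k-th feature map of sample ``i`` as float32
    in [0, 1], resized to the classifier input shape.
    """

    stack: np.ndarray  # (6, n, H, W) float32
    labels: np.ndarray  # (n,) int
    map_sets: list[FeatureMapSet]
    paths: list[str | None]


def _resize_map(m: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if m.shape == tuple(shape):
        return m.astype(np.float32)
    zoom = (shape[0] / m.shape[0], shape[1] / m.shape[1])
    return ndimage.zoom(m.astype(np.float32), zoom, order=1, mode="nearest",
                        grid_mode=True)


def featurize_samples(
    samples: Sequence[VeinSample],
    lbp: LbpParams = LbpParams(),
    bank: GaborBank = GaborBank(),
    input_shape: tuple[int, int] = (64, 128),
) -> FeatureData:
    """Build the six maps of every sample and stack them for training."""
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    n = len(samples)
    stack = np.empty((6, n) + tuple(input_shape), dtype=np.float32)
    map_sets = []
    for i, sample in enumerate(samples):
        ms = build_feature_maps(sample.image, lbp=lbp, bank=bank)
        map_sets.append(ms)
        floats = ms.as_float_stack()
        for k in range(6):
            stack[k, i] = _resize_map(floats[k], input_shape)
    labels = np.array([s.class_id for s in samples], dtype=int)
    return FeatureData(
        stack=stack,
        labels=labels,
        map_sets=map_sets,
        paths=[s.path for s in samples],
    )


# --------------------------------------------------------------------------
# Configuration and model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    k_steps: int = 4
    p_epochs: int = 8
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int | None = None
    seed: int = 0
    gate_threshold: float = 0.5
    #: learning-rate multiplier for shared (fine-tuning) epochs; full-rate
    #: updates on a foreign map destabilize the classifier
    shared_lr_factor: float = 0.25
    input_shape: tuple[int, int] = (64, 128)
    total_epochs: int | None = None  # optional redundancy check: R = K * P
    lbp: LbpParams = LbpParams()
    bank: GaborBank = GaborBank()
    fsim_params: FsimParams = FsimParams()
    pc_params: PhaseCongruencyParams = PhaseCongruencyParams()

    def __post_init__(self) -> None:
        if self.k_steps < 1 or self.p_epochs < 1:
            raise ValueError("k_steps and p_epochs must be >= 1")
        if (
            self.total_epochs is not None
            and self.total_epochs != self.k_steps * self.p_epochs
        ):
            raise ValueError(
                f"inconsistent schedule: total_epochs={self.total_epochs} "
                f"but K * P = {self.k_steps * self.p_epochs}"
            )


@dataclass
class EnsembleModel:
    classifiers: list[ClassifierState]
    weights: np.ndarray
    gate: np.ndarray
    e_plus: np.ndarray
    e_minus: np.ndarray
    config: TrainConfig
    regime: str
    similarity: SimilarityMatrix | None = None
    ec_table: dict[tuple[int, int], int] | None = None
    weight_history: list[dict] = field(default_factory=list)
    run_log: list[dict] = field(default_factory=list)
    class_ids: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.classifiers[0].n_classes


@dataclass
class EvaluationResult:
    accuracy: float
    per_classifier_accuracy: np.ndarray
    records: pd.DataFrame


# --------------------------------------------------------------------------
# Training regimes
# --------------------------------------------------------------------------

def _check_sspp(labels: np.ndarray) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if (counts != 1).any():
        bad = uniq[counts != 1].tolist()
        raise ValueError(
            f"single-sample protocol violated: classes {bad} have more "
            "than one training image"
        )
    if not np.array_equal(uniq, np.arange(len(uniq))):
        raise ValueError("class ids must be contiguous from 0")


def _shared_plan(
    sim: SimilarityMatrix, p_epochs: int
) -> dict[tuple[int, int], int]:
    """Ec for every ordered pair (i, j), i != j, from the St matrix."""
    plan = {}
    for i in range(1, 7):
        for j in range(1, 7):
            if i == j:
                continue
            plan[(i, j)] = shared_epochs(sim.pair(i, j), p_epochs)
    return plan


def _shared_order(sim: SimilarityMatrix, i: int) -> list[int]:
    """Other maps sorted by similarity to map ``i``, most similar first."""
    others = [j for j in range(1, 7) if j != i]
    return sorted(others, key=lambda j: (-sim.pair(i, j), j))


def _train_regime(
    train_data: FeatureData,
    config: TrainConfig,
    regime: str,
    shared: bool,
    speed: bool,
) -> EnsembleModel:
    _check_sspp(train_data.labels)
    labels = train_data.labels
    n_classes = int(labels.max()) + 1

    sim = None
    ec_table = None
    if shared:
        sim = similarity_matrix_from_maps(
            train_data.map_sets,
            params=config.fsim_params,
            pc_params=config.pc_params,
        )
        ec_table = _shared_plan(sim, config.p_epochs)

    run_log: list[dict] = []
    classifiers: list[ClassifierState] = []
    for i in range(1, 7):
        state = build_cnn(
            arch_for_map(i),
            config.input_shape,
            n_classes,
            seed=config.seed,
            classifier_index=i,
        )
        x_own = train_data.stack[i - 1]
        for u in range(1, config.k_steps + 1):
            if speed and u > 1:
                own = step_epochs(
                    speed_alpha(state.loss_history[-1]), config.p_epochs
                )
            else:
                own = config.p_epochs
            train_epochs(
                state,
                x_own,
                labels,
                own,
                lr=config.lr,
                momentum=config.momentum,
                batch_size=config.batch_size,
            )
            shared_log: dict[int, int] = {}
            if shared:
                any_shared = False
                for j in _shared_order(sim, i):
                    ec = ec_table[(i, j)]
                    if ec < 1:
                        continue
                    # switching data sources invalidates the velocity
                    state.net.reset_momentum()
                    any_shared = True
                    train_epochs(
                        state,
                        train_data.stack[j - 1],
                        labels,
                        ec,
                        lr=config.lr * config.shared_lr_factor,
                        momentum=config.momentum,
                        batch_size=config.batch_size,
                    )
                    shared_log[j] = ec
                if any_shared:
                    state.net.reset_momentum()
            probs = state.predict_proba(x_own)
            loss = float(
                -np.log(probs[np.arange(labels.size), labels] + 1e-12).mean()
            )
            if not np.isfinite(loss):
                # a diverged classifier reports a saturating loss; the
                # close-test gate will keep it out of the vote
                loss = 50.0
            score = float((probs.argmax(axis=1) == labels).mean())
            state.loss_history.append(loss)
            state.score_history.append(score)
            state.epochs_history.append(own)
            run_log.append(
                {
                    "event": "step",
                    "classifier": i,
                    "step": u,
                    "own_epochs": own,
                    "shared_epochs": shared_log,
                    "loss": loss,
                    "score": score,
                }
            )
        classifiers.append(state)

    weight_history = []
    e_plus = e_minus = weights = gate = None
    for u in range(config.k_steps):
        scores_u = [c.score_history[u] for c in classifiers]
        losses_u = [c.loss_history[u] for c in classifiers]
        e_plus = pos_weight(scores_u)
        e_minus = neg_weight(losses_u)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            weights, gate = ensemble_weights(
                e_plus, e_minus, scores_u, config.gate_threshold
            )
        entry = {
            "event": "weights",
            "step": u + 1,
            "e_plus": e_plus.tolist(),
            "e_minus": e_minus.tolist(),
            "w": weights.tolist(),
            "gate": gate.tolist(),
            "fallback": bool(not gate.any()),
        }
        weight_history.append(entry)
        run_log.append(entry)

    return EnsembleModel(
        classifiers=classifiers,
        weights=weights,
        gate=gate,
        e_plus=e_plus,
        e_minus=e_minus,
        config=config,
        regime=regime,
        similarity=sim,
        ec_table=ec_table,
        weight_history=weight_history,
        run_log=run_log,
        class_ids=np.arange(n_classes),
    )


def _prepare(dataset, config: TrainConfig) -> FeatureData:
    if isinstance(dataset, FeatureData):
        return dataset
    return featurize_samples(
        dataset, lbp=config.lbp, bank=config.bank, input_shape=config.input_shape
    )


def train_basic(dataset, config: TrainConfig = TrainConfig()) -> EnsembleModel:
    """Independent per-map training plus gated weighted voting."""
    return _train_regime(_prepare(dataset, config), config, "basic", False, False)


def train_shared(dataset, config: TrainConfig = TrainConfig()) -> EnsembleModel:
    """Basic regime plus FSIM-driven shared learning between classifiers."""
    return _train_regime(_prepare(dataset, config), config, "shared", True, False)


def train_full(dataset, config: TrainConfig = TrainConfig()) -> EnsembleModel:
    """Shared learning plus loss-driven learning-speed adjustment."""
    return _train_regime(_prepare(dataset, config), config, "full", True, True)


# --------------------------------------------------------------------------
# Prediction and evaluation
# --------------------------------------------------------------------------

def _combined_proba(model: EnsembleModel, stack: np.ndarray) -> np.ndarray:
    """Convex combination of gated classifier probabilities.

    ``stack`` has shape (6, n, H, W); returns (n, n_classes).
    """
    n = stack.shape[1]
    combined = np.zeros((n, model.n_classes))
    for i, state in enumerate(model.classifiers):
        if model.weights[i] <= 0:
            continue
        combined += model.weights[i] * state.predict_proba(stack[i])
    return combined


def predict(model: EnsembleModel, image: np.ndarray) -> tuple[int, np.ndarray]:
    """Classify one grayscale image; ties break to the lowest class."""
    if model.weights is None or len(model.classifiers) != 6:
        raise ValueError("model is not trained")
    ms = build_feature_maps(image, lbp=model.config.lbp, bank=model.config.bank)
    floats = ms.as_float_stack()
    stack = np.stack(
        [_resize_map(floats[k], model.config.input_shape) for k in range(6)]
    )[:, None]
    probs = _combined_proba(model, stack)[0]
    return int(probs.argmax()), probs


def evaluate(model: EnsembleModel, test_set) -> EvaluationResult:
    """Identification accuracy of the ensemble on a test set.

    ``test_set`` is either a sequence of :class:`VeinSample` or a
    prefeaturized :class:`FeatureData`.  Returns the ensemble accuracy,
    each weak classifier's accuracy, and a per-sample record table.
    """
    data = _prepare(test_set, model.config)
    if data.labels.size == 0:
        raise ValueError("test set is empty")
    n = data.labels.size
    combined = np.zeros((n, model.n_classes))
    per_clf = np.empty(len(model.classifiers))
    for i, state in enumerate(model.classifiers):
        probs_i = state.predict_proba(data.stack[i])
        per_clf[i] = float((probs_i.argmax(axis=1) == data.labels).mean())
        if model.weights[i] > 0:
            combined += model.weights[i] * probs_i
    pred = combined.argmax(axis=1)
    accuracy = float((pred == data.labels).mean())
    probs = combined
    records = pd.DataFrame(
        {
            "sample_path": [p if p is not None else "" for p in data.paths],
            "true_class": data.labels,
            "predicted_class": pred,
            "top_probability": probs.max(axis=1),
        }
    )
    return EvaluationResult(
        accuracy=accuracy, per_classifier_accuracy=per_clf, records=records
    )
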