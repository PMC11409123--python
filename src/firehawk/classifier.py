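"""Hyperparameter decoding, desk-scale classifiers, and the tuning harness.

The optimizer searches a 3-D box — hidden-layer width N in [50, 200],
learning rate in [0.001, 0.01], batch size in [32, 128] — and the fitness
of a decoded point is the validation accuracy of a classifier freshly
trained with those hyperparameters.  Two architectures are available:

``hidden_layer``
    a single-hidden-layer network on flattened features, trained by
    mini-batch SGD with cross-entropy loss (scikit-learn backend);
``reduced_bottleneck``
    a small fixed-weight convolutional feature extractor — stem 3x3 conv,
    inverted bottleneck blocks (expand 1x1, depthwise 3x3, project 1x1,
    identity shortcut when shapes match), global average pooling —
    followed by a trained softmax head of width N.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from firehawk.optimizer import (
    ConfigurationError,
    DimensionError,
    OptimizerConfig,
    OptimizerResult,
    SearchSpace,
    run_optimizer,
)

#: search box for (N, LR, B)
HYPER_SPACE = SearchSpace(lower=np.array([50.0, 0.001, 32.0]), upper=np.array([200.0, 0.01, 128.0]))


@dataclass(frozen=True)
class Hyperparameters:
    n_hidden: int
    learning_rate: float
    batch_size: int

    def __post_init__(self) -> None:
        if not 50 <= self.n_hidden <= 200:
            raise ConfigurationError("n_hidden must lie in [50, 200]")
        if not 0.001 <= self.learning_rate <= 0.01:
            raise ConfigurationError("learning_rate must lie in [0.001, 0.01]")
        if not 32 <= self.batch_size <= 128:
            raise ConfigurationError("batch_size must lie in [32, 128]")


@dataclass
class ClassifierSpec:
    architecture: str = "hidden_layer"
    epochs: int = 20
    input_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("hidden_layer", "reduced_bottleneck"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def decode_hyperparameters(position: np.ndarray, space: SearchSpace = HYPER_SPACE) -> Hyperparameters:
    """Map a continuous position to concrete hyperparameters.

    Integer variables round half-away-from-zero, then clamp back into the
    box; the learning rate passes through unchanged.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (3,):
        raise DimensionError("hyperparameter position must have length 3")
    n_hidden = min(max(_round_half_away(position[0]), int(space.lower[0])), int(space.upper[0]))
    batch = min(max(_round_half_away(position[2]), int(space.lower[2])), int(space.upper[2]))
    lr = float(min(max(position[1], space.lower[1]), space.upper[1]))
    return Hyperparameters(n_hidden=n_hidden, learning_rate=lr, batch_size=batch)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class TrainedModel:
    """Thin prediction handle around a fitted head (plus optional extractor)."""

    def __init__(self, estimator: MLPClassifier, extractor: Callable[[np.ndarray], np.ndarray] | None = None):
        self._estimator = estimator
        self._extractor = extractor

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._extractor(X) if self._extractor is not None else X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._estimator.predict(self._features(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._estimator.predict_proba(self._features(X))


def _conv2d(x: np.ndarray, kernels: np.ndarray, stride: int = 1) -> np.ndarray:
    """Valid 2-D convolution. x: (M,H,W,Cin); kernels: (kh,kw,Cin,Cout)."""
    kh, kw = kernels.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (M, Ho, Wo, Cin, kh, kw)
    return np.einsum("mhwcij,ijco->mhwo", win, kernels)


def _depthwise3x3(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Depthwise 3x3 convolution with same padding. kernels: (3,3,C)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    return np.einsum("mhwcij,ijc->mhwc", win, kernels)


def _make_bottleneck_extractor(side: int, seed: int) -> Callable[[np.ndarray], np.ndarray]:
    """Fixed-random-weight convolutional feature extractor.

    Stem 3x3 stride-2 conv -> ReLU, then two inverted bottleneck blocks
    (1x1 expand, depthwise 3x3, 1x1 project, identity shortcut), then
    global average pooling.  Weights come from ``seed`` only, so the
    extracted representation is deterministic.
    """
    rng = np.random.default_rng(seed)
    c_stem, expand = 16, 4
    w_stem = rng.normal(0, 1.0 / 3.0, (3, 3, 1, c_stem))
    blocks = []
    for _ in range(2):
        w_exp = rng.normal(0, 1.0 / math.sqrt(c_stem), (1, 1, c_stem, c_stem * expand))
        w_dw = rng.normal(0, 1.0 / 3.0, (3, 3, c_stem * expand))
        w_proj = rng.normal(0, 1.0 / math.sqrt(c_stem * expand), (1, 1, c_stem * expand, c_stem))
        blocks.append((w_exp, w_dw, w_proj))

    def extract(X: np.ndarray) -> np.ndarray:
        imgs = X.reshape(-1, side, side, 1)
        h = np.maximum(_conv2d(imgs, w_stem, stride=2), 0.0)
        for w_exp, w_dw, w_proj in blocks:
            t = np.maximum(_conv2d(h, w_exp), 0.0)
            t = np.maximum(_depthwise3x3(t, w_dw), 0.0)
            t = _conv2d(t, w_proj)
            h = h + t  # stride 1, matched channels -> shortcut
        return h.mean(axis=(1, 2))

    return extract


def train_classifier(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> TrainedModel:
    """Train a classifier with the decoded hyperparameters.

    Deterministic for a given ``rng`` state: the SGD shuffling seed and any
    fixed convolutional weights derive from it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ConfigurationError("empty training set")
    if np.unique(y).size < 2:
        raise ConfigurationError("training set must contain two classes")
    train_seed = int(rng.integers(2**31 - 1))

    extractor = None
    if spec.architecture == "reduced_bottleneck":
        side = int(round(math.sqrt(X.shape[1])))
        if side * side != X.shape[1]:
            raise DimensionError("reduced_bottleneck expects square grayscale inputs")
        extractor = _make_bottleneck_extractor(side, spec.seed)
        X = extractor(X)

    estimator = MLPClassifier(
        hidden_layer_sizes=(hyper.n_hidden,),
        solver="sgd",
        learning_rate_init=hyper.learning_rate,
        batch_size=min(hyper.batch_size, X.shape[0]),
        max_iter=spec.epochs,
        n_iter_no_change=spec.epochs,
        momentum=0.9,
        random_state=train_seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(X, y)
    return TrainedModel(estimator, extractor)


def fitness_accuracy(model: TrainedModel, X_val: np.ndarray, y_val: np.ndarray) -> float:
    """Fraction of validation samples whose prediction matches the label."""
    y_val = np.asarray(y_val, dtype=int)
    if y_val.size == 0:
        raise ConfigurationError("validation set must be non-empty")
    return float(np.mean(model.predict(X_val) == y_val))


def stratified_split(
    y: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation index split (e.g. 0.2 for an 80:20 split)."""
    y = np.asarray(y, dtype=int)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        rows = rng.permutation(rows)
        n_val = max(1, int(round(val_fraction * rows.size)))
        val_idx.extend(rows[:n_val])
        train_idx.extend(rows[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


@dataclass
class TuningResult:
    best: Hyperparameters
    best_fitness: float
    optimizer_result: OptimizerResult
    trace: list[dict] = field(default_factory=list)
    trainings: int = 0


def tune_hyperparameters(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    optimizer_config: OptimizerConfig,
    spec: ClassifierSpec,
    fitness_fn: Callable[[Hyperparameters], float] | None = None,
    position_fitness_fn: Callable[[np.ndarray], float] | None = None,
) -> TuningResult:
    """Maximize validation accuracy over the hyperparameter box.

    Fitness evaluations are cached by decoded hyperparameter key, so
    positions rounding to the same configuration train only once.
    ``fitness_fn`` replaces training entirely (analytic surfaces keyed on
    decoded hyperparameters); ``position_fitness_fn`` does the same but is
    evaluated on the raw continuous decision variables, bypassing the
    decode/cache step.
    """
    config = OptimizerConfig(
        pop_size=optimizer_config.pop_size,
        max_iters=optimizer_config.max_iters,
        max_evals=optimizer_config.max_evals,
        variant=optimizer_config.variant,
        direction="maximize",
        hawk_fraction_cap=optimizer_config.hawk_fraction_cap,
        schedule=optimizer_config.schedule,
        seed=optimizer_config.seed,
    )
    cache: dict[tuple, float] = {}
    trace: list[dict] = []
    trainings = 0

    def evaluate(hyper: Hyperparameters) -> float:
        nonlocal trainings
        if fitness_fn is not None:
            return float(fitness_fn(hyper))
        # per-key deterministic training stream: identical keys reproduce
        key_tag = zlib.crc32(repr((hyper.n_hidden, hyper.learning_rate, hyper.batch_size)).encode())
        model = train_classifier(
            spec, X_train, y_train, hyper, np.random.default_rng([spec.seed, key_tag])
        )
        trainings += 1
        return fitness_accuracy(model, X_val, y_val)

    def objective(position: np.ndarray) -> float:
        if position_fitness_fn is not None:
            return float(position_fitness_fn(position))
        hyper = decode_hyperparameters(position)
        key = (hyper.n_hidden, hyper.learning_rate, hyper.batch_size)
        if key not in cache:
            cache[key] = evaluate(hyper)
            trace.append({"hyperparameters": key, "fitness": cache[key]})
        return cache[key]

    result = run_optimizer(objective, HYPER_SPACE, config)
    best = decode_hyperparameters(result.best_position)
    best_key = (best.n_hidden, best.learning_rate, best.batch_size)
    return TuningResult(
        best=best,
        best_fitness=cache.get(best_key, result.best_value),
        optimizer_result=result,
        trace=trace,
        trainings=trainings,
    )
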