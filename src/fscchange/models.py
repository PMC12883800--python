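"""Classifiers: RF and SVM baselines, a backpropagation neural network
(BPNN), and the particle-swarm-optimized PSO-BPNN hybrid.

The BPNN is a three-layer feedforward network (two hidden layers, ReLU,
softmax output) trained full-batch with Adam on cross-entropy.  PSO-BPNN
wraps it in two particle-swarm stages:

1. an architecture/learning-rate search over (hidden₁, hidden₂, lr) within
   (16–128, 16–128, 0.001–0.1), scored by validation cross-entropy after a
   short proxy training on an internal 80/20 split, and
2. a search over the initial weight vector of the stage-1 architecture
   (bounds ±0.5 per weight), scored the same way,

followed by full Adam training from the stage-2 initialization.  The PSO is
the canonical inertia-weight formulation: per-dimension r₁, r₂ ~ U(0,1),
velocity v ← w·v + c₁r₁(pbest − x) + c₂r₂(gbest − x), inertia w decayed
linearly from 0.9 to 0.4, positions clipped to bounds and velocities clamped
to a fraction of each bound's range.

Class order is fixed as (Arbor, Shrub, Bamboo, Bare, Other) everywhere;
probability vectors always have length 5 and argmax ties break toward the
earlier class.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigError, FormatError
from .geo_io import CLASS_ORDER

logger = logging.getLogger(__name__)

DEFAULT_HIDDEN = (50, 50)
DEFAULT_EPOCHS = 300
DEFAULT_LEARNING_RATE = 0.01
ARCH_BOUNDS = ((16.0, 128.0), (16.0, 128.0), (0.001, 0.1))
WEIGHT_BOUND = 0.5


@dataclass(frozen=True)
class BPNNSpec:
    """Architecture and training settings of the backpropagation network."""

    input_size: int
    hidden_sizes: tuple[int, int] = DEFAULT_HIDDEN
    num_classes: int = len(CLASS_ORDER)
    learning_rate: float = DEFAULT_LEARNING_RATE
    epochs: int = DEFAULT_EPOCHS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if any(h < 1 for h in self.hidden_sizes):
            raise ConfigError("hidden sizes must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning rate must be positive")


@dataclass(frozen=True)
class PSOConfig:
    """Particle swarm settings (canonical inertia-weight PSO)."""

    swarm_size: int = 50
    iterations: int = 100
    c1: float = 1.5
    c2: float = 1.5
    w_start: float = 0.9
    w_end: float = 0.4
    bounds: tuple[tuple[float, float], ...] = ()
    velocity_clamp: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ConfigError("swarm_size must be >= 2")
        if self.w_start < self.w_end:
            raise ConfigError("inertia must not increase (w_start >= w_end)")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ConfigError("each bound must satisfy low < high")


@dataclass
class TrainedClassifier:
    """A fitted model plus everything needed to apply it reproducibly."""

    kind: str  # RF | SVM | BPNN | PSO-BPNN
    model: object
    class_order: tuple[str, ...]
    scaler: StandardScaler | None
    feature_names: tuple[str, ...]
    loss_history: list[float] = field(default_factory=list)
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Backpropagation network (numpy, full-batch Adam)
# ---------------------------------------------------------------------------

class MLP:
    """Two-hidden-layer ReLU network with softmax output."""

    def __init__(self, spec: BPNNSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        sizes = (spec.input_size, *spec.hidden_sizes, spec.num_classes)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- weight vector interface (used by PSO stage 2) --

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def get_flat(self) -> np.ndarray:
        parts = [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        return np.concatenate(parts)

    def set_flat(self, flat: np.ndarray) -> None:
        if flat.size != self.n_parameters:
            raise ValueError("flat weight vector has the wrong length")
        pos = 0
        for w in self.weights:
            w[...] = flat[pos : pos + w.size].reshape(w.shape)
            pos += w.size
        for b in self.biases:
            b[...] = flat[pos : pos + b.size]
            pos += b.size

    # -- forward / loss --

    def _forward(self, X: np.ndarray):
        activations = [X]
        a = X
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
            activations.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        return logits, activations

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(X)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))

    def train(self, X: np.ndarray, y: np.ndarray, epochs: int | None = None,
              learning_rate: float | None = None) -> list[float]:
        """Full-batch Adam on softmax cross-entropy; returns per-epoch loss."""
        epochs = self.spec.epochs if epochs is None else epochs
        lr = self.spec.learning_rate if learning_rate is None else learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        params = self.weights + self.biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        history: list[float] = []
        n = len(X)
        onehot = np.zeros((n, self.spec.num_classes))
        onehot[np.arange(n), y] = 1.0
        for t in range(1, epochs + 1):
            logits, activations = self._forward(X)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            p = e / e.sum(axis=1, keepdims=True)
            loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {t} (lr={lr})"
                )
            history.append(loss)
            delta = (p - onehot) / n
            grads_w = []
            grads_b = []
            for layer in range(len(self.weights) - 1, -1, -1):
                grads_w.append(activations[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ self.weights[layer].T) * (activations[layer] > 0)
            grads = grads_w[::-1] + grads_b[::-1]
            for k, (param, grad) in enumerate(zip(params, grads)):
                m[k] = beta1 * m[k] + (1 - beta1) * grad
                v[k] = beta2 * v[k] + (1 - beta2) * grad**2
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)
        return history


# ---------------------------------------------------------------------------
# Training entry points
# ---------------------------------------------------------------------------

def _encode_labels(labels) -> np.ndarray:
    idx = np.array([CLASS_ORDER.index(lb) for lb in labels])
    if len(np.unique(idx)) < 2:
        raise ConfigError("training requires at least 2 classes")
    return idx


def _as_matrix(features) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), tuple(features.columns)
    arr = np.asarray(features, dtype=float)
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def train_baseline(kind: str, features, labels, seed: int = 42) -> TrainedClassifier:
    """Train an RF (50 trees, depth 8) or RBF-SVM (C=100, gamma='scale')
    baseline with standardized features and probability outputs."""
    X, names = _as_matrix(features)
    y = _encode_labels(labels)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if kind == "RF":
        model = RandomForestClassifier(
            n_estimators=50, max_depth=8, random_state=seed, n_jobs=1
        )
    elif kind == "SVM":
        model = SVC(
            kernel="rbf", C=100.0, gamma="scale", probability=True, random_state=seed
        )
    else:
        raise ConfigError(f"unknown baseline kind {kind!r} (expected RF or SVM)")
    model.fit(Xs, y)
    return TrainedClassifier(
        kind=kind, model=model, class_order=CLASS_ORDER, scaler=scaler,
        feature_names=names,
    )


def train_bpnn(spec: BPNNSpec, features, labels) -> TrainedClassifier:
    """Train a plain BPNN; the per-epoch loss trajectory is recorded."""
    X, names = _as_matrix(features)
    y = _encode_labels(labels)
    if X.shape[1] != spec.input_size:
        raise ConfigError(
            f"spec.input_size={spec.input_size} but features have {X.shape[1]} columns"
        )
    scaler = StandardScaler().fit(X)
    net = MLP(spec)
    history = net.train(scaler.transform(X), y)
    return TrainedClassifier(
        kind="BPNN", model=net, class_order=CLASS_ORDER, scaler=scaler,
        feature_names=names, loss_history=history,
    )


def pso_minimize(fitness, config: PSOConfig):
    """Minimize ``fitness`` over the box in ``config.bounds``.

    Returns ``(best_position, best_fitness, trajectory)`` where trajectory
    is the global-best fitness after initialization and after each
    iteration (monotonically nonincreasing).  A non-finite fitness value
    penalizes that particle with +inf and the run continues.
    """
    if not config.bounds:
        raise ConfigError("PSO requires at least one bounded dimension")
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    vmax = config.velocity_clamp * span
    n, d = config.swarm_size, len(config.bounds)

    x = lo + rng.uniform(size=(n, d)) * span
    v = rng.uniform(-1.0, 1.0, size=(n, d)) * vmax

    def evaluate(positions: np.ndarray) -> np.ndarray:
        vals = np.empty(len(positions))
        for k, pos in enumerate(positions):
            f = fitness(pos)
            vals[k] = f if np.isfinite(f) else np.inf
        return vals

    fit = evaluate(x)
    pbest, pbest_fit = x.copy(), fit.copy()
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    trajectory = [gbest_fit]

    for it in range(config.iterations):
        frac = it / max(config.iterations - 1, 1)
        w = config.w_start - (config.w_start - config.w_end) * frac
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        v = w * v + config.c1 * r1 * (pbest - x) + config.c2 * r2 * (gbest - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        fit = evaluate(x)
        improved = fit < pbest_fit
        pbest[improved] = x[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trajectory.append(gbest_fit)
    return gbest, gbest_fit, trajectory


def _stratified_indices(y: np.ndarray, train_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if len(members) < 2:
            train_idx.extend(members)
            continue
        order = rng.permutation(len(members))
        k = min(max(int(round(train_fraction * len(members))), 1), len(members) - 1)
        train_idx.extend(members[order[:k]])
        val_idx.extend(members[order[k:]])
    return np.sort(train_idx), np.sort(val_idx)


def train_pso_bpnn(
    features,
    labels,
    pso_config: PSOConfig | None = None,
    arch_bounds: tuple = ARCH_BOUNDS,
    proxy_epochs: int = 30,
    final_epochs: int = DEFAULT_EPOCHS,
    optimize_weights: bool = True,
    seed: int = 0,
) -> TrainedClassifier:
    """Two-stage PSO-optimized BPNN.

    Stage 1 searches (hidden₁, hidden₂, learning rate); stage 2 (optional)
    searches the initial weight vector of the winning architecture.  Both
    stages score candidates by validation cross-entropy after
    ``proxy_epochs`` of training on an internal stratified 80/20 split.
    The final network is trained on all provided samples for
    ``final_epochs`` from the stage-2 initialization.
    """
    X, names = _as_matrix(features)
    y = _encode_labels(labels)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    rng = np.random.default_rng(seed)
    tr, va = _stratified_indices(y, 0.8, rng)
    if len(va) == 0:
        raise ConfigError("internal validation split is empty")
    Xtr, ytr, Xva, yva = Xs[tr], y[tr], Xs[va], y[va]
    base = pso_config or PSOConfig(seed=seed)

    def make_spec(h1: float, h2: float, lr: float) -> BPNNSpec:
        return BPNNSpec(
            input_size=X.shape[1],
            hidden_sizes=(
                int(np.clip(round(h1), arch_bounds[0][0], arch_bounds[0][1])),
                int(np.clip(round(h2), arch_bounds[1][0], arch_bounds[1][1])),
            ),
            learning_rate=float(lr),
            epochs=proxy_epochs,
            seed=seed,
        )

    def stage1_fitness(pos: np.ndarray) -> float:
        net = MLP(make_spec(*pos))
        try:
            net.train(Xtr, ytr)
        except FloatingPointError:
            return np.inf
        return net.loss(Xva, yva)

    cfg1 = PSOConfig(
        swarm_size=base.swarm_size, iterations=base.iterations, c1=base.c1,
        c2=base.c2, w_start=base.w_start, w_end=base.w_end,
        bounds=tuple(arch_bounds), velocity_clamp=base.velocity_clamp,
        seed=base.seed,
    )
    best_arch, arch_fit, traj1 = pso_minimize(stage1_fitness, cfg1)
    spec = make_spec(*best_arch)
    logger.info(
        "PSO stage 1: hidden=%s lr=%.4g (val loss %.4f)",
        spec.hidden_sizes, spec.learning_rate, arch_fit,
    )

    template = MLP(spec)
    init_flat = template.get_flat()
    traj2: list[float] = []
    if optimize_weights:
        dim = template.n_parameters

        def stage2_fitness(pos: np.ndarray) -> float:
            net = MLP(spec)
            net.set_flat(pos)
            try:
                net.train(Xtr, ytr)
            except FloatingPointError:
                return np.inf
            return net.loss(Xva, yva)

        cfg2 = PSOConfig(
            swarm_size=base.swarm_size, iterations=base.iterations, c1=base.c1,
            c2=base.c2, w_start=base.w_start, w_end=base.w_end,
            bounds=((-WEIGHT_BOUND, WEIGHT_BOUND),) * dim,
            velocity_clamp=base.velocity_clamp, seed=base.seed + 1,
        )
        init_flat, _, traj2 = pso_minimize(stage2_fitness, cfg2)

    final = MLP(
        BPNNSpec(
            input_size=spec.input_size, hidden_sizes=spec.hidden_sizes,
            learning_rate=spec.learning_rate, epochs=final_epochs, seed=seed,
        )
    )
    final.set_flat(np.asarray(init_flat, dtype=float))
    history = final.train(Xs, y)
    return TrainedClassifier(
        kind="PSO-BPNN", model=final, class_order=CLASS_ORDER, scaler=scaler,
        feature_names=names, loss_history=history,
        details={
            "hidden_sizes": spec.hidden_sizes,
            "learning_rate": spec.learning_rate,
            "stage1_trajectory": traj1,
            "stage2_trajectory": traj2,
        },
    )


def predict(model: TrainedClassifier, features) -> tuple[list[str], np.ndarray]:
    """Apply a trained classifier.

    Returns predicted labels and an (n, 5) probability matrix ordered by the
    fixed class order.  The label is the argmax; exact ties break toward the
    earlier class.  A missing feature column raises an error naming it.
    """
    if isinstance(features, pd.DataFrame):
        missing = [n for n in model.feature_names if n not in features.columns]
        if missing:
            raise FormatError(f"missing feature column(s): {', '.join(missing)}")
        X = features[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise FormatError(
                f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
            )
    if model.scaler is not None:
        X = model.scaler.transform(X)
    probs = np.zeros((len(X), len(model.class_order)))
    if isinstance(model.model, MLP):
        probs = model.model.predict_proba(X)
    else:
        trained = model.model.predict_proba(X)
        for k, cls_idx in enumerate(model.model.classes_):
            probs[:, int(cls_idx)] = trained[:, k]
    labels = [model.class_order[int(i)] for i in np.argmax(probs, axis=1)]
    return labels, probs


def save_model(model: TrainedClassifier, path) -> None:
    """Persist a trained classifier (pickle archive)."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> TrainedClassifier:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedClassifier):
        raise FormatError(f"{path} does not contain a trained classifier")
    return model
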