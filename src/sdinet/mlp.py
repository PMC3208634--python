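"""Supervised multilayer perceptron, written out in full.

The classifier of the evolutionary pipeline is deliberately small: a
feed-forward network ``n_in -> n_hidden (default 4) -> 1`` with sigmoid
units throughout, trained by gradient descent with momentum on the
sum-of-squared-errors loss (cross-entropy available as an option).  The
single output is a continuous score in (0, 1); hard classification uses the
threshold convention that scores up to and including 0.5 map to class 0 and
scores strictly above 0.5 map to class 1.

Everything is seeded: weight initialisation and (in online mode) the
example order derive from the configured seed, so a trained model is a pure
function of (data, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


class TrainingDivergedError(RuntimeError):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


@dataclass
class TrainConfig:
    learning_rate: float = 0.1
    momentum: float = 0.9
    max_epochs: int = 500
    n_hidden: int = 4
    batch_mode: str = "full"  # 'full' | 'online'
    patience: int = 25
    min_improvement: float = 1e-9
    weight_init_scale: float = 0.5  # init ~ uniform(-scale, scale)
    loss: str = "sse"  # 'sse' | 'cross_entropy'
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_mode not in ("full", "online"):
            raise ValueError("batch_mode must be 'full' or 'online'")
        if self.loss not in ("sse", "cross_entropy"):
            raise ValueError("loss must be 'sse' or 'cross_entropy'")


@dataclass
class MlpModel:
    """Weights of the trained network; ``predict`` is the forward pass."""

    w_hidden: np.ndarray  # (n_hidden, n_inputs)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray  # (n_hidden,)
    b_out: float
    config: TrainConfig = field(default_factory=TrainConfig)

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[1]

    def predict(self, X) -> np.ndarray:
        """Continuous score in (0, 1) per row; deterministic."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"model expects {self.n_inputs} inputs, got {X.shape[1]}"
            )
        hidden = _sigmoid(X @ self.w_hidden.T + self.b_hidden)
        return _sigmoid(hidden @ self.w_out + self.b_out)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
            "config": asdict(self.config),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MlpModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            w_hidden=np.asarray(payload["w_hidden"], dtype=float),
            b_hidden=np.asarray(payload["b_hidden"], dtype=float),
            w_out=np.asarray(payload["w_out"], dtype=float),
            b_out=float(payload["b_out"]),
            config=TrainConfig(**payload["config"]),
        )


def classify(score, threshold: float = 0.5) -> np.ndarray:
    """Hard label from the continuous output: 1 iff score > threshold.

    A score of exactly 0.5 belongs to class 0 (the 0-0.5 / 0.51-1 rule).
    """
    return (np.asarray(score, dtype=float) > threshold).astype(int)


def _loss_and_grad(model, X, y, loss):
    hidden = _sigmoid(X @ model.w_hidden.T + model.b_hidden)  # (n, h)
    out = _sigmoid(hidden @ model.w_out + model.b_out)  # (n,)
    err = out - y
    if loss == "sse":
        value = 0.5 * float(err @ err)
        delta_out = err * out * (1.0 - out)
    else:  # cross-entropy: sigmoid derivative cancels
        eps = 1e-12
        value = -float(np.sum(y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps)))
        delta_out = err
    g_w_out = hidden.T @ delta_out
    g_b_out = float(delta_out.sum())
    delta_hidden = np.outer(delta_out, model.w_out) * hidden * (1.0 - hidden)
    g_w_hidden = delta_hidden.T @ X
    g_b_hidden = delta_hidden.sum(axis=0)
    return value, (g_w_hidden, g_b_hidden, g_w_out, g_b_out)


def train(X, y, config: TrainConfig | None = None) -> tuple[MlpModel, list[float]]:
    """Fit the network by (momentum) gradient descent.

    Returns the trained model and the per-epoch training-loss trajectory.
    Training stops at ``max_epochs`` or when the loss has not improved by
    ``min_improvement`` for ``patience`` consecutive epochs.
    """
    config = config or TrainConfig()
    config.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of records")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in the training data")

    rng = np.random.default_rng(config.seed)
    s = config.weight_init_scale
    h, d = config.n_hidden, X.shape[1]
    model = MlpModel(
        w_hidden=rng.uniform(-s, s, (h, d)),
        b_hidden=rng.uniform(-s, s, h),
        w_out=rng.uniform(-s, s, h),
        b_out=float(rng.uniform(-s, s)),
        config=config,
    )
    vel = [np.zeros_like(model.w_hidden), np.zeros_like(model.b_hidden),
           np.zeros_like(model.w_out), 0.0]

    def step(Xb, yb):
        value, grads = _loss_and_grad(model, Xb, yb, config.loss)
        for i, g in enumerate(grads):
            vel[i] = config.momentum * vel[i] - config.learning_rate * g
        model.w_hidden += vel[0]
        model.b_hidden += vel[1]
        model.w_out += vel[2]
        model.b_out += vel[3]
        return value

    errors: list[float] = []
    best = np.inf
    stale = 0
    for _ in range(config.max_epochs):
        if config.batch_mode == "full":
            value = step(X, y)
        else:
            order = rng.permutation(X.shape[0])
            for i in order:
                step(X[i : i + 1], y[i : i + 1])
            value, _ = _loss_and_grad(model, X, y, config.loss)
        if not (
            np.isfinite(value)
            and np.isfinite(model.w_hidden).all()
            and np.isfinite(model.w_out).all()
        ):
            raise TrainingDivergedError(
                f"training diverged (non-finite loss or weights) at epoch "
                f"{len(errors) + 1}; learning_rate={config.learning_rate}"
            )
        errors.append(value)
        if value < best - config.min_improvement:
            best = value
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return model, errors
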