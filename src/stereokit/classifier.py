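"""The action-recognition network and its training loop.

Architecture (many-to-one): each frame's 13 x/y joint pairs are flattened
to 26 features, passed through a fully connected layer with ReLU, then
through two stacked LSTM layers; only the final time step's hidden state
feeds a fully connected softmax head with one output per action class.  A
detection is reported only when the winning class probability strictly
exceeds a threshold (default 0.9).

Zero-padded frames are passed through unmasked: short clips are padded with
all-zero skeleton frames and the network reads them like any other input,
so the trailing zeros become part of the learned signal.

Training standardizes the 26 per-frame features with the training set's
mean and standard deviation (stored as model buffers and applied inside
``forward``); without this, the optimizer reliably stalls on class pairs
whose distinguishing signal is small relative to the coordinate scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .lstm import Adam, DTYPE, Dense, LSTMLayer, cross_entropy, softmax
from .types import ACTIONS, ActionSample, N_CLASSES

logger = logging.getLogger(__name__)

#: Probability a class must strictly exceed to count as a detection.
DETECTION_THRESHOLD = 0.9

N_FEATURES = 26  # 13 joints x 2 coordinates per frame


@dataclass
class ModelConfig:
    """Hyperparameters of the recognition network.

    Defaults are the best parameters from the time-steps/hidden-states
    sweep: 32 time steps (~1.3 s at 25 fps), 128 hidden states, learning
    rate 0.001.  The FC front width defaults to the hidden size.  Optimizer
    (Adam), epoch budget and batch size are implementation defaults.
    """

    time_steps: int = 32
    hidden_states: int = 128
    learning_rate: float = 0.001
    n_classes: int = N_CLASSES
    fc_width: int | None = None
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    #: stop early once training accuracy has saturated (>= plateau_acc for
    #: plateau_patience consecutive epochs); 0 disables.
    plateau_acc: float = 0.999
    plateau_patience: int = 2

    def __post_init__(self) -> None:
        if self.hidden_states < 1:
            raise ValueError("hidden_states must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.time_steps < 1:
            raise ValueError("time_steps must be >= 1")
        if self.fc_width is None:
            self.fc_width = self.hidden_states


@dataclass
class Prediction:
    probs: np.ndarray
    label: int = field(init=False)
    detected: int | None = field(init=False)

    threshold: float = DETECTION_THRESHOLD

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.label = int(np.argmax(self.probs))
        self.detected = self.label if self.probs[self.label] > self.threshold else None

    @property
    def label_name(self) -> str:
        return ACTIONS[self.label]


class ActionRecognitionModel:
    """FC+ReLU -> two stacked LSTMs -> softmax head over the action classes."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        H = cfg.hidden_states
        self.fc_in = Dense(N_FEATURES, cfg.fc_width, rng, relu=True)
        self.lstm1 = LSTMLayer(cfg.fc_width, H, rng)
        self.lstm2 = LSTMLayer(H, H, rng)
        self.fc_out = Dense(H, cfg.n_classes, rng)
        self.layers = [self.fc_in, self.lstm1, self.lstm2, self.fc_out]
        # input standardization buffers, fitted from the training set
        self._mu = np.zeros(N_FEATURES, dtype=DTYPE)
        self._sd = np.ones(N_FEATURES, dtype=DTYPE)

    # -- plumbing ---------------------------------------------------------

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    @staticmethod
    def _flatten(X: np.ndarray) -> np.ndarray:
        """(B, T, 13, 2) or (B, T, 26) -> (B, T, 26) float32."""
        X = np.asarray(X)
        if X.ndim == 4:
            X = X.reshape(X.shape[0], X.shape[1], -1)
        if X.ndim != 3 or X.shape[2] != N_FEATURES:
            raise ValueError(f"expected (B, T, 13, 2) input, got shape {X.shape}")
        return np.ascontiguousarray(X, dtype=DTYPE)

    # -- forward / backward ----------------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (B, n_classes)."""
        x = self._flatten(X)
        if x.shape[1] != self.cfg.time_steps:
            raise ValueError(
                f"expected {self.cfg.time_steps} time steps, got {x.shape[1]}"
            )
        x = (x - self._mu) / self._sd
        h = self.fc_in.forward(x)
        h = self.lstm1.forward(h)
        h = self.lstm2.forward(h)
        logits = self.fc_out.forward(h[:, -1])  # many-to-one readout
        return softmax(logits)

    def _backward(self, probs: np.ndarray, labels: np.ndarray) -> None:
        B, T = probs.shape[0], self.cfg.time_steps
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        dh_last = self.fc_out.backward(dlogits.astype(DTYPE))
        dh_seq = np.zeros((B, T, self.cfg.hidden_states), dtype=DTYPE)
        dh_seq[:, -1] = dh_last
        dx = self.lstm2.backward(dh_seq)
        dx = self.lstm1.backward(dx)
        self.fc_in.backward(dx)

    # -- training / inference --------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> list[dict]:
        """Minimize cross-entropy with Adam; returns the per-epoch history."""
        cfg = self.cfg
        X = self._flatten(X)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("empty training set")
        flat = X.reshape(-1, N_FEATURES)
        self._mu[...] = flat.mean(axis=0)
        self._sd[...] = np.maximum(flat.std(axis=0), 1e-6)
        opt = Adam(self.params, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        history: list[dict] = []
        plateau_run = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(X))
            losses = []
            correct = 0
            for start in range(0, len(X), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                probs = self.forward(X[idx])
                loss = cross_entropy(probs, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {loss!r}; "
                        f"lr={cfg.learning_rate}, batch={cfg.batch_size}"
                    )
                losses.append(loss)
                correct += int((probs.argmax(axis=1) == y[idx]).sum())
                if cfg.learning_rate > 0:
                    self._backward(probs, y[idx])
                    opt.step(self.grads)
            record = {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "train_acc": correct / len(X),
            }
            if X_val is not None and y_val is not None:
                record["val_acc"] = self.score(X_val, y_val)
            history.append(record)
            logger.debug("epoch %(epoch)d loss %(loss).4f acc %(train_acc).4f", record)
            if cfg.plateau_patience > 0 and record["train_acc"] >= cfg.plateau_acc:
                plateau_run += 1
                if plateau_run >= cfg.plateau_patience:
                    break
            else:
                plateau_run = 0
        return history

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = self._flatten(X)
        return np.concatenate(
            [self.forward(X[i:i + batch_size]) for i in range(0, len(X), batch_size)]
        )

    def predict(self, sample: ActionSample | np.ndarray,
                threshold: float = DETECTION_THRESHOLD) -> Prediction:
        data = sample.data if isinstance(sample, ActionSample) else np.asarray(sample)
        probs = self.predict_proba(data[None])[0]
        return Prediction(probs=probs, threshold=threshold)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self.predict_proba(X)
        return float((probs.argmax(axis=1) == np.asarray(y)).mean())

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        arrays["mu"], arrays["sd"] = self._mu, self._sd
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg)))

    @classmethod
    def load(cls, path: str | Path) -> "ActionRecognitionModel":
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.params):
                p[...] = data[f"p{i}"]
            model._mu[...] = data["mu"]
            model._sd[...] = data["sd"]
        return model


def build_model(cfg: ModelConfig) -> ActionRecognitionModel:
    return ActionRecognitionModel(cfg)


def expected_parameter_count(cfg: ModelConfig) -> int:
    """Closed-form parameter count of the architecture, for sanity checks."""
    F, H, C = cfg.fc_width, cfg.hidden_states, cfg.n_classes
    fc_in = N_FEATURES * F + F
    lstm1 = 4 * (F * H + H * H + H)
    lstm2 = 4 * (H * H + H * H + H)
    fc_out = H * C + C
    return fc_in + lstm1 + lstm2 + fc_out


def hyperparameter_sweep(
    sequences: list[np.ndarray],
    labels: list[int],
    train_idx: list[int],
    test_idx: list[int],
    time_steps_grid: list[int],
    hidden_grid: list[int],
    base_cfg: ModelConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """Test accuracy for every (time_steps, hidden_states) grid cell.

    ``sequences`` are variable-length (n, 13, 2) clips; each grid value of T
    rebuilds fixed-length samples by pad/subsample before training.
    """
    from .sequence_prep import normalize_length

    if not time_steps_grid or not hidden_grid:
        raise ValueError("grids must be non-empty")
    base = base_cfg or ModelConfig()
    results = []
    for T in time_steps_grid:
        rng = np.random.default_rng(seed)
        samples = np.stack(
            [normalize_length(s, T, rng=rng).data for s in sequences]
        )
        y = np.asarray(labels)
        for H in hidden_grid:
            cfg = ModelConfig(
                time_steps=T, hidden_states=H, learning_rate=base.learning_rate,
                epochs=base.epochs, batch_size=base.batch_size, seed=seed,
                plateau_acc=base.plateau_acc, plateau_patience=base.plateau_patience,
            )
            model = ActionRecognitionModel(cfg)
            model.fit(samples[train_idx], y[train_idx])
            acc = model.score(samples[test_idx], y[test_idx])
            results.append({"time_steps": T, "hidden_states": H, "test_acc": acc})
    return results
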