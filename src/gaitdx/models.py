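"""Classifiers for the four gait forms and their training loops.

Three model families operate on the extracted features:

* an MLP on the flattened 81 x 20 spectral vectors (one prediction per
  trial),
* a single-layer LSTM on 75 x 81 angle windows (one prediction per
  window), and
* an RBF-kernel SVM baseline on the spectral vectors.

The shared training loss is the categorical cross entropy averaged over
both samples and classes,

    L = -(1/(N*M)) sum_n sum_m  y_t[n,m] * ln y_p[n,m],

with N samples and M = 4 forms; note the 1/M factor, so the uniform
predictor scores ln(4)/4 ~= 0.347 and the MLP stopping threshold of 0.10
corresponds to a conventional per-sample cross entropy of 0.40.

Both networks train with Adam at default parameters, minibatches of 100
with per-epoch reshuffling.  The MLP stops when the epoch training loss
drops below 0.10 (hard cap 500 epochs); the LSTM always trains for exactly
15 epochs.  Features are standardized to zero mean / unit variance using
training-set statistics before entering any model.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from ._nn import LSTM, Adam, Dense, Dropout, ReLU, Sequential, softmax
from .dataset import LabeledExample

logger = logging.getLogger(__name__)

N_FORMS = 4
_CLIP = 1e-12


@dataclasses.dataclass(frozen=True)
class MlpConfig:
    """Fully connected network configuration (input: 1620 spectral dims)."""

    hidden_sizes: tuple[int, ...] = (256, 128, 64, 32)
    dropout_rate: float = 0.5
    input_dim: int = 1620
    output_dim: int = N_FORMS

    @staticmethod
    def layer_growth(n_layers: int) -> tuple[int, ...]:
        """Hidden-layer sweep rule: first layer 32 units, each further
        layer doubling the previous (32, 64, 128, ...)."""
        return tuple(32 * 2**i for i in range(n_layers))


@dataclasses.dataclass(frozen=True)
class LstmConfig:
    """Single-recurrent-layer network configuration (input: 75 x 81)."""

    recurrent_units: int = 128
    fc_sizes: tuple[int, ...] = (128, 64, 32)
    input_dim: int = 81
    output_dim: int = N_FORMS


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 100
    mlp_loss_threshold: float = 0.10
    mlp_max_epochs: int = 500
    lstm_epochs: int = 15
    reshuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.mlp_max_epochs, self.lstm_epochs) < 1:
            raise ValueError("batch_size and epoch counts must be positive")


@dataclasses.dataclass
class Prediction:
    """A probability distribution over the 4 forms for one trial/window."""

    probs: np.ndarray
    patient_id: str | None = None
    trial_id: str | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_FORMS,) or np.any(self.probs < 0):
            raise ValueError("probs must be a non-negative length-4 vector")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must sum to 1")

    @property
    def form(self) -> int:
        return int(np.argmax(self.probs)) + 1


def categorical_cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Cross entropy averaged over both the N samples and the M classes.

    Predicted probabilities below 1e-12 at the true class are clipped so
    confident-wrong predictions yield a large finite loss.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    n, m = y_true.shape
    if np.any(y_pred[y_true > 0] < _CLIP):
        logger.warning("predicted probabilities clipped at %.0e for the loss", _CLIP)
    return float(-(y_true * np.log(np.clip(y_pred, _CLIP, None))).sum() / (n * m))


class _Standardizer:
    """Zero-mean/unit-variance scaling fit on training features."""

    def fit(self, x: np.ndarray) -> "_Standardizer":
        flat = x.reshape(-1, x.shape[-1])
        self.mean = flat.mean(axis=0)
        self.std = flat.std(axis=0)
        self.std[self.std < 1e-9] = 1.0
        return self

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


class _NetClassifier:
    """Shared plumbing: a Sequential net with softmax head and a scaler."""

    def __init__(self, net: Sequential, config):
        self.net = net
        self.config = config
        self.scaler: _Standardizer | None = None

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.scaler is not None:
            x = self.scaler(x)
        return softmax(self.net.forward(x, training=False))

    def predict(self, examples: list[LabeledExample]) -> list[Prediction]:
        x = np.stack([e.features for e in examples])
        probs = self.predict_proba(x)
        return [
            Prediction(p, e.patient_id, e.trial_id) for p, e in zip(probs, examples)
        ]


class MlpClassifier(_NetClassifier):
    pass


class LstmClassifier(_NetClassifier):
    pass


def build_mlp(config: MlpConfig = MlpConfig(), seed: int = 0) -> MlpClassifier:
    """Dense ReLU stack with one dropout layer after the first hidden layer
    and a softmax output; an empty ``hidden_sizes`` reduces the network to
    multinomial logistic regression."""
    rng = np.random.default_rng(seed)
    layers = []
    n_in = config.input_dim
    for k, width in enumerate(config.hidden_sizes):
        layers += [Dense(n_in, width, rng), ReLU()]
        if k == 0 and config.dropout_rate > 0:
            layers.append(Dropout(config.dropout_rate, rng))
        n_in = width
    layers.append(Dense(n_in, config.output_dim, rng))
    return MlpClassifier(Sequential(layers), config)


def build_lstm(config: LstmConfig = LstmConfig(), seed: int = 0) -> LstmClassifier:
    """One tanh LSTM layer read at its final hidden state, a ReLU dense
    stack, and a softmax output."""
    rng = np.random.default_rng(seed)
    layers = [LSTM(config.input_dim, config.recurrent_units, rng)]
    n_in = config.recurrent_units
    for width in config.fc_sizes:
        layers += [Dense(n_in, width, rng), ReLU()]
        n_in = width
    layers.append(Dense(n_in, config.output_dim, rng))
    return LstmClassifier(Sequential(layers), config)


def _training_arrays(examples: list[LabeledExample]):
    x = np.stack([e.features for e in examples]).astype(float)
    y = np.stack([e.label for e in examples])
    return x, y


def _run_epochs(model, x, y, cfg: TrainConfig, n_epochs, stop_threshold=None):
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.net)
    n, m = len(x), y.shape[1]
    trace = []
    for _ in range(n_epochs):
        order = rng.permutation(n) if cfg.reshuffle_each_epoch else np.arange(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.net.forward(xb, training=True)
            probs = softmax(logits)
            loss = categorical_cross_entropy(yb, probs)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {len(trace) + 1}"
                )
            total += loss * len(idx)
            model.net.backward((probs - yb) / (len(idx) * m))
            optimizer.step()
        trace.append(total / n)
        if stop_threshold is not None and trace[-1] < stop_threshold:
            break
    return trace


def train_mlp(
    model: MlpClassifier, train: list[LabeledExample], cfg: TrainConfig = TrainConfig()
) -> tuple[MlpClassifier, list[float]]:
    """Train until the epoch loss drops below the 0.10 threshold (at most
    500 epochs); returns the model and its per-epoch loss trace."""
    x, y = _training_arrays(train)
    model.scaler = _Standardizer().fit(x)
    trace = _run_epochs(
        model, model.scaler(x), y, cfg, cfg.mlp_max_epochs, cfg.mlp_loss_threshold
    )
    return model, trace


def train_lstm(
    model: LstmClassifier, train: list[LabeledExample], cfg: TrainConfig = TrainConfig()
) -> tuple[LstmClassifier, list[float]]:
    """Train for exactly the configured number of epochs (default 15)."""
    x, y = _training_arrays(train)
    model.scaler = _Standardizer().fit(x)
    trace = _run_epochs(model, model.scaler(x), y, cfg, cfg.lstm_epochs)
    return model, trace


class SvmBaseline:
    """One-vs-rest RBF-kernel SVM on standardized spectral vectors."""

    def __init__(self, C: float = 1.0, gamma="scale"):
        self.C = C
        self.gamma = gamma
        self._clf = OneVsRestClassifier(SVC(kernel="rbf", C=C, gamma=gamma))
        self.scaler: _Standardizer | None = None

    def predict(self, examples: list[LabeledExample]) -> list[Prediction]:
        x = self.scaler(np.stack([e.features for e in examples]))
        forms = self._clf.predict(x)
        out = []
        for f, e in zip(forms, examples):
            probs = np.zeros(N_FORMS)
            probs[int(f) - 1] = 1.0
            out.append(Prediction(probs, e.patient_id, e.trial_id))
        return out


def train_svm_baseline(
    train: list[LabeledExample], C: float = 1.0, gamma="scale"
) -> SvmBaseline:
    """Fit the RBF-SVM baseline on spectral-mode examples."""
    x, y = _training_arrays(train)
    forms = y.argmax(axis=1) + 1
    if len(np.unique(forms)) < 2:
        raise ValueError("SVM baseline needs at least two classes in training data")
    model = SvmBaseline(C=C, gamma=gamma)
    model.scaler = _Standardizer().fit(x)
    model._clf.fit(model.scaler(x), forms)
    return model
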