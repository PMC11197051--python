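"""Nonlinear windowed decoder: a feed-forward network over a spatiotemporal
window of EMG features.

Each input is the flattened ``history_samples x channels`` image of the most
recent feature samples (zero-padded at trial starts, so predictions are
causal and never mix trials). The default stack has eight weighted layers
(seven hidden + output). Training is minibatch Adam with early stopping on
trials held out of the training set, all seeded for reproducibility.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor

from .dataset import TrainingDataset
from .features import FeatureMatrix
from .kinematics import KinematicTrace

DEFAULT_HIDDEN = (96, 64, 64, 48, 32, 24, 16)


@dataclass
class WindowedNetSpec:
    """Architecture and optimization settings.

    ``validation`` is either ``{"n_trials": k}`` (trials re-reserved from the
    training split, the offline default of 5) or ``{"fraction": f}``.
    """

    history_samples: int = 10
    hidden_layers: tuple[int, ...] = DEFAULT_HIDDEN
    learning_rate: float = 1e-4
    validation: dict = field(default_factory=lambda: {"n_trials": 5})
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.history_samples < 1:
            raise ValueError("history_samples must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def small_spec(seed: int = 0) -> WindowedNetSpec:
    """Desk-scale spec: short history, two hidden layers, fast optimizer
    settings; used by the reduced-channel learning-curve analyses."""
    return WindowedNetSpec(history_samples=5, hidden_layers=(40, 20),
                           learning_rate=1e-3, max_epochs=40, patience=6, seed=seed)


@dataclass
class WindowedNetModel:
    net: MLPRegressor
    spec: WindowedNetSpec
    feat_mean: np.ndarray
    feat_std: np.ndarray
    n_channels: int
    history: list[float] = field(default_factory=list)  # per-epoch validation RMSE


def build_windows(features: np.ndarray, history: int,
                  trial_index: np.ndarray | None = None) -> np.ndarray:
    """Flattened trailing windows, zero-padded before each trial start."""
    f = np.asarray(features, dtype=np.float64)
    n, c = f.shape
    out = np.zeros((n, history, c))
    t = np.arange(n)
    for s in range(history):
        src = t - s
        ok = src >= 0
        if trial_index is not None:
            ok &= trial_index[np.maximum(src, 0)] == trial_index
        out[ok, history - 1 - s] = f[src[ok]]
    return out.reshape(n, history * c)


def _split_validation(trials: np.ndarray, spec: WindowedNetSpec,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if "n_trials" in spec.validation:
        n_val = int(spec.validation["n_trials"])
    else:
        n_val = max(1, round(float(spec.validation["fraction"]) * trials.size))
    if n_val >= trials.size:
        raise ValueError("validation trials must be fewer than training trials")
    val = rng.choice(trials, size=n_val, replace=False)
    train = np.setdiff1d(trials, val)
    return train, np.sort(val)


def fit_windowed_net(train: TrainingDataset, spec: WindowedNetSpec | None = None
                     ) -> WindowedNetModel:
    """Train with minibatch Adam and early stopping on held-out trials."""
    spec = spec or WindowedNetSpec()
    rng = np.random.default_rng(spec.seed)
    trials = np.unique(train.trial_index)
    tr_trials, val_trials = _split_validation(trials, spec, rng)

    X = build_windows(train.features, spec.history_samples, train.trial_index)
    y = np.asarray(train.labels, dtype=np.float64)
    tr_rows = train.rows_for_trials(tr_trials)
    val_rows = train.rows_for_trials(val_trials)

    mean = train.features[tr_rows].mean(axis=0)
    std = train.features[tr_rows].std(axis=0)
    std[std < 1e-12] = 1.0
    tile = spec.history_samples
    mean_w = np.tile(mean, tile)
    std_w = np.tile(std, tile)
    Xs = (X - mean_w) / std_w

    net = MLPRegressor(hidden_layer_sizes=spec.hidden_layers, solver="adam",
                       learning_rate_init=spec.learning_rate,
                       batch_size=min(spec.batch_size, tr_rows.size),
                       random_state=spec.seed)
    Xtr, ytr = Xs[tr_rows], y[tr_rows]
    Xval, yval = Xs[val_rows], y[val_rows]
    best = np.inf
    best_state = None
    wait = 0
    history = []
    for epoch in range(spec.max_epochs):
        # one shuffled pass over the training rows (internal minibatching)
        net.partial_fit(Xtr, ytr)
        pred = net.predict(Xval)
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError("non-finite validation predictions during training")
        val_rmse = float(np.sqrt(np.mean((pred - yval) ** 2)))
        history.append(val_rmse)
        if val_rmse < best - 1e-6:
            best = val_rmse
            best_state = (copy.deepcopy(net.coefs_), copy.deepcopy(net.intercepts_))
            wait = 0
        else:
            wait += 1
            if wait > spec.patience:
                break
    if best_state is not None:
        net.coefs_, net.intercepts_ = best_state
    return WindowedNetModel(net=net, spec=spec, feat_mean=mean, feat_std=std,
                            n_channels=train.features.shape[1], history=history)


def windowed_net_predict(model: WindowedNetModel, features: FeatureMatrix | np.ndarray,
                         trial_index: np.ndarray | None = None) -> KinematicTrace:
    """Causal predictions over a feature stream, clipped to [-1, 1]."""
    f = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if f.shape[1] != model.n_channels:
        raise ValueError("feature channel count does not match the trained model")
    X = build_windows(f, model.spec.history_samples, trial_index)
    Xs = (X - np.tile(model.feat_mean, model.spec.history_samples)) / \
        np.tile(model.feat_std, model.spec.history_samples)
    pred = np.clip(model.net.predict(Xs), -1.0, 1.0)
    rate = features.rate if isinstance(features, FeatureMatrix) else 30.0
    return KinematicTrace(pred, rate, [])
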