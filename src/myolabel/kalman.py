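"""Linear Kalman-filter decoder and the modified-Kalman post-processing.

The state is the 8-vector of joint positions. The prior model (A, W) is fit
by least squares of x_t on x_{t-1}; the likelihood model (H, Q) by ridge
regression of a correlation-selected feature subset on the kinematics. The
runtime modification (MKF) zeroes predictions below a fraction of the full
kinematic range and linearly rescales the remainder to the full range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import TrainingDataset
from .features import FeatureMatrix
from .kinematics import KinematicTrace


@dataclass
class MKFConfig:
    threshold: float = 0.20
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must lie in [0, 1)")


@dataclass
class KalmanModel:
    A: np.ndarray
    W: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    channel_subset: np.ndarray
    ridge_lambda: float

    def __post_init__(self) -> None:
        for name in ("W", "Q"):
            m = getattr(self, name)
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")

    @property
    def n_dof(self) -> int:
        return self.A.shape[0]


def _observations(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    return features.values if isinstance(features, FeatureMatrix) else np.asarray(features)


def select_channels(features: np.ndarray, labels: np.ndarray, n_channels: int) -> np.ndarray:
    """Indices of the feature columns with the highest absolute correlation
    to any DOF (constant columns score zero)."""
    f = features - features.mean(axis=0)
    l = labels - labels.mean(axis=0)
    fs = f.std(axis=0)
    ls = l.std(axis=0)
    fs[fs == 0] = np.inf
    ls[ls == 0] = np.inf
    corr = (f / fs).T @ (l / ls) / f.shape[0]
    score = np.abs(corr).max(axis=1)
    order = np.argsort(-score, kind="stable")[:n_channels]
    return np.sort(order)


def fit_kalman(train: TrainingDataset, ridge_lambda: float = 1e-3,
               n_channels: int = 48) -> KalmanModel:
    """Fit prior and likelihood models from aligned features and labels.

    Consecutive-sample pairs that cross a trial boundary are excluded from
    the prior fit. Deterministic given its input.
    """
    X = np.asarray(train.labels, dtype=np.float64)
    F = np.asarray(train.features, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if n_channels > F.shape[1]:
        raise ValueError("n_channels exceeds available feature columns")

    same_trial = train.trial_index[1:] == train.trial_index[:-1]
    x_prev, x_next = X[:-1][same_trial], X[1:][same_trial]
    # ridge-loaded: preprogrammed labels can be exactly collinear across DOFs
    # that only ever move together (e.g. digits within a grip movement)
    G = x_prev.T @ x_prev + ridge_lambda * np.eye(X.shape[1])
    try:
        A = np.linalg.solve(G, x_prev.T @ x_next).T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations in the prior fit; use ridge_lambda > 0") from err
    resid = x_next - x_prev @ A.T
    W = resid.T @ resid / resid.shape[0]

    subset = select_channels(F, X, n_channels)
    Y = F[:, subset]
    d = X.shape[1]
    gram = X.T @ X + ridge_lambda * np.eye(d)
    try:
        H = np.linalg.solve(gram, X.T @ Y).T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular normal equations in the likelihood fit; "
            "use ridge_lambda > 0") from err
    if ridge_lambda == 0 and np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError(
            "ill-conditioned likelihood fit at ridge_lambda=0; use ridge_lambda > 0")
    robs = Y - X @ H.T
    Q = robs.T @ robs / robs.shape[0] + ridge_lambda * np.eye(Y.shape[1])
    W = (W + W.T) / 2
    Q = (Q + Q.T) / 2
    return KalmanModel(A=A, W=W, H=H, Q=Q, channel_subset=subset, ridge_lambda=ridge_lambda)


PRIOR_VARIANCE = 1e2  # diffuse initial state covariance


def kalman_filter(model: KalmanModel, obs: np.ndarray, clip: bool = True) -> np.ndarray:
    """Run the predict/update recursion over an observation stream."""
    A, W, H, Q = model.A, model.W, model.H, model.Q
    d = model.n_dof
    x = np.zeros(d)
    P = PRIOR_VARIANCE * np.eye(d)
    out = np.empty((obs.shape[0], d))
    eye = np.eye(d)
    for t in range(obs.shape[0]):
        x = A @ x
        P = A @ P @ A.T + W
        S = H @ P @ H.T + Q
        try:
            K = np.linalg.solve(S, H @ P).T
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "non-invertible innovation covariance; Q is ill-conditioned") from err
        x = x + K @ (obs[t] - H @ x)
        P = (eye - K @ H) @ P
        out[t] = x
    return np.clip(out, -1.0, 1.0) if clip else out


def kalman_predict(model: KalmanModel, features: FeatureMatrix | np.ndarray) -> KinematicTrace:
    """Decode a feature stream into a clipped kinematic trace."""
    F = _observations(features)
    obs = F[:, model.channel_subset] if F.shape[1] != model.H.shape[0] else F
    rate = features.rate if isinstance(features, FeatureMatrix) else 30.0
    return KinematicTrace(kalman_filter(model, obs), rate, [])


def mkf_postprocess(pred: KinematicTrace | np.ndarray, cfg: MKFConfig | None = None):
    """Threshold/rescale runtime rule.

    Per sample and DOF with magnitude m: below the threshold the output is
    zero; above it, sign(value) * (m - threshold) / (1 - threshold) * gain,
    clipped to [-1, 1]. Odd, continuous at the threshold, and monotone.
    """
    cfg = cfg or MKFConfig()
    vals = pred.values if isinstance(pred, KinematicTrace) else np.asarray(pred, dtype=np.float64)
    m = np.abs(vals)
    scaled = (m - cfg.threshold) / (1.0 - cfg.threshold) * cfg.gain
    out = np.where(m < cfg.threshold, 0.0, np.sign(vals) * scaled)
    out = np.clip(out, -1.0, 1.0)
    if isinstance(pred, KinematicTrace):
        return KinematicTrace(out, pred.rate, list(pred.trial_boundaries))
    return out
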