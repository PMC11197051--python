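"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (per-window loops, stacked
least-squares solves) kept separate from the library code paths they check.
"""

import numpy as np


def brute_force_mav(raw: np.ndarray, raw_rate: float, window_s: float,
                    out_rate: float) -> np.ndarray:
    """Trailing-window MAV for every single-ended channel and every ordered
    pair, one explicit window at a time."""
    n_raw, n_ch = raw.shape
    w = round(window_s * raw_rate)
    n_out = int(np.floor((n_raw - 1) * out_rate / raw_rate)) + 1
    signals = [raw[:, i] for i in range(n_ch)]
    signals += [raw[:, i] - raw[:, j] for i in range(n_ch) for j in range(i + 1, n_ch)]
    out = np.empty((n_out, len(signals)))
    for k in range(n_out):
        anchor = min(int(round(k * raw_rate / out_rate)), n_raw - 1)
        lo = max(anchor - w + 1, 0)
        for c, sig in enumerate(signals):
            out[k, c] = np.mean(np.abs(sig[lo:anchor + 1]))
    return out


def batch_kalman_means(A, W, H, Q, P0, ys):
    """Filtered state means via stacked weighted least squares.

    For each t, the filtered mean equals the MAP estimate of x_t in the
    joint Gaussian over x_{0..t} given y_{0..t}, with x_0 ~ N(0, A P0 A' + W)
    (matching a filter that predicts from a zero state with covariance P0
    before the first update). Solved densely from the information matrix.
    """
    d = A.shape[0]
    T = ys.shape[0]
    Wi = np.linalg.inv(W)
    Qi = np.linalg.inv(Q)
    P0i = np.linalg.inv(A @ P0 @ A.T + W)
    out = np.empty((T, d))
    for t in range(T):
        n = t + 1
        J = np.zeros((n * d, n * d))
        b = np.zeros(n * d)
        J[:d, :d] += P0i
        for k in range(n):
            sl = slice(k * d, (k + 1) * d)
            J[sl, sl] += H.T @ Qi @ H
            b[k * d:(k + 1) * d] += H.T @ Qi @ ys[k]
        for k in range(1, n):
            s0 = slice((k - 1) * d, k * d)
            s1 = slice(k * d, (k + 1) * d)
            J[s1, s1] += Wi
            J[s0, s0] += A.T @ Wi @ A
            J[s0, s1] += -A.T @ Wi
            J[s1, s0] += -Wi @ A
        x = np.linalg.solve(J, b)
        out[t] = x[t * d:(t + 1) * d]
    return out


def random_kalman_system(rng, d=3, m=4):
    """A random stable linear-Gaussian system and a simulated trajectory."""
    A = 0.9 * np.eye(d) + 0.05 * rng.standard_normal((d, d))
    A *= 0.95 / max(np.abs(np.linalg.eigvals(A)).max(), 0.95)
    Lw = 0.1 * rng.standard_normal((d, d))
    W = Lw @ Lw.T + 0.01 * np.eye(d)
    H = rng.standard_normal((m, d))
    Lq = 0.2 * rng.standard_normal((m, m))
    Q = Lq @ Lq.T + 0.05 * np.eye(m)
    T = 40
    x = np.zeros(d)
    xs, ys = [], []
    cw = np.linalg.cholesky(W)
    cq = np.linalg.cholesky(Q)
    for _ in range(T):
        x = A @ x + cw @ rng.standard_normal(d)
        y = H @ x + cq @ rng.standard_normal(m)
        xs.append(x.copy())
        ys.append(y)
    return A, W, H, Q, np.array(ys)
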