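"""Per-epoch functional networks from lag-maximized cross-correlation.

For every pair of channels the Pearson correlation is computed on the
overlapping samples at every integer lag ``h`` in ``[-max_lag, +max_lag]``;
the lag with maximal ``|r|`` is selected and the signed ``r`` at that lag
becomes the edge weight.  A positive lag ``h`` for pair ``(i, j)`` means
channel *j* lags (is delayed relative to) channel *i* by ``h`` samples.
Ties in ``|r|`` are broken toward the smallest ``|h|``, then the negative
lag, so results are deterministic.

Normalization uses the overlapping segment's own means and SDs at each lag
(no zero padding), so every weight is a true correlation in ``[-1, 1]`` and
comparable across pairs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datatypes import ConnectivityMatrix, Epoch, LagMatrix

__all__ = [
    "max_lag_crosscorr",
    "connectivity_matrix",
    "active_network",
    "default_max_lag",
    "DEFAULT_MAX_LAG_MS",
]

DEFAULT_MAX_LAG_MS = 100.0


def default_max_lag(fs: float, max_lag_ms: float = DEFAULT_MAX_LAG_MS) -> int:
    """Lag bound in samples for a physiological 100 ms window (51 at 512 Hz)."""
    return int(round(max_lag_ms / 1000.0 * fs))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("correlation undefined for a constant segment")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _lag_priority(max_lag: int):
    """Candidate lags in tie-break order: 0, -1, +1, -2, +2, ..."""
    yield 0
    for h in range(1, max_lag + 1):
        yield -h
        yield h


def max_lag_crosscorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[float, int]:
    """Correlation of two signals maximized in absolute value over lags.

    Returns ``(r, h)`` where ``r`` is the signed Pearson correlation of the
    overlapping samples at the optimal lag ``h``; ``h > 0`` means ``y`` is
    delayed relative to ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("signals must be 1-D and equally long")
    if max_lag < 0 or max_lag >= len(x):
        raise ValueError("max_lag must satisfy 0 <= max_lag < signal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant signal")
    best_r, best_h = 0.0, 0
    first = True
    for h in _lag_priority(max_lag):
        if h >= 0:
            r = _pearson(x[: len(x) - h] if h else x, y[h:])
        else:
            r = _pearson(x[-h:], y[: len(y) + h])
        if first or abs(r) > abs(best_r):
            best_r, best_h = r, h
            first = False
    return best_r, best_h


def _standardized(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    bad = np.where(sd.ravel() == 0)[0]
    if bad.size:
        raise ValueError(f"channel {bad[0]} is constant over the correlation window")
    return X / sd


def connectivity_matrix(
    epoch: Epoch,
    max_lag: Optional[int] = None,
    epoch_index: int = 0,
) -> tuple[ConnectivityMatrix, LagMatrix]:
    """All-pairs lag-optimized correlation network for one epoch.

    Every unordered channel pair is evaluated once (vectorized across pairs,
    one matrix product per lag) and mirrored, so the weight matrix is exactly
    symmetric with zero diagonal and the lag matrix exactly antisymmetric.
    """
    X = np.asarray(epoch.samples, dtype=float)
    n, L = X.shape
    if n < 2:
        raise ValueError("need at least 2 channels")
    if max_lag is None:
        max_lag = default_max_lag(epoch.fs)
    if max_lag >= L:
        raise ValueError("max_lag must be smaller than the epoch length")
    for ch in range(n):
        if np.ptp(X[ch]) == 0:
            raise ValueError(f"channel {ch} is constant; correlation undefined")

    best_r = np.zeros((n, n))
    best_h = np.zeros((n, n), dtype=int)
    # M_h[i, j] = corr(x_i[:L-h], x_j[h:]) covers lag +h for (i, j) and its
    # transpose covers lag -h, so one pass over h >= 0 sees every candidate.
    for h in range(max_lag + 1):
        A = _standardized(X[:, : L - h] if h else X)
        B = _standardized(X[:, h:])
        M = (A @ B.T) / (L - h)
        np.clip(M, -1.0, 1.0, out=M)
        if h == 0:
            best_r = M.copy()
        else:
            for cand, lag in ((M.T, -h), (M, h)):  # negative lag first on ties
                better = np.abs(cand) > np.abs(best_r)
                best_r = np.where(better, cand, best_r)
                best_h = np.where(better, lag, best_h)

    iu, ju = np.triu_indices(n, k=1)
    W = np.zeros((n, n))
    H = np.zeros((n, n), dtype=int)
    W[iu, ju] = best_r[iu, ju]
    W[ju, iu] = best_r[iu, ju]
    H[iu, ju] = best_h[iu, ju]
    H[ju, iu] = -best_h[iu, ju]
    return ConnectivityMatrix(W, epoch_index=epoch_index), LagMatrix(H, epoch_index=epoch_index)


def active_network(
    matrix: ConnectivityMatrix,
    mode: str = "weighted",
    threshold: float = 0.5,
) -> ConnectivityMatrix:
    """Interpret high correlation as an active network.

    ``weighted`` mode passes the matrix through unchanged (the default
    pipeline operates on weighted graphs); ``binarized`` mode sets entries
    with ``|r| >= threshold`` to 1 and everything else (and the diagonal)
    to 0.
    """
    if mode == "weighted":
        return matrix
    if mode != "binarized":
        raise ValueError(f"unknown active-network mode {mode!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    B = (np.abs(matrix.weights) >= threshold).astype(float)
    np.fill_diagonal(B, 0.0)
    return ConnectivityMatrix(B, epoch_index=matrix.epoch_index)
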