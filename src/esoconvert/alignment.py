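"""Parallel-utterance alignment: length normalization and DTW.

Before conversion training the source ("pathological") sentence is
resampled to the sample count of its target ("healthy") counterpart, and
the two static feature sequences are then aligned frame-by-frame with
dynamic time warping.  The aligned frame pairs are stacked into joint
vectors z = [x || y] that feed the joint-GMM estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["AlignmentPath", "length_normalize", "dtw_align", "build_mapping_list"]


@dataclass(frozen=True)
class AlignmentPath:
    """Monotone DTW path: ordered (i, j) pairs from (0,0) to (Tx-1, Ty-1)."""

    pairs: tuple[tuple[int, int], ...]
    cost: float

    def __len__(self) -> int:
        return len(self.pairs)


def length_normalize(x: np.ndarray, target_len: int) -> np.ndarray:
    """Uniformly time-scale a waveform to exactly ``target_len`` samples.

    Polyphase resampling when the rational rate factor is small, Fourier
    resampling otherwise.  This is a plain speed change: pitch scales with
    tempo, which is acceptable because DTW absorbs residual misalignment.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty mono waveform")
    if target_len < 1:
        raise ValueError("target length must be positive")
    if target_len == x.size:
        return x.copy()
    g = math.gcd(target_len, x.size)
    up, down = target_len // g, x.size // g
    if max(up, down) <= 1024:
        y = signal.resample_poly(x, up, down)
    else:
        y = signal.resample(x, target_len)
    if y.size > target_len:
        y = y[:target_len]
    elif y.size < target_len:
        y = np.pad(y, (0, target_len - y.size))
    return y


def dtw_align(X: np.ndarray, Y: np.ndarray) -> AlignmentPath:
    """Minimum-cost monotone alignment of two feature sequences.

    Steps are (1,1), (1,0) and (0,1) with unit weights and Euclidean
    local distance.  Ties are broken deterministically: diagonal first,
    then the (0,1) step.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("cannot align an empty sequence")
    Tx, Ty = X.shape[0], Y.shape[0]
    # local distance matrix
    d2 = np.sum(X**2, axis=1)[:, None] + np.sum(Y**2, axis=1)[None, :] - 2.0 * X @ Y.T
    dist = np.sqrt(np.maximum(d2, 0.0))

    D = np.full((Tx, Ty), np.inf)
    step = np.zeros((Tx, Ty), dtype=np.int8)  # 0=diag, 1=(0,1), 2=(1,0)
    D[0, 0] = dist[0, 0]
    for j in range(1, Ty):
        D[0, j] = D[0, j - 1] + dist[0, j]
        step[0, j] = 1
    for i in range(1, Tx):
        D[i, 0] = D[i - 1, 0] + dist[i, 0]
        step[i, 0] = 2
        prev_diag = D[i - 1, :-1]
        prev_up = D[i - 1, 1:]
        row = D[i]
        for j in range(1, Ty):
            best = prev_diag[j - 1]
            s = 0
            if row[j - 1] < best:
                best, s = row[j - 1], 1
            if prev_up[j - 1] < best:
                best, s = prev_up[j - 1], 2
            row[j] = best + dist[i, j]
            step[i, j] = s

    pairs = []
    i, j = Tx - 1, Ty - 1
    while True:
        pairs.append((i, j))
        if i == 0 and j == 0:
            break
        s = step[i, j]
        if s == 0:
            i, j = i - 1, j - 1
        elif s == 1:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return AlignmentPath(pairs=tuple(pairs), cost=float(D[-1, -1]))


def build_mapping_list(X: np.ndarray, Y: np.ndarray, path: AlignmentPath) -> np.ndarray:
    """Stack aligned frame pairs into joint vectors, one row per path pair.

    With 13-dimensional statics each joint vector has 26 components
    [x || y]; the training set for the joint GMM is the concatenation of
    these lists over all parallel sentences.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if len(path) == 0:
        raise ValueError("empty alignment path")
    idx_x = np.fromiter((p[0] for p in path.pairs), dtype=int)
    idx_y = np.fromiter((p[1] for p in path.pairs), dtype=int)
    if idx_x.max() >= X.shape[0] or idx_y.max() >= Y.shape[0]:
        raise IndexError("alignment path indexes beyond the sequences")
    if idx_x.min() < 0 or idx_y.min() < 0:
        raise IndexError("negative path index")
    return np.concatenate([X[idx_x], Y[idx_y]], axis=1)
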