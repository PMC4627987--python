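"""MFCC front-end for the conversion/recognition pipeline.

Static feature vectors are 13-dimensional: cepstral coefficients c1..c12
computed from a 26-channel Mel filterbank, plus the per-frame log energy
normalized over the whole utterance.  Dynamic (delta) coefficients use the
HTK regression formula over a five-frame window and can be stacked to 26,
39 or 52 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft

__all__ = [
    "FrameConfig",
    "preemphasize",
    "frame_signal",
    "mel_filterbank",
    "extract_static",
    "delta",
    "stack_derivatives",
    "n_frames",
]


@dataclass(frozen=True)
class FrameConfig:
    """Analysis configuration for the short-time front-end.

    Defaults follow HTK-style processing at 16 kHz: 25 ms Hamming windows
    shifted by 10 ms, pre-emphasis 0.97, a 26-filter Mel bank and 12
    retained cepstra (c0 is discarded; normalized log energy is appended).
    """

    sample_rate: int = 16000
    window_ms: float = 25.0
    shift_ms: float = 10.0
    preemphasis: float = 0.97
    n_filters: int = 26
    n_cepstra: int = 12
    n_fft: int = 512
    low_hz: float = 0.0
    high_hz: float | None = None  # defaults to Nyquist
    lifter: int = 0  # 0 disables cepstral liftering
    energy_norm: str = "max"  # "max" (HTK-style, max E*=0) or "zscore"

    def __post_init__(self) -> None:
        if self.window_ms < self.shift_ms:
            raise ValueError("window must be at least as long as the shift")
        if self.n_cepstra >= self.n_filters:
            raise ValueError("n_cepstra must be smaller than n_filters")
        if not 0.0 <= self.preemphasis < 1.0:
            raise ValueError("pre-emphasis coefficient must lie in [0, 1)")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.sample_rate / 1000.0))

    @property
    def shift_samples(self) -> int:
        return int(round(self.shift_ms * self.sample_rate / 1000.0))


def preemphasize(x: np.ndarray, coeff: float = 0.97) -> np.ndarray:
    """First-order high-pass filter y[t] = x[t] - coeff*x[t-1].

    The first sample is passed through unchanged (HTK boundary convention).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("waveform must be one-dimensional (mono)")
    if x.size == 0:
        raise ValueError("empty waveform: no audio to process")
    if not 0.0 <= coeff < 1.0:
        raise ValueError("pre-emphasis coefficient must lie in [0, 1)")
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - coeff * x[:-1]
    return y


def n_frames(n_samples: int, cfg: FrameConfig) -> int:
    """Number of complete analysis windows; frame t covers
    samples [t*shift, t*shift + window)."""
    win, hop = cfg.window_samples, cfg.shift_samples
    if n_samples < win:
        return 0
    return (n_samples - win) // hop + 1


def frame_signal(x: np.ndarray, cfg: FrameConfig) -> np.ndarray:
    """Slice a waveform into overlapping frames (T x window_samples)."""
    x = np.asarray(x, dtype=np.float64)
    T = n_frames(x.size, cfg)
    if T == 0:
        raise ValueError(
            f"waveform of {x.size} samples is shorter than one "
            f"{cfg.window_samples}-sample window"
        )
    win, hop = cfg.window_samples, cfg.shift_samples
    idx = np.arange(win)[None, :] + hop * np.arange(T)[:, None]
    return x[idx]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(cfg: FrameConfig) -> np.ndarray:
    """Triangular Mel filterbank, shape (n_filters, n_fft//2 + 1)."""
    high = cfg.high_hz if cfg.high_hz is not None else cfg.sample_rate / 2.0
    mels = np.linspace(_hz_to_mel(cfg.low_hz), _hz_to_mel(high), cfg.n_filters + 2)
    edges = _mel_to_hz(mels)
    bins = np.floor((cfg.n_fft + 1) * edges / cfg.sample_rate).astype(int)
    fb = np.zeros((cfg.n_filters, cfg.n_fft // 2 + 1))
    for i in range(cfg.n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        for b in range(lo, mid):
            if mid > lo:
                fb[i, b] = (b - lo) / (mid - lo)
        for b in range(mid, hi):
            if hi > mid:
                fb[i, b] = (hi - b) / (hi - mid)
    return fb


def extract_static(x: np.ndarray, cfg: FrameConfig | None = None) -> np.ndarray:
    """Waveform -> T x 13 static features [c1..c12, E*].

    E* is the frame log energy normalized over the utterance: with the
    default "max" rule the per-utterance maximum is subtracted so that
    max(E*) = 0 and a global gain change leaves the track invariant;
    "zscore" standardizes instead.
    """
    cfg = cfg or FrameConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty mono waveform")
    emph = preemphasize(x, cfg.preemphasis) if cfg.preemphasis > 0 else x
    frames = frame_signal(emph, cfg)

    # log energy is taken on the pre-emphasized, un-windowed frame
    energy = np.sum(frames**2, axis=1)
    energy = np.maximum(energy, np.finfo(np.float64).tiny)
    log_e = np.log(energy)
    if cfg.energy_norm == "max":
        log_e = log_e - log_e.max()
    elif cfg.energy_norm == "zscore":
        sd = log_e.std()
        log_e = (log_e - log_e.mean()) / (sd if sd > 0 else 1.0)
    else:
        raise ValueError(f"unknown energy normalization {cfg.energy_norm!r}")

    window = np.hamming(cfg.window_samples)
    spec = rfft(frames * window, n=cfg.n_fft, axis=1)
    power = np.abs(spec) ** 2
    fbank = mel_filterbank(cfg)
    mel_energy = power @ fbank.T
    mel_energy = np.maximum(mel_energy, np.finfo(np.float64).tiny)
    ceps = dct(np.log(mel_energy), type=2, axis=1, norm="ortho")
    ceps = ceps[:, 1 : cfg.n_cepstra + 1]  # drop c0
    if cfg.lifter > 0:
        n = np.arange(1, cfg.n_cepstra + 1)
        ceps = ceps * (1.0 + (cfg.lifter / 2.0) * np.sin(np.pi * n / cfg.lifter))
    return np.column_stack([ceps, log_e])


def delta(seq: np.ndarray, n_delta: int = 2, *, strict: bool = False) -> np.ndarray:
    """HTK delta regression over a (2*n_delta + 1)-frame window.

    dC(t) = sum_{i=1..N} i*(C[t+i] - C[t-i]) / (2*sum_{i=1..N} i^2),
    with edge frames replicated so the output has the input's shape.
    Sequences shorter than the window raise when ``strict`` and otherwise
    proceed on the replicated-edge sequence.
    """
    seq = np.atleast_2d(np.asarray(seq, dtype=np.float64))
    if n_delta < 1:
        raise ValueError("n_delta must be >= 1")
    T = seq.shape[0]
    if T < 2 * n_delta + 1:
        msg = f"sequence of {T} frames is shorter than the {2*n_delta+1}-frame window"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn("degenerate sequence: " + msg, stacklevel=2)
    pad = np.concatenate(
        [np.repeat(seq[:1], n_delta, axis=0), seq, np.repeat(seq[-1:], n_delta, axis=0)]
    )
    denom = 2.0 * sum(i * i for i in range(1, n_delta + 1))
    out = np.zeros_like(seq)
    for i in range(1, n_delta + 1):
        out += i * (pad[n_delta + i : n_delta + i + T] - pad[n_delta - i : n_delta - i + T])
    return out / denom


def stack_derivatives(static: np.ndarray, order: int = 3, n_delta: int = 2) -> np.ndarray:
    """Concatenate the statics with their first ``order`` time derivatives.

    order 2 -> 39 columns (statics, delta, delta-delta); order 3 -> 52
    columns, the widest configuration used before HLDA reduction.  Higher
    derivatives are obtained by re-applying the delta regression to the
    previous order's output.
    """
    static = np.atleast_2d(np.asarray(static, dtype=np.float64))
    if static.shape[1] != 13:
        raise ValueError(f"expected 13 static columns, got {static.shape[1]}")
    if order not in (1, 2, 3):
        raise ValueError("derivative order must be 1, 2 or 3")
    blocks = [static]
    cur = static
    for _ in range(order):
        cur = delta(cur, n_delta)
        blocks.append(cur)
    return np.concatenate(blocks, axis=1)
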