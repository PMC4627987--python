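"""Corpus and model I/O.

Formats:

* RIFF WAV, PCM 16-bit mono (``read_wav``/``write_wav``).
* TIMIT-dialect ``.phn``/``.wrd`` transcriptions: one ``start end label``
  line per segment, sample units, 0-based half-open intervals.
* Feature files: plain text, a ``#`` header line carrying the frame count,
  dimensionality and frame period, then one whitespace-separated row per
  frame printed with round-trip (``%.17g``) precision.
* Models (joint GMM, HLDA transform, phone HMM set, bigram LM): JSON, with
  floats serialized at full precision so a write/read cycle is
  bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .conversion import ConversionFunction, JointGMM
from .hlda import HLDATransform
from .recognizer import BigramLM, GMMState, PhoneHMM
from .synthetic import Transcription

__all__ = [
    "read_wav",
    "write_wav",
    "read_phn",
    "write_phn",
    "frame_labels",
    "read_features",
    "write_features",
    "save_conversion",
    "load_conversion",
    "save_hlda",
    "load_hlda",
    "save_models",
    "load_models",
    "save_bigram",
    "load_bigram",
]


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read PCM WAV as float64 in [-1, 1); rejects multi-channel audio."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    return data, int(rate)


def write_wav(path, samples: np.ndarray, rate: int = 16000) -> None:
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0 - 1.0 / 32768)
    wavfile.write(path, rate, (x * 32768.0).astype(np.int16))


# ---------------------------------------------------------------------------
# transcriptions


def read_phn(path, known_labels: list[str] | None = None) -> Transcription:
    """Parse a TIMIT-style segmentation file.

    Intervals must be sorted, non-overlapping, 0-based half-open and in
    sample units; an optional label inventory is enforced when given.
    """
    entries = []
    prev_end = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'start end label'")
            try:
                start, end = int(parts[0]), int(parts[1])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer boundary") from e
            label = parts[2]
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"{path}:{lineno}: overlapping interval")
            if known_labels is not None and label not in known_labels:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            entries.append((start, end, label))
            prev_end = end
    return Transcription(entries)


def write_phn(path, trans: Transcription) -> None:
    with open(path, "w") as fh:
        for start, end, label in trans.entries:
            fh.write(f"{start} {end} {label}\n")


def frame_labels(
    trans: Transcription,
    T: int,
    shift_samples: int = 160,
    window_samples: int = 160,
    silence: str = "sil",
) -> list[str]:
    """Label each of T frames by the interval containing its center sample.

    Frame t covers samples [t*shift, t*shift + window); its center is
    t*shift + window//2.  Centers outside every interval fall back to the
    silence label with a warning.
    """
    import warnings

    labels = []
    warned = False
    for t in range(T):
        center = t * shift_samples + window_samples // 2
        hit = None
        for start, end, label in trans.entries:
            if start <= center < end:
                hit = label
                break
        if hit is None:
            hit = silence
            if not warned:
                warnings.warn(
                    f"frame center {center} not covered by the transcription; "
                    "assigning silence",
                    stacklevel=2,
                )
                warned = True
        labels.append(hit)
    return labels


# ---------------------------------------------------------------------------
# feature files


def write_features(path, feats: np.ndarray, frame_period_ms: float = 10.0) -> None:
    feats = np.atleast_2d(np.asarray(feats, dtype=np.float64))
    with open(path, "w") as fh:
        fh.write(
            f"# frames={feats.shape[0]} dim={feats.shape[1]} "
            f"frame_period_ms={frame_period_ms:g}\n"
        )
        for row in feats:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_features(path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing feature header")
        rows = [
            [float(v) for v in line.split()] for line in fh if line.strip()
        ]
    return np.array(rows, dtype=np.float64)


# ---------------------------------------------------------------------------
# model serialization (JSON; floats round-trip bit-identically)


def save_conversion(path, fn: ConversionFunction) -> None:
    g = fn.gmm
    doc = {
        "kind": "joint_gmm_conversion",
        "dim_x": g.dim_x,
        "weights": g.weights.tolist(),
        "means": g.means.tolist(),
        "covariances": g.covariances.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_conversion(path) -> ConversionFunction:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "joint_gmm_conversion":
        raise ValueError(f"{path}: not a conversion model")
    gmm = JointGMM(
        weights=np.array(doc["weights"]),
        means=np.array(doc["means"]),
        covariances=np.array(doc["covariances"]),
        dim_x=int(doc["dim_x"]),
    )
    return ConversionFunction(gmm)


def save_hlda(path, t: HLDATransform) -> None:
    doc = {"kind": "hlda", "p": t.p, "theta": t.theta.tolist()}
    Path(path).write_text(json.dumps(doc))


def load_hlda(path) -> HLDATransform:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "hlda":
        raise ValueError(f"{path}: not an HLDA transform")
    return HLDATransform(theta=np.array(doc["theta"]), p=int(doc["p"]))


def save_models(path, models: dict[str, PhoneHMM]) -> None:
    doc = {"kind": "phone_hmm_set", "models": {}}
    for name, m in models.items():
        doc["models"][name] = {
            "trans": m.trans.tolist(),
            "states": [
                {
                    "weights": st.weights.tolist(),
                    "means": st.means.tolist(),
                    "variances": st.variances.tolist(),
                }
                for st in m.states
            ],
        }
    Path(path).write_text(json.dumps(doc))


def load_models(path) -> dict[str, PhoneHMM]:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "phone_hmm_set":
        raise ValueError(f"{path}: not a phone HMM set")
    models = {}
    for name, md in doc["models"].items():
        models[name] = PhoneHMM(
            name=name,
            trans=np.array(md["trans"]),
            states=[
                GMMState(
                    weights=np.array(sd["weights"]),
                    means=np.array(sd["means"]),
                    variances=np.array(sd["variances"]),
                )
                for sd in md["states"]
            ],
        )
    return models


def save_bigram(path, lm: BigramLM) -> None:
    doc = {
        "kind": "bigram_lm",
        "labels": lm.labels,
        "log_trans": lm.log_trans.tolist(),
        "log_start": lm.log_start.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_bigram(path) -> BigramLM:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "bigram_lm":
        raise ValueError(f"{path}: not a bigram LM")
    return BigramLM(
        labels=list(doc["labels"]),
        log_trans=np.array(doc["log_trans"]),
        log_start=np.array(doc["log_start"]),
    )
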