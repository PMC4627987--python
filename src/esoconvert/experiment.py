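"""End-to-end experiment driver.

Reproduces the three-way recognition comparison on a synthetic parallel
corpus: (1) converted statics + first/second derivatives (39 dims),
(2) converted statics + three derivative orders (52 dims), (3) the 52-dim
features reduced to 39 by HLDA.  A no-conversion baseline runs the same
recognizer on the raw pathological features.  Every stage consumes the
frame-level phone labels carried by the generated transcriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .conversion import ConversionFunction, convert, train_conversion
from .features import stack_derivatives
from .hlda import accumulate_stats, estimate_hlda, project
from .recognizer import (
    ScoreReport,
    baum_welch,
    flat_start,
    score,
    split_mixtures,
    train_bigram,
    viterbi_decode,
)
from .synthetic import (
    DistortionSpec,
    SpeakerModel,
    Transcription,
    generate_parallel_corpus,
    make_speaker,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

Mode = Literal["exp1", "exp2", "exp3"]


@dataclass
class ExperimentConfig:
    """Knobs of one synthetic end-to-end run.

    ``mode`` selects the feature pipeline: exp1 -> 39-dim (statics + two
    derivative orders), exp2 -> 52-dim (three orders), exp3 -> 52-dim
    reduced to 39 by HLDA.  ``use_conversion`` toggles the voice-
    conversion front half (off = the no-conversion baseline).
    """

    mode: Mode = "exp3"
    use_conversion: bool = True
    n_phones: int = 36
    n_conversion_sentences: int = 50
    n_train_sentences: int = 100
    n_test_sentences: int = 20
    gmm_components: int = 64
    conversion_iters: int = 3
    max_gaussians: int = 4
    bw_iters: int = 4
    hlda_p: int = 39
    hlda_iters: int = 20
    lm_scale: float = 5.0
    ins_penalty: float = -10.0
    lm_k: float = 1.0
    separation: float = 4.0
    seed: int = 0
    distortion: DistortionSpec | None = None


@dataclass
class ExperimentResult:
    report: ScoreReport
    per_utterance: list[ScoreReport]
    conversion_mse: list[float]
    feature_dim: int
    manifest: dict


def _frame_labels_from_trans(trans: Transcription) -> list[str]:
    """Frame labels straight from a frame-aligned synthetic transcription."""
    labels = []
    for s0, s1, ph in trans.entries:
        labels.extend([ph] * ((s1 - s0) // 160))
    return labels


def _feature_pipeline(statics, mode):
    order = 2 if mode == "exp1" else 3
    return [stack_derivatives(s, order=order) for s in statics]


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Generate data, train the pipeline, decode the test set and score it."""
    rng = np.random.default_rng(cfg.seed)
    speaker = make_speaker(
        cfg.n_phones, seed=int(rng.integers(2**31 - 1)), separation=cfg.separation
    )
    spec = cfg.distortion or DistortionSpec.default(
        speaker.dim, seed=int(rng.integers(2**31 - 1))
    )

    # conversion-training corpus (parallel) and recognition corpus (source side)
    conv_corpus = generate_parallel_corpus(
        cfg.n_conversion_sentences, speaker, spec, seed=int(rng.integers(2**31 - 1))
    )
    rec_corpus = generate_parallel_corpus(
        cfg.n_train_sentences + cfg.n_test_sentences,
        speaker,
        spec,
        seed=int(rng.integers(2**31 - 1)),
    )

    conversion_mse: list[float] = []
    if cfg.use_conversion:
        fn, trace = train_conversion(
            conv_corpus["source"],
            conv_corpus["target"],
            G=cfg.gmm_components,
            n_outer_iters=cfg.conversion_iters,
            seed=int(rng.integers(2**31 - 1)),
        )
        conversion_mse = trace.mse
        statics = [convert(x, fn) for x in rec_corpus["source"]]
    else:
        statics = [np.asarray(x) for x in rec_corpus["source"]]

    trans = rec_corpus["source_trans"]
    feats = _feature_pipeline(statics, cfg.mode)

    n_train = cfg.n_train_sentences
    train_feats, test_feats = feats[:n_train], feats[n_train:]
    train_trans, test_trans = trans[:n_train], trans[n_train:]

    if cfg.mode == "exp3":
        labels = [_frame_labels_from_trans(t) for t in train_trans]
        stats = accumulate_stats(train_feats, labels)
        hlda = estimate_hlda(stats, p=cfg.hlda_p, n_iters=cfg.hlda_iters)
        train_feats = [project(hlda, f) for f in train_feats]
        test_feats = [project(hlda, f) for f in test_feats]

    phone_names = speaker.phones
    phone_seqs = [t.labels() for t in train_trans]
    models = flat_start(phone_names, train_feats)
    models, _ = baum_welch(models, train_feats, phone_seqs, n_iters=cfg.bw_iters)
    if cfg.max_gaussians > 1:
        models = split_mixtures(
            models, cfg.max_gaussians, train_feats, phone_seqs, n_iters=max(2, cfg.bw_iters // 2)
        )
    lm = train_bigram(phone_seqs, phone_names, k=cfg.lm_k)

    reports = []
    for f, t in zip(test_feats, test_trans):
        hyp = viterbi_decode(models, lm, f, cfg.lm_scale, cfg.ins_penalty)
        reports.append(score(t.labels(), hyp))
    total = reports[0]
    for r in reports[1:]:
        total = total + r

    manifest = {
        "mode": cfg.mode,
        "use_conversion": cfg.use_conversion,
        "seed": cfg.seed,
        "n_phones": cfg.n_phones,
        "n_conversion_sentences": cfg.n_conversion_sentences,
        "n_train_sentences": cfg.n_train_sentences,
        "n_test_sentences": cfg.n_test_sentences,
        "gmm_components": cfg.gmm_components,
        "max_gaussians": cfg.max_gaussians,
        "feature_dim": train_feats[0].shape[1],
    }
    return ExperimentResult(
        report=total,
        per_utterance=reports,
        conversion_mse=conversion_mse,
        feature_dim=train_feats[0].shape[1],
        manifest=manifest,
    )
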