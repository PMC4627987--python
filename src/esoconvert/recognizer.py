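"""Monophone HMM/GMM phone recognizer.

Each phone (including silence) is a 5-state left-to-right HMM whose three
middle states emit through diagonal-covariance Gaussian mixtures of up to
16 components.  Training is flat-start initialization followed by embedded
Baum-Welch over phone-concatenated utterance models, with binary mixture
splitting (1 -> 2 -> 4 -> 8 -> 16) between re-estimation rounds.  Decoding
runs token-passing Viterbi over a phone loop weighted by an add-k smoothed
bigram phone language model, and hypotheses are scored against reference
transcriptions by minimum-edit-distance alignment yielding substitution,
deletion and insertion counts with

    Accuracy = (N - S - D - I) / N      Correct = (N - S - D) / N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GMMState",
    "PhoneHMM",
    "BigramLM",
    "ScoreReport",
    "flat_start",
    "baum_welch",
    "split_mixtures",
    "train_bigram",
    "viterbi_decode",
    "score",
]

N_EMITTING = 3  # states 2..4 of the 5-state topology
LOG_ZERO = -1e30


@dataclass
class GMMState:
    """Diagonal-covariance Gaussian mixture emission for one HMM state."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    variances: np.ndarray  # (K, d)

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    def log_prob(self, obs: np.ndarray) -> np.ndarray:
        """Per-frame log b(o_t); obs is (T, d)."""
        return logsumexp(self.component_log_prob(obs), axis=1)

    def component_log_prob(self, obs: np.ndarray) -> np.ndarray:
        """(T, K) log c_k N(o_t; mu_k, Sigma_k)."""
        obs = np.atleast_2d(obs)
        d = obs.shape[1]
        diff2 = (obs[:, None, :] - self.means[None, :, :]) ** 2 / self.variances[None]
        logdet = np.sum(np.log(self.variances), axis=1)  # (K,)
        return (
            np.log(self.weights)[None, :]
            - 0.5 * (d * np.log(2 * np.pi) + logdet)[None, :]
            - 0.5 * diff2.sum(axis=2)
        )


@dataclass
class PhoneHMM:
    """5-state left-to-right phone model; states 2-4 emit.

    ``trans`` is the full 5x5 transition matrix: row 0 is the non-emitting
    entry state (jumps to state 2 with probability 1), rows 1-3 are the
    emitting states with self and forward transitions only, and state 5
    (index 4) is the non-emitting exit.
    """

    name: str
    trans: np.ndarray  # (5, 5)
    states: list[GMMState]  # 3 emitting states

    def validate(self) -> None:
        rows = self.trans[:4].sum(axis=1)
        if not np.allclose(rows, 1.0):
            raise ValueError(f"transition rows of {self.name!r} must sum to 1")
        legal = np.zeros((5, 5), dtype=bool)
        legal[0, 1] = True
        for i in (1, 2, 3):
            legal[i, i] = legal[i, i + 1] = True
        if np.any(self.trans[~legal] != 0):
            raise ValueError(f"{self.name!r} has transitions outside the topology")
        for st in self.states:
            if not np.isclose(st.weights.sum(), 1.0):
                raise ValueError("mixture weights must sum to 1")


def _default_trans() -> np.ndarray:
    A = np.zeros((5, 5))
    A[0, 1] = 1.0
    for i in (1, 2, 3):
        A[i, i] = 0.5
        A[i, i + 1] = 0.5
    return A


def flat_start(
    phone_names: list[str], features: list[np.ndarray]
) -> dict[str, PhoneHMM]:
    """Initialize every phone model from the global data statistics.

    All emitting states start as the same single Gaussian (global mean and
    per-dimension variance); transitions are uniform over the legal arcs.
    """
    if len(features) == 0:
        raise ValueError("empty corpus")
    X = np.concatenate([np.atleast_2d(f) for f in features], axis=0)
    if X.shape[0] == 0:
        raise ValueError("empty corpus")
    mean = X.mean(axis=0)
    var = np.maximum(X.var(axis=0), 1e-8)
    models = {}
    for name in phone_names:
        states = [
            GMMState(
                weights=np.array([1.0]),
                means=mean[None, :].copy(),
                variances=var[None, :].copy(),
            )
            for _ in range(N_EMITTING)
        ]
        models[name] = PhoneHMM(name=name, trans=_default_trans(), states=states)
    return models


# ---------------------------------------------------------------------------
# embedded Baum-Welch


def _composite(models: dict[str, PhoneHMM], phones: list[str]):
    """Chain of emitting states for one transcription.

    Returns (state_owner, log_self, log_fwd) where state_owner[q] =
    (phone name, local emitting index).  Forward from the last state of a
    phone carries its exit probability into the next phone's first state;
    the same exit probability terminates the utterance after the last
    phone.
    """
    owner = []
    log_self = []
    log_fwd = []
    for ph in phones:
        m = models[ph]
        for s in range(N_EMITTING):
            owner.append((ph, s))
            a_self = m.trans[1 + s, 1 + s]
            a_fwd = m.trans[1 + s, 2 + s]
            log_self.append(np.log(a_self) if a_self > 0 else LOG_ZERO)
            log_fwd.append(np.log(a_fwd) if a_fwd > 0 else LOG_ZERO)
    return owner, np.array(log_self), np.array(log_fwd)


def _log_forward(log_b, log_self, log_fwd):
    """log alpha over the banded left-to-right chain; includes emission."""
    T, S = log_b.shape
    la = np.full((T, S), LOG_ZERO)
    la[0, 0] = log_b[0, 0]
    for t in range(1, T):
        stay = la[t - 1] + log_self
        move = np.full(S, LOG_ZERO)
        move[1:] = la[t - 1, :-1] + log_fwd[:-1]
        la[t] = np.logaddexp(stay, move) + log_b[t]
    return la


def _log_backward(log_b, log_self, log_fwd):
    """log beta; beta_T(last) closes through the final exit arc."""
    T, S = log_b.shape
    lb = np.full((T, S), LOG_ZERO)
    lb[T - 1, S - 1] = log_fwd[S - 1]  # exit probability of the last phone
    for t in range(T - 2, -1, -1):
        stay = log_self + log_b[t + 1] + lb[t + 1]
        move = np.full(S, LOG_ZERO)
        move[:-1] = log_fwd[:-1] + log_b[t + 1, 1:] + lb[t + 1, 1:]
        lb[t] = np.logaddexp(stay, move)
    return lb


def forward_loglik(models, phones, obs) -> float:
    """Utterance log-likelihood by the forward recursion."""
    owner, ls, lf = _composite(models, phones)
    log_b = _emission_matrix(models, owner, obs)
    la = _log_forward(log_b, ls, lf)
    return float(la[-1, -1] + lf[-1])


def backward_loglik(models, phones, obs) -> float:
    """Utterance log-likelihood by the backward recursion (independent path)."""
    owner, ls, lf = _composite(models, phones)
    log_b = _emission_matrix(models, owner, obs)
    lb = _log_backward(log_b, ls, lf)
    return float(log_b[0, 0] + lb[0, 0])


def _emission_matrix(models, owner, obs):
    obs = np.atleast_2d(obs)
    cache = {}
    cols = []
    for ph, s in owner:
        key = (ph, s)
        if key not in cache:
            cache[key] = models[ph].states[s].log_prob(obs)
        cols.append(cache[key])
    return np.stack(cols, axis=1)  # (T, S)


def baum_welch(
    models: dict[str, PhoneHMM],
    corpus: list[np.ndarray],
    transcriptions: list[list[str]],
    n_iters: int = 5,
    var_floor_scale: float = 1e-2,
) -> tuple[dict[str, PhoneHMM], list[float]]:
    """Embedded MLE re-estimation over phone-concatenated utterance models.

    Returns the updated models and the per-iteration total log-likelihood
    trace (non-decreasing up to the variance floor).  Utterances with
    fewer frames than emitting states in their transcription are skipped
    with a warning.
    """
    if len(corpus) != len(transcriptions):
        raise ValueError("one transcription per utterance required")
    allX = np.concatenate([np.atleast_2d(f) for f in corpus], axis=0)
    floor = var_floor_scale * np.maximum(allX.var(axis=0), 1e-10)
    trace = []
    usable = []
    for obs, phones in zip(corpus, transcriptions):
        obs = np.atleast_2d(obs)
        if obs.shape[0] < N_EMITTING * len(phones):
            warnings.warn(
                f"utterance of {obs.shape[0]} frames cannot traverse "
                f"{len(phones)} phones; skipped",
                stacklevel=2,
            )
            continue
        usable.append((obs, list(phones)))
    if not usable:
        raise ValueError("no trainable utterances")

    for _ in range(n_iters):
        acc = _new_accumulators(models)
        total_ll = 0.0
        for obs, phones in usable:
            total_ll += _accumulate_utterance(models, phones, obs, acc)
        trace.append(total_ll)
        models = _reestimate(models, acc, floor)
    return models, trace


def _new_accumulators(models):
    acc = {}
    for name, m in models.items():
        d = m.states[0].means.shape[1]
        acc[name] = {
            "occ": [np.zeros(st.n_components) for st in m.states],
            "mu": [np.zeros((st.n_components, d)) for st in m.states],
            "sq": [np.zeros((st.n_components, d)) for st in m.states],
            "self": np.zeros(N_EMITTING),
            "fwd": np.zeros(N_EMITTING),
        }
    return acc


def _accumulate_utterance(models, phones, obs, acc):
    owner, ls, lf = _composite(models, phones)
    log_b = _emission_matrix(models, owner, obs)
    la = _log_forward(log_b, ls, lf)
    lb = _log_backward(log_b, ls, lf)
    ll = float(la[-1, -1] + lf[-1])
    T, S = log_b.shape

    log_gamma = la + lb - ll
    gamma = np.exp(np.clip(log_gamma, -700, 0))  # (T, S)

    # transition posteriors along the band
    if T > 1:
        xi_self = np.exp(
            np.clip(la[:-1] + ls[None, :] + log_b[1:] + lb[1:] - ll, -700, 50)
        )
        xi_fwd = np.zeros((T - 1, S))
        xi_fwd[:, :-1] = np.exp(
            np.clip(
                la[:-1, :-1] + lf[None, :-1] + log_b[1:, 1:] + lb[1:, 1:] - ll,
                -700,
                50,
            )
        )
    else:
        xi_self = np.zeros((0, S))
        xi_fwd = np.zeros((0, S))
    # the final exit of the last state counts as one forward transition
    exit_occ = np.exp(np.clip(la[-1, -1] + lf[-1] - ll, -700, 0))

    for q, (ph, s) in enumerate(owner):
        a = acc[ph]
        st = models[ph].states[s]
        g = gamma[:, q]
        comp = np.exp(
            st.component_log_prob(obs) - logsumexp(st.component_log_prob(obs), axis=1, keepdims=True)
        )
        w = comp * g[:, None]  # (T, K)
        a["occ"][s] += w.sum(axis=0)
        a["mu"][s] += w.T @ obs
        a["sq"][s] += w.T @ (obs**2)
        a["self"][s] += xi_self[:, q].sum()
        a["fwd"][s] += xi_fwd[:, q].sum()
        if q == S - 1:
            a["fwd"][s] += exit_occ
    return ll


def _reestimate(models, acc, floor):
    new = {}
    for name, m in models.items():
        a = acc[name]
        states = []
        A = _default_trans().copy()
        for s in range(N_EMITTING):
            occ = a["occ"][s]
            tot = occ.sum()
            old = m.states[s]
            if tot < 1e-6:
                states.append(
                    GMMState(old.weights.copy(), old.means.copy(), old.variances.copy())
                )
            else:
                w = np.maximum(occ / tot, 1e-8)
                w = w / w.sum()
                mu = a["mu"][s] / np.maximum(occ[:, None], 1e-10)
                var = a["sq"][s] / np.maximum(occ[:, None], 1e-10) - mu**2
                var = np.maximum(var, floor[None, :])
                states.append(GMMState(weights=w, means=mu, variances=var))
            denom = a["self"][s] + a["fwd"][s]
            if denom > 1e-8:
                A[1 + s, 1 + s] = a["self"][s] / denom
                A[1 + s, 2 + s] = a["fwd"][s] / denom
            else:
                A[1 + s, 1 + s] = m.trans[1 + s, 1 + s]
                A[1 + s, 2 + s] = m.trans[1 + s, 2 + s]
        new[name] = PhoneHMM(name=name, trans=A, states=states)
    return new


def split_mixtures(
    models: dict[str, PhoneHMM],
    target_n: int,
    corpus: list[np.ndarray] | None = None,
    transcriptions: list[list[str]] | None = None,
    n_iters: int = 3,
    perturb: float = 0.2,
) -> dict[str, PhoneHMM]:
    """Grow state mixtures to ``target_n`` by successive binary splitting.

    Each round doubles every state's components by perturbing means by
    +/- ``perturb`` standard deviations, halves the weights, and (when a
    corpus is supplied) re-runs embedded re-estimation.  The schedule for
    16 components from 1 is four rounds (1->2->4->8->16).
    """
    cur = max(st.n_components for m in models.values() for st in m.states)
    if target_n < cur:
        raise ValueError("target mixture size below current size")
    if target_n > 16:
        warnings.warn("more than 16 Gaussians per state exceeds the usual ceiling")
    while cur < target_n:
        cur = min(cur * 2, target_n)
        split = {}
        for name, m in models.items():
            states = []
            for st in m.states:
                k = st.n_components
                take = min(k, cur - k) if k < cur else 0
                if take <= 0:
                    states.append(st)
                    continue
                order = np.argsort(-st.weights)[:take]
                sd = np.sqrt(st.variances[order])
                w = np.concatenate([st.weights, st.weights[order] / 2.0])
                w[order] /= 2.0
                mu = np.concatenate(
                    [st.means, st.means[order] + perturb * sd], axis=0
                )
                mu[order] -= perturb * sd
                var = np.concatenate([st.variances, st.variances[order]], axis=0)
                states.append(GMMState(weights=w / w.sum(), means=mu, variances=var))
            split[name] = PhoneHMM(name=name, trans=m.trans.copy(), states=states)
        models = split
        if corpus is not None:
            models, _ = baum_welch(models, corpus, transcriptions, n_iters=n_iters)
    return models


# ---------------------------------------------------------------------------
# language model


@dataclass
class BigramLM:
    """Add-k smoothed phone bigram: P(phone_j | phone_i) plus a start row."""

    labels: list[str]
    log_trans: np.ndarray  # (K, K) rows normalized
    log_start: np.ndarray  # (K,)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def train_bigram(
    transcriptions: list[list[str]],
    labels: list[str],
    k: float = 1.0,
) -> BigramLM:
    """Maximum-likelihood bigram counts with add-k smoothing over ``labels``.

    Sentence starts contribute to a dedicated start distribution; the end
    of a sentence is left unmodeled (the decoder may stop in any phone).
    """
    if not transcriptions:
        raise ValueError("need at least one transcription")
    K = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((K, K))
    start = np.zeros(K)
    for trans in transcriptions:
        prev = None
        for ph in trans:
            if ph not in idx:
                raise ValueError(f"unknown phone label {ph!r}")
            j = idx[ph]
            if prev is None:
                start[j] += 1
            else:
                counts[prev, j] += 1
            prev = j
    trans_p = (counts + k) / (counts.sum(axis=1, keepdims=True) + k * K)
    start_p = (start + k) / (start.sum() + k * K)
    with np.errstate(divide="ignore"):
        return BigramLM(
            labels=list(labels),
            log_trans=np.log(trans_p),
            log_start=np.log(start_p),
        )


# ---------------------------------------------------------------------------
# decoding


def viterbi_decode(
    models: dict[str, PhoneHMM],
    lm: BigramLM | None,
    obs: np.ndarray,
    lm_scale: float = 1.0,
    ins_penalty: float = 0.0,
) -> list[str]:
    """Best phone sequence through the bigram-weighted phone loop.

    Token passing with a per-frame max over the 3 emitting states of every
    phone; cross-phone arcs carry ``lm_scale`` times the bigram log
    probability plus ``ins_penalty`` (a log-domain word-insertion term).
    Deterministic: ties resolve to the lowest phone index.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=np.float64))
    labels = lm.labels if lm is not None else sorted(models)
    if obs.shape[0] == 0 or obs.size == 0:
        return []
    P = len(labels)
    S = P * N_EMITTING

    log_self = np.empty(S)
    log_fwd = np.empty(S)
    log_b = np.empty((obs.shape[0], S))
    for p, name in enumerate(labels):
        m = models[name]
        for s in range(N_EMITTING):
            q = p * N_EMITTING + s
            a_s, a_f = m.trans[1 + s, 1 + s], m.trans[1 + s, 2 + s]
            log_self[q] = np.log(a_s) if a_s > 0 else LOG_ZERO
            log_fwd[q] = np.log(a_f) if a_f > 0 else LOG_ZERO
            log_b[:, q] = m.states[s].log_prob(obs)

    if lm is not None:
        lm_start = lm_scale * lm.log_start
        lm_mat = lm_scale * lm.log_trans  # (prev, next)
    else:
        lm_start = np.zeros(P)
        lm_mat = np.zeros((P, P))

    T = obs.shape[0]
    entry = np.arange(P) * N_EMITTING  # first emitting state per phone
    exit_ = entry + N_EMITTING - 1

    delta = np.full((T, S), LOG_ZERO)
    # backpointer: state index at t-1, plus phone-entry marker
    bp = np.full((T, S), -1, dtype=np.int32)
    delta[0, entry] = lm_start + ins_penalty + log_b[0, entry]

    for t in range(1, T):
        prev = delta[t - 1]
        stay = prev + log_self
        move = np.full(S, LOG_ZERO)
        move[1:] = prev[:-1] + log_fwd[:-1]
        move[entry] = LOG_ZERO  # no within-chain arc into a phone's first state
        best = np.where(stay >= move, stay, move)
        ptr = np.where(stay >= move, np.arange(S), np.arange(S) - 1)
        # cross-phone arcs into entry states
        exit_scores = prev[exit_] + log_fwd[exit_]  # (P,)
        cand = exit_scores[:, None] + lm_mat + ins_penalty  # (prev P, next P)
        best_prev = np.argmax(cand, axis=0)
        best_entry = cand[best_prev, np.arange(P)]
        better = best_entry > best[entry]
        best[entry] = np.where(better, best_entry, best[entry])
        ptr[entry] = np.where(better, exit_[best_prev], ptr[entry])
        delta[t] = best + log_b[t]
        bp[t] = ptr

    final = delta[T - 1] + np.where(log_fwd > LOG_ZERO / 2, log_fwd, LOG_ZERO)
    # terminate only in a phone's last emitting state
    mask = np.full(S, LOG_ZERO)
    mask[exit_] = 0.0
    q = int(np.argmax(final + mask))
    # backtrace
    states = [q]
    for t in range(T - 1, 0, -1):
        q = int(bp[t, q])
        states.append(q)
    states.reverse()
    # a new phone starts at t=0 and on every arrival at an entry state
    # through a cross-phone arc (within-chain arcs into entry states are
    # disallowed, so any change of state into an entry state is a new phone)
    phones = [labels[states[0] // N_EMITTING]]
    for t in range(1, len(states)):
        q = states[t]
        if q % N_EMITTING == 0 and states[t - 1] != q:
            phones.append(labels[q // N_EMITTING])
    return phones


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScoreReport:
    """Edit-distance phone scoring counts and derived percentages."""

    N: int
    S: int
    D: int
    I: int

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.N - self.S - self.D - self.I) / self.N

    @property
    def correct(self) -> float:
        return 100.0 * (self.N - self.S - self.D) / self.N

    def __add__(self, other: "ScoreReport") -> "ScoreReport":
        return ScoreReport(
            self.N + other.N, self.S + other.S, self.D + other.D, self.I + other.I
        )


def score(
    reference: list[str],
    hypothesis: list[str],
    sub_cost: float = 1.0,
    del_cost: float = 1.0,
    ins_cost: float = 1.0,
) -> ScoreReport:
    """Align hypothesis to reference by minimum edit distance; count S, D, I.

    Default unit costs; pass (10, 7, 7) for HTK-compatible weighting.  On
    cost ties the backtrace prefers match/substitution, then deletion.
    """
    if len(reference) == 0:
        raise ValueError("empty reference")
    R, H = len(reference), len(hypothesis)
    D = np.zeros((R + 1, H + 1))
    D[:, 0] = np.arange(R + 1) * del_cost
    D[0, :] = np.arange(H + 1) * ins_cost
    op = np.zeros((R + 1, H + 1), dtype=np.int8)  # 0 diag, 1 del, 2 ins
    op[1:, 0] = 1
    op[0, 1:] = 2
    for i in range(1, R + 1):
        for j in range(1, H + 1):
            c_diag = D[i - 1, j - 1] + (
                0.0 if reference[i - 1] == hypothesis[j - 1] else sub_cost
            )
            c_del = D[i - 1, j] + del_cost
            c_ins = D[i, j - 1] + ins_cost
            best, o = c_diag, 0
            if c_del < best:
                best, o = c_del, 1
            if c_ins < best:
                best, o = c_ins, 2
            D[i, j] = best
            op[i, j] = o
    i, j = R, H
    s = d = ins = 0
    while i > 0 or j > 0:
        o = op[i, j]
        if o == 0:
            if reference[i - 1] != hypothesis[j - 1]:
                s += 1
            i, j = i - 1, j - 1
        elif o == 1:
            d += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return ScoreReport(N=R, S=s, D=d, I=ins)
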