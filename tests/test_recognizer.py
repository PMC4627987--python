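import itertools

import numpy as np
import pytest

from esoconvert.recognizer import (
    backward_loglik,
    baum_welch,
    flat_start,
    forward_loglik,
    score,
    split_mixtures,
    train_bigram,
    viterbi_decode,
)
from conftest import brute_force_edit


def _separated_models(labels, shifts, dim=2):
    """Single-Gaussian models with well-separated state means."""
    rng = np.random.default_rng(0)
    models = flat_start(list(labels), [rng.standard_normal((50, dim))])
    for name, shift in zip(labels, shifts):
        for st in models[name].states:
            st.means[:] = shift
            st.variances[:] = 1.0
    return models


def brute_force_decode(models, lm, obs, lm_scale=1.0, ins_penalty=0.0):
    """Exhaustive enumeration over phone sequences and state alignments."""
    T = obs.shape[0]
    labels = lm.labels
    best_lp, best_seq = -np.inf, None

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(1, total - parts + 2):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    for m in range(1, T // 3 + 1):
        for seq in itertools.product(range(len(labels)), repeat=m):
            chain = [(p, s) for p in seq for s in range(3)]
            for dur in compositions(T, 3 * m):
                lp = lm_scale * lm.log_start[seq[0]] + ins_penalty
                for k in range(1, m):
                    lp += lm_scale * lm.log_trans[seq[k - 1], seq[k]] + ins_penalty
                t = 0
                ok = True
                for (p, s), dd in zip(chain, dur):
                    mdl = models[labels[p]]
                    a_self = mdl.trans[1 + s, 1 + s]
                    a_fwd = mdl.trans[1 + s, 2 + s]
                    if (dd > 1 and a_self <= 0) or a_fwd <= 0:
                        ok = False
                        break
                    lp += float(mdl.states[s].log_prob(obs[t : t + dd]).sum())
                    lp += np.log(a_self) * (dd - 1) + np.log(a_fwd)
                    t += dd
                if ok and lp > best_lp:
                    best_lp, best_seq = lp, [labels[p] for p in seq]
    return best_seq, best_lp


class TestFlatStart:
    def test_states_share_global_gaussian(self, rng):
        feats = [rng.standard_normal((30, 39)) for _ in range(3)]
        models = flat_start(["a", "b", "sil"], feats)
        allX = np.vstack(feats)
        for m in models.values():
            for st in m.states:
                assert st.means.shape == (1, 39)
                np.testing.assert_allclose(st.means[0], allX.mean(axis=0))
                np.testing.assert_allclose(st.variances[0], allX.var(axis=0))

    def test_transition_rows_sum_to_one(self, rng):
        models = flat_start(["a"], [rng.standard_normal((10, 5))])
        np.testing.assert_allclose(models["a"].trans[:4].sum(axis=1), 1.0)
        models["a"].validate()

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            flat_start(["a"], [])


class TestBaumWelch:
    def test_stationary_single_phone_converges_to_sample_mean(self):
        # on stationary Gaussian data every state's mean estimate is an
        # occupancy-weighted average of i.i.d. frames, so all states drift
        # to the sample mean as the data grows
        rng = np.random.default_rng(1)
        utts = [rng.standard_normal((60, 3)) + 2.5 for _ in range(30)]
        models = flat_start(["a"], utts)
        models, _ = baum_welch(models, utts, [["a"]] * 30, n_iters=20)
        sample_mean = np.vstack(utts).mean(axis=0)
        for st in models["a"].states:
            mix_mean = st.weights @ st.means
            np.testing.assert_allclose(mix_mean, sample_mean, atol=0.2)

    def test_loglik_trace_non_decreasing(self, rng):
        from esoconvert import make_speaker, sample_utterance

        speaker = make_speaker(4, seed=3)
        utts, seqs = [], []
        for i in range(6):
            u, t = sample_utterance(speaker, n_phones=3, seed=i)
            utts.append(u)
            seqs.append(t.labels())
        models = flat_start(speaker.phones, utts)
        _, trace = baum_welch(models, utts, seqs, n_iters=6)
        for a, b in zip(trace, trace[1:]):
            assert b >= a - 1e-6 * abs(a)

    def test_forward_equals_backward(self, rng):
        models = _separated_models(["a", "b"], [-2.0, 2.0])
        obs = rng.standard_normal((12, 2))
        f = forward_loglik(models, ["a", "b", "a"], obs)
        b = backward_loglik(models, ["a", "b", "a"], obs)
        assert f == pytest.approx(b, abs=1e-8)

    def test_too_short_utterance_skipped_with_warning(self, rng):
        utts = [rng.standard_normal((20, 2)), rng.standard_normal((2, 2))]
        models = flat_start(["a"], utts)
        with pytest.warns(UserWarning, match="skipped"):
            baum_welch(models, utts, [["a"], ["a"]], n_iters=1)


class TestMixtureSplitting:
    def test_schedule_reaches_16_in_four_rounds(self, rng):
        utts = [rng.standard_normal((60, 2)) for _ in range(4)]
        models = flat_start(["a"], utts)
        models = split_mixtures(models, 16)
        for st in models["a"].states:
            assert st.n_components == 16

    def test_weights_stay_normalized(self, rng):
        utts = [rng.standard_normal((80, 2)) for _ in range(4)]
        models = flat_start(["a"], utts)
        models, _ = baum_welch(models, utts, [["a"]] * 4, n_iters=2)
        models = split_mixtures(models, 4, utts, [["a"]] * 4, n_iters=2)
        for st in models["a"].states:
            assert st.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_likelihood_not_hurt_by_split_and_retrain(self):
        rng = np.random.default_rng(9)
        # bimodal emission: mixtures should help
        utts = [
            np.vstack(
                [rng.standard_normal((15, 2)) - 3, rng.standard_normal((15, 2)) + 3]
            )[rng.permutation(30)]
            for _ in range(5)
        ]
        seqs = [["a"]] * 5
        models = flat_start(["a"], utts)
        models, trace1 = baum_welch(models, utts, seqs, n_iters=5)
        before = trace1[-1]
        models = split_mixtures(models, 2, utts, seqs, n_iters=5)
        _, trace2 = baum_welch(models, utts, seqs, n_iters=1)
        assert trace2[0] >= before - 1e-6 * abs(before)

    def test_shrinking_target_rejected(self, rng):
        models = flat_start(["a"], [rng.standard_normal((30, 2))])
        models = split_mixtures(models, 4)
        with pytest.raises(ValueError):
            split_mixtures(models, 2)


class TestBigram:
    def test_add_k_counts_on_single_sentence(self):
        labels = [f"p{i}" for i in range(36)]
        trans = [["p0", "p1", "p0", "p1"]]
        k = 1.0
        lm = train_bigram(trans, labels, k=k)
        expected = (2 + k) / (2 + 36 * k)
        assert np.exp(lm.log_trans[0, 1]) == pytest.approx(expected)

    def test_rows_sum_to_one(self, rng):
        labels = ["a", "b", "c"]
        lm = train_bigram([["a", "b", "c", "a"]], labels, k=0.5)
        np.testing.assert_allclose(np.exp(lm.log_trans).sum(axis=1), 1.0, atol=1e-12)
        assert np.exp(lm.log_start).sum() == pytest.approx(1.0, abs=1e-12)

    def test_unsmoothed_relative_frequencies(self):
        labels = ["a", "b"]
        lm = train_bigram([["a", "b", "a", "b", "a"]], labels, k=0.0)
        assert np.exp(lm.log_trans[0, 1]) == pytest.approx(1.0)
        assert np.exp(lm.log_trans[1, 0]) == pytest.approx(1.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            train_bigram([["a", "z"]], ["a", "b"])


class TestViterbi:
    def test_matches_brute_force_on_toys(self, rng):
        models = _separated_models(["a", "b"], [-2.0, 2.0])
        lm = train_bigram([["a", "b"], ["b", "a"], ["a", "a"]], ["a", "b"])
        for trial in range(6):
            T = int(rng.integers(3, 7))
            obs = rng.standard_normal((T, 2)) * 2
            hyp = viterbi_decode(models, lm, obs)
            ref, _ = brute_force_decode(models, lm, obs)
            assert hyp == ref

    def test_matches_brute_force_with_lm_weights(self, rng):
        models = _separated_models(["a", "b", "c"], [-3.0, 0.0, 3.0])
        lm = train_bigram([["a", "b", "c"], ["c", "b", "a"]], ["a", "b", "c"])
        obs = rng.standard_normal((6, 2))
        hyp = viterbi_decode(models, lm, obs, lm_scale=2.0, ins_penalty=-1.0)
        ref, _ = brute_force_decode(models, lm, obs, lm_scale=2.0, ins_penalty=-1.0)
        assert hyp == ref

    def test_zero_lm_scale_is_acoustic_only(self, rng):
        models = _separated_models(["a", "b"], [-2.0, 2.0])
        # LM strongly prefers "b" but the acoustics are pure "a"
        lm = train_bigram([["b", "b", "b", "b"]], ["a", "b"], k=0.01)
        obs = np.full((5, 2), -2.0) + 0.01 * rng.standard_normal((5, 2))
        hyp = viterbi_decode(models, lm, obs, lm_scale=0.0)
        ref, _ = brute_force_decode(models, lm, obs, lm_scale=0.0)
        assert hyp == ref == ["a"]

    def test_far_separated_emissions_decode_to_all_a(self, rng):
        models = _separated_models(["a", "b"], [0.0, 10.0])
        lm = train_bigram([["a", "b"]], ["a", "b"])
        obs = 0.1 * rng.standard_normal((12, 2))  # 10 sigma from phone b
        assert set(viterbi_decode(models, lm, obs)) == {"a"}

    def test_empty_feature_stream_gives_empty_output(self):
        models = _separated_models(["a"], [0.0])
        lm = train_bigram([["a"]], ["a"])
        assert viterbi_decode(models, lm, np.zeros((0, 2))) == []


class TestScore:
    def test_perfect_match(self):
        r = score(list("abc"), list("abc"))
        assert (r.S, r.D, r.I) == (0, 0, 0)
        assert r.accuracy == pytest.approx(100.0)
        assert r.correct == pytest.approx(100.0)

    def test_single_deletion(self):
        r = score(list("abc"), list("ac"))
        assert (r.S, r.D, r.I) == (0, 1, 0)
        assert r.accuracy == pytest.approx(100 * 2 / 3)
        assert r.correct == pytest.approx(100 * 2 / 3)

    def test_insertions_hit_accuracy_not_correct(self):
        r = score(list("ab"), list("axby"))
        assert (r.S, r.D, r.I) == (0, 0, 2)
        assert r.accuracy == pytest.approx(0.0)
        assert r.correct == pytest.approx(100.0)

    def test_matches_exhaustive_alignment_oracle(self, rng):
        alphabet = list("abcd")
        for _ in range(40):
            ref = list(rng.choice(alphabet, size=rng.integers(1, 8)))
            hyp = list(rng.choice(alphabet, size=rng.integers(0, 8)))
            r = score(ref, hyp)
            best_cost, optimal_set = brute_force_edit(ref, hyp)
            assert r.S + r.D + r.I == best_cost
            assert (r.S, r.D, r.I) in optimal_set
            assert r.correct >= r.accuracy

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score([], ["a"])
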