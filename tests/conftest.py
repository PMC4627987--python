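import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_dtw(X, Y):
    """Exhaustive monotone-path enumeration oracle for DTW cost.

    Walks every path from (0,0) to (Tx-1,Ty-1) with steps (1,1), (1,0),
    (0,1) and returns the minimum accumulated Euclidean distance.  Only
    usable for tiny sequences.
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    Tx, Ty = len(X), len(Y)

    def d(i, j):
        return float(np.linalg.norm(X[i] - Y[j]))

    best = [np.inf]
    stack = [(0, 0, d(0, 0))]
    while stack:
        i, j, c = stack.pop()
        if c >= best[0]:
            continue
        if i == Tx - 1 and j == Ty - 1:
            best[0] = min(best[0], c)
            continue
        if i + 1 < Tx and j + 1 < Ty:
            stack.append((i + 1, j + 1, c + d(i + 1, j + 1)))
        if i + 1 < Tx:
            stack.append((i + 1, j, c + d(i + 1, j)))
        if j + 1 < Ty:
            stack.append((i, j + 1, c + d(i, j + 1)))
    return best[0]


def brute_force_edit(ref, hyp):
    """Exhaustive edit-script enumeration oracle.

    Walks every alignment of hyp to ref (match/substitute, delete,
    insert), and returns (min_cost, {(S, D, I) decompositions attaining
    it}).  Minimal-cost alignments are generally not unique, so the
    scorer under test is checked for membership in the optimal set.
    """
    results = {}

    def walk(i, j, s, d, ins):
        if i == len(ref) and j == len(hyp):
            c = s + d + ins
            results.setdefault(c, set()).add((s, d, ins))
            return
        if i < len(ref) and j < len(hyp):
            walk(i + 1, j + 1, s + (ref[i] != hyp[j]), d, ins)
        if i < len(ref):
            walk(i + 1, j, s, d + 1, ins)
        if j < len(hyp):
            walk(i, j + 1, s, d, ins + 1)

    walk(0, 0, 0, 0, 0)
    best = min(results)
    return best, results[best]
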