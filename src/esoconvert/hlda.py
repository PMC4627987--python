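"""Heteroscedastic linear discriminant analysis (HLDA).

A full-rank linear transform Theta (n x n) is estimated by maximum
likelihood under the model in which the first p projected dimensions carry
class-dependent diagonal variances (the discriminative subspace) and the
remaining n - p dimensions share a single global diagonal variance (the
nuisance subspace).  Features are then projected with the first p rows.

Estimation uses the efficient generalized-EM row-wise update: with the
ML variances substituted, the objective

    Q(Theta) = N log|det Theta|
               - 1/2 sum_{j<=p} sum_c N_c log(theta_j W_c theta_j^T)
               - N/2  sum_{j>p}        log(theta_j T   theta_j^T)  + const

(W_c class covariance, T total covariance) is maximized one row at a time;
each row has the closed-form optimum

    theta_j = c_j G_j^{-1} sqrt(N / (c_j G_j^{-1} c_j^T))

where c_j is the j-th row of cofactors of Theta and G_j the variance-
weighted scatter for that row.  Every update is guaranteed not to decrease
Q.  Initialization is the LDA eigenbasis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

__all__ = [
    "ClassStats",
    "HLDATransform",
    "accumulate_stats",
    "estimate_hlda",
    "project",
    "hlda_loglik",
]


@dataclass
class ClassStats:
    """Per-class and global first/second moments of labeled feature frames."""

    counts: np.ndarray  # (C,)
    means: np.ndarray  # (C, n)
    covariances: np.ndarray  # (C, n, n) population (1/N) convention
    class_ids: np.ndarray  # (C,) original labels, sorted

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    @property
    def global_mean(self) -> np.ndarray:
        return self.counts @ self.means / self.total_count

    @property
    def total_covariance(self) -> np.ndarray:
        """Total scatter / N: within + between class covariance."""
        gm = self.global_mean
        within = np.einsum("c,cij->ij", self.counts, self.covariances)
        dm = self.means - gm
        between = np.einsum("c,ci,cj->ij", self.counts, dm, dm)
        return (within + between) / self.total_count

    @property
    def within_covariance(self) -> np.ndarray:
        return np.einsum("c,cij->ij", self.counts, self.covariances) / self.total_count

    @property
    def between_covariance(self) -> np.ndarray:
        gm = self.global_mean
        dm = self.means - gm
        return np.einsum("c,ci,cj->ij", self.counts, dm, dm) / self.total_count


@dataclass
class HLDATransform:
    """Full transform Theta with its retained dimensionality p."""

    theta: np.ndarray  # (n, n)
    p: int

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    @property
    def theta_p(self) -> np.ndarray:
        return self.theta[: self.p]


def accumulate_stats(
    features: list[np.ndarray] | np.ndarray,
    labels: list[np.ndarray] | np.ndarray,
) -> ClassStats:
    """Exact sample moments per class and globally from labeled frames.

    ``features`` is one (T, n) matrix or a list of them; ``labels`` gives
    one class id per frame.  Classes with fewer frames than dimensions are
    kept but flagged: the estimator diagonal-loads covariances before any
    inversion.
    """
    if isinstance(features, np.ndarray):
        features = [features]
        labels = [labels]
    X = np.concatenate([np.atleast_2d(f) for f in features], axis=0)
    y = np.concatenate([np.asarray(l).ravel() for l in labels])
    if X.shape[0] != y.shape[0]:
        raise ValueError("one label per frame required")
    class_ids = np.unique(y)
    if class_ids.size < 2:
        raise ValueError("need at least 2 classes for a discriminant transform")
    n = X.shape[1]
    C = class_ids.size
    counts = np.empty(C)
    means = np.empty((C, n))
    covs = np.empty((C, n, n))
    for ci, c in enumerate(class_ids):
        sel = X[y == c]
        counts[ci] = sel.shape[0]
        means[ci] = sel.mean(axis=0)
        centered = sel - means[ci]
        covs[ci] = centered.T @ centered / sel.shape[0]
        if sel.shape[0] < n:
            warnings.warn(
                f"class {c!r} has {sel.shape[0]} frames < {n} dims; "
                "covariance will be diagonally loaded",
                stacklevel=2,
            )
    return ClassStats(counts=counts, means=means, covariances=covs, class_ids=class_ids)


def _loaded(M: np.ndarray, scale: float = 1e-6) -> np.ndarray:
    """Diagonal loading: add scale*trace/n to the diagonal."""
    n = M.shape[0]
    return M + np.eye(n) * (scale * np.trace(M) / n)


def _lda_init(stats: ClassStats) -> np.ndarray:
    """Full-rank LDA eigenbasis, eigenvalue-descending, index tie-break."""
    Sw = _loaded(stats.within_covariance)
    Sb = stats.between_covariance
    vals, vecs = eigh(Sb, Sw)
    order = np.argsort(-vals, kind="stable")
    theta = vecs[:, order].T
    if np.linalg.matrix_rank(theta) < theta.shape[0]:
        theta = theta + 1e-8 * np.eye(theta.shape[0])
    return theta


def _objective_from(
    theta: np.ndarray, counts: np.ndarray, W: np.ndarray, T: np.ndarray, p: int
) -> float:
    """Q(Theta) with ML variances substituted (full log-likelihood incl. consts)."""
    N = float(counts.sum())
    n = theta.shape[0]
    _, logdet = np.linalg.slogdet(theta)
    q = N * logdet
    tp = theta[:p]
    class_proj = np.einsum("ji,cik,jk->cj", tp, W, tp)  # (C, p)
    class_proj = np.maximum(class_proj, np.finfo(float).tiny)
    q -= 0.5 * np.sum(counts[:, None] * np.log(class_proj))
    if p < n:
        tn = theta[p:]
        glob_proj = np.einsum("ji,ik,jk->j", tn, T, tn)
        glob_proj = np.maximum(glob_proj, np.finfo(float).tiny)
        q -= 0.5 * N * np.sum(np.log(glob_proj))
    q -= 0.5 * N * n * (1.0 + np.log(2.0 * np.pi))
    return float(q)


def _objective(theta: np.ndarray, stats: ClassStats, p: int) -> float:
    return _objective_from(
        theta, stats.counts, stats.covariances, stats.total_covariance, p
    )


def estimate_hlda(
    stats: ClassStats,
    p: int,
    n_iters: int = 100,
    seed: int = 0,
    rel_tol: float = 1e-6,
    load_scale: float = 1e-6,
) -> HLDATransform:
    """Maximum-likelihood HLDA transform via row-wise generalized EM.

    ``p`` is the retained dimensionality (52 -> 39 in the standard stacked-
    derivative configuration).  The per-sweep objective is non-decreasing;
    iteration stops at ``n_iters`` sweeps or relative objective change
    below ``rel_tol``.  ``seed`` is accepted for interface symmetry; the
    estimator itself is deterministic from the LDA start.
    """
    n = stats.dim
    if not 1 <= p <= n:
        raise ValueError(f"need 1 <= p <= n, got p={p}, n={n}")
    N = stats.total_count
    T = _loaded(stats.total_covariance, load_scale)
    W = np.stack([_loaded(stats.covariances[c], load_scale) for c in range(stats.n_classes)])
    counts = stats.counts

    theta = _lda_init(stats)
    if not np.all(np.isfinite(theta)):
        raise np.linalg.LinAlgError("singular global covariance; LDA init failed")
    prev_q = _objective_from(theta, counts, W, T, p)

    for _ in range(n_iters):
        for j in range(n):
            # cofactor row: c_j = det(Theta) * (Theta^{-1})^T[j]
            inv = np.linalg.inv(theta)
            cj = inv[:, j]  # proportional to the cofactor row; scale cancels
            if j < p:
                proj = np.einsum("i,cik,k->c", theta[j], W, theta[j])
                proj = np.maximum(proj, np.finfo(float).tiny)
                Gj = np.einsum("c,cik->ik", counts / proj, W)
            else:
                proj = float(theta[j] @ T @ theta[j])
                Gj = (N / max(proj, np.finfo(float).tiny)) * T
            sol = np.linalg.solve(Gj, cj)
            denom = float(cj @ sol)
            if denom <= 0:
                continue  # numerically degenerate row; leave unchanged
            theta[j] = sol * np.sqrt(N / denom)
        q = _objective_from(theta, counts, W, T, p)
        if q < prev_q - 1e-8 * max(1.0, abs(prev_q)):
            warnings.warn("HLDA objective decreased; stopping early", stacklevel=2)
            break
        if abs(q - prev_q) < rel_tol * max(1.0, abs(prev_q)):
            prev_q = q
            break
        prev_q = q
    return HLDATransform(theta=theta, p=p)


def project(t: HLDATransform, x: np.ndarray) -> np.ndarray:
    """Project n-dim vectors to the retained p dimensions: y = Theta_p x."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != t.n:
        raise ValueError(f"expected {t.n}-dim input, got {x2.shape[1]}")
    y = x2 @ t.theta_p.T
    return y[0] if single else y


def hlda_loglik(t: HLDATransform, stats: ClassStats) -> float:
    """Total data log-likelihood under the HLDA model, from sufficient stats.

    Class c is modeled in the projected space with mean
    [Theta_p mu_c ; Theta_{n-p} mu_g] and diagonal variances
    [theta_j W_c theta_j^T (j <= p) ; theta_j T theta_j^T (j > p)];
    the Jacobian term N log|det Theta| accounts for the transform.
    Equals a per-frame evaluation summed over the raw data.
    """
    theta, p, n = t.theta, t.p, t.n
    if n != stats.dim:
        raise ValueError("transform/stats dimension mismatch")
    covs = stats.covariances
    if np.any(np.linalg.eigvalsh(stats.total_covariance) < -1e-10):
        raise np.linalg.LinAlgError("non-PSD total covariance")
    return _objective(theta, stats, p)
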