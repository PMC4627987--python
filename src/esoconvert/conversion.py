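"""Joint-density GMM voice conversion trained by direct statistical estimation.

A G-component Gaussian mixture is fitted over joint source/target vectors
z = [x || y].  Rather than classical EM, parameters are estimated directly
from a hard vector-quantization of the joint data: k-means provides the
initial classes, each class contributes its relative frequency as the
mixture weight, its sample mean, and its full joint sample covariance
(whose blocks Sigma_xx, Sigma_yy, Sigma_xy fall out at once).  Hard
re-assignment to the nearest class centroid alternates with re-estimation
until the assignment stabilizes.

The conversion function is the conditional expectation of the target given
the source under the fitted joint model:

    F(x) = sum_i p(i|x) * (mu_i^y + Sigma_i^yx (Sigma_i^xx)^-1 (x - mu_i^x))

An outer loop re-runs the DTW alignment between converted and target
sequences to refine the frame mapping list, re-estimating the mixture each
time, and returns the iteration with the lowest mean squared conversion
error on the aligned training pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .alignment import build_mapping_list, dtw_align

__all__ = [
    "JointGMM",
    "ConversionFunction",
    "kmeans_init",
    "estimate_joint_gmm",
    "posterior",
    "convert",
    "train_conversion",
]

_VAR_FLOOR_SCALE = 1e-4  # fraction of global variance added to diagonals


@dataclass
class JointGMM:
    """Mixture over stacked source||target vectors.

    ``dim_x`` source dimensions come first; means are (G, dx+dy) and
    covariances (G, dx+dy, dx+dy) with the cross blocks Sigma_xy/Sigma_yx
    as sub-matrices.
    """

    weights: np.ndarray  # (G,)
    means: np.ndarray  # (G, d)
    covariances: np.ndarray  # (G, d, d)
    dim_x: int

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim_y(self) -> int:
        return self.means.shape[1] - self.dim_x

    def validate(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValueError("mixture weights must be positive")
        sym = np.max(np.abs(self.covariances - np.swapaxes(self.covariances, 1, 2)))
        if sym > 1e-8:
            raise ValueError("covariances must be symmetric")

    # block accessors
    def mu_x(self) -> np.ndarray:
        return self.means[:, : self.dim_x]

    def mu_y(self) -> np.ndarray:
        return self.means[:, self.dim_x :]

    def sigma_xx(self) -> np.ndarray:
        return self.covariances[:, : self.dim_x, : self.dim_x]

    def sigma_yy(self) -> np.ndarray:
        return self.covariances[:, self.dim_x :, self.dim_x :]

    def sigma_yx(self) -> np.ndarray:
        return self.covariances[:, self.dim_x :, : self.dim_x]


@dataclass
class ConversionFunction:
    """Joint GMM plus the per-class regression terms of F(x), precomputed."""

    gmm: JointGMM
    regression: np.ndarray = field(init=False)  # (G, dy, dx): Sigma_yx Sigma_xx^-1

    def __post_init__(self) -> None:
        sxx = self.gmm.sigma_xx()
        syx = self.gmm.sigma_yx()
        try:
            self.regression = np.stack(
                [np.linalg.solve(sxx[i].T, syx[i].T).T for i in range(self.gmm.n_components)]
            )
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular source covariance block despite variance flooring"
            ) from e

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return convert(x, self)


def kmeans_init(Z: np.ndarray, G: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Vector-quantize the joint vectors into G classes.

    Returns (assignment, centroids).  Deterministic under ``seed``; empty
    clusters are repaired by re-seeding from the point farthest from its
    centroid so that all G classes are live.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    n = Z.shape[0]
    if G < 1 or G > n:
        raise ValueError(f"need 1 <= G <= n_pairs, got G={G}, n={n}")
    km = KMeans(n_clusters=G, n_init=1, random_state=seed & 0x7FFFFFFF)
    labels = km.fit_predict(Z)
    centroids = km.cluster_centers_.copy()
    labels, centroids = _repair_empty(Z, labels, centroids)
    return labels, centroids


def _repair_empty(Z, labels, centroids):
    """Re-seed any empty class from the point farthest from its centroid."""
    G = centroids.shape[0]
    for g in range(G):
        if np.any(labels == g):
            continue
        resid = np.linalg.norm(Z - centroids[labels], axis=1)
        donor = int(np.argmax(resid))
        labels = labels.copy()
        labels[donor] = g
        centroids[g] = Z[donor]
    # recompute centroids of touched classes
    for g in range(G):
        mask = labels == g
        if np.any(mask):
            centroids[g] = Z[mask].mean(axis=0)
    return labels, centroids


def _spd(M: np.ndarray, rel_tol: float = 1e-10) -> bool:
    """True when M is comfortably positive definite (smallest eigenvalue
    above rel_tol times the mean diagonal)."""
    thresh = rel_tol * max(np.trace(M) / M.shape[0], np.finfo(float).tiny)
    try:
        ev = np.linalg.eigvalsh(M)
    except np.linalg.LinAlgError:
        return False
    return bool(ev[0] > thresh)


def estimate_joint_gmm(
    Z: np.ndarray,
    assignment: np.ndarray,
    dim_x: int | None = None,
    var_floor_scale: float = _VAR_FLOOR_SCALE,
) -> JointGMM:
    """Direct statistical estimation of the joint mixture from classified data.

    Per class i: weight alpha_i = N_i / N, mean = class sample mean, and
    covariance = class sample covariance of the joint vectors (population
    1/N convention), which yields all four blocks at once.  Classes whose
    source covariance block is not safely positive definite (tiny classes,
    degenerate data) get a variance floor proportional to the global
    per-dimension variance added to the joint diagonal; well-conditioned
    classes are left untouched so that noiseless closed-form cases are
    recovered exactly.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    assignment = np.asarray(assignment)
    n, d = Z.shape
    if dim_x is None:
        dim_x = d // 2
    classes = np.unique(assignment)
    G = classes.size
    if G == 0:
        raise ValueError("no classes in assignment")
    global_var = Z.var(axis=0)
    floor = var_floor_scale * np.maximum(global_var, np.finfo(float).tiny)

    weights = np.empty(G)
    means = np.empty((G, d))
    covs = np.empty((G, d, d))
    import warnings

    for gi, g in enumerate(classes):
        sel = Z[assignment == g]
        if sel.shape[0] == 0:
            raise ValueError(f"class {g} is empty")
        weights[gi] = sel.shape[0] / n
        means[gi] = sel.mean(axis=0)
        centered = sel - means[gi]
        covs[gi] = centered.T @ centered / sel.shape[0]
        if sel.shape[0] < 2:
            warnings.warn(
                f"class {g} has a single member; covariance is the floor", stacklevel=2
            )
        if not _spd(covs[gi][:dim_x, :dim_x]):
            covs[gi][np.diag_indices(d)] += floor
    return JointGMM(weights=weights, means=means, covariances=covs, dim_x=dim_x)


def _log_gauss(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log N(x; mu_i, Sigma_i) for each component; x is (n, d) or (d,)."""
    from scipy.linalg import cholesky as sp_cholesky, solve_triangular

    x = np.atleast_2d(x)
    G, d = means.shape
    out = np.empty((x.shape[0], G))
    for i in range(G):
        L = sp_cholesky(covs[i], lower=True)
        diff = (x - means[i]).T
        sol = solve_triangular(L, diff, lower=True)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, i] = -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)
    return out


def posterior(x: np.ndarray, gmm: JointGMM) -> np.ndarray:
    """Component posteriors p(i|x) from the source marginal of the joint GMM.

    Computed in the log domain; rows sum to one.  Accepts a single source
    vector or an (n, dx) batch.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite source vector")
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != gmm.dim_x:
        raise ValueError(f"expected {gmm.dim_x}-dim source vectors, got {x2.shape[1]}")
    logp = _log_gauss(x2, gmm.mu_x(), gmm.sigma_xx()) + np.log(gmm.weights)
    logp -= logsumexp(logp, axis=1, keepdims=True)
    p = np.exp(logp)
    return p[0] if single else p


def convert(x: np.ndarray, fn: ConversionFunction) -> np.ndarray:
    """Apply F(x) = E[y|x]: posterior-weighted per-class linear regressions."""
    gmm = fn.gmm
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    p = np.atleast_2d(posterior(x2, gmm))  # (n, G)
    diff = x2[:, None, :] - gmm.mu_x()[None, :, :]  # (n, G, dx)
    reg = np.einsum("gij,ngj->ngi", fn.regression, diff)  # (n, G, dy)
    comp = gmm.mu_y()[None, :, :] + reg
    y = np.einsum("ng,ngi->ni", p, comp)
    return y[0] if single else y


def _reassign(Z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(Z**2, axis=1)[:, None]
        - 2.0 * Z @ centroids.T
        + np.sum(centroids**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def fit_joint_gmm(
    Z: np.ndarray,
    G: int,
    seed: int = 0,
    max_passes: int = 20,
    dim_x: int | None = None,
) -> JointGMM:
    """k-means init + iterated hard re-assignment / re-estimation.

    Vectors move to the nearest class mean in joint space between
    estimation passes; iteration stops at assignment stability or after
    ``max_passes`` sweeps.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    labels, centroids = kmeans_init(Z, G, seed)
    for _ in range(max_passes):
        new = _reassign(Z, centroids)
        new, centroids = _repair_empty(Z, new, centroids)
        if np.array_equal(new, labels):
            break
        labels = new
        for g in range(G):
            centroids[g] = Z[labels == g].mean(axis=0)
    return estimate_joint_gmm(Z, labels, dim_x=dim_x)


@dataclass
class TrainTrace:
    """Per-outer-iteration diagnostics of conversion training."""

    mse: list[float] = field(default_factory=list)
    n_pairs: list[int] = field(default_factory=list)


def train_conversion(
    src_corpus: list[np.ndarray],
    tgt_corpus: list[np.ndarray],
    G: int = 64,
    n_outer_iters: int = 3,
    seed: int = 0,
    rel_tol: float = 1e-4,
    max_vq_passes: int = 20,
) -> tuple[ConversionFunction, TrainTrace]:
    """Train the conversion function with iterative DTW re-alignment.

    Iteration 1 aligns raw source statics x with target statics y; from
    iteration 2 the alignment runs between the *converted* statics F(x)
    and y, pairing the original x frames through the refined path.  The
    model with the lowest mean squared error between converted and target
    aligned vectors is returned, together with the iteration trace.
    """
    if len(src_corpus) != len(tgt_corpus):
        raise ValueError(
            f"non-parallel corpora: {len(src_corpus)} source vs "
            f"{len(tgt_corpus)} target sentences"
        )
    if len(src_corpus) == 0:
        raise ValueError("empty corpus")
    trace = TrainTrace()
    best_fn: ConversionFunction | None = None
    best_mse = np.inf
    fn: ConversionFunction | None = None

    for it in range(n_outer_iters):
        pairs = []
        for X, Y in zip(src_corpus, tgt_corpus):
            probe = X if fn is None else convert(X, fn)
            path = dtw_align(probe, Y)
            pairs.append(build_mapping_list(X, Y, path))
        Z = np.concatenate(pairs, axis=0)
        gmm = fit_joint_gmm(Z, G, seed=seed + it, max_passes=max_vq_passes)
        fn = ConversionFunction(gmm)
        dx = gmm.dim_x
        yhat = convert(Z[:, :dx], fn)
        mse = float(np.mean((yhat - Z[:, dx:]) ** 2))
        trace.mse.append(mse)
        trace.n_pairs.append(Z.shape[0])
        if mse < best_mse:
            best_mse, best_fn = mse, fn
        if it > 0 and abs(trace.mse[-2] - mse) < rel_tol * max(abs(trace.mse[-2]), 1e-12):
            break
    assert best_fn is not None
    return best_fn, trace
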