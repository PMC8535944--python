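"""Segment selection by Gaussian-mixture biclustering.

Heart-cycle segments cut from noisy recordings are not all usable: some carry
ambient noise, friction or clipped transients that poison downstream
training.  Working from the assumption that the clean majority of segments
have correlated cepstral statistics, the per-segment feature vectors are
clustered with a two-component Gaussian mixture fitted by
expectation-maximization, and the minority cluster is discarded as noise.

The mixture density is f(x) = sum_k pi_k N(x | mu_k, sigma2_k) with diagonal
covariances.  EM alternates the estimation step

    t(i,k) = pi_k N(x_i|mu_k, sigma2_k) / sum_j pi_j N(x_i|mu_j, sigma2_j)

with the maximization updates pi_k = mean_i t(i,k),
mu_k = sum_i t(i,k) x_i / sum_i t(i,k) and
sigma2_k = sum_i t(i,k)(x_i - mu_k)^2 / sum_i t(i,k), and is guaranteed not
to decrease the log-likelihood.  Initialization is k-means++-style seeding
with a handful of restarts, keeping the best final log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, VarianceCollapse

VARIANCE_FLOOR = 1e-9


@dataclass
class GMMParams:
    """Mixture parameters theta_k = (pi_k, mu_k, sigma2_k), diagonal covariance."""

    weights: np.ndarray  # (M,)
    means: np.ndarray  # (M, d)
    variances: np.ndarray  # (M, d)

    @property
    def M(self) -> int:
        return self.weights.size

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("mixture weights must be non-negative")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")


@dataclass
class Responsibilities:
    """Posterior membership probabilities t(i,k) and their argmax labels."""

    t: np.ndarray  # (n, M)

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.t, axis=1)


@dataclass
class SelectionResult:
    kept: list[str]
    ignored: list[str]
    kept_cluster: int
    params: GMMParams | None = None


def _log_component_densities(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """log N(x_i | mu_k, diag sigma2_k) for all i, k -> (n, M)."""
    diff = X[:, None, :] - params.means[None, :, :]  # (n, M, d)
    var = params.variances[None, :, :]
    log_det = np.sum(np.log(params.variances), axis=1)  # (M,)
    quad = np.sum(diff**2 / var, axis=2)  # (n, M)
    d = X.shape[1]
    return -0.5 * (d * np.log(2.0 * np.pi) + log_det[None, :] + quad)


def gmm_pdf(x: np.ndarray, params: GMMParams) -> float:
    """Mixture density f(x) = sum_k pi_k N(x | mu_k, sigma2_k)."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    if x.size != params.d:
        raise ShapeError(f"x has dimension {x.size}, params expect {params.d}")
    log_comp = _log_component_densities(x[None, :], params)[0]
    return float(np.sum(params.weights * np.exp(log_comp)))


def _log_likelihood(X: np.ndarray, params: GMMParams) -> tuple[float, np.ndarray]:
    """Total log-likelihood and the responsibility matrix in one pass."""
    log_joint = np.log(params.weights)[None, :] + _log_component_densities(X, params)
    m = log_joint.max(axis=1, keepdims=True)
    log_norm = m[:, 0] + np.log(np.sum(np.exp(log_joint - m), axis=1))
    t = np.exp(log_joint - log_norm[:, None])
    return float(log_norm.sum()), t


def _kmeanspp_means(X: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial means proportionally to squared distance."""
    n = X.shape[0]
    means = [X[rng.integers(n)]]
    for _ in range(1, M):
        d2 = np.min(
            np.sum((X[:, None, :] - np.asarray(means)[None, :, :]) ** 2, axis=2), axis=1
        )
        total = d2.sum()
        if total == 0:
            means.append(X[rng.integers(n)])
        else:
            means.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(means)


def _init_params(X: np.ndarray, M: int, rng: np.random.Generator) -> GMMParams:
    var = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    return GMMParams(
        weights=np.full(M, 1.0 / M),
        means=_kmeanspp_means(X, M, rng),
        variances=np.tile(var, (M, 1)),
    )


def em_fit(
    X: np.ndarray,
    M: int,
    *,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    n_restarts: int = 5,
    reg_covar: float = 1e-6,
) -> tuple[GMMParams, Responsibilities, np.ndarray]:
    """Fit an M-component diagonal GMM by EM.

    Returns the best-of-``n_restarts`` parameters, the responsibilities and
    the per-iteration log-likelihood trace of the winning run.  ``reg_covar``
    is added to every variance in the M-step, which bounds the otherwise
    unbounded mixture likelihood (a component shrinking onto a single point).
    A component whose variance still lands below the floor is re-initialized
    once; a second collapse raises :class:`VarianceCollapse`.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < M:
        raise ValueError(f"need at least M={M} rows, got {X.shape[0]}")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < M:
        raise ValueError(f"need at least M={M} distinct rows, got {n_distinct}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if M == 1:
        # closed form in one step: MLE of a single Gaussian
        params = GMMParams(
            weights=np.array([1.0]),
            means=X.mean(axis=0, keepdims=True),
            variances=np.maximum(X.var(axis=0, keepdims=True), VARIANCE_FLOOR),
        )
        ll, t = _log_likelihood(X, params)
        return params, Responsibilities(t=t), np.array([ll])

    best: tuple[float, GMMParams, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        params = _init_params(X, M, rng)
        trace: list[float] = []
        reinit_done = False
        t = None
        for _ in range(max_iter):
            ll, t = _log_likelihood(X, params)  # estimation step
            trace.append(ll)
            if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
                break
            # maximization step
            nk = t.sum(axis=0)  # (M,)
            weights = nk / X.shape[0]
            means = (t.T @ X) / nk[:, None]
            diff2 = (X[:, None, :] - means[None, :, :]) ** 2
            variances = np.einsum("nm,nmd->md", t, diff2) / nk[:, None] + reg_covar
            if np.any(variances < VARIANCE_FLOOR):
                if reinit_done:
                    raise VarianceCollapse(
                        "mixture component collapsed twice (variance below floor)"
                    )
                bad = np.any(variances < VARIANCE_FLOOR, axis=1)
                means[bad] = X[rng.integers(X.shape[0], size=int(bad.sum()))]
                variances[bad] = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
                reinit_done = True
            params = GMMParams(weights=weights, means=means, variances=variances)
        ll, t = _log_likelihood(X, params)
        if not trace or ll >= trace[-1] - 1e-12:
            trace.append(ll)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], params, t, np.asarray(trace))
    assert best is not None
    _, params, t, trace_arr = best
    return params, Responsibilities(t=t), trace_arr


def select_segments(
    features: dict[str, np.ndarray] | tuple[list[str], np.ndarray],
    seed: int = 0,
    *,
    standardize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 200,
    reg_covar: float = 1e-6,
) -> SelectionResult:
    """Bicluster per-segment feature vectors and keep the larger cluster.

    ``features`` maps segment id -> feature vector (or is an (ids, matrix)
    pair).  Features are z-scored per dimension before EM because cepstral
    coefficient scales differ by orders of magnitude.  With fewer than two
    segments, selection is skipped and everything is kept.
    """
    if isinstance(features, dict):
        ids = list(features.keys())
        X = np.asarray([features[i] for i in ids], dtype=np.float64)
    else:
        ids, X = features
        X = np.asarray(X, dtype=np.float64)
    if len(ids) < 2:
        warnings.warn("fewer than 2 segments: selection skipped, all kept", stacklevel=2)
        return SelectionResult(kept=list(ids), ignored=[], kept_cluster=0)
    Z = X
    if standardize:
        mu, sigma = X.mean(axis=0), X.std(axis=0)
        sigma = np.where(sigma == 0.0, 1.0, sigma)
        Z = (X - mu) / sigma
    params, resp, _ = em_fit(
        Z, M=2, seed=seed, tol=tol, max_iter=max_iter, reg_covar=reg_covar
    )
    labels = resp.hard_labels
    sizes = np.bincount(labels, minlength=2)
    if sizes[0] != sizes[1]:
        keep_k = int(np.argmax(sizes))
    else:
        # tie-break: the cluster whose component explains its members best
        log_comp = _log_component_densities(Z, params)
        ll_by_cluster = [log_comp[labels == k, k].sum() for k in (0, 1)]
        keep_k = int(np.argmax(ll_by_cluster))
    kept = [i for i, l in zip(ids, labels) if l == keep_k]
    ignored = [i for i, l in zip(ids, labels) if l != keep_k]
    return SelectionResult(kept=kept, ignored=ignored, kept_cluster=keep_k, params=params)
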