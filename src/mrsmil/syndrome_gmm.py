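"""Per-class Gaussian-mixture feature models, fitted by EM with MDL order selection.

Each class is modelled in the similarity space spanned by its selected
representative symptoms: the positive bags are embedded (one vector per
bag, dimension = number of prototypes) and a Gaussian mixture is fitted to
those vectors. The number of components k is chosen by minimum description
length,

    MDL(k) = -loglik + (P/2) * ln(n * m),
    P = (k - 1) + k*m + k*m*(m + 1)/2   (weights, means, covariances),

with the smallest k winning ties. EM is standard (k-means++ initialisation,
responsibility E-step, closed-form M-step) with a per-M-step ridge of
``1e-6 * trace(cov)/m`` and, for the pipeline's embedded data, an absolute
eigenvalue floor on each covariance: embedded symptom profiles are heavily
duplicated, and without the floor components collapse onto duplicate rows,
the likelihood is unbounded and MDL degenerates (see ``_regularise``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .data_model import MILDataset, binary_view
from .representative_selection import RepresentativeInstanceSet, embed_bags

__all__ = [
    "GaussianMixture",
    "GMMConfig",
    "ClassModel",
    "em_fit",
    "mdl_score",
    "select_k",
    "build_class_model",
]

_RIDGE_SCALE = 1e-6
_ABS_RIDGE_FLOOR = 1e-10


@dataclass(frozen=True)
class GaussianMixture:
    """A fitted k-component Gaussian mixture in m dimensions."""

    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, m)
    covariances: np.ndarray  # (k, m, m)
    fitted_loglik: float
    loglik_trace: tuple[float, ...] = ()
    n_iter: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture weights sum to {w.sum()}, expected 1")
        if np.any(w < 0):
            raise ValueError("mixture weights must be nonnegative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "covariances", np.asarray(self.covariances, dtype=float))

    @property
    def k(self) -> int:
        return int(self.weights.shape[0])

    @property
    def m(self) -> int:
        return int(self.means.shape[1])

    def component_logpdf(self, X: np.ndarray) -> np.ndarray:
        """(n, k) log densities of each point under each component."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, m = X.shape
        out = np.empty((n, self.k))
        for j in range(self.k):
            L = np.linalg.cholesky(self.covariances[j])
            diff = X - self.means[j]
            sol = np.linalg.solve(L, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            out[:, j] = -0.5 * (m * math.log(2 * math.pi) + logdet + maha)
        return out

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        """Log mixture density per point."""
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        return logsumexp(self.component_logpdf(X) + logw, axis=1)

    def pdf(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(X))


@dataclass(frozen=True)
class GMMConfig:
    """Mixture-fit configuration; ``k_max=None`` means min(5, n-1).

    ``var_floor`` is an absolute per-coordinate variance floor. The default
    0.02 is scaled to the unit-bounded similarity embedding the pipeline
    fits mixtures on (coordinates in (0, 1]): it caps the log-density cost
    of one unexpressed signature symptom at a few tens of nats, so a class
    whose positives happen to cluster tightly cannot produce astronomically
    negative scores for slightly atypical bags. Set 0.0 for data on other
    scales (the relative trace ridge then applies alone).
    """

    k_max: int | None = None
    seeds_per_k: int = 3
    covariance: Literal["full", "diag"] = "full"
    tol: float = 1e-6
    max_iter: int = 200
    var_floor: float = 0.02


def _regularise(cov: np.ndarray, mode: str, var_floor: float) -> np.ndarray:
    """Ridge plus an optional eigenvalue floor.

    The relative ridge (1e-6 * trace/m) keeps the covariance numerically
    positive definite, but it does not bound the likelihood when several
    identical points fall into one component — embedded symptom profiles are
    heavily duplicated, the MLE covariance collapses and the mixture
    degenerates into spikes. ``var_floor`` clips the covariance eigenvalues
    from below; it binds only on collapsed directions, so healthy fits (and
    the EM monotonicity guarantee) are untouched.
    """
    m = cov.shape[0]
    ridge = max(_RIDGE_SCALE * np.trace(cov) / m, _ABS_RIDGE_FLOOR)
    cov = cov + ridge * np.eye(m)
    if mode == "diag":
        cov = np.diag(np.diag(cov))
    if var_floor > 0.0:
        vals, vecs = np.linalg.eigh(cov)
        if vals[0] < var_floor:
            cov = (vecs * np.maximum(vals, var_floor)) @ vecs.T
            cov = (cov + cov.T) / 2.0
            if mode == "diag":
                cov = np.diag(np.diag(cov))
    return cov


def em_fit(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    covariance: str = "full",
    var_floor: float = 0.0,
) -> GaussianMixture:
    """Fit a k-component Gaussian mixture by EM.

    Initialisation: k-means++ centres from ``seed``, hard-assignment M-step.
    The per-iteration log-likelihood is guaranteed nondecreasing (within
    1e-9); iteration stops when the relative change drops below ``tol``.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, m = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")

    rng = np.random.RandomState(seed % (2**31 - 1))
    if k == 1:
        centers = X.mean(axis=0, keepdims=True)
    else:
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rng)
    # hard assignment to the nearest centre -> initial parameters
    assign = np.argmin(
        ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    resp = np.zeros((n, k))
    resp[np.arange(n), assign] = 1.0
    # guard against empty initial clusters
    empty = resp.sum(axis=0) == 0
    if empty.any():
        resp[:, empty] = 1e-3
        resp /= resp.sum(axis=1, keepdims=True)

    weights, means, covs = _m_step(X, resp, covariance, var_floor)
    trace: list[float] = []
    loglik = -math.inf
    for it in range(1, max_iter + 1):
        gmm = GaussianMixture(weights, means, covs, fitted_loglik=0.0)
        log_joint = gmm.component_logpdf(X) + np.log(np.maximum(weights, 1e-300))
        per_point = logsumexp(log_joint, axis=1)
        new_loglik = float(per_point.sum())
        if trace and new_loglik < trace[-1]:
            # the regularised M-step can drift the plain likelihood by
            # rounding-scale amounts near convergence; keep the better params
            weights, means, covs = prev_params
            loglik = trace[-1]
            break
        trace.append(new_loglik)
        resp = np.exp(log_joint - per_point[:, None])
        prev_params = (weights, means, covs)
        weights, means, covs = _m_step(X, resp, covariance, var_floor)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (
            1.0 + abs(new_loglik)
        ):
            loglik = new_loglik
            break
        loglik = new_loglik
    return GaussianMixture(
        weights, means, covs, fitted_loglik=loglik,
        loglik_trace=tuple(trace), n_iter=len(trace),
    )


def _m_step(
    X: np.ndarray, resp: np.ndarray, covariance: str, var_floor: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, m = X.shape
    k = resp.shape[1]
    nk = resp.sum(axis=0) + 1e-300
    weights = nk / nk.sum()
    means = (resp.T @ X) / nk[:, None]
    covs = np.empty((k, m, m))
    for j in range(k):
        diff = X - means[j]
        cov = (resp[:, j][:, None] * diff).T @ diff / nk[j]
        covs[j] = _regularise(cov, covariance, var_floor)
    return weights, means, covs


def n_parameters(k: int, m: int, covariance: str = "full") -> int:
    """Free-parameter count P of a k-component mixture in m dimensions."""
    cov_terms = k * m * (m + 1) // 2 if covariance == "full" else k * m
    return (k - 1) + k * m + cov_terms


def mdl_score(
    gmm: GaussianMixture, points: np.ndarray, covariance: str = "full"
) -> float:
    """Minimum-description-length score; lower is better."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, m = X.shape
    loglik = float(gmm.logpdf(X).sum())
    P = n_parameters(gmm.k, m, covariance)
    return -loglik + 0.5 * P * math.log(n * m)


def select_k(
    points: np.ndarray,
    k_max: int | None = None,
    seeds_per_k: int = 3,
    seed: int = 0,
    config: GMMConfig | None = None,
) -> GaussianMixture:
    """Fit k = 1..k_max (best of ``seeds_per_k`` restarts each) and return
    the mixture minimising the MDL score (ties: smaller k)."""
    cfg = config or GMMConfig()
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    if k_max is None:
        k_max = cfg.k_max if cfg.k_max is not None else min(5, max(1, n - 1))
    k_max = min(k_max, n)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    best: GaussianMixture | None = None
    best_score = math.inf
    ss = np.random.SeedSequence([seed, 0x6A3])
    sub_seeds = ss.generate_state(k_max * seeds_per_k) % (2**31 - 1)
    for k in range(1, k_max + 1):
        for r in range(seeds_per_k):
            gmm = em_fit(
                X, k,
                seed=int(sub_seeds[(k - 1) * seeds_per_k + r]),
                tol=cfg.tol, max_iter=cfg.max_iter, covariance=cfg.covariance,
                var_floor=cfg.var_floor,
            )
            score = mdl_score(gmm, X, cfg.covariance)
            if score < best_score:
                best_score = score
                best = gmm
    assert best is not None
    return best


@dataclass(frozen=True)
class ClassModel:
    """Everything needed to score a bag for one class: the class's
    representative symptoms, the mixture over the embedded positives, and
    the class prior (positive-bag fraction)."""

    target_class: str
    representatives: RepresentativeInstanceSet
    gmm: GaussianMixture
    prior: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prior <= 1.0:
            raise ValueError(f"prior must be in (0, 1], got {self.prior}")


def build_class_model(
    dataset: MILDataset,
    target_class: str,
    representatives: RepresentativeInstanceSet,
    gmm_config: GMMConfig | None = None,
    seed: int = 0,
) -> ClassModel:
    """Embed the class's positive bags on its prototypes and fit the mixture."""
    view = binary_view(dataset, target_class)
    if view.n_positive < 2:
        raise ValueError(
            f"class {target_class!r} has {view.n_positive} positive bags; need >= 2"
        )
    E = embed_bags(
        view.positive_bags, representatives.prototypes, representatives.embedding_sigma
    )
    gmm = select_k(E, seed=seed, config=gmm_config)
    prior = view.n_positive / len(dataset.bags)
    return ClassModel(target_class, representatives, gmm, prior)
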