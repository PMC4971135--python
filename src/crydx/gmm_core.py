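"""Diagonal-covariance Gaussian mixture models.

Likelihood of a D-dimensional frame x under a K-component mixture:

    F(x | lambda) = sum_i c_i N(x | mu_i, Sigma_i),   c_i >= 0, sum c_i = 1

with diagonal Sigma_i.  This module provides stable log-domain density
evaluation, duration-normalized average log-likelihood (the 1/T factor
removes the effect of cry-unit length), native EM training for UBM
construction, and balanced frame pooling across health subclasses so the
UBM is not biased toward the dominant class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

WEIGHT_TOL = 1e-9
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GMMParams:
    """Weights, means and diagonal variances of one mixture model."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        self.validate()

    def validate(self) -> None:
        K, D = self.means.shape
        if self.weights.shape != (K,) or self.variances.shape != (K, D):
            raise ValueError("inconsistent GMM parameter shapes")
        if np.any(self.weights < -WEIGHT_TOL):
            raise ValueError("mixture weights must be nonnegative")
        if abs(float(self.weights.sum()) - 1.0) > 1e-6:
            raise ValueError(f"mixture weights must sum to 1, got {self.weights.sum()}")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def copy(self, tag: str | None = None) -> "GMMParams":
        return GMMParams(
            weights=self.weights.copy(),
            means=self.means.copy(),
            variances=self.variances.copy(),
            tag=self.tag if tag is None else tag,
        )

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "dim": self.dim,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "tag": self.tag,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GMMParams":
        return cls(
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            tag=d.get("tag", ""),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GMMParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class EMConfig:
    """Knobs for native EM training of a UBM."""

    n_components: int = 64
    max_iters: int = 100
    loglik_rel_tol: float = 1e-5
    variance_floor_factor: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.loglik_rel_tol <= 0 or self.variance_floor_factor <= 0:
            raise ValueError("tolerances must be positive")


def _as_matrix(X) -> np.ndarray:
    X = getattr(X, "X", X)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return X


def component_logpdfs(X, gmm: GMMParams) -> np.ndarray:
    """T x K matrix of log N(x_t | mu_k, Sigma_k)."""
    X = _as_matrix(X)
    if X.shape[1] != gmm.dim:
        raise ValueError(f"feature dim {X.shape[1]} != model dim {gmm.dim}")
    inv = 1.0 / gmm.variances  # K x D
    const = -0.5 * (gmm.dim * _LOG_2PI + np.sum(np.log(gmm.variances), axis=1))  # K
    # -(1/2) sum_d (x_d - mu_d)^2 / var_d, expanded to avoid a T x K x D temp
    quad = (
        (X * X) @ inv.T
        - 2.0 * X @ (gmm.means * inv).T
        + np.sum(gmm.means * gmm.means * inv, axis=1)[None, :]
    )
    return const[None, :] - 0.5 * quad


def gmm_logpdf(x, gmm: GMMParams) -> float | np.ndarray:
    """log F(x | lambda) via log-sum-exp; vectorized over rows of x."""
    x = np.asarray(x, dtype=np.float64)
    was_vector = x.ndim == 1
    lp = logsumexp(component_logpdfs(x, gmm) + np.log(gmm.weights)[None, :], axis=1)
    return float(lp[0]) if was_vector else lp


def avg_loglik(X, gmm: GMMParams) -> float:
    """(1/T) sum_t log F(x_t | lambda): duration-normalized log-likelihood."""
    X = _as_matrix(X)
    if X.shape[0] == 0:
        raise ValueError("empty feature sequence")
    return float(np.mean(gmm_logpdf(X, gmm)))


def log_responsibilities(X, gmm: GMMParams) -> np.ndarray:
    """T x K log posterior Pr(k | x_t)."""
    lp = component_logpdfs(X, gmm) + np.log(np.maximum(gmm.weights, 1e-300))[None, :]
    return lp - logsumexp(lp, axis=1, keepdims=True)


def variance_floor(X, factor: float) -> np.ndarray:
    """Per-dimension floor = factor * global variance (itself floored)."""
    X = _as_matrix(X)
    gv = np.var(X, axis=0)
    return np.maximum(factor * gv, 1e-12)


def train_gmm_em(X, config: EMConfig = EMConfig(), tag: str = "") -> GMMParams:
    """Fit a diagonal-covariance GMM by EM from k-means++ initialization.

    The per-iteration average log-likelihood is monotonically
    non-decreasing; variances are clamped to a floor proportional to the
    global per-dimension variance; components losing all soft mass are
    re-seeded at the lowest-likelihood frame.  Bit-reproducible for a
    fixed seed.
    """
    X = _as_matrix(X)
    T, D = X.shape
    K = config.n_components
    if K > T:
        raise ValueError(f"cannot fit {K} components to {T} frames")
    rng = np.random.default_rng(config.seed)
    floor = variance_floor(X, config.variance_floor_factor)
    if K == 1:
        means = np.mean(X, axis=0, keepdims=True)
    else:
        means, _ = kmeans_plusplus(X, n_clusters=K, random_state=int(rng.integers(2**31)))
    gv = np.maximum(np.var(X, axis=0), floor)
    gmm = GMMParams(
        weights=np.full(K, 1.0 / K),
        means=means,
        variances=np.tile(gv, (K, 1)),
        tag=tag,
    )
    history: list[float] = []
    for _ in range(config.max_iters):
        log_r = log_responsibilities(X, gmm)
        ll = float(np.mean(gmm_logpdf(X, gmm)))
        history.append(ll)
        r = np.exp(log_r)  # T x K
        nk = r.sum(axis=0)
        empty = nk <= 1e-10
        if np.any(empty):
            worst = int(np.argmin(gmm_logpdf(X, gmm)))
            for k in np.flatnonzero(empty):
                r[:, k] = 0.0
                r[worst, k] = 1.0
            nk = r.sum(axis=0)
        means = (r.T @ X) / nk[:, None]
        sq = (r.T @ (X * X)) / nk[:, None] - means**2
        variances = np.maximum(sq, floor[None, :])
        weights = nk / nk.sum()
        gmm = GMMParams(weights=weights, means=means, variances=variances, tag=tag)
        if len(history) >= 2:
            prev, cur = history[-2], history[-1]
            if abs(cur - prev) < config.loglik_rel_tol * max(abs(prev), 1.0):
                break
    gmm.loglik_history = history  # type: ignore[attr-defined]
    return gmm


def pool_balanced(
    class_frames: Mapping[str, np.ndarray],
    mode: str = "health_independent",
    seed: int = 0,
    healthy_class: str = "Healthy",
) -> np.ndarray:
    """Subsample frames so every subclass contributes equally to UBM data.

    ``health_independent`` additionally balances the healthy total
    against the pooled-sick total (each sick subclass contributing
    equally within the sick half).  ``pathology_independent`` balances
    the sick subclasses only and requires at least two of them.
    Sampling is seeded and without replacement except when a subclass
    has fewer frames than its quota, in which case it is upsampled with
    replacement to keep the contributions equal.
    """
    if mode not in {"health_independent", "pathology_independent"}:
        raise ValueError(f"unknown pooling mode {mode!r}")
    frames = {name: _as_matrix(Xc) for name, Xc in class_frames.items()}
    for name, Xc in frames.items():
        if Xc.shape[0] == 0:
            raise ValueError(f"class {name!r} has zero frames")
    rng = np.random.default_rng(seed)

    def take(Xc: np.ndarray, n: int) -> np.ndarray:
        idx = rng.choice(Xc.shape[0], size=n, replace=n > Xc.shape[0])
        return Xc[np.sort(idx)]

    if mode == "pathology_independent":
        sick = {n: Xc for n, Xc in frames.items() if n != healthy_class}
        if len(sick) < 2:
            raise ValueError("pathology_independent pooling needs >= 2 pathology classes")
        per = min(Xc.shape[0] for Xc in sick.values())
        return np.vstack([take(Xc, per) for _, Xc in sorted(sick.items())])

    if healthy_class not in frames:
        raise ValueError(f"health_independent pooling needs class {healthy_class!r}")
    sick = {n: Xc for n, Xc in frames.items() if n != healthy_class}
    if not sick:
        raise ValueError("health_independent pooling needs at least one sick class")
    n_healthy = frames[healthy_class].shape[0]
    n_sick_total = sum(Xc.shape[0] for Xc in sick.values())
    side = min(n_healthy, n_sick_total)
    per_sick = side // len(sick)
    side = per_sick * len(sick)
    parts = [take(frames[healthy_class], side)]
    parts += [take(Xc, per_sick) for _, Xc in sorted(sick.items())]
    return np.vstack(parts)
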