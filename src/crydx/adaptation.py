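"""Deriving health-condition models from a UBM.

Four adaptation methods are provided, mirroring the comparison set used
in cry-based diagnostics:

1. **MAP (Bayesian) adaptation, means only** — the reference method:
   mu_i' = alpha_i E_i(x) + (1 - alpha_i) mu_i with
   alpha_i = n_i / (n_i + r) and relevance factor r = 16.
2. **BML adaptation of means and variances** — boosted-mixture-learning
   updates that refine one component at a time while the remaining
   mixture F_{K-1} is held fixed.
3. **Coupled BML** — BML estimates blended with the UBM's using the
   single coefficient alpha_i = n_i / (n_i + r) for both the mean and
   the variance (second-moment matching).
4. **BML adaptation of means only.**

The BML sample weight for component k at frame x_t is

    w(x_t) = f_k(x_t) / [c_k f_k(x_t) + (1 - c_k) F_{K-1}(x_t)]
           = f_k(x_t) / F(x_t),

so c_k * w(x_t) is the ordinary posterior Pr(k | x_t).  Per-component
updates (one boosting iteration):

    c_k'     = (1/T) sum_t c_k w(x_t)
    gamma_t  = w(x_t) / sum_t w(x_t)
    mu_k'    = sum_t gamma_t x_t
    Sigma_k' = sum_t gamma_t (x_t - mu_k')^2        (diagonal)

Frames that the rest of the mixture explains poorly receive large
weights, so each component concentrates on the data it is responsible
for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from crydx.gmm_core import GMMParams, _as_matrix, component_logpdfs, variance_floor

DEFAULT_RELEVANCE_FACTOR = 16.0


@dataclass(frozen=True)
class AdaptationConfig:
    """Settings shared by the four adaptation methods.

    ``method``: 1 = MAP mean-only, 2 = BML mean+variance,
    3 = coupled BML, 4 = BML mean-only.  ``min_effective_frames`` skips
    components with almost no soft data mass, leaving them at their UBM
    values.
    """

    method: int = 2
    relevance_factor: float = DEFAULT_RELEVANCE_FACTOR
    n_sweeps: int = 2
    per_component_iters: int = 3
    min_effective_frames: float = 1.0
    variance_floor_factor: float = 1e-3
    literal_weight_update: bool = False

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3, 4):
            raise ValueError("method must be 1, 2, 3 or 4")
        if self.relevance_factor <= 0:
            raise ValueError("relevance_factor must be positive")
        if self.n_sweeps < 1 or self.per_component_iters < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class ComponentResponsibilities:
    """BML sample weights and statistics for one component."""

    w: np.ndarray  # T, sample weights f_k / F
    gamma: np.ndarray  # T, normalized to sum 1 (zeros if no mass)
    n_k: float  # effective count sum_t c_k w_t

    @property
    def has_mass(self) -> bool:
        return self.n_k > 0


def component_responsibilities(X, gmm: GMMParams, k: int) -> ComponentResponsibilities:
    """Sample weights w_t = f_k(x_t)/F(x_t) and their normalization.

    Computed in the log domain; c_k * w_t equals the posterior
    Pr(k | x_t).
    """
    X = _as_matrix(X)
    if not (0 <= k < gmm.K):
        raise IndexError(f"component index {k} out of range for K={gmm.K}")
    comp = component_logpdfs(X, gmm)
    log_mix = logsumexp(comp + np.log(np.maximum(gmm.weights, 1e-300))[None, :], axis=1)
    log_w = comp[:, k] - log_mix
    w = np.exp(log_w)
    total = float(w.sum())
    gamma = w / total if total > 0 else np.zeros_like(w)
    n_k = float(gmm.weights[k]) * total
    return ComponentResponsibilities(w=w, gamma=gamma, n_k=n_k)


def effective_counts(X, gmm: GMMParams) -> np.ndarray:
    """n_k = sum_t Pr(k | x_t) for all components at once."""
    X = _as_matrix(X)
    comp = component_logpdfs(X, gmm) + np.log(np.maximum(gmm.weights, 1e-300))[None, :]
    post = np.exp(comp - logsumexp(comp, axis=1, keepdims=True))
    return post.sum(axis=0)


def bml_update_component(
    gmm: GMMParams,
    X,
    k: int,
    iters: int = 1,
    update_variance: bool = True,
    update_weights: bool = True,
    var_floor: np.ndarray | float = 1e-12,
    literal_weight_update: bool = False,
) -> GMMParams:
    """Refine component k by ``iters`` boosting iterations, others fixed.

    The fixed part F_{K-1} (the other components, weights renormalized)
    enters the sample-weight denominator through the full mixture F.  If
    the component has no responsibility mass the model is returned
    unchanged with a warning.
    """
    X = _as_matrix(X)
    T = X.shape[0]
    if T == 0:
        raise ValueError("empty feature sequence")
    out = gmm.copy()
    c_k = float(out.weights[k])
    others = np.arange(out.K) != k
    if out.K > 1:
        other_w = out.weights[others]
        log_rest = logsumexp(
            component_logpdfs(X, out)[:, others]
            + np.log(np.maximum(other_w / max(1.0 - c_k, 1e-300), 1e-300))[None, :],
            axis=1,
        )
    else:
        log_rest = np.full(T, -np.inf)
    mu_k = out.means[k].copy()
    var_k = out.variances[k].copy()
    for _ in range(iters):
        comp_k = _single_component_logpdf(X, mu_k, var_k)
        log_mix = np.logaddexp(
            np.log(max(c_k, 1e-300)) + comp_k,
            (np.log(max(1.0 - c_k, 1e-300)) + log_rest) if out.K > 1 else np.full(T, -np.inf),
        )
        w = np.exp(comp_k - log_mix)
        total = float(w.sum())
        if c_k * total <= 0:
            warnings.warn(f"component {k} has no responsibility mass; left unchanged")
            return gmm.copy()
        gamma = w / total
        if literal_weight_update:
            new_c = c_k * c_k * total / T  # literal self-multiplying form
        else:
            new_c = c_k * total / T  # mean posterior responsibility
        new_c = min(max(new_c, 1e-12), 1.0)
        mu_k = gamma @ X
        if update_variance:
            diff = X - mu_k[None, :]
            var_k = np.maximum(gamma @ (diff * diff), var_floor)
        if update_weights:
            c_k = new_c
    if update_weights:
        out.weights[k] = c_k
        if out.K > 1:
            old_rest = out.weights[others].sum()
            if old_rest > 0:
                out.weights[others] *= (1.0 - c_k) / old_rest
        else:
            out.weights[k] = 1.0
        out.weights /= out.weights.sum()
    out.means[k] = mu_k
    if update_variance:
        out.variances[k] = var_k
    out.validate()
    return out


def _single_component_logpdf(X: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    diff = X - mu[None, :]
    return -0.5 * (
        len(mu) * np.log(2.0 * np.pi) + np.sum(np.log(var)) + np.sum(diff * diff / var[None, :], axis=1)
    )


def adapt_bml(gmm_ubm: GMMParams, X, config: AdaptationConfig = AdaptationConfig(method=2)) -> GMMParams:
    """Full BML adaptation: sweep all components, best-populated first.

    Method 2 updates weights, means and variances; method 4 updates
    means only, leaving weights and variances bit-identical to the
    UBM's.  Components with effective count below
    ``min_effective_frames`` are skipped.
    """
    if config.method not in (2, 4):
        raise ValueError("adapt_bml handles methods 2 and 4")
    X = _as_matrix(X)
    if X.shape[0] == 0:
        raise ValueError("empty feature sequence")
    update_variance = config.method == 2
    update_weights = config.method == 2
    floor = variance_floor(X, config.variance_floor_factor)
    out = gmm_ubm.copy()
    T = X.shape[0]
    # cache per-component log-densities; only the updated column changes
    comp_lp = component_logpdfs(X, out)
    for _ in range(config.n_sweeps):
        log_w = np.log(np.maximum(out.weights, 1e-300))
        post = np.exp(comp_lp + log_w[None, :] - logsumexp(comp_lp + log_w[None, :], axis=1, keepdims=True))
        counts = post.sum(axis=0)
        order = np.argsort(-counts, kind="stable")
        for k in order:
            k = int(k)
            c_k = float(out.weights[k])
            others = np.arange(out.K) != k
            if out.K > 1:
                other_w = np.maximum(out.weights[others] / max(1.0 - c_k, 1e-300), 1e-300)
                log_rest = logsumexp(comp_lp[:, others] + np.log(other_w)[None, :], axis=1)
            else:
                log_rest = np.full(T, -np.inf)
            mu_k = out.means[k].copy()
            var_k = out.variances[k].copy()
            skipped = False
            for _it in range(config.per_component_iters):
                lp_k = _single_component_logpdf(X, mu_k, var_k)
                log_mix = np.logaddexp(np.log(max(c_k, 1e-300)) + lp_k,
                                       np.log(max(1.0 - c_k, 1e-300)) + log_rest)
                w = np.exp(lp_k - log_mix)
                total = float(w.sum())
                n_k = c_k * total
                if n_k < config.min_effective_frames:
                    skipped = True
                    break
                gamma = w / total
                if config.literal_weight_update:
                    new_c = c_k * c_k * total / T
                else:
                    new_c = c_k * total / T
                mu_k = gamma @ X
                if update_variance:
                    diff = X - mu_k[None, :]
                    var_k = np.maximum(gamma @ (diff * diff), floor)
                if update_weights:
                    c_k = min(max(new_c, 1e-12), 1.0)
            if skipped:
                continue
            out.means[k] = mu_k
            if update_variance:
                out.variances[k] = var_k
            if update_weights:
                out.weights[k] = c_k
                old_rest = out.weights[others].sum()
                if out.K > 1 and old_rest > 0:
                    out.weights[others] *= (1.0 - c_k) / old_rest
                out.weights /= out.weights.sum()
            comp_lp[:, k] = _single_component_logpdf(X, out.means[k], out.variances[k])
    out.validate()
    out.tag = f"{gmm_ubm.tag}+bml{config.method}" if gmm_ubm.tag else f"bml{config.method}"
    return out


def adapt_map(gmm_ubm: GMMParams, X, r: float = DEFAULT_RELEVANCE_FACTOR) -> GMMParams:
    """Classic mean-only MAP (Bayesian) adaptation with relevance factor r.

    n_i = sum_t Pr(i | x_t);  E_i = (1/n_i) sum_t Pr(i | x_t) x_t;
    alpha_i = n_i / (n_i + r);  mu_i' = alpha_i E_i + (1 - alpha_i) mu_i.
    Weights and variances stay at their UBM values.
    """
    if r <= 0:
        raise ValueError("relevance factor must be positive")
    X = _as_matrix(X)
    if X.shape[0] == 0:
        raise ValueError("empty feature sequence")
    comp = component_logpdfs(X, gmm_ubm) + np.log(np.maximum(gmm_ubm.weights, 1e-300))[None, :]
    post = np.exp(comp - logsumexp(comp, axis=1, keepdims=True))  # T x K
    n = post.sum(axis=0)  # K
    out = gmm_ubm.copy()
    populated = n > 0
    E = np.zeros_like(out.means)
    E[populated] = (post.T @ X)[populated] / n[populated, None]
    alpha = n / (n + r)
    out.means[populated] = (
        alpha[populated, None] * E[populated] + (1.0 - alpha[populated, None]) * out.means[populated]
    )
    out.tag = f"{gmm_ubm.tag}+map" if gmm_ubm.tag else "map"
    return out


def adapt_coupled(gmm_ubm: GMMParams, X, config: AdaptationConfig = AdaptationConfig(method=3)) -> GMMParams:
    """Coupled BML (method 3): blend BML estimates with the UBM's.

    With alpha_i = n_i / (n_i + r) computed from the UBM posteriors:
    mu_i' = alpha_i mu_i^BML + (1 - alpha_i) mu_i, and the variance is
    coupled through second moments,
    Sigma_i' = alpha_i (Sigma_i^BML + mu_i^BML^2)
             + (1 - alpha_i)(Sigma_i + mu_i^2) - mu_i'^2.
    Weights stay at their UBM values.
    """
    if config.method != 3:
        raise ValueError("adapt_coupled is method 3")
    X = _as_matrix(X)
    if X.shape[0] == 0:
        raise ValueError("empty feature sequence")
    bml_cfg = AdaptationConfig(
        method=2,
        relevance_factor=config.relevance_factor,
        n_sweeps=config.n_sweeps,
        per_component_iters=config.per_component_iters,
        min_effective_frames=config.min_effective_frames,
        variance_floor_factor=config.variance_floor_factor,
        literal_weight_update=config.literal_weight_update,
    )
    bml = adapt_bml(gmm_ubm, X, bml_cfg)
    n = effective_counts(X, gmm_ubm)
    alpha = n / (n + config.relevance_factor)
    out = gmm_ubm.copy()
    mu_new = alpha[:, None] * bml.means + (1.0 - alpha[:, None]) * gmm_ubm.means
    second = alpha[:, None] * (bml.variances + bml.means**2) + (1.0 - alpha[:, None]) * (
        gmm_ubm.variances + gmm_ubm.means**2
    )
    floor = variance_floor(X, config.variance_floor_factor)
    out.means = mu_new
    out.variances = np.maximum(second - mu_new**2, floor[None, :])
    out.tag = f"{gmm_ubm.tag}+coupled" if gmm_ubm.tag else "coupled"
    return out


def adapt(gmm_ubm: GMMParams, X, config: AdaptationConfig) -> GMMParams:
    """Dispatch to the configured adaptation method (1-4)."""
    if config.method == 1:
        return adapt_map(gmm_ubm, X, r=config.relevance_factor)
    if config.method in (2, 4):
        return adapt_bml(gmm_ubm, X, config)
    return adapt_coupled(gmm_ubm, X, config)
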