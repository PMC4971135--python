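"""Likelihood-ratio scoring of cry units and files.

A detector scores a feature sequence X with the duration-normalized
log-likelihood ratio

    Lambda(X) = (1/T) sum_t log p(x_t | lambda_hyp)
              - log p(X | lambda_alt)

where the alternative is either a single UBM or a set of B equally
likely background models combined as log((1/B) sum_b p(X | lambda_b)),
each term itself duration-normalized.  File-level scores average the
per-unit scores; HNORM rescales scores so the imposter (non-target)
distribution has zero mean and unit standard deviation per detector and
cry type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from crydx.gmm_core import GMMParams, _as_matrix, avg_loglik


@dataclass
class HypothesisModels:
    """Target model plus its alternative (UBM or background set)."""

    hypothesis: GMMParams
    alternative: GMMParams | Sequence[GMMParams]

    def __post_init__(self) -> None:
        if not isinstance(self.alternative, GMMParams) and len(self.alternative) == 0:
            raise ValueError("background set must contain at least one model")


@dataclass
class LLRScore:
    """One log-likelihood-ratio score (nats)."""

    value: float
    cry_type: str = ""
    unit_id: str = ""
    file_id: str = ""
    normalized: bool = False


@dataclass(frozen=True)
class HNormParams:
    """Imposter-score mean/std for one (detector, cry type) pair."""

    mu_imp: float
    sigma_imp: float
    cry_type: str = ""
    detector: str = ""

    def __post_init__(self) -> None:
        if self.sigma_imp <= 0:
            raise ValueError("sigma_imp must be positive")


def alt_loglik(X, background: GMMParams | Sequence[GMMParams]) -> float:
    """Alternative-hypothesis log-likelihood.

    Single model: the duration-normalized average log-likelihood.
    Background set: log-mean of the (duration-normalized) likelihoods,
    computed stably as logsumexp(scores) - log B.
    """
    if isinstance(background, GMMParams):
        return avg_loglik(X, background)
    scores = np.array([avg_loglik(X, b) for b in background])
    return float(logsumexp(scores) - np.log(len(scores)))


def llr_score(X, models: HypothesisModels, cry_type: str = "", unit_id: str = "", file_id: str = "") -> LLRScore:
    """Lambda(X) = avg loglik under the hypothesis minus the alternative."""
    value = avg_loglik(X, models.hypothesis) - alt_loglik(X, models.alternative)
    return LLRScore(value=float(value), cry_type=cry_type, unit_id=unit_id, file_id=file_id)


def fit_hnorm(imposter_scores: Sequence[float], cry_type: str = "", detector: str = "") -> HNormParams:
    """Estimate normalization parameters from non-target (imposter) scores."""
    scores = np.asarray([s.value if isinstance(s, LLRScore) else s for s in imposter_scores], dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 imposter scores to fit HNORM")
    sigma = float(np.std(scores))  # population std
    if sigma == 0.0:
        raise ValueError("imposter scores have zero spread")
    return HNormParams(mu_imp=float(np.mean(scores)), sigma_imp=sigma, cry_type=cry_type, detector=detector)


def apply_hnorm(score: LLRScore, params: HNormParams) -> LLRScore:
    """Rescale so the imposter distribution maps to mean 0, std 1."""
    return LLRScore(
        value=(score.value - params.mu_imp) / params.sigma_imp,
        cry_type=score.cry_type,
        unit_id=score.unit_id,
        file_id=score.file_id,
        normalized=True,
    )


@dataclass
class FileScore:
    """Per-recording score: mean of unit LLRs plus unit bookkeeping.

    ``n_full_units`` counts complete ~3-s units, which drives the
    dataset filters (any evidence / >= 1 full unit / >= 3 full units).
    """

    value: float
    cry_type: str
    file_id: str
    n_units: int
    n_full_units: int
    normalized: bool = False


def score_file(
    unit_sequences: Sequence,
    models: HypothesisModels,
    cry_type: str,
    file_id: str = "",
    concatenate_units: bool = False,
) -> FileScore | None:
    """Score all units of one cry type in a recording.

    Returns the unweighted mean of per-unit LLR scores (or, with
    ``concatenate_units``, a single LLR over the stacked frames).  When
    the recording has no units of the requested type the score is
    *absent* (None), never silently zero.
    """
    units = [
        u
        for u in unit_sequences
        if getattr(u, "cry_type", "") in ("", cry_type)  # unlabeled sequences accepted
    ]
    units = [u for u in units if _as_matrix(u).shape[0] > 0]
    if not units:
        return None
    n_full = sum(1 for u in units if not getattr(u, "partial", False))
    if concatenate_units:
        stacked = np.vstack([_as_matrix(u) for u in units])
        value = llr_score(stacked, models).value
    else:
        value = float(np.mean([llr_score(u, models).value for u in units]))
    return FileScore(
        value=value, cry_type=cry_type, file_id=file_id, n_units=len(units), n_full_units=n_full
    )


def ml_classify(X, class_models: Sequence[GMMParams]) -> int:
    """Closed-set maximum-likelihood classification (equal priors).

    Returns the index of the model with the largest duration-normalized
    log-likelihood; ties break toward the lowest index.
    """
    if len(class_models) == 0:
        raise ValueError("empty model set")
    scores = np.array([avg_loglik(X, m) for m in class_models])
    return int(np.argmax(scores))
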