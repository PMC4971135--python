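"""End-to-end detector experiments and the hierarchical decision.

``run_detector_experiment`` glues the stages together on a feature-mode
corpus: balanced UBM training on the ubm split, class-model adaptation
on the adapt split, per-unit/per-file LLR scoring of the test split
(HNORM fitted on adapt-split imposters), dataset filtering by available
cry-unit evidence, DET/EER/AUC evaluation per cry type, and score-level
fusion of the two experts.

``hierarchical_decide`` implements the two-stage clinical decision:
first healthy-vs-sick (verification); only for sick infants a closed-set
maximum-likelihood identification over the enrolled pathologies runs,
with rejection to "others" when even the winning model scores below a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from crydx.adaptation import AdaptationConfig, adapt
from crydx.evaluation import ScoreSet, eer, optimal_operating_point, roc_auc
from crydx.fusion import (
    ClassifierSpec,
    CVPlan,
    build_score_vectors,
    evaluate_fusion,
    fused_decision_scores,
)
from crydx.gmm_core import EMConfig, GMMParams, pool_balanced, train_gmm_em
from crydx.scoring import (
    FileScore,
    HNormParams,
    HypothesisModels,
    fit_hnorm,
    ml_classify,
    score_file,
    llr_score,
)
from crydx.synthetic_fixtures import CRY_TYPES, FeatureCorpus

#: Dataset filters by available full 3-s cry units per test file.
DATASET_FILTERS = {"A": 0, "B": 1, "C": 3}


@dataclass
class ExperimentConfig:
    """Configuration of one detector experiment."""

    target_class: str = "Healthy"
    adaptation: AdaptationConfig = field(default_factory=lambda: AdaptationConfig(method=2))
    em: EMConfig = field(default_factory=lambda: EMConfig(n_components=8, seed=0))
    alternative: str = "ubm"  # "ubm" | "background_set"
    dataset_filter: str = "A"
    fusion_plan: CVPlan = field(default_factory=lambda: CVPlan(n_folds=10, rounds=5, seed=0))
    fusion_classifiers: tuple[str, ...] = ("mlp", "svm-linear", "svm-mlp")
    hnorm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dataset_filter not in DATASET_FILTERS:
            raise ValueError("dataset_filter must be A, B or C")
        if self.alternative not in {"ubm", "background_set"}:
            raise ValueError("alternative must be 'ubm' or 'background_set'")


@dataclass
class HierarchicalDecision:
    """Outcome of the two-stage decision for one recording."""

    stage1: str  # "healthy" | "sick"
    stage1_score: float
    stage2: str | None = None  # pathology label, "others", or None if healthy


def train_ubms(corpus: FeatureCorpus, em: EMConfig, seed: int = 0) -> dict[str, GMMParams]:
    """Health-independent UBM per cry type from balanced pooled frames."""
    ubms: dict[str, GMMParams] = {}
    for i, ct in enumerate(CRY_TYPES):
        frames = corpus.frames_by_class("ubm", ct)
        pooled = pool_balanced(frames, mode="health_independent", seed=seed + i)
        cfg = EMConfig(
            n_components=em.n_components,
            max_iters=em.max_iters,
            loglik_rel_tol=em.loglik_rel_tol,
            variance_floor_factor=em.variance_floor_factor,
            seed=seed + i,
        )
        ubms[ct] = train_gmm_em(pooled, cfg, tag=f"HI-UBM-{ct}")
    return ubms


def adapt_class_models(
    corpus: FeatureCorpus, ubms: dict[str, GMMParams], config: AdaptationConfig
) -> dict[str, dict[str, GMMParams]]:
    """Adapt one model per (cry type, health class) on the adapt split."""
    models: dict[str, dict[str, GMMParams]] = {}
    for ct in CRY_TYPES:
        frames = corpus.frames_by_class("adapt", ct)
        models[ct] = {}
        for cls, X in frames.items():
            m = adapt(ubms[ct], X, config)
            m.tag = f"{cls}-{ct}-m{config.method}"
            models[ct][cls] = m
    return models


def _score_split(
    corpus: FeatureCorpus,
    split: str,
    cry_type: str,
    models: HypothesisModels,
) -> list[tuple[str, str, FileScore]]:
    """(health_class, infant_id, FileScore) per recording with units."""
    out = []
    for rec in corpus.subset(split):
        fs = score_file(rec.units.get(cry_type, []), models, cry_type, file_id=rec.file_id)
        if fs is not None:
            out.append((rec.health_class, rec.infant_id, fs))
    return out


def run_detector_experiment(config: ExperimentConfig, corpus: FeatureCorpus) -> dict:
    """Run the full detector chain; returns a JSON-able report.

    The report carries per-cry-type EER/AUC/operating point, test-set
    sizes after the dataset filter, fusion CV summaries, and the fused
    out-of-fold EER.
    """
    corpus.manifest().validate()  # re-verify infant-disjoint splits
    target = config.target_class
    ubms = train_ubms(corpus, config.em, seed=config.seed)
    class_models = adapt_class_models(corpus, ubms, config.adaptation)

    min_units = DATASET_FILTERS[config.dataset_filter]
    report: dict = {
        "config": {
            "target_class": target,
            "method": config.adaptation.method,
            "alternative": config.alternative,
            "dataset_filter": config.dataset_filter,
            "n_components": config.em.n_components,
        },
        "per_cry_type": {},
    }
    tables: dict[str, pd.DataFrame] = {}
    for ct in CRY_TYPES:
        if target not in class_models[ct]:
            continue
        if config.alternative == "ubm":
            alternative: GMMParams | list[GMMParams] = ubms[ct]
        else:
            alternative = [m for cls, m in sorted(class_models[ct].items()) if cls != target]
        models = HypothesisModels(hypothesis=class_models[ct][target], alternative=alternative)

        hnorm: HNormParams | None = None
        if config.hnorm:
            imposters = [
                fs.value
                for cls, _, fs in _score_split(corpus, "adapt", ct, models)
                if cls != target
            ]
            if len(imposters) >= 2 and float(np.std(imposters)) > 0:
                hnorm = fit_hnorm(imposters, cry_type=ct, detector=target)

        rows = []
        for cls, infant, fs in _score_split(corpus, "test", ct, models):
            value = (fs.value - hnorm.mu_imp) / hnorm.sigma_imp if hnorm else fs.value
            rows.append(
                {
                    "file_id": fs.file_id,
                    "infant_id": infant,
                    "label": int(cls == target),
                    "score": value,
                    "n_units": fs.n_units,
                    "n_full_units": fs.n_full_units,
                }
            )
        table = pd.DataFrame(rows)
        if min_units > 0 and len(table):
            table = table[table["n_full_units"] >= min_units].reset_index(drop=True)
        tables[ct] = table
        if len(table) == 0 or table["label"].nunique() < 2:
            report["per_cry_type"][ct] = {"error": "insufficient test files after filter"}
            continue
        scores = ScoreSet(
            target_scores=table.loc[table["label"] == 1, "score"].to_numpy(),
            nontarget_scores=table.loc[table["label"] == 0, "score"].to_numpy(),
        )
        op = optimal_operating_point(scores)
        report["per_cry_type"][ct] = {
            "eer": eer(scores),
            "auc": roc_auc(scores),
            "op_threshold": op.threshold,
            "op_far": op.far,
            "op_frr": op.frr,
            "n_target": int(scores.target_scores.size),
            "n_nontarget": int(scores.nontarget_scores.size),
        }

    # Score-level fusion over files carrying both cry types
    if all(ct in tables and len(tables[ct]) for ct in CRY_TYPES):
        vectors = build_score_vectors(tables["EXP"], tables["INSV"])
        if len(vectors) and vectors["label"].nunique() == 2 and vectors["label"].value_counts().min() >= 2:
            counts = vectors["label"].value_counts()
            folds = min(config.fusion_plan.n_folds, int(counts.min()))
            plan = CVPlan(n_folds=max(2, folds), rounds=config.fusion_plan.rounds, seed=config.fusion_plan.seed)
            specs = [ClassifierSpec(kind=k) for k in config.fusion_classifiers]
            summaries = evaluate_fusion(vectors, specs, plan)
            report["fusion"] = {
                kind: {
                    "error": s.p_cv,
                    "ci": list(s.ci),
                    "accuracy": s.accuracy,
                    "sensitivity": s.sensitivity,
                    "specificity": s.specificity,
                    "fpr": s.fpr,
                    "fnr": s.fnr,
                }
                for kind, s in summaries.items()
            }
            fused_eers = {}
            for spec in specs:
                sc, y = fused_decision_scores(vectors, spec, plan)
                fused_eers[spec.kind] = eer(ScoreSet(sc[y == 1], sc[y == 0]))
            report["fusion_eer"] = fused_eers
            report["n_fused_files"] = int(len(vectors))
    report["score_tables"] = {ct: tables[ct] for ct in tables}
    return report


def hierarchical_decide(
    units_by_type: dict[str, Sequence],
    stage1_models: dict[str, HypothesisModels],
    pathology_models: dict[str, list[tuple[str, GMMParams]]],
    stage1_threshold: float = 0.0,
    rejection_threshold: float = -np.inf,
    hnorm: dict[str, HNormParams] | None = None,
) -> HierarchicalDecision:
    """Two-stage decision for one recording.

    Stage 1 verifies the healthy hypothesis from the fused (or single
    available) expert score; healthy stops the process.  Stage 2 runs
    closed-set maximum-likelihood identification over the enrolled
    pathology models on the EXP units, rejecting to "others" when the
    winner's average LLR against its alternative falls below
    ``rejection_threshold``.
    """
    scores = []
    for ct, models in stage1_models.items():
        fs = score_file(units_by_type.get(ct, []), models, ct)
        if fs is None:
            continue
        value = fs.value
        if hnorm and ct in hnorm:
            value = (value - hnorm[ct].mu_imp) / hnorm[ct].sigma_imp
        scores.append(value)
    if not scores:
        raise ValueError("recording has no scoreable units of any cry type")
    stage1_score = float(np.mean(scores))
    if stage1_score >= stage1_threshold:
        return HierarchicalDecision(stage1="healthy", stage1_score=stage1_score)

    ct = "EXP" if pathology_models.get("EXP") else "INSV"
    entries = pathology_models[ct]
    units = [u for u in units_by_type.get(ct, [])]
    if not units:
        return HierarchicalDecision(stage1="sick", stage1_score=stage1_score, stage2="others")
    X = np.vstack([np.atleast_2d(getattr(u, "X", u)) for u in units])
    idx = ml_classify(X, [m for _, m in entries])
    label, winner = entries[idx]
    alt = [m for j, (_, m) in enumerate(entries) if j != idx]
    if alt:
        models = HypothesisModels(hypothesis=winner, alternative=alt)
        margin = llr_score(X, models).value
    else:
        margin = np.inf
    stage2 = label if margin >= rejection_threshold else "others"
    return HierarchicalDecision(stage1="sick", stage1_score=stage1_score, stage2=stage2)
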