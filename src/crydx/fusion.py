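"""Score-level fusion of the EXP and INSV experts.

Each test recording that carries both cry types contributes a 2-D point
(EXP HNORM-LLR, INSV HNORM-LLR); fusion is a binary classification
problem in that plane.  The classifier bank mirrors the comparison set
used for cry diagnostics: a one-hidden-layer MLP (10 tanh units,
softmax/cross-entropy output, <= 1000 iterations), a probabilistic
neural network (Parzen classifier, Gaussian spread 0.1 in standardized
units), and SVMs with linear, quadratic, cubic-polynomial, Gaussian-RBF
and sigmoid ("MLP") kernels.  Evaluation uses repeated stratified K-fold
cross-validation with random oversampling of the minority class inside
each training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from crydx.evaluation import CVErrorSummary, confusion_stats, wald_ci

#: Default repetition counts per fold count (rounds x K-fold).
DEFAULT_ROUNDS = {3: 400, 5: 200, 10: 100}

CLASSIFIER_KINDS = ("mlp", "pnn", "svm-linear", "svm-quad", "svm-poly3", "svm-rbf", "svm-mlp")


@dataclass(frozen=True)
class ClassifierSpec:
    """One entry of the fusion classifier bank."""

    kind: str
    hidden_units: int = 10
    max_iter: int = 1000
    pnn_spread: float = 0.1
    svm_gamma: float = 1.0
    svm_coef0: float = -1.0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {CLASSIFIER_KINDS}")
        if self.pnn_spread <= 0:
            raise ValueError("pnn_spread must be positive")


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified K-fold plan (K in {3, 5, 10} by convention)."""

    n_folds: int = 10
    rounds: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @property
    def n_rounds(self) -> int:
        if self.rounds is not None:
            return self.rounds
        return DEFAULT_ROUNDS.get(self.n_folds, 100)


def build_score_vectors(exp_table: pd.DataFrame, insv_table: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the per-file EXP and INSV score tables on file_id.

    Files missing either score are dropped; the drop count is attached
    as ``result.attrs['n_dropped']``.  Each table needs columns
    ``file_id`` and ``score`` (plus optional ``label``/``infant_id``).
    """
    for name, tbl in (("exp", exp_table), ("insv", insv_table)):
        if tbl["file_id"].duplicated().any():
            raise ValueError(f"duplicate file_id in {name} score table")
    keep = [c for c in ("file_id", "infant_id", "label") if c in exp_table.columns]
    merged = exp_table[keep + ["score"]].rename(columns={"score": "exp_score"}).merge(
        insv_table[["file_id", "score"]].rename(columns={"score": "insv_score"}),
        on="file_id",
        how="inner",
    )
    total = len(set(exp_table["file_id"]) | set(insv_table["file_id"]))
    merged.attrs["n_dropped"] = total - len(merged)
    return merged


def random_oversample(X: np.ndarray, y: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate random minority-class rows until the classes balance.

    Only existing rows are duplicated (no synthetic points); the
    majority class is untouched; deterministic for a fixed seed.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling needs two classes")
    if counts[0] == counts[1]:
        return np.asarray(X), y
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    idx_min = np.flatnonzero(y == minority)
    extra = rng.choice(idx_min, size=int(counts.max() - counts.min()), replace=True)
    keep = np.concatenate([np.arange(len(y)), extra])
    return np.asarray(X)[keep], y[keep]


def stratified_repeated_kfold(y: np.ndarray, plan: CVPlan) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Yield (round, train_idx, test_idx) over ``plan.n_rounds`` rounds.

    Each round reshuffles with a seed derived from the plan seed; folds
    keep class proportions within one sample of the global mix and
    partition the indices.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < plan.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot form {plan.n_folds} folds"
        )
    for rnd in range(plan.n_rounds):
        skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=(plan.seed + rnd) % (2**31))
        for train_idx, test_idx in skf.split(np.zeros_like(y), y):
            yield rnd, train_idx, test_idx


class PNNClassifier:
    """Probabilistic neural network (Parzen-window classifier).

    The pattern layer holds every training point as a Gaussian kernel of
    width ``spread``; the summation layer averages kernels per class and
    the competitive output picks the larger class density.
    """

    def __init__(self, spread: float = 0.1):
        self.spread = spread

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PNNClassifier":
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y)
        self.classes_ = np.unique(self.y_)
        return self

    def _class_densities(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        k = np.exp(-d2 / (2.0 * self.spread**2))
        return np.column_stack([k[:, self.y_ == c].mean(axis=1) for c in self.classes_])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._class_densities(X), axis=1)]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        dens = np.maximum(self._class_densities(X), 1e-300)
        return np.log(dens[:, -1]) - np.log(dens[:, 0])


class _Standardized:
    """Wrap a classifier with train-fold standardization of the inputs."""

    def __init__(self, inner):
        self.inner = inner

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Standardized":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.std_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.inner.fit((X - self.mean_) / self.std_, y)
        return self

    def _tx(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.inner.predict(self._tx(X))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        inner = self.inner
        if hasattr(inner, "decision_function"):
            return inner.decision_function(self._tx(X))
        proba = inner.predict_proba(self._tx(X))
        p = np.clip(proba[:, -1], 1e-12, 1 - 1e-12)
        return np.log(p) - np.log1p(-p)


def train_fusion_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one bank classifier on (standardized) 2-D score vectors."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class")
    if spec.kind == "mlp":
        inner = MLPClassifier(
            hidden_layer_sizes=(spec.hidden_units,),
            activation="tanh",
            solver="lbfgs",
            max_iter=spec.max_iter,
            random_state=seed % (2**31),
        )
    elif spec.kind == "pnn":
        inner = PNNClassifier(spread=spec.pnn_spread)
    else:
        kernel = {
            "svm-linear": dict(kernel="linear"),
            "svm-quad": dict(kernel="poly", degree=2, coef0=1.0),
            "svm-poly3": dict(kernel="poly", degree=3, coef0=1.0),
            "svm-rbf": dict(kernel="rbf"),
            "svm-mlp": dict(kernel="sigmoid", gamma=spec.svm_gamma, coef0=spec.svm_coef0),
        }[spec.kind]
        inner = SVC(random_state=seed % (2**31), **kernel)
    model = _Standardized(inner)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def evaluate_fusion(
    vectors: pd.DataFrame,
    specs: Sequence[ClassifierSpec],
    plan: CVPlan,
    alpha: float = 0.2,
    oversample: bool = True,
) -> dict[str, CVErrorSummary]:
    """Repeated stratified K-fold evaluation of the classifier bank.

    Oversampling (when enabled) happens inside each training fold only.
    Returns mean test-fold rates with a Wald confidence interval on the
    cross-validated error, keyed by classifier kind.
    """
    X = vectors[["exp_score", "insv_score"]].to_numpy(dtype=float)
    y = vectors["label"].to_numpy(dtype=int)
    summaries: dict[str, CVErrorSummary] = {}
    for spec in specs:
        stats: list[dict[str, float]] = []
        for rnd, train_idx, test_idx in stratified_repeated_kfold(y, plan):
            X_tr, y_tr = X[train_idx], y[train_idx]
            if oversample:
                X_tr, y_tr = random_oversample(X_tr, y_tr, seed=plan.seed * 100003 + rnd)
            model = train_fusion_classifier(spec, X_tr, y_tr, seed=plan.seed + rnd)
            pred = model.predict(X[test_idx])
            stats.append(confusion_stats(pred, y[test_idx]))
        frame = pd.DataFrame(stats)
        means = frame.mean(skipna=True)
        p_cv = 1.0 - float(means["accuracy"])
        summaries[spec.kind] = CVErrorSummary(
            p_cv=p_cv,
            n=len(y),
            alpha=alpha,
            ci=wald_ci(p_cv, len(y), alpha),
            accuracy=float(means["accuracy"]),
            sensitivity=float(means["sensitivity"]),
            specificity=float(means["specificity"]),
            fpr=float(means["fpr"]),
            fnr=float(means["fnr"]),
        )
    return summaries


def default_classifier_bank() -> list[ClassifierSpec]:
    return [ClassifierSpec(kind=k) for k in CLASSIFIER_KINDS]


def fused_decision_scores(
    vectors: pd.DataFrame, spec: ClassifierSpec, plan: CVPlan, oversample: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold fused decision scores over one CV round per sample.

    Each sample's score comes from the model trained on the other folds
    of round 0, giving an unbiased pooled score set for EER evaluation
    of the fused system.
    """
    X = vectors[["exp_score", "insv_score"]].to_numpy(dtype=float)
    y = vectors["label"].to_numpy(dtype=int)
    scores = np.zeros(len(y))
    one_round = CVPlan(n_folds=plan.n_folds, rounds=1, seed=plan.seed)
    for _, train_idx, test_idx in stratified_repeated_kfold(y, one_round):
        X_tr, y_tr = X[train_idx], y[train_idx]
        if oversample:
            X_tr, y_tr = random_oversample(X_tr, y_tr, seed=plan.seed)
        model = train_fusion_classifier(spec, X_tr, y_tr, seed=plan.seed)
        scores[test_idx] = model.decision_function(X[test_idx])
    return scores, y
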