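"""Baseline missing-data strategies and the repeated cross-validation harness.

Three strategies are compared on the same fold plans:

* ``deletion`` — listwise deletion: train only on fully observed cases;
* ``imputation`` — per-feature mean imputation, with means learned on the
  training folds only and applied to both train and test;
* ``local-validity`` — the pattern/cluster/ensemble pipeline, trained on the
  incomplete training folds directly.

Evaluation is repeated stratified k-fold cross-validation (default ten times
10-fold): within each repeat every case is used exactly once for testing and
accuracy is the fraction of all test predictions that are correct; repeats are
averaged.  Scoring detail: a model trained after deletion (or on complete
data) can still face incomplete test cases — here such queries are mean-filled
with training means by default (``deletion_scoring="all"``), or excluded from
the denominator with ``deletion_scoring="complete_only"``.  All preprocessing
(deletion, imputation statistics, pattern extraction, clustering, classifier
training) happens strictly inside the training folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import DomainError, IncompleteDataset
from .ensemble import (
    BaseSpec,
    LocalValidityClassifier,
    _decide,
    make_base_classifier,
)

__all__ = [
    "EvaluationReport",
    "STRATEGIES",
    "cross_validate",
    "listwise_delete",
    "mean_impute",
]

STRATEGIES = ("deletion", "imputation", "local-validity")


@dataclass
class EvaluationReport:
    """Per-repeat accuracies of one strategy under one fold plan."""

    strategy: str
    per_repeat_accuracy: list[float]
    mean_accuracy: float
    fold_plan: dict
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "per_repeat_accuracy": self.per_repeat_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "fold_plan": self.fold_plan,
            "error": self.error,
        }


def listwise_delete(ds: IncompleteDataset) -> IncompleteDataset:
    """Keep only fully observed cases."""
    keep = np.flatnonzero(ds.observed_mask().all(axis=1))
    if keep.size == 0:
        raise DomainError("listwise deletion removed every case")
    return ds.take_cases(keep)


def _feature_means(ds: IncompleteDataset) -> np.ndarray:
    """Per-feature mean of observed values; errors on never-observed features."""
    obs = ds.observed_mask()
    never = np.flatnonzero(~obs.any(axis=0))
    if never.size:
        names = [ds.feature_names[j] for j in never]
        raise DomainError(f"feature(s) observed nowhere: {names}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(ds.values, axis=0)


def _fill(values: np.ndarray, means: np.ndarray) -> np.ndarray:
    out = values.copy()
    holes = np.isnan(out)
    out[holes] = np.broadcast_to(means, out.shape)[holes]
    return out


def mean_impute(
    ds: IncompleteDataset, means: np.ndarray | None = None
) -> IncompleteDataset:
    """Replace each missing cell by the per-feature mean of observed values.

    ``means`` may be supplied (e.g. learned on training folds) to avoid
    leaking test information; by default they are computed from ``ds`` itself.
    """
    if means is None:
        means = _feature_means(ds)
    return IncompleteDataset(
        case_ids=ds.case_ids,
        feature_names=ds.feature_names,
        values=_fill(ds.values, means),
        labels=None if ds.labels is None else ds.labels.copy(),
    )


def _predict_with_base(model, classes, class_counts, X: np.ndarray) -> np.ndarray:
    """Argmax of predict_proba with the shared deterministic tie-break."""
    proba = model.predict_proba(X)
    out = []
    for row in proba:
        full = np.zeros(len(classes))
        for p, c in zip(row, model.classes_):
            full[list(classes).index(c)] = p
        out.append(_decide(full, classes, class_counts))
    return np.asarray(out)


def _run_fold(
    strategy: str,
    train: IncompleteDataset,
    test: IncompleteDataset,
    base_spec: BaseSpec,
    seed: int,
    deletion_scoring: str,
    lv_params: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictions and the mask of scored test cases for one fold."""
    scored = np.ones(test.n_cases, dtype=bool)
    if strategy == "local-validity":
        clf = LocalValidityClassifier(base_spec=base_spec, seed=seed, **lv_params)
        clf.fit(train)
        return clf.predict(test), scored

    if strategy == "deletion":
        fit_ds = listwise_delete(train)
        means = _feature_means(fit_ds)
    elif strategy == "imputation":
        means = _feature_means(train)
        fit_ds = mean_impute(train, means)
    else:
        raise DomainError(f"unknown strategy {strategy!r}")

    classes, class_counts = np.unique(fit_ds.labels, return_counts=True)
    model = make_base_classifier(base_spec, seed)
    model.fit(fit_ds.values, fit_ds.labels)
    X_test = test.values
    if strategy == "deletion" and deletion_scoring == "complete_only":
        scored = test.observed_mask().all(axis=1)
    X_test = _fill(X_test, means)
    preds = np.empty(test.n_cases, dtype=object)
    if scored.any():
        preds[scored] = _predict_with_base(
            model, classes, class_counts, X_test[scored]
        )
    return preds, scored


def _fold_indices(
    labels: np.ndarray, folds: int, rng_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified splits, with a warned non-stratified fallback for tiny classes."""
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        warnings.warn(
            "a class has fewer cases than folds; falling back to "
            "non-stratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        return list(splitter.split(labels))
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    return list(splitter.split(np.zeros(len(labels)), labels))


def cross_validate(
    ds: IncompleteDataset,
    strategy: str,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    base_spec: BaseSpec = "tree",
    deletion_scoring: str = "all",
    lv_params: dict | None = None,
) -> EvaluationReport:
    """Repeated stratified k-fold cross-validation of one strategy.

    The fold plan depends only on ``(labels, folds, repeats, seed)``, so
    different strategies evaluated with the same arguments share identical
    splits.  Accuracy per repeat is (correct test predictions) / (scored test
    cases); with the default scoring every case is scored exactly once per
    repeat so the denominator is |U|.
    """
    if ds.labels is None:
        raise DomainError("cross_validate requires labels")
    if folds < 2:
        raise DomainError("folds must be >= 2")
    if strategy not in STRATEGIES:
        raise DomainError(
            f"unknown strategy {strategy!r}; choose from {STRATEGIES}"
        )
    lv_params = dict(lv_params or {})
    fold_plan = {
        "folds": folds,
        "repeats": repeats,
        "seed": seed,
        "stratified": True,
        "deletion_scoring": deletion_scoring,
    }
    per_repeat: list[float] = []
    try:
        for r in range(repeats):
            rep_seed = (seed * 1000 + r) % 2**31
            correct = 0
            total = 0
            for f, (tr, te) in enumerate(
                _fold_indices(ds.labels, folds, rep_seed)
            ):
                train = ds.take_cases(tr)
                test = ds.take_cases(te)
                fold_seed = (rep_seed * 100 + f) % 2**31
                preds, scored = _run_fold(
                    strategy,
                    train,
                    test,
                    base_spec,
                    fold_seed,
                    deletion_scoring,
                    lv_params,
                )
                truth = test.labels
                correct += int(
                    (preds[scored] == truth[scored]).sum()
                )
                total += int(scored.sum())
            per_repeat.append(correct / total if total else float("nan"))
    except DomainError as exc:
        return EvaluationReport(
            strategy=strategy,
            per_repeat_accuracy=[],
            mean_accuracy=float("nan"),
            fold_plan=fold_plan,
            error=str(exc),
        )
    return EvaluationReport(
        strategy=strategy,
        per_repeat_accuracy=per_repeat,
        mean_accuracy=float(np.mean(per_repeat)),
        fold_plan=fold_plan,
    )
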