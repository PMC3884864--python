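"""Per-cluster classifiers and completeness-weighted combination.

One base classifier is trained on each cluster's complete sub-table (members
of the merged subset restricted to the merged pattern).  A query case, which
may itself have missing features, is scored by every cluster; cluster i's
class-score vector G_i is weighted by its *complete degree*

    lambda_i = |pattern_i  intersect  observed(query)| / |pattern_i|,

the fraction of the cluster's feature pattern actually observed in the query,
and the decision is

    Y = argmax_w  sum_i lambda_i * G_i[w]

over the training label set.  Clusters whose pattern is fully observed score
the raw query; partially covered clusters either mean-fill the few missing
pattern features from their own training data (policy ``"partial"``, default)
or abstain (policy ``"strict"``); clusters with lambda = 0 never vote.  If no
cluster can vote at all, the prediction falls back to the most frequent
training class and is flagged.

On a complete dataset there is exactly one pattern, one cluster and lambda = 1,
so the whole construction collapses to the base classifier fitted on the full
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .clustering import ClusterSet, cluster_lvs
from .dataset import DomainError, IncompleteDataset
from .patterns import build_all_lvs

__all__ = [
    "ClassificationMatrix",
    "ClusterClassifier",
    "LocalValidityClassifier",
    "LocalValidityEnsemble",
    "completeness_weight",
    "make_base_classifier",
    "predict",
    "predict_batch",
    "train_ensemble",
]

BaseSpec = str | BaseEstimator | Callable[[int], BaseEstimator]


def make_base_classifier(spec: BaseSpec, seed: int) -> BaseEstimator:
    """Instantiate a base classifier from a spec.

    Accepts a name (``"tree"``, ``"knn1"``, ``"knn3"``, ``"logreg"``), an
    estimator instance (cloned), or a callable ``seed -> estimator``.
    """
    if callable(spec) and not isinstance(spec, BaseEstimator):
        return spec(seed)
    if isinstance(spec, BaseEstimator):
        return clone(spec)
    if spec == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if spec == "knn1":
        return KNeighborsClassifier(n_neighbors=1)
    if spec == "knn3":
        return KNeighborsClassifier(n_neighbors=3)
    if spec == "logreg":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise DomainError(f"unknown base classifier spec {spec!r}")


@dataclass
class ClusterClassifier:
    """A trained scorer for one cluster's feature pattern.

    ``model`` is ``None`` for degenerate single-class clusters, which emit
    probability 1 for ``constant_class``.  ``train_means`` are the per-feature
    means of the cluster's training sub-table, used to fill missing pattern
    features of partially covered queries.
    """

    cluster_id: int
    features: tuple[str, ...]
    feature_idx: tuple[int, ...]
    model: BaseEstimator | None
    classes: np.ndarray  # global training label set, sorted
    train_size: int
    train_means: np.ndarray
    constant_class: object | None = None
    completeness: float = 1.0  # N_i |P_i| / (|U| |F|), the cluster's data coverage
    quality: float = 1.0  # out-of-fold training accuracy (1.0 unless estimated)

    def scores(self, vec: np.ndarray) -> np.ndarray:
        """Class-probability vector over the global label set for one complete
        vector on this cluster's pattern."""
        out = np.zeros(len(self.classes))
        if self.model is None:
            # classes come from np.unique and are sorted
            out[np.searchsorted(self.classes, self.constant_class)] = 1.0
            return out
        proba = self.model.predict_proba(vec.reshape(1, -1))[0]
        out[np.searchsorted(self.classes, self.model.classes_)] = proba
        return out


@dataclass(frozen=True)
class ClassificationMatrix:
    """Per-cluster scores, weights, combined scores and the decision for one query."""

    per_cluster_scores: np.ndarray  # (n_clusters, n_classes)
    weights: np.ndarray  # lambda_i, in [0, 1]
    combined: np.ndarray  # (n_classes,)
    classes: np.ndarray
    decision: object
    fallback: bool = False


@dataclass
class LocalValidityEnsemble:
    """All trained cluster classifiers plus global label statistics."""

    classifiers: list[ClusterClassifier]
    classes: np.ndarray
    class_counts: np.ndarray  # training frequency of each class
    feature_names: tuple[str, ...]

    @property
    def prior_class(self):
        return self.classes[int(np.argmax(self.class_counts))]


def _out_of_fold_accuracy(
    base_spec: BaseSpec, X: np.ndarray, y: np.ndarray, seed: int
) -> float:
    """Cheap out-of-fold accuracy estimate for one cluster (<= 3 folds)."""
    from sklearn.model_selection import StratifiedKFold

    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(3, counts.min()))
    if n_splits < 2:
        return 1.0
    correct = 0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        m = make_base_classifier(base_spec, seed)
        m.fit(X[tr], y[tr])
        correct += int((m.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def train_ensemble(
    ds: IncompleteDataset,
    clusters: ClusterSet,
    base_spec: BaseSpec = "tree",
    seed: int = 0,
    quality_weight: bool = False,
) -> LocalValidityEnsemble:
    """Fit one base classifier per cluster on its complete sub-table.

    Single-class clusters become constant scorers for their class.  Training
    is reproducible: cluster c's classifier is seeded from ``seed + c``.
    With ``quality_weight=True`` each cluster also receives an out-of-fold
    accuracy estimate that later multiplies its vote weight.
    """
    if ds.labels is None:
        raise DomainError("train_ensemble requires a labelled dataset")
    classes, class_counts = np.unique(ds.labels, return_counts=True)
    total_cells = ds.n_cases * ds.n_features
    classifiers: list[ClusterClassifier] = []
    for c, sub in enumerate(clusters.merged_subsets):
        y = ds.labels[list(sub.member_idx)]
        X = sub.data
        uniq = np.unique(y)
        cseed = (seed + c) % 2**31
        quality = 1.0
        if len(uniq) == 1:
            model = None
            const = uniq[0]
        else:
            model = make_base_classifier(base_spec, cseed)
            model.fit(X, y)
            const = None
            if quality_weight:
                quality = _out_of_fold_accuracy(base_spec, X, y, cseed)
        classifiers.append(
            ClusterClassifier(
                cluster_id=c,
                features=sub.pattern.features,
                feature_idx=sub.pattern.feature_idx,
                model=model,
                classes=classes,
                train_size=sub.size,
                train_means=X.mean(axis=0),
                constant_class=const,
                completeness=sub.size * len(sub.pattern.feature_idx) / total_cells,
                quality=quality,
            )
        )
    if not classifiers:
        raise DomainError("no cluster available for training")
    return LocalValidityEnsemble(
        classifiers=classifiers,
        classes=classes,
        class_counts=class_counts,
        feature_names=ds.feature_names,
    )


def completeness_weight(query: np.ndarray, c: ClusterClassifier) -> float:
    """Fraction of the cluster's pattern observed in the query (lambda_i)."""
    obs = ~np.isnan(np.asarray(query, dtype=float))
    idx = np.asarray(c.feature_idx, dtype=int)
    return float(obs[idx].mean())


def _decide(
    combined: np.ndarray, classes: np.ndarray, class_counts: np.ndarray
):
    """Argmax with deterministic tie-breaks: score, then training frequency,
    then label order."""
    best = combined.max()
    tied = np.flatnonzero(combined >= best - 1e-12)
    if len(tied) > 1:
        freq = class_counts[tied]
        tied = tied[freq == freq.max()]
    return classes[tied[0]]


def _vote_weight(lam_cov: float, c: ClusterClassifier, lambda_mode: str) -> float:
    lam = lam_cov if lambda_mode == "coverage" else c.completeness
    return lam * c.quality


def predict(
    ensemble: LocalValidityEnsemble,
    query: np.ndarray,
    policy: str = "partial",
    lambda_mode: str = "coverage",
) -> ClassificationMatrix:
    """Score one query (full-length feature vector, NaN = missing).

    ``policy="partial"`` lets partially covered clusters vote after mean
    filling their missing pattern features; ``policy="strict"`` restricts
    voting to fully covered clusters.  ``lambda_mode="coverage"`` (default)
    weights cluster i by the fraction of its pattern observed in the query;
    ``"completeness"`` weights it by the cluster's share of the training
    grid, N_i |P_i| / (|U| |F|).  A query no cluster can score falls back to
    the most frequent training class, flagged via ``fallback``.
    """
    if policy not in ("partial", "strict"):
        raise DomainError(f"unknown fallback policy {policy!r}")
    if lambda_mode not in ("coverage", "completeness"):
        raise DomainError(f"unknown lambda_mode {lambda_mode!r}")
    query = np.asarray(query, dtype=float)
    if query.shape != (len(ensemble.feature_names),):
        raise DomainError(
            f"query must have {len(ensemble.feature_names)} features"
        )
    n_cls = len(ensemble.classes)
    scores = np.zeros((len(ensemble.classifiers), n_cls))
    weights = np.zeros(len(ensemble.classifiers))
    for i, c in enumerate(ensemble.classifiers):
        lam = completeness_weight(query, c)
        if lam == 0.0:
            continue
        if lam < 1.0 and policy == "strict":
            continue
        vec = query[list(c.feature_idx)]
        if lam < 1.0:
            hole = np.isnan(vec)
            vec = vec.copy()
            vec[hole] = c.train_means[hole]
        weights[i] = _vote_weight(lam, c, lambda_mode)
        scores[i] = c.scores(vec)
    combined = weights @ scores
    if weights.sum() == 0.0:
        decision = ensemble.prior_class
        return ClassificationMatrix(
            per_cluster_scores=scores,
            weights=weights,
            combined=combined,
            classes=ensemble.classes,
            decision=decision,
            fallback=True,
        )
    decision = _decide(combined, ensemble.classes, ensemble.class_counts)
    return ClassificationMatrix(
        per_cluster_scores=scores,
        weights=weights,
        combined=combined,
        classes=ensemble.classes,
        decision=decision,
    )


def predict_batch(
    ensemble: LocalValidityEnsemble,
    queries: np.ndarray,
    policy: str = "partial",
    lambda_mode: str = "coverage",
) -> tuple[np.ndarray, np.ndarray]:
    """Decisions and fallback flags for many queries at once.

    Equivalent to calling :func:`predict` per row, but scores each cluster's
    eligible queries in a single ``predict_proba`` call.
    """
    if policy not in ("partial", "strict"):
        raise DomainError(f"unknown fallback policy {policy!r}")
    if lambda_mode not in ("coverage", "completeness"):
        raise DomainError(f"unknown lambda_mode {lambda_mode!r}")
    queries = np.asarray(queries, dtype=float)
    if queries.ndim != 2 or queries.shape[1] != len(ensemble.feature_names):
        raise DomainError(
            f"queries must be 2-D with {len(ensemble.feature_names)} features"
        )
    nq = queries.shape[0]
    n_cls = len(ensemble.classes)
    combined = np.zeros((nq, n_cls))
    weight_sum = np.zeros(nq)
    obs = ~np.isnan(queries)
    for c in ensemble.classifiers:
        idx = np.asarray(c.feature_idx, dtype=int)
        lam_cov = obs[:, idx].mean(axis=1)
        eligible = lam_cov > 0 if policy == "partial" else lam_cov == 1.0
        if not eligible.any():
            continue
        if lambda_mode == "coverage":
            lam = lam_cov * c.quality
        else:
            lam = np.full_like(lam_cov, c.completeness * c.quality)
        X = queries[np.ix_(eligible, idx)].copy()
        holes = np.isnan(X)
        if holes.any():
            X[holes] = np.broadcast_to(c.train_means, X.shape)[holes]
        if c.model is None:
            scores = np.zeros((int(eligible.sum()), n_cls))
            scores[:, np.searchsorted(ensemble.classes, c.constant_class)] = 1.0
        else:
            proba = c.model.predict_proba(X)
            scores = np.zeros((len(X), n_cls))
            scores[:, np.searchsorted(ensemble.classes, c.model.classes_)] = proba
        combined[eligible] += lam[eligible, None] * scores
        weight_sum += np.where(eligible, lam, 0.0)
    decisions = np.empty(nq, dtype=object)
    fallback = weight_sum == 0.0
    for q in range(nq):
        if fallback[q]:
            decisions[q] = ensemble.prior_class
        else:
            decisions[q] = _decide(
                combined[q], ensemble.classes, ensemble.class_counts
            )
    return decisions, fallback


class LocalValidityClassifier:
    """End-to-end pipeline: patterns -> LVS -> clusters -> weighted ensemble.

    Parameters
    ----------
    base_spec
        Base classifier for each cluster (see :func:`make_base_classifier`).
    k_neighbors
        Neighbour links per subset during clustering.
    sigma2
        Gaussian-kernel variance; ``None`` selects the median heuristic.
    max_clusters
        Cap on cluster count (``None`` = no forced merging).
    policy
        Fallback policy for partially covered queries.
    seed
        Seeds every stochastic element of training.
    """

    def __init__(
        self,
        base_spec: BaseSpec = "tree",
        k_neighbors: int = 1,
        sigma2: float | None = None,
        max_clusters: int | None = None,
        policy: str = "partial",
        lambda_mode: str = "coverage",
        quality_weight: bool = False,
        seed: int = 0,
    ):
        self.base_spec = base_spec
        self.k_neighbors = k_neighbors
        self.sigma2 = sigma2
        self.max_clusters = max_clusters
        self.policy = policy
        self.lambda_mode = lambda_mode
        self.quality_weight = quality_weight
        self.seed = seed
        self.ensemble_: LocalValidityEnsemble | None = None
        self.clusters_: ClusterSet | None = None

    def fit(self, ds: IncompleteDataset) -> "LocalValidityClassifier":
        subsets = build_all_lvs(ds)
        self.clusters_ = cluster_lvs(
            subsets,
            k_neighbors=self.k_neighbors,
            sigma2=self.sigma2,
            max_clusters=self.max_clusters,
        )
        self.ensemble_ = train_ensemble(
            ds,
            self.clusters_,
            base_spec=self.base_spec,
            seed=self.seed,
            quality_weight=self.quality_weight,
        )
        return self

    def predict_one(self, query: np.ndarray) -> ClassificationMatrix:
        if self.ensemble_ is None:
            raise DomainError("classifier is not fitted")
        return predict(
            self.ensemble_, query, policy=self.policy, lambda_mode=self.lambda_mode
        )

    def predict(self, ds: IncompleteDataset) -> np.ndarray:
        """Predicted label for every case of ``ds`` (labels, if any, ignored)."""
        if self.ensemble_ is None:
            raise DomainError("classifier is not fitted")
        decisions, _ = predict_batch(
            self.ensemble_,
            ds.values,
            policy=self.policy,
            lambda_mode=self.lambda_mode,
        )
        return decisions
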