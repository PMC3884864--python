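import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from localvalidity import (
    ClusterClassifier,
    DomainError,
    IncompleteDataset,
    LocalValidityClassifier,
    LocalValidityEnsemble,
    build_all_lvs,
    cluster_lvs,
    completeness_weight,
    predict,
    predict_batch,
    train_ensemble,
)


class FixedScores:
    """Stub scikit-learn-style model emitting constant class probabilities."""

    def __init__(self, classes, proba):
        self.classes_ = np.asarray(classes)
        self.proba = np.asarray(proba, dtype=float)

    def predict_proba(self, X):
        return np.tile(self.proba, (len(X), 1))


def two_cluster_ensemble():
    """lambda = (1, 0.5) fixture: cluster 1 on two observed features, cluster 2
    on four features of which the query observes two."""
    classes = np.array(["c1", "c2"])
    c1 = ClusterClassifier(
        cluster_id=0,
        features=("f1", "f2"),
        feature_idx=(0, 1),
        model=FixedScores(classes, [0.2, 0.8]),
        classes=classes,
        train_size=4,
        train_means=np.zeros(2),
    )
    c2 = ClusterClassifier(
        cluster_id=1,
        features=("f3", "f4", "f5", "f6"),
        feature_idx=(2, 3, 4, 5),
        model=FixedScores(classes, [0.9, 0.1]),
        classes=classes,
        train_size=4,
        train_means=np.zeros(4),
    )
    return LocalValidityEnsemble(
        classifiers=[c1, c2],
        classes=classes,
        class_counts=np.array([2, 2]),
        feature_names=("f1", "f2", "f3", "f4", "f5", "f6"),
    )


class TestCompletenessWeight:
    def test_fully_observed_pattern(self):
        c = two_cluster_ensemble().classifiers[0]
        assert completeness_weight(np.array([1, 2, np.nan, np.nan, 0, 0]), c) == 1.0

    def test_half_observed_pattern(self):
        c = two_cluster_ensemble().classifiers[1]
        q = np.array([1, 2, 3.0, 4.0, np.nan, np.nan])
        assert completeness_weight(q, c) == 0.5

    def test_disjoint_query(self):
        c = two_cluster_ensemble().classifiers[0]
        q = np.array([np.nan, np.nan, 1, 1, 1, 1.0])
        assert completeness_weight(q, c) == 0.0


class TestCombination:
    def test_weighted_two_cluster_combination(self):
        # lambda = (1, 0.5), scores (0.2, 0.8) and (0.9, 0.1):
        # combined = (0.2 + 0.45, 0.8 + 0.05) = (0.65, 0.85) -> second class
        ens = two_cluster_ensemble()
        q = np.array([1.0, 2.0, 3.0, 4.0, np.nan, np.nan])
        cm = predict(ens, q)
        np.testing.assert_allclose(cm.weights, [1.0, 0.5])
        np.testing.assert_allclose(cm.combined, [0.65, 0.85], atol=1e-12)
        assert cm.decision == "c2"
        assert not cm.fallback

    def test_combined_is_exact_weighted_sum(self):
        ens = two_cluster_ensemble()
        q = np.array([1.0, 2.0, 3.0, 4.0, np.nan, np.nan])
        cm = predict(ens, q)
        np.testing.assert_array_equal(cm.combined, cm.weights @ cm.per_cluster_scores)

    def test_single_cluster_argmax(self):
        ens = two_cluster_ensemble()
        ens.classifiers = ens.classifiers[:1]
        cm = predict(ens, np.array([1.0, 2.0, np.nan, np.nan, np.nan, np.nan]))
        assert cm.decision == "c2"
        np.testing.assert_allclose(cm.combined, [0.2, 0.8])

    def test_scaling_weights_never_changes_decision(self):
        ens = two_cluster_ensemble()
        q = np.array([1.0, 2.0, 3.0, 4.0, np.nan, np.nan])
        base = predict(ens, q).decision
        for c in ens.classifiers:
            c.quality = 2.0  # doubles every vote weight
        assert predict(ens, q).decision == base

    def test_cluster_order_never_changes_decision(self):
        ens = two_cluster_ensemble()
        q = np.array([1.0, 2.0, 3.0, 4.0, np.nan, np.nan])
        d1 = predict(ens, q).decision
        ens.classifiers = ens.classifiers[::-1]
        d2 = predict(ens, q).decision
        assert d1 == d2

    def test_strict_policy_drops_partial_clusters(self):
        ens = two_cluster_ensemble()
        q = np.array([1.0, 2.0, 3.0, 4.0, np.nan, np.nan])
        cm = predict(ens, q, policy="strict")
        np.testing.assert_allclose(cm.weights, [1.0, 0.0])
        assert cm.decision == "c2"

    def test_fully_missing_query_falls_back_to_prior(self):
        ens = two_cluster_ensemble()
        ens.class_counts = np.array([5, 2])
        cm = predict(ens, np.full(6, np.nan))
        assert cm.fallback
        assert cm.decision == "c1"  # most frequent training class

    def test_batch_matches_single_query_path(self):
        ens = two_cluster_ensemble()
        queries = np.array(
            [
                [1, 2, 3, 4, np.nan, np.nan],
                [np.nan, np.nan, 1, 1, 1, 1],
                [np.nan] * 6,
            ],
            dtype=float,
        )
        dec, fb = predict_batch(ens, queries)
        singles = [predict(ens, q) for q in queries]
        assert list(dec) == [s.decision for s in singles]
        assert list(fb) == [s.fallback for s in singles]


class TestTraining:
    def labelled(self, values, labels):
        values = np.asarray(values, dtype=float)
        return IncompleteDataset(
            case_ids=tuple(f"x{i + 1}" for i in range(len(values))),
            feature_names=tuple(f"f{j + 1}" for j in range(values.shape[1])),
            values=values,
            labels=np.asarray(labels),
        )

    def test_single_class_cluster_becomes_constant_scorer(self):
        ds = self.labelled([[1, 2], [2, 1], [1, 1]], ["a", "a", "a"])
        clusters = cluster_lvs(build_all_lvs(ds))
        ens = train_ensemble(ds, clusters)
        c = ens.classifiers[0]
        assert c.model is None
        cm = predict(ens, np.array([9.0, 9.0]))
        np.testing.assert_allclose(cm.combined, [1.0])
        assert cm.decision == "a"

    def test_unlabelled_data_rejected(self):
        ds = IncompleteDataset(("a",), ("f1",), np.array([[1.0]]))
        with pytest.raises(DomainError):
            train_ensemble(ds, cluster_lvs(build_all_lvs(ds)))

    def test_one_nearest_neighbour_hand_trace(self):
        # Two hand-built clusters; 1-NN on each sub-table traced by hand.
        # Cluster A trains on f1,f2 rows (0,0),(0,1),(4,4),(4,5) with labels
        # a,a,b,b; cluster B trains on f3 values 0,0,10,10 with labels a,a,b,b.
        values = np.array(
            [
                [0, 0, 0.0],
                [0, 1, 0.0],
                [4, 4, 10.0],
                [4, 5, 10.0],
                [1, 0, np.nan],  # only cluster A's pattern
                [np.nan, np.nan, 9.0],  # only cluster B's pattern
            ]
        )
        ds = self.labelled(values, ["a", "a", "b", "b", "a", "b"])
        subsets = build_all_lvs(ds)
        clusters = cluster_lvs(subsets, k_neighbors=1, sigma2=1.0)
        ens = train_ensemble(ds, clusters, base_spec="knn1")
        # query (1, 1, 9): nearest in A is (0,1)->a; nearest in B is 10->b
        cm = predict(ens, np.array([1.0, 1.0, 9.0]))
        by_pattern = {
            c.features: cm.per_cluster_scores[i]
            for i, c in enumerate(ens.classifiers)
        }
        for feats, scores in by_pattern.items():
            if feats == ("f1", "f2"):
                np.testing.assert_allclose(scores, [1.0, 0.0])  # votes a
            elif feats == ("f3",):
                np.testing.assert_allclose(scores, [0.0, 1.0])  # votes b

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        values = rng.integers(1, 5, size=(30, 4)).astype(float)
        values[rng.random((30, 4)) < 0.2] = np.nan
        values[np.isnan(values).all(axis=1)] = 1.0
        ds = self.labelled(values, rng.integers(0, 2, 30).astype(str))
        q = np.array([1.0, np.nan, 3.0, 2.0])
        runs = []
        for _ in range(2):
            clf = LocalValidityClassifier(seed=11).fit(ds)
            cm = clf.predict_one(q)
            runs.append((cm.decision, cm.combined.tolist(), cm.weights.tolist()))
        assert runs[0] == runs[1]


class TestCollapseOnCompleteData:
    def test_equivalence_with_base_classifier(self):
        rng = np.random.default_rng(9)
        values = rng.integers(1, 5, size=(40, 5)).astype(float)
        labels = rng.integers(0, 3, 40).astype(str)
        ds = IncompleteDataset(
            tuple(f"x{i}" for i in range(40)),
            tuple(f"f{j}" for j in range(5)),
            values,
            labels,
        )
        clf = LocalValidityClassifier(base_spec="tree", seed=4).fit(ds)
        assert clf.clusters_.n_clusters == 1
        assert all(
            completeness_weight(v, clf.ensemble_.classifiers[0]) == 1.0
            for v in values
        )
        base = DecisionTreeClassifier(random_state=4).fit(values, labels)
        proba = base.predict_proba(values)
        # identical fitted model up to the decision rule: on rows with a
        # unique argmax the raw base prediction must match exactly ...
        untied = (
            np.abs(proba - proba.max(axis=1, keepdims=True)) < 1e-12
        ).sum(axis=1) == 1
        preds = clf.predict(ds)
        np.testing.assert_array_equal(preds[untied], base.predict(values)[untied])
        # ... and every row matches under the package's shared tie-break
        from localvalidity.evaluate import _predict_with_base

        classes, counts = np.unique(labels, return_counts=True)
        np.testing.assert_array_equal(
            preds, _predict_with_base(base, classes, counts, values)
        )
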