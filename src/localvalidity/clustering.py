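"""Similarity and clustering of local-validity subsets.

When missingness is high the number of local-validity subsets (LVS) grows and
training one classifier per subset becomes both expensive and noisy.  Subsets
with similar patterns are therefore merged.  Similarity between two subsets is
measured in two steps:

* a Gaussian-kernel cross-entropy between the member clouds on their shared
  feature space,  mu = -log( (1/(Ni*Nk)) * sum_pq exp(-||x_p - y_q||^2 / (2 sigma^2)) ),
  which is 0 for coincident singletons and grows as the clouds separate
  (the kernel is unnormalized so mu >= 0 always);
* an overlap-weighted mutual information  I = mu * log(N_ik / (Ni + Nk)),
  where N_ik counts the cases belonging to both subsets.  Pairs with no
  common member carry a no-correlation sentinel ranked below every finite
  value.

Note that the log factor is <= 0, so for mu > 0 the product I is <= 0; the
ranking convention "larger I = stronger correlation" is applied to the value
as defined, with the zero-overlap sentinel lowest.  Clustering links each
subset to its k most similar peers, takes connected components of the mutual
links, and represents each cluster by the intersection of its patterns and
the union of its memberships — which keeps every cluster's sub-table complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .dataset import DomainError
from .patterns import LocalValiditySubset, Pattern

__all__ = [
    "NO_CORRELATION",
    "ClusterSet",
    "SubsetSimilarity",
    "cluster_lvs",
    "cross_entropy",
    "median_sigma2",
    "mutual_information",
]

#: sentinel for pairs with zero membership overlap (or disjoint patterns);
#: compares below every finite mutual-information value
NO_CORRELATION = float("-inf")


@dataclass(frozen=True)
class SubsetSimilarity:
    """Similarity statistics between two local-validity subsets (nats)."""

    mu: float
    overlap: int
    mi: float
    sigma2: float


@dataclass(frozen=True)
class ClusterSet:
    """A partition of LVS indices into clusters.

    ``clusters[c]`` is the tuple of LVS indices in cluster c;
    ``merged_subsets[c]`` is the merged subset itself — pattern = intersection
    of member-LVS patterns, members = union of member-LVS memberships — whose
    sub-table is complete by construction.
    """

    clusters: tuple[tuple[int, ...], ...]
    merged_subsets: tuple[LocalValiditySubset, ...]

    @property
    def merged_patterns(self) -> tuple[tuple[str, ...], ...]:
        return tuple(s.pattern.features for s in self.merged_subsets)

    @property
    def merged_members(self) -> tuple[tuple[str, ...], ...]:
        return tuple(s.members for s in self.merged_subsets)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _shared_columns(
    a: LocalValiditySubset, b: LocalValiditySubset
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Column selectors of the shared feature set in each subset's data."""
    shared = sorted(set(a.pattern.feature_idx) & set(b.pattern.feature_idx))
    if not shared:
        raise DomainError(
            "disjoint patterns: no shared feature between "
            f"{a.pattern.features!r} and {b.pattern.features!r}"
        )
    pos_a = [a.pattern.feature_idx.index(j) for j in shared]
    pos_b = [b.pattern.feature_idx.index(j) for j in shared]
    return a.data[:, pos_a], b.data[:, pos_b], tuple(shared)


def median_sigma2(xa: np.ndarray, xb: np.ndarray, max_points: int = 64) -> float:
    """Median-heuristic kernel variance for two pooled point clouds.

    Median squared pairwise distance over the pooled vectors; clouds larger
    than ``max_points`` are thinned to an evenly spaced deterministic subset
    (the median is stable under subsampling).  Falls back to 1.0 when all
    points coincide (any positive value gives the same kernel there).
    """
    pooled = np.vstack([xa, xb])
    if len(pooled) < 2:
        return 1.0
    if len(pooled) > max_points:
        step = np.linspace(0, len(pooled) - 1, max_points).astype(int)
        pooled = pooled[step]
    d2 = pdist(pooled, metric="sqeuclidean")
    med = float(np.median(d2))
    return med if med > 0 else 1.0


def _mu_from_clouds(xa: np.ndarray, xb: np.ndarray, sigma2: float) -> float:
    if sigma2 <= 0:
        raise DomainError(f"sigma2 must be positive, got {sigma2}")
    d2 = cdist(xa, xb, metric="sqeuclidean")
    mean_kernel = float(np.exp(-d2 / (2.0 * sigma2)).mean())
    if mean_kernel <= 0.0:  # all kernel values underflowed
        return float("inf")
    # kernel <= 1 everywhere, hence mean <= 1 and mu >= 0 (clamp rounding)
    return max(0.0, -math.log(mean_kernel))


def cross_entropy(
    lvs_i: LocalValiditySubset,
    lvs_k: LocalValiditySubset,
    sigma2: float | None = None,
) -> float:
    """Gaussian-kernel cross-entropy between two subsets on their shared features.

    ``sigma2=None`` applies the median heuristic to the pooled shared-feature
    vectors.  Raises :class:`DomainError` if the patterns are disjoint or
    ``sigma2 <= 0``.
    """
    xa, xb, _ = _shared_columns(lvs_i, lvs_k)
    if sigma2 is None:
        sigma2 = median_sigma2(xa, xb)
    return _mu_from_clouds(xa, xb, sigma2)


def mutual_information(
    lvs_i: LocalValiditySubset,
    lvs_k: LocalValiditySubset,
    sigma2: float | None = None,
) -> SubsetSimilarity:
    """Overlap-weighted mutual information between two subsets."""
    xa, xb, _ = _shared_columns(lvs_i, lvs_k)
    if sigma2 is None:
        sigma2 = median_sigma2(xa, xb)
    mu = _mu_from_clouds(xa, xb, sigma2)
    overlap = len(set(lvs_i.member_idx) & set(lvs_k.member_idx))
    if overlap == 0:
        mi = NO_CORRELATION
    else:
        mi = mu * math.log(overlap / (lvs_i.size + lvs_k.size))
    return SubsetSimilarity(mu=mu, overlap=overlap, mi=mi, sigma2=float(sigma2))


def _merge_component(
    subsets: list[LocalValiditySubset], comp: tuple[int, ...]
) -> LocalValiditySubset | None:
    """Merge a component: intersect patterns, union members.

    Returns ``None`` when the pattern intersection is empty (the component
    cannot share a classifier).  Member values on the merged pattern are read
    off the constituent subsets, so no access to the parent dataset is needed.
    """
    comp = tuple(sorted(comp))
    shared = set(subsets[comp[0]].pattern.feature_idx)
    for c in comp[1:]:
        shared &= set(subsets[c].pattern.feature_idx)
    if not shared:
        return None
    fidx = tuple(sorted(shared))
    first = subsets[comp[0]].pattern
    names = tuple(
        first.features[first.feature_idx.index(j)] for j in fidx
    )
    member_rows: dict[int, np.ndarray] = {}
    member_order: list[int] = []
    for c in comp:
        sub = subsets[c]
        pos = [sub.pattern.feature_idx.index(j) for j in fidx]
        for r, m in enumerate(sub.member_idx):
            if m not in member_rows:
                member_rows[m] = sub.data[r, pos]
                member_order.append(m)
    member_order.sort()
    id_of = {}
    for c in comp:
        for m, cid in zip(subsets[c].member_idx, subsets[c].members):
            id_of[m] = cid
    sources: list[int] = []
    for c in comp:
        sources.extend(subsets[c].pattern.source_case_idx)
    src_idx = tuple(sorted(set(sources)))
    pattern = Pattern(
        feature_idx=fidx,
        features=names,
        source_case_idx=src_idx,
        source_cases=tuple(id_of.get(i, str(i)) for i in src_idx),
    )
    return LocalValiditySubset(
        pattern=pattern,
        member_idx=tuple(member_order),
        members=tuple(id_of[m] for m in member_order),
        data=np.vstack([member_rows[m] for m in member_order]),
    )


def _featurewise_medians(
    subsets: list[LocalValiditySubset], n_features: int, max_points: int = 256
) -> np.ndarray:
    """Per-feature median squared pairwise difference over pooled member values.

    Used to price the kernel variance of a subset pair as the sum over shared
    features, a featurewise median heuristic computed once per clustering run
    (cases appearing in several subsets are pooled with repetition; the
    median is insensitive to that).
    """
    med = np.zeros(n_features)
    pooled: list[list[np.ndarray]] = [[] for _ in range(n_features)]
    for s in subsets:
        for pos, j in enumerate(s.pattern.feature_idx):
            pooled[j].append(s.data[:, pos])
    for j in range(n_features):
        if not pooled[j]:
            continue
        v = np.concatenate(pooled[j])
        if len(v) > max_points:
            v = v[np.linspace(0, len(v) - 1, max_points).astype(int)]
        if len(v) < 2:
            continue
        d2 = (v[:, None] - v[None, :]) ** 2
        med[j] = float(np.median(d2[np.triu_indices(len(v), 1)]))
    return med


def _pair_sigma2(
    shared: tuple[int, ...], sigma2: float | None, medians: np.ndarray | None
) -> float:
    if sigma2 is not None:
        return sigma2
    s2 = float(medians[list(shared)].sum())
    return s2 if s2 > 0 else 1.0


def _similarity_matrix(
    subsets: list[LocalValiditySubset],
    sigma2: float | None,
    medians: np.ndarray | None,
) -> np.ndarray:
    n = len(subsets)
    mi = np.full((n, n), NO_CORRELATION)
    members = [set(s.member_idx) for s in subsets]
    for i in range(n):
        for k in range(i + 1, n):
            overlap = len(members[i] & members[k])
            if overlap == 0:
                continue
            try:
                xa, xb, shared = _shared_columns(subsets[i], subsets[k])
            except DomainError:  # disjoint patterns: unmergeable anyway
                continue
            mu = _mu_from_clouds(xa, xb, _pair_sigma2(shared, sigma2, medians))
            val = mu * math.log(overlap / (subsets[i].size + subsets[k].size))
            mi[i, k] = mi[k, i] = val
    return mi


def cluster_lvs(
    subsets: list[LocalValiditySubset],
    k_neighbors: int = 1,
    sigma2: float | None = None,
    max_clusters: int | None = None,
) -> ClusterSet:
    """Group LVS into clusters of mutually similar subsets.

    Each subset is linked to its ``k_neighbors`` most similar subsets by
    mutual information (ties broken toward the lower index); an edge is kept
    only when both endpoints link each other, and connected components of the
    kept edges become clusters.  A component whose pattern intersection is
    empty is split back into singletons.  If more than ``max_clusters``
    clusters remain, the two clusters with the highest inter-cluster mutual
    information (computed on the merged subsets) are merged repeatedly, as
    long as a merge with a nonempty shared pattern exists.

    With ``sigma2=None`` the kernel variance of each pair is the sum, over
    the shared features, of per-feature median squared pairwise differences,
    computed once per run (a featurewise median heuristic that adapts to the
    dimension of each shared space without re-pooling every pair).
    """
    if not subsets:
        raise DomainError("cluster_lvs requires at least one subset")
    if k_neighbors < 1:
        raise DomainError("k_neighbors must be >= 1")
    n = len(subsets)
    if n == 1:
        return ClusterSet(clusters=((0,),), merged_subsets=(subsets[0],))

    medians = None
    if sigma2 is None:
        n_features = 1 + max(max(s.pattern.feature_idx) for s in subsets)
        medians = _featurewise_medians(subsets, n_features)
    mi = _similarity_matrix(subsets, sigma2, medians)

    # top-k link lists; NO_CORRELATION never produces a link
    links: list[set[int]] = []
    for i in range(n):
        order = sorted(
            (k for k in range(n) if k != i and mi[i, k] > NO_CORRELATION),
            key=lambda k: (-mi[i, k], k),
        )
        links.append(set(order[:k_neighbors]))

    # union-find over mutual links
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(n):
        for k in links[i]:
            if i in links[k]:
                union(i, k)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    merged: list[tuple[tuple[int, ...], LocalValiditySubset]] = []
    for root in sorted(comps):
        comp = tuple(sorted(comps[root]))
        sub = _merge_component(subsets, comp)
        if sub is None:  # empty shared pattern: fall back to singletons
            for i in comp:
                merged.append(((i,), subsets[i]))
        else:
            merged.append((comp, sub))
    merged.sort(key=lambda t: t[0][0])

    if max_clusters is not None and max_clusters >= 1:
        merged = _force_merge(merged, max_clusters, sigma2, medians)

    return ClusterSet(
        clusters=tuple(c for c, _ in merged),
        merged_subsets=tuple(s for _, s in merged),
    )


def _force_merge(
    merged: list[tuple[tuple[int, ...], LocalValiditySubset]],
    max_clusters: int,
    sigma2: float | None,
    medians: np.ndarray | None,
) -> list[tuple[tuple[int, ...], LocalValiditySubset]]:
    """Greedily merge the most similar cluster pair until the cap is met."""
    while len(merged) > max_clusters:
        best: tuple[float, int, int] | None = None
        best_sub: LocalValiditySubset | None = None
        for a in range(len(merged)):
            for b in range(a + 1, len(merged)):
                all_subs = [merged[a][1], merged[b][1]]
                cand = _merge_component(all_subs, (0, 1))
                if cand is None:
                    continue
                try:
                    xa, xb, shared = _shared_columns(merged[a][1], merged[b][1])
                except DomainError:
                    continue
                if medians is None and sigma2 is None:
                    s2 = median_sigma2(xa, xb)
                else:
                    s2 = _pair_sigma2(shared, sigma2, medians)
                mu = _mu_from_clouds(xa, xb, s2)
                overlap = len(
                    set(merged[a][1].member_idx) & set(merged[b][1].member_idx)
                )
                if overlap == 0:
                    mi_val = NO_CORRELATION
                else:
                    mi_val = mu * math.log(
                        overlap / (merged[a][1].size + merged[b][1].size)
                    )
                key = (mi_val, -a, -b)
                if best is None or key > (best[0], -best[1], -best[2]):
                    best = (mi_val, a, b)
                    best_sub = cand
        if best is None:  # no mergeable pair left
            break
        _, a, b = best
        comp = tuple(sorted(merged[a][0] + merged[b][0]))
        rest = [merged[i] for i in range(len(merged)) if i not in (a, b)]
        rest.append((comp, best_sub))
        rest.sort(key=lambda t: t[0][0])
        merged = rest
    return merged
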