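"""Mask matrices, local-validity patterns and local-validity subsets.

The observed/missing structure of an incomplete table is captured by a binary
mask matrix M (cases as rows, 1 = observed).  Every distinct nonzero row of M
defines a *local-validity pattern*: the largest feature subset on which its
source cases are fully observed.  The *local-validity subset* (LVS) of a
pattern is the set of all cases observed on every feature of the pattern —
the complete sub-table on which one ensemble member can be trained without
deleting or imputing anything.

Nested patterns are all retained: a pattern is maximal for its own source
cases, not globally maximal, so the number of patterns is bounded by the
number of cases and exact enumeration always suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import DomainError, IncompleteDataset

__all__ = [
    "LocalValiditySubset",
    "MaskMatrix",
    "Pattern",
    "build_all_lvs",
    "build_lvs",
    "build_mask_matrix",
    "extract_patterns",
]


@dataclass(frozen=True)
class MaskMatrix:
    """Binary observed/missing indicator with cases as rows (1 = observed)."""

    entries: np.ndarray
    case_ids: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=np.int8)
        if not np.isin(e, (0, 1)).all():
            raise DomainError("mask entries must be exactly 0 or 1")
        object.__setattr__(self, "entries", e)


@dataclass(frozen=True)
class Pattern:
    """A feature subset, with the cases whose observed set equals it.

    ``feature_idx`` is sorted ascending in dataset column order;
    ``source_case_idx`` lists the cases whose observed-feature set is exactly
    this pattern (first-occurrence order).
    """

    feature_idx: tuple[int, ...]
    features: tuple[str, ...]
    source_case_idx: tuple[int, ...]
    source_cases: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.feature_idx:
            raise DomainError("a pattern must contain at least one feature")


@dataclass(frozen=True)
class LocalValiditySubset:
    """All cases observed on every feature of ``pattern``.

    ``data`` is the complete ``(size, len(pattern))`` sub-table of member
    values on the pattern's features (dataset column order), guaranteed free
    of missing cells.
    """

    pattern: Pattern
    member_idx: tuple[int, ...]
    members: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        if not self.member_idx:
            raise DomainError("a local-validity subset cannot be empty")
        if np.isnan(self.data).any():
            raise DomainError("LVS sub-table contains missing cells")

    @property
    def size(self) -> int:
        return len(self.member_idx)


def build_mask_matrix(ds: IncompleteDataset) -> MaskMatrix:
    """Binary matrix with a 1 exactly at each observed cell."""
    if ds.n_cases == 0:
        raise DomainError("cannot build a mask matrix for an empty dataset")
    return MaskMatrix(
        entries=ds.observed_mask().astype(np.int8),
        case_ids=ds.case_ids,
        feature_names=ds.feature_names,
    )


def extract_patterns(
    mask: MaskMatrix, with_rejects: bool = False
) -> list[Pattern] | tuple[list[Pattern], list[str]]:
    """Enumerate the distinct nonzero row-masks of M as patterns.

    Patterns appear in first-occurrence case order.  Cases with every feature
    missing match no pattern; they are returned in a rejects list when
    ``with_rejects`` is true rather than silently dropped.
    """
    entries = mask.entries
    seen: dict[tuple[int, ...], list[int]] = {}
    rejects: list[str] = []
    for i, row in enumerate(entries):
        key = tuple(int(v) for v in row)
        if not any(key):
            rejects.append(mask.case_ids[i])
            continue
        seen.setdefault(key, []).append(i)
    patterns = []
    for key, cases in seen.items():
        fidx = tuple(j for j, v in enumerate(key) if v)
        patterns.append(
            Pattern(
                feature_idx=fidx,
                features=tuple(mask.feature_names[j] for j in fidx),
                source_case_idx=tuple(cases),
                source_cases=tuple(mask.case_ids[i] for i in cases),
            )
        )
    if with_rejects:
        return patterns, rejects
    return patterns


def build_lvs(ds: IncompleteDataset, p: Pattern) -> LocalValiditySubset:
    """Materialize the LVS of pattern ``p``: every case complete on it."""
    cols = np.asarray(p.feature_idx, dtype=int)
    ok = ds.observed_mask()[:, cols].all(axis=1)
    member_idx = np.flatnonzero(ok)
    if member_idx.size == 0:
        raise DomainError(
            f"no case is complete on pattern {p.features!r}"
        )
    return LocalValiditySubset(
        pattern=p,
        member_idx=tuple(int(i) for i in member_idx),
        members=tuple(ds.case_ids[i] for i in member_idx),
        data=ds.values[np.ix_(member_idx, cols)].copy(),
    )


def build_all_lvs(ds: IncompleteDataset) -> list[LocalValiditySubset]:
    """One LVS per extracted pattern; their memberships jointly cover U.

    A case with every feature missing belongs to no LVS and would be lost, so
    it is a hard error here (prediction-time fallbacks for such queries live
    in the ensemble layer).
    """
    mask = build_mask_matrix(ds)
    patterns, rejects = extract_patterns(mask, with_rejects=True)
    if rejects:
        raise DomainError(
            f"cases with all features missing cannot be covered: {rejects}"
        )
    return [build_lvs(ds, p) for p in patterns]
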