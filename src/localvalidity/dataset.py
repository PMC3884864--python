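"""Incomplete labelled case-by-feature tables.

A dataset is a rectangular grid of numeric (typically ordinal-coded) feature
values in which some cells are missing.  On disk missing cells are written as a
configurable marker string (``"*"`` by default); in memory they are ``NaN`` so
that no numeric code can ever collide with a legitimate feature level.  Class
labels live outside the feature grid and are never maskable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_MISSING_MARKER",
    "DomainError",
    "IncompleteDataset",
    "MissingnessSummary",
    "ParseError",
    "missingness_summary",
    "read_table",
    "write_table",
]

DEFAULT_MISSING_MARKER = "*"

#: header names auto-recognised as a case-identifier column
_ID_HEADER_CANDIDATES = ("case_id", "id", "case", "U")


class ParseError(ValueError):
    """Malformed on-disk table (ragged row, unparseable cell, bad header)."""


class DomainError(ValueError):
    """Input violates a documented precondition of an operation."""


@dataclass(frozen=True)
class MissingnessSummary:
    """The three distinct missing-data rates of an incomplete table.

    ``case_missing_fraction`` is the fraction of cases containing at least one
    missing entry; ``per_feature_fraction`` maps each feature to the fraction
    of cases missing it; ``cell_missing_fraction`` is the fraction of all
    cells missing.  They are deliberately separate fields: a single symbol is
    often overloaded across all three rates, and conflating them silently
    changes experiment definitions.
    """

    case_missing_fraction: float
    per_feature_fraction: dict[str, float]
    cell_missing_fraction: float


@dataclass
class IncompleteDataset:
    """A labelled case-by-feature table with explicit missingness.

    Parameters
    ----------
    case_ids
        Unique, ordered case identifiers.
    feature_names
        Unique, ordered feature identifiers.
    values
        ``(n_cases, n_features)`` float array; ``NaN`` marks a missing cell,
        every non-missing entry must be finite.
    labels
        Optional per-case class labels (any hashable values); ``None`` for
        prediction-only tables.
    """

    case_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.case_ids = tuple(str(c) for c in self.case_ids)
        self.feature_names = tuple(str(f) for f in self.feature_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("values must be a 2-D case-by-feature grid")
        n, d = self.values.shape
        if n != len(self.case_ids) or d != len(self.feature_names):
            raise DomainError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.case_ids)} cases x {len(self.feature_names)} features"
            )
        if len(set(self.case_ids)) != n:
            raise DomainError("case_ids are not unique")
        if len(set(self.feature_names)) != d:
            raise DomainError("feature_names are not unique")
        observed = ~np.isnan(self.values)
        if not np.isfinite(self.values[observed]).all():
            raise DomainError("non-missing values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise DomainError("labels must be one per case")

    # -- basic geometry -------------------------------------------------

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> np.ndarray:
        """Boolean ``(n_cases, n_features)`` array, True where observed."""
        return ~np.isnan(self.values)

    def is_complete(self) -> bool:
        return bool(self.observed_mask().all())

    # -- subsetting -----------------------------------------------------

    def take_cases(self, idx: Sequence[int]) -> "IncompleteDataset":
        idx = np.asarray(idx, dtype=int)
        return IncompleteDataset(
            case_ids=tuple(self.case_ids[i] for i in idx),
            feature_names=self.feature_names,
            values=self.values[idx].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
        )

    def without_labels(self) -> "IncompleteDataset":
        return replace(self, values=self.values.copy(), labels=None)

    def copy(self) -> "IncompleteDataset":
        return IncompleteDataset(
            self.case_ids,
            self.feature_names,
            self.values.copy(),
            None if self.labels is None else self.labels.copy(),
        )


def read_table(
    path,
    missing_marker: str = DEFAULT_MISSING_MARKER,
    label_column: str | None = None,
    id_column: str | None = None,
) -> IncompleteDataset:
    """Read a delimited-text table into an :class:`IncompleteDataset`.

    The file must be comma-separated with a header row.  Cells equal to
    ``missing_marker`` become missing; every other cell must parse as a
    number.  ``id_column`` names the case-identifier column; when ``None`` the
    first column is used as identifiers if its header is one of
    ``case_id``/``id``/``case``/``U``, otherwise ids ``x1..xn`` are generated.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if id_column is None and header and header[0] in _ID_HEADER_CANDIDATES:
        id_column = header[0]
    special = [c for c in (id_column, label_column) if c is not None]
    for col in special:
        if col not in header:
            raise ParseError(f"{path}: column {col!r} not found in header")
    feature_names = [h for h in header if h not in special]
    if not feature_names:
        raise ParseError(f"{path}: no feature columns")
    id_pos = header.index(id_column) if id_column else None
    label_pos = header.index(label_column) if label_column else None
    feat_pos = [i for i, h in enumerate(header) if h not in special]

    case_ids: list[str] = []
    labels: list[str] = []
    values = np.empty((len(rows) - 1, len(feature_names)), dtype=float)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: row {r} has {len(row)} cells, expected {len(header)}"
            )
        case_ids.append(row[id_pos].strip() if id_pos is not None else f"x{r - 1}")
        if label_pos is not None:
            labels.append(row[label_pos].strip())
        for j, pos in enumerate(feat_pos):
            cell = row[pos].strip()
            if cell == missing_marker:
                values[r - 2, j] = np.nan
            else:
                try:
                    values[r - 2, j] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {r}, column {header[pos]!r}: "
                        f"cannot parse {cell!r} as a number"
                    ) from None
    return IncompleteDataset(
        case_ids=tuple(case_ids),
        feature_names=tuple(feature_names),
        values=values,
        labels=np.asarray(labels) if label_pos is not None else None,
    )


def write_table(
    ds: IncompleteDataset,
    path,
    missing_marker: str = DEFAULT_MISSING_MARKER,
    label_column: str = "label",
    id_column: str = "case_id",
) -> None:
    """Write the dataset as CSV with ``missing_marker`` for missing cells.

    Integral values are written without a trailing ``.0`` so that ordinal
    levels round-trip as the same text.
    """

    def fmt(v: float) -> str:
        if np.isnan(v):
            return missing_marker
        if float(v).is_integer():
            return str(int(v))
        return repr(float(v))

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = [id_column, *ds.feature_names]
        if ds.labels is not None:
            header.append(label_column)
        w.writerow(header)
        for i, cid in enumerate(ds.case_ids):
            row = [cid, *(fmt(v) for v in ds.values[i])]
            if ds.labels is not None:
                row.append(str(ds.labels[i]))
            w.writerow(row)


def missingness_summary(ds: IncompleteDataset) -> MissingnessSummary:
    """Compute case-, feature- and cell-level missing fractions."""
    if ds.n_cases == 0 or ds.n_features == 0:
        raise DomainError("missingness_summary requires a nonempty dataset")
    missing = np.isnan(ds.values)
    return MissingnessSummary(
        case_missing_fraction=float(missing.any(axis=1).mean()),
        per_feature_fraction={
            f: float(missing[:, j].mean()) for j, f in enumerate(ds.feature_names)
        },
        cell_missing_fraction=float(missing.mean()),
    )
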