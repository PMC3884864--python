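"""Synthetic incomplete ordinal datasets.

Generators for three things:

* complete labelled tables with class-conditional ordinal features (levels
  coded 1..L, each class preferring different levels — ``separation`` moves
  the preferred-level probability from uniform at 0 to deterministic at 1);
* MCAR masking: a fixed number of cells replaced by the missing marker,
  chosen uniformly and independently of both values and labels;
* a fixture emulating a 153-case, 3-class, 40-feature clinical symptom table
  whose features are severity scores on a four-level ordinal scale
  (1 = symptom absent .. 4 = most serious) and whose per-feature missing
  rates follow a fixed published profile in which 23 of the 40 features have
  missing entries.

The fixture matches marginal structure only (class sizes, value coding,
per-feature missingness); it makes no attempt to reproduce the feature
correlations of any real clinical dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import DomainError, IncompleteDataset

__all__ = [
    "FixtureSpec",
    "LIVER_FEATURE_MISSING_PCT",
    "MaskingConfig",
    "inject_mcar",
    "make_classification_data",
    "make_liver_fixture",
]

#: per-feature missing percentages of the 40-symptom liver-cirrhosis profile
#: (percent of the 153 cases; 23 entries are nonzero)
LIVER_FEATURE_MISSING_PCT: tuple[float, ...] = (
    5, 0.1, 10, 0, 4, 0.2, 3.1, 0, 0, 1,
    2.3, 1.2, 0, 0, 3.2, 1.1, 0.2, 2.1, 0, 0.3,
    0, 0, 3.8, 0.1, 0, 0, 0, 0.1, 2.1, 0,
    0.3, 0, 0, 0, 4.1, 0.1, 0.2, 0, 0, 0.1,
)

LIVER_CLASS_NAMES = ("stasis-heat", "damp-heat", "yin-deficiency")


@dataclass(frozen=True)
class MaskingConfig:
    """How to inject missingness into a complete table.

    ``level="cell"`` masks exactly ``round(alpha * n * d)`` cells uniformly;
    ``level="case"`` makes exactly ``round(alpha * n)`` cases incomplete (a
    random nonempty proper feature subset of each is masked);
    ``level="feature-profile"`` interprets ``per_feature_pct`` as per-feature
    missing percentages.  Labels are never masked, and every case keeps at
    least one observed feature.
    """

    alpha: float = 0.0
    level: str = "cell"
    seed: int = 0
    per_feature_pct: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise DomainError("alpha must be in [0, 1)")
        if self.level not in ("cell", "case", "feature-profile"):
            raise DomainError(f"unknown masking level {self.level!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of the emulated liver-cirrhosis symptom table."""

    n_cases: int = 153
    class_sizes: tuple[int, ...] = (52, 61, 40)
    n_features: int = 40
    value_levels: tuple[int, ...] = (1, 2, 3, 4)
    per_feature_missing: tuple[float, ...] = LIVER_FEATURE_MISSING_PCT
    class_separation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_sizes) != self.n_cases:
            raise DomainError("class sizes must sum to n_cases")
        if len(self.per_feature_missing) != self.n_features:
            raise DomainError("need one missing rate per feature")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def make_classification_data(
    n: int,
    d: int,
    classes: int = 3,
    separation: float = 0.5,
    seed: int = 0,
    levels: tuple[int, ...] = (1, 2, 3, 4),
    class_sizes: tuple[int, ...] | None = None,
    class_names: tuple[str, ...] | None = None,
) -> IncompleteDataset:
    """Complete table with class-conditional ordinal features.

    Class c prefers level index ``(c + j) % L`` on feature j with probability
    ``1/L + (1 - 1/L) * separation``; the remaining mass is uniform over the
    other levels.  ``separation=0`` gives identical class-conditionals (chance
    is the best attainable accuracy); ``separation=1`` gives deterministic,
    perfectly separable levels.
    """
    if classes < 2 or n < classes or d < 1:
        raise DomainError("need n >= classes >= 2 and d >= 1")
    if not 0.0 <= separation <= 1.0:
        raise DomainError("separation must be in [0, 1]")
    if class_sizes is None:
        base, extra = divmod(n, classes)
        class_sizes = tuple(base + (1 if c < extra else 0) for c in range(classes))
    if sum(class_sizes) != n or len(class_sizes) != classes:
        raise DomainError("class_sizes must have `classes` entries summing to n")
    if class_names is None:
        class_names = tuple(f"class{c}" for c in range(classes))
    L = len(levels)
    p_pref = 1.0 / L + (1.0 - 1.0 / L) * separation
    p_other = (1.0 - p_pref) / (L - 1)
    rng = np.random.default_rng(seed)
    values = np.empty((n, d))
    labels = np.empty(n, dtype=object)
    row = 0
    for c, size in enumerate(class_sizes):
        for j in range(d):
            probs = np.full(L, p_other)
            probs[(c + j) % L] = p_pref
            draws = rng.choice(L, size=size, p=probs)
            values[row : row + size, j] = np.asarray(levels)[draws]
        labels[row : row + size] = class_names[c]
        row += size
    return IncompleteDataset(
        case_ids=tuple(f"x{i + 1}" for i in range(n)),
        feature_names=tuple(f"f{j + 1}" for j in range(d)),
        values=values,
        labels=labels,
    )


def _mask_cells(shape, n_mask: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform cell mask of exactly ``n_mask`` cells, no case fully masked."""
    n, d = shape
    for _ in range(100):
        flat = rng.choice(n * d, size=n_mask, replace=False)
        hit = np.zeros(n * d, dtype=bool)
        hit[flat] = True
        grid = hit.reshape(n, d)
        if not grid.all(axis=1).any():
            return grid
    raise DomainError(
        "could not draw a mask leaving every case at least one observed feature"
    )


def inject_mcar(ds: IncompleteDataset, cfg: MaskingConfig) -> IncompleteDataset:
    """Mask a complete table per ``cfg``; labels are untouched."""
    if not ds.is_complete():
        raise DomainError("inject_mcar expects a complete dataset")
    n, d = ds.values.shape
    rng = np.random.default_rng(cfg.seed)
    values = ds.values.copy()

    if cfg.level == "cell":
        n_mask = _round_half_away(cfg.alpha * n * d)
        if n_mask:
            values[_mask_cells((n, d), n_mask, rng)] = np.nan
    elif cfg.level == "case":
        n_cases = _round_half_away(cfg.alpha * n)
        chosen = rng.choice(n, size=n_cases, replace=False)
        for i in chosen:
            k = int(rng.integers(1, d))  # keep >= 1 observed, >= 1 missing
            cols = rng.choice(d, size=k, replace=False)
            values[i, cols] = np.nan
    else:  # feature-profile
        if cfg.per_feature_pct is None:
            raise DomainError("feature-profile masking needs per_feature_pct")
        if len(cfg.per_feature_pct) != d:
            raise DomainError("need one percentage per feature")
        for j, pct in enumerate(cfg.per_feature_pct):
            target = _round_half_away(pct / 100.0 * n)
            if pct > 0 and target == 0:
                target = 1  # any nonzero rate must mask at least one case
            if target:
                rows = rng.choice(n, size=target, replace=False)
                values[rows, j] = np.nan
        if np.isnan(values).all(axis=1).any():
            raise DomainError("profile masking left a case with no observed feature")

    return IncompleteDataset(
        case_ids=ds.case_ids,
        feature_names=ds.feature_names,
        values=values,
        labels=None if ds.labels is None else ds.labels.copy(),
    )


def make_liver_fixture(spec: FixtureSpec = FixtureSpec()) -> IncompleteDataset:
    """Emulated liver-cirrhosis symptom table: 153 cases, classes of sizes
    (52, 61, 40), 40 four-level ordinal features, per-feature masking at the
    published percentage profile."""
    complete = make_classification_data(
        n=spec.n_cases,
        d=spec.n_features,
        classes=len(spec.class_sizes),
        separation=spec.class_separation,
        seed=spec.seed,
        levels=spec.value_levels,
        class_sizes=spec.class_sizes,
        class_names=LIVER_CLASS_NAMES[: len(spec.class_sizes)],
    )
    cfg = MaskingConfig(
        alpha=0.0,
        level="feature-profile",
        seed=spec.seed + 1,
        per_feature_pct=tuple(spec.per_feature_missing),
    )
    return inject_mcar(complete, cfg)
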