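"""Labelled dataset construction and the stratified train/validation/test split.

The ground-truthed data are split 60/20/20 by stratified sampling so that
each split preserves the relative class frequencies (per-class counts match
the target fractions to within one observation).  The split seed is an
explicit argument — there is no hidden global random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sharketho.io import CLASSES, LabelTrack


@dataclass
class LabelledDataset:
    """A feature table paired row-for-row with behaviour labels."""

    features: pd.DataFrame
    labels: np.ndarray
    class_order: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        if isinstance(self.labels, LabelTrack):
            self.labels = self.labels.labels
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.features) != len(self.labels):
            raise ValueError(
                f"{len(self.features)} feature rows vs {len(self.labels)} labels"
            )
        bad = set(self.labels) - set(self.class_order)
        if bad:
            raise ValueError(f"labels outside class order: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.class_order}

    def subset(self, idx: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            class_order=self.class_order,
        )


def _canonical_class_order(data: LabelledDataset, idx: np.ndarray) -> np.ndarray:
    """Order class-member indices by feature content, not input position.

    Sorting by row content before the seeded shuffle makes the split a
    function of the (feature, label) multiset alone, so shuffling the
    input rows does not change which observations land in which split.
    """
    sub = data.features.iloc[idx]
    keys = [sub[c].to_numpy() for c in reversed(sub.columns)]
    return idx[np.lexsort(keys)]


def _allocate(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n items to fractions (sums to n)."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    # hand leftover items to the largest fractional remainders, earlier
    # splits (train first) winning ties
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(
    data: LabelledDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[LabelledDataset, LabelledDataset, LabelledDataset]:
    """Split into train/validation/test, stratified by behaviour class.

    Per-class counts in each split equal the class total times the split
    fraction, rounded by largest remainder — i.e. within +-1 of exact
    proportionality.  Splits are disjoint, exhaustive and reproducible for
    a given seed; classes with fewer than 3 members go entirely to the
    training split, with a warning.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions {fractions} do not sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in data.class_order:
        idx = np.nonzero(data.labels == cls)[0]
        if idx.size == 0:
            continue
        if idx.size < 3:
            warnings.warn(
                f"class {cls!r} has only {idx.size} member(s); all assigned to train",
                stacklevel=2,
            )
            parts[0].extend(idx.tolist())
            continue
        idx = rng.permutation(_canonical_class_order(data, idx))
        counts = _allocate(idx.size, fractions)
        pos = 0
        for k, c in enumerate(counts):
            parts[k].extend(idx[pos : pos + c].tolist())
            pos += c
    out = []
    for p in parts:
        p = np.sort(np.array(p, dtype=int))
        out.append(data.subset(p))
    return tuple(out)


def split_manifest(
    data: LabelledDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Row-index manifest of the split (columns: row, label, split)."""
    rng = np.random.default_rng(seed)
    rows, splits = [], []
    names = ("train", "validation", "test")
    for cls in data.class_order:
        idx = np.nonzero(data.labels == cls)[0]
        if idx.size == 0:
            continue
        if idx.size < 3:
            rows.extend(idx.tolist())
            splits.extend(["train"] * idx.size)
            continue
        idx = rng.permutation(_canonical_class_order(data, idx))
        counts = _allocate(idx.size, fractions)
        pos = 0
        for k, c in enumerate(counts):
            rows.extend(idx[pos : pos + c].tolist())
            splits.extend([names[k]] * c)
            pos += c
    df = pd.DataFrame({"row": rows, "split": splits})
    df["label"] = data.labels[df["row"].to_numpy()]
    return df.sort_values("row").reset_index(drop=True)


def standardise(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Z-score feature tables using training-set mean/SD (constant cols -> 0)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0).replace(0.0, 1.0)
    return tuple((df - mu) / sd for df in (train, *others))
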