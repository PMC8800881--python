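"""Data model, validation and file I/O for ordinal item-score matrices.

The universal input of Mokken scale analysis is an ``N x J`` matrix of
integer item scores (e.g. 1--5 Likert responses), optionally accompanied by
a cluster label per respondent (school class, hospital, neighbourhood, ...)
when the data were collected with a two-stage sampling design.

Scores are shifted to a 0-based integer coding internally.  Every
scalability and ICC statistic computed downstream is invariant to that
shift (covariances are translation invariant), so results can be reported
on the original scale without adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemScoreMatrix",
    "GroupDesign",
    "AnalysisConfig",
    "read_item_scores",
    "write_item_scores",
    "recode_reversed",
    "listwise_deletion",
]


@dataclass(frozen=True)
class ItemScoreMatrix:
    """Validated matrix of integer item scores.

    Parameters
    ----------
    scores : ndarray of shape (n_respondents, n_items)
        Integer item scores.
    item_labels : list of str
        One identifier per column.
    min_score, max_score : ndarray of shape (n_items,)
        Declared category range per item.  Defaults to the observed range.
    """

    scores: np.ndarray
    item_labels: list[str] = field(default=None)  # type: ignore[assignment]
    min_score: np.ndarray = field(default=None)  # type: ignore[assignment]
    max_score: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2:
            raise ValueError(f"scores must be 2-D, got shape {scores.shape}")
        if scores.size and not np.issubdtype(scores.dtype, np.integer):
            as_int = scores.astype(np.int64)
            if not np.array_equal(as_int, scores):
                raise ValueError("item scores must be integers")
            scores = as_int
        else:
            scores = scores.astype(np.int64)
        object.__setattr__(self, "scores", scores)
        n, j = scores.shape
        labels = self.item_labels
        if labels is None:
            labels = [f"item{k + 1}" for k in range(j)]
        labels = [str(x) for x in labels]
        if len(labels) != j:
            raise ValueError(f"{len(labels)} labels for {j} items")
        if len(set(labels)) != j:
            raise ValueError("duplicate item labels")
        object.__setattr__(self, "item_labels", labels)
        lo = self.min_score
        hi = self.max_score
        if lo is None:
            lo = scores.min(axis=0) if n else np.zeros(j, dtype=np.int64)
        if hi is None:
            hi = scores.max(axis=0) if n else np.zeros(j, dtype=np.int64)
        lo = np.asarray(lo, dtype=np.int64)
        hi = np.asarray(hi, dtype=np.int64)
        if lo.shape != (j,) or hi.shape != (j,):
            raise ValueError("min_score/max_score must have one entry per item")
        if np.any(lo > hi):
            raise ValueError("min_score exceeds max_score for some item")
        if n:
            bad = (scores < lo) | (scores > hi)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    f"score {scores[r, c]} at row {r}, item "
                    f"'{labels[c]}' outside declared range [{lo[c]}, {hi[c]}]"
                )
        object.__setattr__(self, "min_score", lo)
        object.__setattr__(self, "max_score", hi)

    @property
    def n_respondents(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def zero_based(self) -> np.ndarray:
        """Scores shifted so every item's minimum category is 0."""
        return self.scores - self.min_score[np.newaxis, :]

    def item_index(self, item: str | int) -> int:
        if isinstance(item, (int, np.integer)):
            if not 0 <= item < self.n_items:
                raise KeyError(f"item index {item} out of range")
            return int(item)
        try:
            return self.item_labels.index(item)
        except ValueError:
            raise KeyError(f"unknown item label {item!r}") from None

    def subset(self, items: Sequence[str | int]) -> "ItemScoreMatrix":
        idx = [self.item_index(i) for i in items]
        return ItemScoreMatrix(
            self.scores[:, idx],
            [self.item_labels[i] for i in idx],
            self.min_score[idx],
            self.max_score[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.item_labels)


@dataclass(frozen=True)
class GroupDesign:
    """Cluster membership of each respondent row.

    ``labels`` may be any hashable group identifiers; they are mapped to
    integer codes ``0..G-1`` in order of first appearance.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ValueError("group labels must be 1-D")
        if labels.size == 0:
            raise ValueError("empty group design")
        object.__setattr__(self, "labels", labels)
        uniques, codes = np.unique(labels, return_inverse=True)
        # preserve order of first appearance for stable reporting
        order = np.argsort([np.argmax(codes == k) for k in range(len(uniques))])
        remap = np.empty(len(uniques), dtype=np.int64)
        remap[order] = np.arange(len(uniques))
        object.__setattr__(self, "_codes", remap[codes])
        object.__setattr__(self, "_names", uniques[order])

    @property
    def codes(self) -> np.ndarray:
        return self._codes  # type: ignore[attr-defined]

    @property
    def group_names(self) -> np.ndarray:
        return self._names  # type: ignore[attr-defined]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.n_groups)

    @property
    def n_respondents(self) -> int:
        return self.labels.shape[0]

    def require_multilevel(self) -> None:
        if self.n_groups < 2:
            raise ValueError(
                "two-level analysis requires at least 2 groups, "
                f"got {self.n_groups}"
            )


@dataclass
class AnalysisConfig:
    """Settings shared by the selection procedures and the full workflow.

    alpha
        Significance level of every criterion test (default 0.05).
    lowerbounds
        Strictly increasing grid of lowerbound values ``c``; the default
        grid 0.00--0.55 in steps of 0.05 probes how stable the formed
        scales are as the scalability requirement tightens.
    method
        ``"classic"`` point-estimate-checked AISP or ``"test_guided"``
        T-AISP in which both Mokken-scale criteria are Wald-tested.
    level
        ``"one"`` (simple random sample) or ``"two"`` (clustered sample)
        standard errors.
    """

    alpha: float = 0.05
    lowerbounds: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.56, 0.05), 2))
    method: str = "test_guided"
    level: str = "one"
    test_flavor: str = "wald"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        lbs = tuple(float(c) for c in np.atleast_1d(self.lowerbounds))
        if any(not 0.0 <= c < 1.0 for c in lbs):
            raise ValueError("every lowerbound must lie in [0, 1)")
        if any(b <= a for a, b in zip(lbs, lbs[1:])):
            raise ValueError("lowerbounds must be strictly increasing")
        self.lowerbounds = lbs
        if self.method not in ("classic", "test_guided"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.level not in ("one", "two"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.test_flavor not in ("wald", "range_preserving"):
            raise ValueError(f"unknown test flavor {self.test_flavor!r}")


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_item_scores(
    path: str | Path,
    group_column: str | None = None,
    sep: str | None = None,
) -> tuple[ItemScoreMatrix, GroupDesign | None]:
    """Read a delimited score file with a header row.

    All non-group columns must parse as integers; the delimiter is derived
    from the file extension (``.tsv`` -> tab, otherwise comma) unless
    given explicitly.  Missing or non-integer cells raise a ``ValueError``
    naming the offending row and column: missing data are rejected at
    ingestion, and :func:`listwise_deletion` must be invoked deliberately.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=object,
                        keep_default_na=False)
    if frame.shape[1] < 1:
        raise ValueError(f"{path}: no columns found")
    design = None
    if group_column is not None:
        if group_column not in frame.columns:
            raise ValueError(
                f"group column {group_column!r} not in header "
                f"{list(frame.columns)}"
            )
        design = GroupDesign(frame[group_column].to_numpy())
        frame = frame.drop(columns=[group_column])
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no item columns besides the group column")
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    scores = np.empty(frame.shape, dtype=np.int64)
    for c, col in enumerate(frame.columns):
        raw = frame[col].to_numpy()
        try:
            scores[:, c] = np.array([int(v) for v in raw])
        except (TypeError, ValueError):
            for r, v in enumerate(raw):
                try:
                    int(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-integer value {v!r} in row {r}, "
                        f"column {col!r}"
                    ) from None
            raise
    matrix = ItemScoreMatrix(scores, list(frame.columns))
    return matrix, design


def write_item_scores(
    matrix: ItemScoreMatrix,
    path: str | Path,
    design: GroupDesign | None = None,
    group_column: str = "group",
    sep: str | None = None,
) -> None:
    """Write a matrix (and optional group column) back to delimited text."""
    path = Path(path)
    frame = matrix.to_frame()
    if design is not None:
        if design.n_respondents != matrix.n_respondents:
            raise ValueError("design length does not match matrix rows")
        frame[group_column] = design.labels
    frame.to_csv(path, sep=_detect_sep(path, sep), index=False)


def recode_reversed(
    matrix: ItemScoreMatrix, items: Sequence[str | int]
) -> ItemScoreMatrix:
    """Reflect reversely worded items: score ``x`` becomes ``min+max-x``.

    The category range is unchanged and applying the recode twice restores
    the original matrix.
    """
    idx = [matrix.item_index(i) for i in items]
    scores = matrix.scores.copy()
    for k in idx:
        scores[:, k] = matrix.min_score[k] + matrix.max_score[k] - scores[:, k]
    return ItemScoreMatrix(
        scores, list(matrix.item_labels), matrix.min_score, matrix.max_score
    )


def listwise_deletion(
    frame: pd.DataFrame,
    group_column: str | None = None,
) -> tuple[ItemScoreMatrix, GroupDesign | None, int]:
    """Drop rows with any missing/non-integer cell, then validate.

    Returns the matrix, the optional design and the number of rows
    removed.  This is the only supported missing-data route; the reader
    itself refuses incomplete rows so that deletion is always deliberate.
    """
    work = frame.copy()
    item_cols = [c for c in work.columns if c != group_column]

    def _as_int(v: object) -> float:
        try:
            return float(int(v))  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return np.nan

    converted = work[item_cols].map(_as_int)
    keep = ~converted.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    kept = converted[keep].to_numpy().astype(np.int64)
    if kept.shape[0] == 0:
        raise ValueError("listwise deletion removed every row")
    design = None
    if group_column is not None:
        design = GroupDesign(work.loc[keep, group_column].to_numpy())
    return ItemScoreMatrix(kept, item_cols), design, n_dropped


def as_item_matrix(X, labels=None) -> ItemScoreMatrix:
    """Coerce an array-like / DataFrame / ItemScoreMatrix to a matrix."""
    if isinstance(X, ItemScoreMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ItemScoreMatrix(X.to_numpy(), list(X.columns))
    return ItemScoreMatrix(np.asarray(X), labels)


def as_group_design(groups) -> GroupDesign | None:
    if groups is None or isinstance(groups, GroupDesign):
        return groups
    return GroupDesign(np.asarray(groups))
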