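"""Automated item selection: the classic AISP and the test-guided T-AISP.

Both procedures greedily partition items into Mokken scales, i.e. item
sets in which (Criterion 1) every item pair has positive scalability
``H_ij > 0`` and (Criterion 2) every item is sufficiently discriminating,
``H_i`` above a lowerbound ``c``:

1. *Start a scale* with the pair of unassigned items that has the highest
   ``H_ij`` among pairs for which both criteria are accepted; if no pair
   qualifies the procedure stops and the remaining items are unscalable.
2. *Extend the scale*, repeatedly adding the candidate item for which both
   criteria are accepted and that maximises the total ``H`` of the
   enlarged scale, until no candidate qualifies.
3. *Start the next scale* from the unassigned items.

The two procedures differ only in how the criteria are evaluated:

===========  ==============================  ==================================
criterion    classic AISP                    T-AISP
===========  ==============================  ==================================
1: H_ij > 0  Delta_ij >= z_crit              z_ij >= z_crit   (null H_ij <= 0)
2: H_i > c   Delta_i >= z_crit and H_i >= c  z_i >= z_crit    (null H_i <= c)
===========  ==============================  ==================================

The classic evaluation checks the lowerbound only on the point estimate,
which ignores the sampling fluctuation of ``H_i`` and tends to be too
liberal; the T-AISP Wald-tests both criteria, so it is more conservative
and, with two-level standard errors, valid for clustered samples.  With
one-level methods on clustered data the criterion tests use standard
errors that are typically too small, so a prominent warning is emitted.

``z_crit`` is Bonferroni-adjusted at every step: a running counter
accumulates all criterion tests performed in previous steps plus those of
the current step, and ``z_crit = Phi^{-1}(1 - alpha / counter)``.  The
counter and every decision are recorded in the partition's trace.  All
tie-breaks are deterministic (lexicographically smallest item indices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_data import (
    GroupDesign,
    ItemScoreMatrix,
    as_group_design,
    as_item_matrix,
)
from .scalability import DegenerateItemError, compute_scalability
from .testing import critical_value
from .uncertainty import _one_level_se, _pair_influence, _two_level_se

__all__ = [
    "ScalePartition",
    "run_aisp",
    "lowerbound_sweep",
    "LowerboundSweep",
    "MokkenScaleSelector",
]


@dataclass(frozen=True)
class ScalePartition:
    """Assignment of items to Mokken scales (0 = unscalable)."""

    assignment: np.ndarray
    lowerbound: float
    method: str  # "classic" | "test_guided"
    level: str  # "one" | "two"
    alpha: float
    item_labels: tuple[str, ...]
    trace: tuple[dict, ...]

    @property
    def n_scales(self) -> int:
        return int(self.assignment.max(initial=0))

    def scale_items(self, index: int) -> list[str]:
        return [lbl for lbl, a in zip(self.item_labels, self.assignment)
                if a == index]

    def to_series(self) -> pd.Series:
        return pd.Series(self.assignment, index=self.item_labels,
                         name=f"c={self.lowerbound:g}")


class _CriterionEngine:
    """Caches the pair-level statistics the greedy search needs.

    ``H_ij`` and its standard error never depend on which scale the items
    sit in, so they are computed once.  ``H_i`` within a candidate scale
    and its standard error are assembled on demand from cached per-pair
    covariances and influence values.
    """

    def __init__(self, matrix: ItemScoreMatrix, design: GroupDesign | None,
                 method: str, level: str):
        self.method = method
        self.level = level
        self.n = matrix.n_respondents
        z = matrix.zero_based()
        self.sd = z.std(axis=0, ddof=0)
        est = compute_scalability(matrix)
        self.cov = est.cov_pair
        self.cmax = est.covmax_pair
        self.h_pair = est.h_pair
        j = matrix.n_items
        self._a = {}
        self._b = {}
        need_se = method == "test_guided" or level == "two"
        if need_se:
            for x in range(j):
                for y in range(x + 1, j):
                    self._a[(x, y)], self._b[(x, y)] = _pair_influence(
                        z[:, x], z[:, y])
        if level == "two":
            design.require_multilevel()
            self.codes = design.codes
            self.n_groups = design.n_groups
        else:
            self.codes = None
            self.n_groups = None
        self.se_pair = np.full((j, j), np.nan)
        if need_se:
            for x in range(j):
                for y in range(x + 1, j):
                    psi = ((self._a[(x, y)]
                            - self.h_pair[x, y] * self._b[(x, y)])
                           / self.cmax[x, y])
                    self.se_pair[x, y] = self.se_pair[y, x] = self._se(psi)

    def _se(self, psi: np.ndarray) -> float:
        if self.level == "one":
            return _one_level_se(psi)
        return _two_level_se(psi, self.codes, self.n_groups)

    # -- scale-level quantities ------------------------------------------
    def scale_total_h(self, items: Iterable[int]) -> float:
        items = list(items)
        num = den = 0.0
        for a_idx, x in enumerate(items):
            for y in items[a_idx + 1:]:
                key = (min(x, y), max(x, y))
                num += self.cov[key]
                den += self.cmax[key]
        return num / den

    def item_h_in_scale(self, i: int, scale: Iterable[int]) -> tuple[float,
                                                                     float]:
        """(H_i, SE(H_i)) of item ``i`` within the given scale."""
        others = [k for k in scale if k != i]
        num = sum(self.cov[(min(i, k), max(i, k))] for k in others)
        den = sum(self.cmax[(min(i, k), max(i, k))] for k in others)
        h_i = num / den
        if not self._a:
            return h_i, np.nan
        a = np.zeros(self.n)
        b = np.zeros(self.n)
        for k in others:
            key = (min(i, k), max(i, k))
            a += self._a[key]
            b += self._b[key]
        return h_i, self._se((a - h_i * b) / den)

    def delta_pair(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        return (self.cov[key] / (self.sd[i] * self.sd[j])
                * np.sqrt(self.n - 1))

    def delta_item(self, i: int, scale: Iterable[int]) -> float:
        others = [k for k in scale if k != i]
        num = sum(self.cov[(min(i, k), max(i, k))] for k in others)
        den = self.sd[i] * sum(self.sd[k] for k in others)
        return num / den * np.sqrt(self.n - 1)

    # -- criterion evaluations -------------------------------------------
    def criterion1_pair(self, i: int, j: int, z_crit: float) -> bool:
        """H_ij > 0, tested."""
        if self.method == "classic" and self.level == "one":
            return self.delta_pair(i, j) >= z_crit
        key = (min(i, j), max(i, j))
        se = self.se_pair[key]
        return self.h_pair[key] / se >= z_crit

    def criterion2_item(self, i: int, scale: list[int], c: float,
                        z_crit: float) -> bool:
        """H_i above the lowerbound, per the method's evaluation rule."""
        if self.method == "classic":
            h_i = self.item_h_in_scale(i, scale)[0]
            if self.level == "one":
                stat = self.delta_item(i, scale)
            else:
                h_i, se = self.item_h_in_scale(i, scale)
                stat = h_i / se
            return stat >= z_crit and h_i >= c
        h_i, se = self.item_h_in_scale(i, scale)
        return (h_i - c) / se >= z_crit


def _pick_max(pairs_or_items, values):
    """First index achieving the maximum (lexicographic tie-break)."""
    best = None
    best_val = -np.inf
    for key, val in zip(pairs_or_items, values):
        if val > best_val:
            best, best_val = key, val
    return best, best_val


def run_aisp(X, groups=None, lowerbound: float = 0.3,
             method: str = "test_guided", level: str = "one",
             alpha: float = 0.05) -> ScalePartition:
    """Partition items into Mokken scales at one lowerbound ``c``.

    Parameters
    ----------
    X : array-like, DataFrame or ItemScoreMatrix
    groups : optional per-row cluster labels (required for level="two")
    lowerbound : minimum required item scalability ``c``
    method : "classic" (point-estimate check of Criterion 2) or
        "test_guided" (both criteria Wald-tested)
    level : "one" or "two" (standard errors for the criterion tests)
    alpha : familywise significance level; every step's critical value is
        Bonferroni-corrected by the running test counter

    Returns
    -------
    ScalePartition with per-item scale indices (0 = unscalable) and a
    full trace of every step's tests and decisions.
    """
    matrix = as_item_matrix(X)
    design = as_group_design(groups)
    if method not in ("classic", "test_guided"):
        raise ValueError(f"unknown method {method!r}")
    if level not in ("one", "two"):
        raise ValueError(f"unknown level {level!r}")
    if not 0.0 <= lowerbound < 1.0:
        raise ValueError("lowerbound must lie in [0, 1)")
    if level == "two" and design is None:
        raise ValueError("level='two' requires group labels")
    if level == "one" and design is not None:
        warnings.warn(
            "one-level criterion tests on clustered data: standard errors "
            "of items with large within-group dependency are likely too "
            "small, risking incorrect item admission; consider level='two'",
            UserWarning,
            stacklevel=2,
        )
    j = matrix.n_items
    assignment = np.zeros(j, dtype=int)
    trace: list[dict] = []
    z = matrix.zero_based()
    alive = [k for k in range(j) if z[:, k].var() > 0]
    dead = sorted(set(range(j)) - set(alive))
    if dead:
        warnings.warn(
            f"items with zero variance marked unscalable: "
            f"{[matrix.item_labels[k] for k in dead]}",
            UserWarning,
            stacklevel=2,
        )
    if len(alive) < 2:
        return ScalePartition(assignment, lowerbound, method, level, alpha,
                              tuple(matrix.item_labels), tuple(trace))
    sub = matrix.subset(alive)
    engine = _CriterionEngine(sub, design, method, level)
    pos = {orig: k for k, orig in enumerate(alive)}  # original -> engine idx

    counter = 0
    available = list(alive)
    scale_idx = 0
    while len(available) >= 2:
        # ---- step 1: start a scale -----------------------------------
        cand_pairs = [(a, b) for ai, a in enumerate(available)
                      for b in available[ai + 1:]]
        tests_step = 2 * len(cand_pairs)  # criterion 1 + criterion 2 per pair
        counter += tests_step
        z_crit = critical_value(alpha, counter)
        qualified, values = [], []
        for a, b in cand_pairs:
            i, k = pos[a], pos[b]
            c1 = engine.criterion1_pair(i, k, z_crit)
            # a 2-item scale has H_i = H_ij for both items, so criterion 2
            # reduces to one evaluation of the pair coefficient against c
            c2 = engine.criterion2_item(i, [i, k], lowerbound, z_crit)
            if c1 and c2:
                qualified.append((a, b))
                values.append(engine.h_pair[min(i, k), max(i, k)])
        trace.append({
            "step": "start_scale", "scale": scale_idx + 1,
            "tests_this_step": tests_step, "cumulative_tests": counter,
            "z_crit": z_crit, "n_candidates": len(cand_pairs),
            "n_qualified": len(qualified),
        })
        if not qualified:
            break
        (a, b), h_start = _pick_max(qualified, values)
        scale_idx += 1
        scale = [a, b]
        trace[-1].update(selected=(matrix.item_labels[a],
                                   matrix.item_labels[b]),
                         h_pair=h_start)
        # ---- step 2: extend the scale --------------------------------
        while True:
            candidates = [k for k in available if k not in scale]
            if not candidates:
                break
            tests_step = sum(len(scale) + 1 for _ in candidates)
            counter += tests_step
            z_crit = critical_value(alpha, counter)
            accepted, values = [], []
            for h in candidates:
                hi = pos[h]
                scale_e = [pos[s] for s in scale]
                c1 = all(engine.criterion1_pair(hi, s, z_crit)
                         for s in scale_e)
                c2 = (c1 and engine.criterion2_item(
                    hi, scale_e + [hi], lowerbound, z_crit))
                if c1 and c2:
                    accepted.append(h)
                    values.append(engine.scale_total_h(scale_e + [hi]))
            trace.append({
                "step": "extend_scale", "scale": scale_idx,
                "tests_this_step": tests_step, "cumulative_tests": counter,
                "z_crit": z_crit, "n_candidates": len(candidates),
                "n_qualified": len(accepted),
            })
            if not accepted:
                break
            pick, h_new = _pick_max(accepted, values)
            scale.append(pick)
            trace[-1].update(selected=matrix.item_labels[pick],
                             h_total=h_new)
        for k in scale:
            assignment[k] = scale_idx
        available = [k for k in available if k not in scale]
    return ScalePartition(assignment, lowerbound, method, level, alpha,
                          tuple(matrix.item_labels), tuple(trace))


@dataclass(frozen=True)
class LowerboundSweep:
    """AISP partitions across a grid of lowerbounds."""

    partitions: tuple[ScalePartition, ...]
    item_labels: tuple[str, ...] = field(default=())

    def table(self) -> pd.DataFrame:
        """Items x lowerbounds table of scale indices (0 = unscalable)."""
        return pd.concat([p.to_series() for p in self.partitions], axis=1)

    def at(self, c: float) -> ScalePartition:
        for p in self.partitions:
            if np.isclose(p.lowerbound, c):
                return p
        raise KeyError(f"no partition at lowerbound {c}")


def lowerbound_sweep(X, groups=None, lowerbounds=None,
                     method: str = "test_guided", level: str = "one",
                     alpha: float = 0.05) -> LowerboundSweep:
    """Run the (T-)AISP for every lowerbound in an increasing grid.

    The default grid is 0.00 to 0.55 in steps of 0.05.  Each run restarts
    the Bonferroni counter: the runs are separate analyses whose joint
    pattern (how scales form and dissolve as ``c`` grows) informs the
    analyst's final-scale choice.
    """
    if lowerbounds is None:
        lowerbounds = np.round(np.arange(0.0, 0.56, 0.05), 2)
    matrix = as_item_matrix(X)
    parts = tuple(
        run_aisp(matrix, groups=groups, lowerbound=float(c), method=method,
                 level=level, alpha=alpha)
        for c in np.atleast_1d(lowerbounds)
    )
    return LowerboundSweep(parts, tuple(matrix.item_labels))


class MokkenScaleSelector(BaseEstimator):
    """Greedy Mokken-scale construction as a scikit-learn estimator.

    Assigns each item (column of ``X``) a scale index, ``0`` meaning
    unscalable — analogous to a clusterer over items.

    Parameters
    ----------
    lowerbound : float, default 0.3
        Minimum required item scalability ``c``.
    method : {"test_guided", "classic"}
        Criterion evaluation rule (see module docstring).
    level : {"one", "two"}
        Standard errors for the criterion tests; "two" requires
        ``groups`` in :meth:`fit`.
    alpha : float, default 0.05
        Familywise level for the Bonferroni-corrected criterion tests.

    Attributes
    ----------
    labels_ : ndarray of shape (n_items,)
        Scale index per item (0 = unscalable).
    partition_ : ScalePartition
    trace_ : tuple of per-step records (tests counted, z_crit, decisions).
    """

    def __init__(self, lowerbound: float = 0.3, method: str = "test_guided",
                 level: str = "one", alpha: float = 0.05):
        self.lowerbound = lowerbound
        self.method = method
        self.level = level
        self.alpha = alpha

    def fit(self, X, y=None, groups=None):
        self.partition_ = run_aisp(
            X, groups=groups, lowerbound=self.lowerbound, method=self.method,
            level=self.level, alpha=self.alpha)
        self.labels_ = self.partition_.assignment
        self.trace_ = self.partition_.trace
        self.n_features_in_ = len(self.labels_)
        return self

    def fit_predict(self, X, y=None, groups=None):
        return self.fit(X, groups=groups).labels_
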