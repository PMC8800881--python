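"""Within-group dependency diagnostics: one-way ANOVA ICC and F test.

The intraclass correlation (ICC) is the expected correlation between the
test scores of two respondents from the same group.  It is estimated here
with the standard one-way ANOVA estimator

    ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW),

where MSB and MSW are the between- and within-group mean squares and

    n0 = (N - sum_g n_g^2 / N) / (G - 1)

is the usual unequal-group-size correction of the average group size.
``F = MSB / MSW`` with ``(G - 1, N - G)`` degrees of freedom tests the
null hypothesis that the ICC is zero (assuming normally distributed
scores within groups).  A significantly positive ICC means subsequent
analyses should use multilevel (two-level) methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_data import GroupDesign, as_group_design, as_item_matrix

__all__ = ["IccResult", "icc_oneway", "total_score"]


@dataclass(frozen=True)
class IccResult:
    """One-way ANOVA ICC with its F test."""

    icc: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n_groups: int
    n_respondents: int

    @property
    def significant(self) -> bool:
        # convenience at the conventional 5% level; callers with another
        # alpha should compare p_value themselves
        return self.p_value < 0.05


def icc_oneway(total_scores, design: GroupDesign,
               truncate_negative: bool = False) -> IccResult:
    """ICC(1) of a score vector under a one-way grouping.

    Negative estimates (possible when group means are more alike than
    chance) are reported as computed unless ``truncate_negative``; the F
    statistic is unaffected either way.
    """
    y = np.asarray(total_scores, dtype=float)
    if y.ndim != 1:
        raise ValueError("total_scores must be a vector")
    design = as_group_design(design)
    if design.n_respondents != len(y):
        raise ValueError("design length does not match score vector")
    design.require_multilevel()
    codes = design.codes
    g = design.n_groups
    n = len(y)
    sizes = design.group_sizes
    if (sizes == 0).any():
        raise ValueError("every group must be nonempty")
    grand = y.mean()
    means = np.bincount(codes, weights=y, minlength=g) / sizes
    ssb = float(sizes @ (means - grand) ** 2)
    ssw = float(((y - means[codes]) ** 2).sum())
    df1, df2 = g - 1, n - g
    msb = ssb / df1
    msw = ssw / df2
    n0 = (n - float(sizes @ sizes) / n) / df1
    if msw == 0.0:
        warnings.warn("zero within-group variance: F reported as infinite",
                      UserWarning, stacklevel=2)
        f = np.inf
        p = 0.0
        icc = 1.0
    else:
        f = msb / msw
        p = float(stats.f.sf(f, df1, df2))
        icc = (msb - msw) / (msb + (n0 - 1.0) * msw)
    if truncate_negative:
        icc = max(icc, 0.0)
    return IccResult(icc=float(icc), f_stat=float(f), df1=df1, df2=df2,
                     p_value=p, n_groups=g, n_respondents=n)


def total_score(X, items: Sequence[str | int] | None = None,
                scale: str = "sum") -> np.ndarray:
    """Per-respondent total over the listed items.

    ``scale="sum"`` returns the plain sum score used to order respondents;
    ``scale="mean"`` divides by the number of items (the metric in which
    Likert questionnaires report their average test score).
    """
    matrix = as_item_matrix(X)
    if items is None:
        items = list(range(matrix.n_items))
    idx = [matrix.item_index(i) for i in items]
    if not idx:
        raise ValueError("need at least one item")
    total = matrix.scores[:, idx].sum(axis=1).astype(float)
    if scale == "mean":
        return total / len(idx)
    if scale == "sum":
        return total
    raise ValueError(f"unknown scale {scale!r}")
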