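"""Point estimation of Mokken's scalability coefficients.

For ordinal items ``i`` and ``j`` the item-pair coefficient is the normed
covariance

    H_ij = S_ij / S_ij^max,

where ``S_ij`` is the observed covariance and ``S_ij^max`` the largest
covariance attainable given the two items' marginal category frequencies.
That maximum is reached by the comonotonic coupling of the two margins:
sort both items' scores and pair them rank by rank (the perfect Guttman
arrangement).  Item coefficients ``H_i`` and the total coefficient ``H``
are the corresponding ratios of summed covariances,

    H_i = sum_{j!=i} S_ij / sum_{j!=i} S_ij^max,
    H   = sum_{i<j}  S_ij / sum_{i<j}  S_ij^max,

so that min(H_ij) <= min(H_i) <= H <= max(H_i) <= max(H_ij) always holds.
Covariances use the population (divide by N) convention throughout; the
ratios are invariant to that choice.

Point estimates are identical under the one-level (simple random sample)
and two-level (clustered sample) methods; only the standard errors differ
(see :mod:`mokkenpy.uncertainty`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_data import ItemScoreMatrix, as_group_design, as_item_matrix

__all__ = [
    "max_covariance",
    "pairwise_H",
    "item_H",
    "total_H",
    "ScalabilityEstimates",
    "ScalabilityEstimator",
]


class DegenerateItemError(ValueError):
    """An item has zero sample variance, so H involving it is undefined."""


def _margin_counts(column: np.ndarray) -> np.ndarray:
    """Category frequency table of a 0-based integer score column."""
    return np.bincount(column)


def max_covariance(margin_i: np.ndarray, margin_j: np.ndarray) -> float:
    """Maximum covariance attainable by two items with the given margins.

    Parameters
    ----------
    margin_i, margin_j : array of nonnegative counts (or weights)
        Frequency of each score category ``0, 1, ..., m`` for the two
        items.  Both must have the same positive total.

    Returns
    -------
    float
        Covariance (divide-by-N convention) of the comonotonic coupling,
        i.e. of the joint table obtained by sorting both score vectors
        and pairing them rank by rank.  Zero iff either margin is
        concentrated on a single category.
    """
    mi = np.asarray(margin_i, dtype=float)
    mj = np.asarray(margin_j, dtype=float)
    if mi.ndim != 1 or mj.ndim != 1:
        raise ValueError("margins must be 1-D frequency tables")
    ni, nj = mi.sum(), mj.sum()
    if not np.isclose(ni, nj):
        raise ValueError(f"margins have different totals ({ni} vs {nj})")
    if ni < 2:
        raise ValueError("need total N >= 2 to define a covariance")
    return _max_covariance_p(mi / ni, mj / ni)


def _max_covariance_p(p: np.ndarray, q: np.ndarray) -> float:
    """Max covariance from marginal *proportions* p, q (each sums to 1)."""
    x = np.arange(len(p), dtype=float)
    y = np.arange(len(q), dtype=float)
    cp = np.concatenate(([0.0], np.cumsum(p)))
    cq = np.concatenate(([0.0], np.cumsum(q)))
    # overlap of [cp[x], cp[x+1]] with [cq[y], cq[y+1]] is the comonotonic
    # mass placed on cell (x, y)
    lo = np.maximum(cp[:-1, None], cq[None, :-1])
    hi = np.minimum(cp[1:, None], cq[None, 1:])
    lam = np.clip(hi - lo, 0.0, None)
    e_xy = float(np.einsum("i,j,ij->", x, y, lam))
    return e_xy - float(x @ p) * float(y @ q)


def _pair_stats(zi: np.ndarray, zj: np.ndarray) -> tuple[float, float]:
    """(observed covariance, max covariance) of two 0-based score columns."""
    n = len(zi)
    s_obs = float(zi @ zj) / n - zi.mean() * zj.mean()
    p = _margin_counts(zi) / n
    q = _margin_counts(zj) / n
    return s_obs, _max_covariance_p(p, q)


def _check_nondegenerate(z: np.ndarray, labels: Sequence[str]) -> None:
    var = z.var(axis=0)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        names = ", ".join(labels[k] for k in dead)
        raise DegenerateItemError(
            f"item(s) {names} have zero sample variance; "
            "H coefficients involving them are undefined"
        )


@dataclass(frozen=True)
class ScalabilityEstimates:
    """All H point estimates of a score matrix, with their ingredients.

    ``h_pair`` is a symmetric J x J table with NaN on the diagonal (H_ii
    is meaningless and deliberately not reported as 1).
    """

    h_pair: np.ndarray
    h_item: np.ndarray
    h_total: float
    cov_pair: np.ndarray
    covmax_pair: np.ndarray
    n_respondents: int
    item_labels: tuple[str, ...]

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    def pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.h_pair, index=self.item_labels,
                            columns=self.item_labels)

    def item_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"H_i": self.h_item}, index=self.item_labels)


def compute_scalability(X, labels=None) -> ScalabilityEstimates:
    """Compute all pairwise, item and total H coefficients of a matrix."""
    matrix = as_item_matrix(X, labels)
    n, j = matrix.n_respondents, matrix.n_items
    if n < 2 or j < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    z = matrix.zero_based()
    _check_nondegenerate(z, matrix.item_labels)
    cov = np.full((j, j), np.nan)
    cmax = np.full((j, j), np.nan)
    for a in range(j):
        for b in range(a + 1, j):
            s, m = _pair_stats(z[:, a], z[:, b])
            cov[a, b] = cov[b, a] = s
            cmax[a, b] = cmax[b, a] = m
    h_pair = cov / cmax
    off = ~np.eye(j, dtype=bool)
    num_item = np.where(off, cov, 0.0).sum(axis=1)
    den_item = np.where(off, cmax, 0.0).sum(axis=1)
    h_item = num_item / den_item
    iu = np.triu_indices(j, 1)
    h_total = float(cov[iu].sum() / cmax[iu].sum())
    return ScalabilityEstimates(
        h_pair=h_pair,
        h_item=h_item,
        h_total=h_total,
        cov_pair=cov,
        covmax_pair=cmax,
        n_respondents=n,
        item_labels=tuple(matrix.item_labels),
    )


def pairwise_H(X, i: str | int, j: str | int) -> float:
    """Item-pair scalability coefficient H_ij of two items of a matrix."""
    matrix = as_item_matrix(X)
    a, b = matrix.item_index(i), matrix.item_index(j)
    if a == b:
        raise ValueError("H_ii is undefined; pick two distinct items")
    z = matrix.zero_based()[:, [a, b]]
    _check_nondegenerate(z, [matrix.item_labels[a], matrix.item_labels[b]])
    s, m = _pair_stats(z[:, 0], z[:, 1])
    return s / m


def item_H(X) -> np.ndarray:
    """Vector of item scalability coefficients H_i."""
    return compute_scalability(X).h_item


def total_H(X) -> float:
    """Total-scale scalability coefficient H."""
    return compute_scalability(X).h_total


class ScalabilityEstimator(BaseEstimator):
    """Scalability coefficients with one- or two-level standard errors.

    A scikit-learn style estimator: ``fit(X, groups=...)`` computes the
    H coefficients of the item-score matrix ``X`` together with standard
    errors appropriate for the sampling design.

    Parameters
    ----------
    level : {"one", "two"}
        "one" treats rows as a simple random sample; "two" treats the
        groups passed to :meth:`fit` as the independent sampling units
        (cluster-robust standard errors).  Point estimates are identical
        under both levels.
    se_method : {"delta", "bootstrap"}
        Delta-method (default) or cluster-bootstrap standard errors.
    n_bootstrap : int
        Replicates for ``se_method="bootstrap"``.
    random_state : int or None
        Seed for the bootstrap.

    Attributes
    ----------
    h_pair_, h_item_, h_total_ : point estimates.
    se_pair_, se_item_, se_total_ : standard errors at the chosen level.
    estimates_ : :class:`ScalabilityEstimates` with all ingredients.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> theta = rng.normal(size=200)
    >>> X = (theta[:, None] > rng.normal(size=(200, 4))).astype(int)
    >>> est = ScalabilityEstimator().fit(X)
    >>> 0 < est.h_total_ <= 1
    True
    """

    def __init__(self, level: str = "one", se_method: str = "delta",
                 n_bootstrap: int = 1000, random_state: int | None = None):
        self.level = level
        self.se_method = se_method
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X, y=None, groups=None):
        from . import uncertainty  # local import to avoid a cycle

        matrix = as_item_matrix(X)
        design = as_group_design(groups)
        if self.level not in ("one", "two"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.level == "two" and design is None:
            raise ValueError("level='two' requires groups")
        self.estimates_ = compute_scalability(matrix)
        if self.se_method == "delta":
            if self.level == "one":
                ses = uncertainty.se_one_level(matrix)
            else:
                ses = uncertainty.se_two_level(matrix, design)
        elif self.se_method == "bootstrap":
            if design is None:
                raise ValueError("bootstrap SEs require groups (use "
                                 "singleton groups for i.i.d. rows)")
            ses = uncertainty.cluster_bootstrap_se(
                matrix, design, n_bootstrap=self.n_bootstrap,
                seed=self.random_state)
        else:
            raise ValueError(f"unknown se_method {self.se_method!r}")
        self.standard_errors_ = ses
        self.h_pair_ = self.estimates_.h_pair
        self.h_item_ = self.estimates_.h_item
        self.h_total_ = self.estimates_.h_total
        self.se_pair_ = ses.se_pair
        self.se_item_ = ses.se_item
        self.se_total_ = ses.se_total
        self.n_features_in_ = matrix.n_items
        return self

    def summary(self) -> pd.DataFrame:
        """Item-level table of H_i with SEs, plus the total row."""
        est = self.estimates_
        rows = pd.DataFrame(
            {"H": np.append(est.h_item, est.h_total),
             "SE": np.append(self.se_item_, self.se_total_)},
            index=list(est.item_labels) + ["Total"],
        )
        return rows
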