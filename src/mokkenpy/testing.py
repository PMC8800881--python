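"""Significance tests and confidence intervals for scalability coefficients.

Three test families are provided:

* Mokken's classical ``Delta`` statistics test marginal independence
  (null ``H <= 0``) and are valid only for simple random samples:

      Delta_ij = S_ij / (S_i S_j) * sqrt(N - 1),

  with item and total variants replacing the covariance and the product
  of standard deviations by the corresponding sums.

* Wald z tests compare a coefficient with any null value ``c`` using its
  standard error: ``z = (H_hat - c) / SE``.  With two-level standard
  errors these are valid for clustered data.

* Range-preserving z tests work on the transformed scale
  ``g(H) = log(1 - H)``, which maps the natural upper bound ``H = 1`` to
  ``-inf``; by the delta method ``SE_g = SE / (1 - H_hat)``.  The statistic
  is oriented so that larger values favour the alternative ``H > c``.

All tests are one-sided against ``H > c``; asymptotically the statistics
are standard normal under the null boundary.  Confidence intervals are
two-sided: the Wald interval is ``H_hat +/- z * SE`` and the
range-preserving interval back-transforms ``g(H_hat) +/- z * SE_g``, so
its upper bound can never exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import as_item_matrix
from .scalability import _check_nondegenerate

__all__ = [
    "TestResult",
    "ConfidenceInterval",
    "delta_statistic",
    "wald_z",
    "range_preserving_z",
    "confidence_interval",
    "critical_value",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a one-sided test of ``H <= null_value`` vs ``H > null_value``."""

    statistic: float
    flavor: str  # "delta" | "wald" | "range_preserving"
    null_value: float
    p_value: float
    alpha: float
    z_crit: float
    rejected: bool


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    flavor: str  # "wald" | "range_preserving"


def critical_value(alpha: float, n_tests: int = 1) -> float:
    """One-sided normal critical value, Bonferroni-adjusted for n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(stats.norm.ppf(1.0 - alpha / n_tests))


def _finish(statistic: float, flavor: str, null_value: float,
            alpha: float, z_crit: float | None) -> TestResult:
    if z_crit is None:
        z_crit = critical_value(alpha)
    p = float(stats.norm.sf(statistic))
    return TestResult(
        statistic=float(statistic),
        flavor=flavor,
        null_value=float(null_value),
        p_value=p,
        alpha=float(alpha),
        z_crit=float(z_crit),
        rejected=bool(statistic >= z_crit),
    )


def delta_statistic(X, scope: str = "total", i: int | str | None = None,
                    j: int | str | None = None, alpha: float = 0.05,
                    z_crit: float | None = None) -> TestResult:
    """Mokken's Delta test of marginal independence (``H <= 0`` vs ``H > 0``).

    ``scope`` is ``"pair"`` (requires ``i`` and ``j``), ``"item"``
    (requires ``i``) or ``"total"``.  Only suited for nonclustered data:
    the null distribution assumes a simple random sample.
    """
    matrix = as_item_matrix(X)
    z = matrix.zero_based()
    _check_nondegenerate(z, matrix.item_labels)
    n, n_items = z.shape
    cov = np.cov(z, rowvar=False, ddof=0)
    sd = np.sqrt(np.diag(cov))
    root = np.sqrt(n - 1)
    if scope == "pair":
        a, b = matrix.item_index(i), matrix.item_index(j)
        if a == b:
            raise ValueError("pair scope needs two distinct items")
        stat = cov[a, b] / (sd[a] * sd[b]) * root
    elif scope == "item":
        a = matrix.item_index(i)
        others = [k for k in range(n_items) if k != a]
        stat = cov[a, others].sum() / (sd[a] * sd[others].sum()) * root
    elif scope == "total":
        iu = np.triu_indices(n_items, 1)
        stat = cov[iu].sum() / (np.outer(sd, sd)[iu]).sum() * root
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return _finish(stat, "delta", 0.0, alpha, z_crit)


def wald_z(h_hat: float, se: float, c: float = 0.0, alpha: float = 0.05,
           z_crit: float | None = None) -> TestResult:
    """Wald z test of ``H <= c`` vs ``H > c``: ``z = (h_hat - c) / se``."""
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return _finish((h_hat - c) / se, "wald", c, alpha, z_crit)


def _g(h: float) -> float:
    return float(np.log1p(-h))


def _g_inv(y: float) -> float:
    return float(1.0 - np.exp(y))


def range_preserving_z(h_hat: float, se: float, c: float = 0.0,
                       alpha: float = 0.05,
                       z_crit: float | None = None) -> TestResult:
    """Range-preserving z test of ``H <= c`` vs ``H > c``.

    Uses ``g(H) = log(1 - H)`` with ``SE_g = SE / (1 - h_hat)``; oriented
    so that the statistic is positive when ``h_hat > c`` (g is
    decreasing).  Requires ``h_hat < 1``.
    """
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    if h_hat >= 1:
        raise ValueError("range-preserving test requires h_hat < 1")
    if c >= 1:
        raise ValueError("null value must be < 1")
    se_g = se / (1.0 - h_hat)
    stat = (_g(c) - _g(h_hat)) / se_g
    return _finish(stat, "range_preserving", c, alpha, z_crit)


def confidence_interval(h_hat: float, se: float, level: float = 0.95,
                        flavor: str = "wald") -> ConfidenceInterval:
    """Two-sided confidence interval for a scalability coefficient.

    ``flavor="wald"`` gives ``h_hat +/- z * se``; it can exceed the
    natural maximum of 1 when ``h_hat`` is large or ``se`` wide.
    ``flavor="range_preserving"`` back-transforms a symmetric interval on
    the ``log(1 - H)`` scale, so its upper bound is always below 1.
    """
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    if flavor == "wald":
        return ConfidenceInterval(h_hat - z * se, h_hat + z * se, level,
                                  "wald")
    if flavor == "range_preserving":
        if h_hat >= 1:
            raise ValueError("range-preserving interval requires h_hat < 1")
        se_g = se / (1.0 - h_hat)
        gl, gu = _g(h_hat) - z * se_g, _g(h_hat) + z * se_g
        lo, hi = sorted((_g_inv(gl), _g_inv(gu)))
        return ConfidenceInterval(lo, hi, level, "range_preserving")
    raise ValueError(f"unknown CI flavor {flavor!r}")
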