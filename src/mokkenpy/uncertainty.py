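"""Standard errors of scalability coefficients.

One-level standard errors treat respondent rows as an i.i.d. sample; they
are appropriate for data collected by simple random sampling.  Two-level
standard errors treat the *groups* of a clustered design (classes,
hospitals, neighbourhoods) as the independent sampling units, which
captures the extra variation that positive within-group dependency adds.
Point estimates are identical under both levels; ignoring clustering only
biases the standard errors (typically downward), so confidence intervals
become too narrow and tests too liberal.

Construction
------------
Every H coefficient is a smooth ratio of the observed inter-item
covariances ``S_ij`` and the margin-determined maximum covariances
``S_ij^max``, both plug-in functionals of the empirical distribution of
score rows.  We linearise: for each respondent row ``r`` we compute the
empirical influence value ``psi_r`` of the coefficient (the Gateaux
derivative of the functional toward the point mass at that row).  Then

    one-level:  Var(H) ~= sum_r (psi_r - mean psi)^2 / N^2
    two-level:  Var(H) ~= G/(G-1) * sum_g T_g^2 / N^2,
                T_g = sum_{r in g} (psi_r - mean psi),

the standard cluster-robust variance of a mean of influence values.  The
influence of ``S_ij`` is closed-form; the influence of ``S_ij^max`` (a
piecewise-linear functional of the two margins, attained by the
comonotonic coupling) is computed as an exact one-sided directional
derivative.  The cluster bootstrap below is the in-repo ground truth used
to validate this construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import GroupDesign, ItemScoreMatrix, as_group_design, as_item_matrix
from .scalability import (
    DegenerateItemError,
    ScalabilityEstimates,
    _check_nondegenerate,
    compute_scalability,
)

__all__ = [
    "ScalabilitySEs",
    "se_one_level",
    "se_two_level",
    "cluster_bootstrap_se",
]


@dataclass(frozen=True)
class ScalabilitySEs:
    """Standard errors for every H coefficient of a matrix.

    ``se_pair`` is a symmetric J x J table (NaN diagonal), ``se_item`` a
    length-J vector and ``se_total`` a scalar.  ``level`` records whether
    rows ("one") or groups ("two") were the sampling units, ``se_method``
    whether the delta method or the cluster bootstrap produced them.
    """

    se_pair: np.ndarray
    se_item: np.ndarray
    se_total: float
    level: str
    se_method: str
    n_bootstrap: int | None = None
    seed: int | None = None


def _cum_slopes(cum: np.ndarray, x: int) -> np.ndarray:
    """d/d eps of the cumulative proportions along (delta_x - p)."""
    k = len(cum)
    ind = (np.arange(k) >= x).astype(float)
    return ind - cum


def _maxcov_directional(p: np.ndarray, q: np.ndarray,
                        cp: np.ndarray, cq: np.ndarray,
                        mu_x: float, mu_y: float) -> np.ndarray:
    """One-sided derivative of S^max toward the point mass at each cell.

    Returns a (K_i, K_j) table D with D[x, y] the right directional
    derivative of the max covariance when the empirical distribution is
    tilted toward a respondent scoring (x, y).  Exact also at ties of the
    two cumulative distributions (where S^max is merely one-sided
    differentiable); the comonotonic-coupling functional is piecewise
    linear so no step size is involved.
    """
    ki, kj = len(p), len(q)
    xs = np.arange(ki, dtype=float)
    ys = np.arange(kj, dtype=float)
    cp0 = np.concatenate(([0.0], cp))   # cp0[x] = F_X(x-1)
    cq0 = np.concatenate(([0.0], cq))
    # static pieces of the overlap lambda_{ab} = clip(min(cp[a], cq[b])
    #                       - max(cp0[a], cq0[b]), 0)
    lo = np.maximum(cp0[:-1, None], cq0[None, :-1])
    hi = np.minimum(cp[:, None], cq[None, :])
    lam = hi - lo
    pos = lam > 1e-12
    zero = np.abs(lam) <= 1e-12
    tie_hi = np.isclose(cp[:, None], cq[None, :], atol=1e-12)
    hi_from_p = cp[:, None] < cq[None, :] - 1e-12
    tie_lo = np.isclose(cp0[:-1, None], cq0[None, :-1], atol=1e-12)
    lo_from_p = cp0[:-1, None] > cq0[None, :-1] + 1e-12
    out = np.empty((ki, kj))
    for x in range(ki):
        du = _cum_slopes(cp, x)           # slopes of F_X at each category
        du0 = np.concatenate(([0.0], du))
        for y in range(kj):
            dv = _cum_slopes(cq, y)
            dv0 = np.concatenate(([0.0], dv))
            dhi = np.where(hi_from_p, du[:, None],
                           np.broadcast_to(dv[None, :], (ki, kj)))
            dhi = np.where(tie_hi, np.minimum(du[:, None], dv[None, :]), dhi)
            dlo = np.where(lo_from_p, du0[:-1, None],
                           np.broadcast_to(dv0[None, :-1], (ki, kj)))
            dlo = np.where(tie_lo, np.maximum(du0[:-1, None],
                                              dv0[None, :-1]), dlo)
            dlam = dhi - dlo
            dlam = np.where(pos, dlam,
                            np.where(zero, np.maximum(dlam, 0.0), 0.0))
            d_exy = float(np.einsum("a,b,ab->", xs, ys, dlam))
            d_mu = (x - mu_x) * mu_y + mu_x * (y - mu_y)
            out[x, y] = d_exy - d_mu
    return out


def _pair_influence(zi: np.ndarray, zj: np.ndarray) -> tuple[np.ndarray,
                                                             np.ndarray]:
    """Per-row influence values of (S_ij, S_ij^max) for one item pair."""
    n = len(zi)
    ki = int(zi.max()) + 1
    kj = int(zj.max()) + 1
    p = np.bincount(zi, minlength=ki) / n
    q = np.bincount(zj, minlength=kj) / n
    mu_x = float(np.arange(ki) @ p)
    mu_y = float(np.arange(kj) @ q)
    s_obs = float(zi @ zj) / n - mu_x * mu_y
    a = (zi - mu_x) * (zj - mu_y) - s_obs
    cp, cq = np.cumsum(p), np.cumsum(q)
    d_table = _maxcov_directional(p, q, cp, cq, mu_x, mu_y)
    b = d_table[zi, zj]
    return a, b


def _influence_values(matrix: ItemScoreMatrix,
                      est: ScalabilityEstimates) -> dict[str, np.ndarray]:
    """Influence values psi_r of every H_ij, H_i and H.

    For a ratio H = A/B with per-row influences a_r (numerator) and b_r
    (denominator), psi_r = (a_r - H b_r) / B.
    """
    z = matrix.zero_based()
    n, j = z.shape
    a_pair = {}
    b_pair = {}
    for x in range(j):
        for y in range(x + 1, j):
            a_pair[(x, y)], b_pair[(x, y)] = _pair_influence(z[:, x], z[:, y])
    psi_pair = np.full((j, j, n), np.nan)
    for (x, y), a in a_pair.items():
        h = est.h_pair[x, y]
        psi = (a - h * b_pair[(x, y)]) / est.covmax_pair[x, y]
        psi_pair[x, y] = psi_pair[y, x] = psi
    psi_item = np.empty((j, n))
    for i in range(j):
        num = np.zeros(n)
        den = np.zeros(n)
        dtot = 0.0
        for k in range(j):
            if k == i:
                continue
            key = (min(i, k), max(i, k))
            num += a_pair[key]
            den += b_pair[key]
            dtot += est.covmax_pair[key]
        psi_item[i] = (num - est.h_item[i] * den) / dtot
    num = np.zeros(n)
    den = np.zeros(n)
    dtot = 0.0
    for key, a in a_pair.items():
        num += a
        den += b_pair[key]
        dtot += est.covmax_pair[key]
    psi_total = (num - est.h_total * den) / dtot
    return {"pair": psi_pair, "item": psi_item, "total": psi_total}


def _one_level_se(psi: np.ndarray) -> float:
    psi = psi - psi.mean()
    n = len(psi)
    return float(np.sqrt((psi @ psi)) / n)


def _two_level_se(psi: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    psi = psi - psi.mean()
    totals = np.bincount(codes, weights=psi, minlength=n_groups)
    g = n_groups
    n = len(psi)
    return float(np.sqrt(g / (g - 1) * (totals @ totals)) / n)


def _assemble(matrix: ItemScoreMatrix, level: str,
              codes: np.ndarray | None = None,
              n_groups: int | None = None) -> ScalabilitySEs:
    est = compute_scalability(matrix)
    psis = _influence_values(matrix, est)
    j = matrix.n_items
    se_pair = np.full((j, j), np.nan)
    for x in range(j):
        for y in range(x + 1, j):
            psi = psis["pair"][x, y]
            se = (_one_level_se(psi) if level == "one"
                  else _two_level_se(psi, codes, n_groups))
            se_pair[x, y] = se_pair[y, x] = se
    if level == "one":
        se_item = np.array([_one_level_se(psis["item"][i]) for i in range(j)])
        se_total = _one_level_se(psis["total"])
    else:
        se_item = np.array([_two_level_se(psis["item"][i], codes, n_groups)
                            for i in range(j)])
        se_total = _two_level_se(psis["total"], codes, n_groups)
    return ScalabilitySEs(se_pair=se_pair, se_item=se_item,
                          se_total=se_total, level=level, se_method="delta")


def se_one_level(X) -> ScalabilitySEs:
    """Delta-method SEs treating respondent rows as an i.i.d. sample."""
    matrix = as_item_matrix(X)
    if matrix.n_respondents < 3:
        raise ValueError("need N >= 3 to estimate one-level standard errors")
    _check_nondegenerate(matrix.zero_based(), matrix.item_labels)
    return _assemble(matrix, "one")


def se_two_level(X, design: GroupDesign) -> ScalabilitySEs:
    """Cluster-robust delta-method SEs with groups as sampling units."""
    matrix = as_item_matrix(X)
    design = as_group_design(design)
    if design is None:
        raise ValueError("two-level standard errors require a group design")
    if design.n_respondents != matrix.n_respondents:
        raise ValueError("group design length does not match matrix rows")
    design.require_multilevel()
    _check_nondegenerate(matrix.zero_based(), matrix.item_labels)
    return _assemble(matrix, "two", design.codes, design.n_groups)


def cluster_bootstrap_se(X, design: GroupDesign, n_bootstrap: int = 1000,
                         seed: int | None = None,
                         max_redraw_factor: int = 10) -> ScalabilitySEs:
    """Nonparametric cluster-bootstrap SEs (groups resampled whole).

    Resamples G groups with replacement, recomputes every H per replicate
    and returns the standard deviations across replicates.  A replicate in
    which some item is degenerate is redrawn; redraws are capped at
    ``max_redraw_factor * n_bootstrap``.  Bit-reproducible given ``seed``.
    """
    matrix = as_item_matrix(X)
    design = as_group_design(design)
    design.require_multilevel()
    if n_bootstrap < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    _check_nondegenerate(matrix.zero_based(), matrix.item_labels)
    rng = np.random.default_rng(seed)
    g = design.n_groups
    codes = design.codes
    rows_by_group = [np.flatnonzero(codes == k) for k in range(g)]
    j = matrix.n_items
    h_pairs = np.empty((n_bootstrap, j, j))
    h_items = np.empty((n_bootstrap, j))
    h_tot = np.empty(n_bootstrap)
    draws = 0
    limit = max_redraw_factor * n_bootstrap
    b = 0
    while b < n_bootstrap:
        draws += 1
        if draws > limit:
            raise RuntimeError(
                "too many degenerate bootstrap replicates; the data are "
                "too sparse for a cluster bootstrap"
            )
        pick = rng.integers(0, g, size=g)
        rows = np.concatenate([rows_by_group[k] for k in pick])
        sub = ItemScoreMatrix(matrix.scores[rows], list(matrix.item_labels),
                              matrix.min_score, matrix.max_score)
        try:
            est = compute_scalability(sub)
        except DegenerateItemError:
            continue
        h_pairs[b] = est.h_pair
        h_items[b] = est.h_item
        h_tot[b] = est.h_total
        b += 1
    se_pair = h_pairs.std(axis=0, ddof=1)
    np.fill_diagonal(se_pair, np.nan)
    return ScalabilitySEs(
        se_pair=se_pair,
        se_item=h_items.std(axis=0, ddof=1),
        se_total=float(h_tot.std(ddof=1)),
        level="two",
        se_method="bootstrap",
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
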