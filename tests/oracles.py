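"""Independent brute-force oracles used by the test suite.

These recompute quantities by enumeration or plain arithmetic, staying
away from the implementation paths they validate.
"""

from __future__ import annotations

import numpy as np

import mokkenpy as mp
from mokkenpy.core_data import as_item_matrix


def exhaustive_max_covariance(margin_i, margin_j):
    """Max covariance over ALL integer joint tables with the given margins.

    Enumerates every contingency table by recursive row filling and takes
    the maximum of the (divide-by-N) covariance.
    """
    mi = np.asarray(margin_i, dtype=int)
    mj = np.asarray(margin_j, dtype=int)
    n = mi.sum()
    assert n == mj.sum() and n >= 2
    ki, kj = len(mi), len(mj)
    mu_x = (np.arange(ki) @ mi) / n
    mu_y = (np.arange(kj) @ mj) / n
    best = -np.inf

    col_left = mj.copy()

    def fill_row(x, exy):
        nonlocal best
        if x == ki:
            best = max(best, exy / n - mu_x * mu_y)
            return
        row_total = mi[x]

        def fill_cell(y, left, acc):
            if y == kj - 1:
                if left <= col_left[y]:
                    col_left[y] -= left
                    fill_row(x + 1, acc + x * y * left)
                    col_left[y] += left
                return
            for v in range(min(left, col_left[y]) + 1):
                col_left[y] -= v
                fill_cell(y + 1, left - v, acc + x * y * v)
                col_left[y] += v

        fill_cell(0, row_total, exy)

    fill_row(0, 0.0)
    return best


def brute_force_H(scores):
    """H coefficients by direct tabulation, independent of the library path.

    Covariances from np.cov (population convention); max covariances from
    sorting both columns and pairing rank by rank (the explicit Guttman
    arrangement), not from the cumulative-overlap formula.
    """
    z = np.asarray(scores, dtype=float)
    n, j = z.shape
    cov = np.cov(z, rowvar=False, ddof=0)
    cmax = np.full((j, j), np.nan)
    for a in range(j):
        for b in range(a + 1, j):
            xa = np.sort(z[:, a])
            xb = np.sort(z[:, b])
            cmax[a, b] = cmax[b, a] = (xa @ xb) / n - xa.mean() * xb.mean()
    h_pair = np.where(np.eye(j, dtype=bool), np.nan, cov / cmax)
    num = np.nansum(np.where(np.eye(j, dtype=bool), np.nan, cov), axis=1)
    den = np.nansum(cmax, axis=1)
    h_item = num / den
    iu = np.triu_indices(j, 1)
    h_total = cov[iu].sum() / cmax[iu].sum()
    return h_pair, h_item, h_total


def greedy_selection_oracle(X, groups=None, lowerbound=0.3,
                            method="test_guided", level="one", alpha=0.05):
    """Plain re-derivation of the greedy (T-)AISP from public primitives.

    Uses whole-submatrix standard-error calls and explicit loops; shares
    no code with mokkenpy.selection.
    """
    matrix = as_item_matrix(X)
    j = matrix.n_items

    def se_of(sub):
        if level == "one":
            return mp.se_one_level(sub)
        return mp.se_two_level(sub, groups)

    full_est = mp.compute_scalability(matrix)
    need_se = method == "test_guided" or level == "two"
    full_se = se_of(matrix) if need_se else None
    z = matrix.zero_based().astype(float)
    sd = z.std(axis=0, ddof=0)
    root = np.sqrt(matrix.n_respondents - 1)
    cov = full_est.cov_pair

    def crit1(a, b, zc):
        if method == "classic" and level == "one":
            return cov[a, b] / (sd[a] * sd[b]) * root >= zc
        return full_est.h_pair[a, b] / full_se.se_pair[a, b] >= zc

    def crit2(i, scale, zc):
        sub_items = sorted(scale)
        sub = matrix.subset(sub_items)
        est = mp.compute_scalability(sub)
        k = sub_items.index(i)
        h_i = est.h_item[k]
        if method == "classic":
            if level == "one":
                others = [t for t in sub_items if t != i]
                stat = (sum(cov[i, t] for t in others)
                        / (sd[i] * sum(sd[t] for t in others)) * root)
            else:
                stat = h_i / se_of(sub).se_item[k]
            return stat >= zc and h_i >= lowerbound
        return (h_i - lowerbound) / se_of(sub).se_item[k] >= zc

    assignment = np.zeros(j, dtype=int)
    available = list(range(j))
    counter = 0
    scale_no = 0
    while len(available) >= 2:
        pairs = [(a, b) for ia, a in enumerate(available)
                 for b in available[ia + 1:]]
        counter += 2 * len(pairs)
        zc = mp.critical_value(alpha, counter)
        best, best_h = None, -np.inf
        for a, b in pairs:
            if crit1(a, b, zc) and crit2(a, [a, b], zc):
                h = full_est.h_pair[a, b]
                if h > best_h:
                    best, best_h = (a, b), h
        if best is None:
            break
        scale_no += 1
        scale = list(best)
        while True:
            candidates = [k for k in available if k not in scale]
            if not candidates:
                break
            counter += sum(len(scale) + 1 for _ in candidates)
            zc = mp.critical_value(alpha, counter)
            pick, pick_h = None, -np.inf
            for h_item in candidates:
                if not all(crit1(min(h_item, s), max(h_item, s), zc)
                           for s in scale):
                    continue
                if not crit2(h_item, scale + [h_item], zc):
                    continue
                enlarged = sorted(scale + [h_item])
                h_tot = mp.compute_scalability(
                    matrix.subset(enlarged)).h_total
                if h_tot > pick_h:
                    pick, pick_h = h_item, h_tot
            if pick is None:
                break
            scale.append(pick)
        for k in scale:
            assignment[k] = scale_no
        available = [k for k in available if k not in scale]
    return assignment
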