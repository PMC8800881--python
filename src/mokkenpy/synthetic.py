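"""Synthetic clustered polytomous item scores with known structure.

The generator draws from a multilevel graded response model (GRM): the
latent trait of respondent ``r`` in group ``g`` is

    theta_gr = tau_g + eps_gr,   Var(tau) = rho,  Var(eps) = 1 - rho,

so the total latent variance is 1 and ``rho`` is the latent intraclass
correlation (the share of trait variance between groups).  Item ``i`` with
discrimination ``a_i > 0`` and ordered thresholds ``b_i1 < ... < b_im``
produces a score in ``0..m`` with cumulative category probabilities

    P(X_i >= k | theta) = link(a_i (theta - b_ik)),

logistic by default (probit optional).  Two-dimensional specs split the
items over two traits with a chosen between-dimension correlation, which
reproduces the typical sweep pattern of multidimensional questionnaires
(one big scale at small lowerbounds, splitting in two as ``c`` grows).

The observable ICC of a total score is attenuated relative to ``rho``
(categorisation adds within-group noise); it is measured empirically,
never asserted equal to ``rho``.

:func:`population_H` integrates the model-implied joint category
probabilities over the latent distribution (Gauss-Hermite quadrature) and
returns the population scalability coefficients — an oracle for checking
that sample estimates converge to the right values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .core_data import GroupDesign, ItemScoreMatrix

__all__ = ["MultilevelGrmSpec", "simulate", "population_H", "default_spec"]


@dataclass(frozen=True)
class MultilevelGrmSpec:
    """Population description of a multilevel graded response model.

    group_sizes : int or sequence
        Constant size for every one of ``n_groups`` groups, or explicit
        per-group sizes.
    icc : float in [0, 1)
        Latent-trait intraclass correlation ``rho``.
    discriminations : per-item slopes ``a_i > 0``.
    thresholds : per-item strictly increasing arrays ``b_ik``; an item
        with ``m`` thresholds has ``m + 1`` score categories ``0..m``.
    item_dims : optional per-item dimension index (0 or 1); all zeros
        means unidimensional.
    dim_correlation : correlation between the two latent dimensions.
    link : "logistic" (default) or "probit".
    """

    n_groups: int
    group_sizes: int | tuple[int, ...]
    icc: float
    discriminations: tuple[float, ...]
    thresholds: tuple[tuple[float, ...], ...]
    item_dims: tuple[int, ...] | None = None
    dim_correlation: float = 1.0
    link: str = "logistic"
    item_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        if len(self.discriminations) != len(self.thresholds):
            raise ValueError("one discrimination per threshold set")
        if any(a <= 0 for a in self.discriminations):
            raise ValueError("discriminations must be positive")
        for b in self.thresholds:
            if len(b) < 1 or any(u >= v for u, v in zip(b, b[1:])) is True:
                raise ValueError("thresholds must be nonempty and "
                                 "strictly increasing")
        if self.item_dims is not None:
            if len(self.item_dims) != self.n_items:
                raise ValueError("one dimension index per item")
            if any(d not in (0, 1) for d in self.item_dims):
                raise ValueError("dimension indices must be 0 or 1")
        if not -1.0 <= self.dim_correlation <= 1.0:
            raise ValueError("dim_correlation must lie in [-1, 1]")
        if self.link not in ("logistic", "probit"):
            raise ValueError(f"unknown link {self.link!r}")

    @property
    def n_items(self) -> int:
        return len(self.discriminations)

    @property
    def sizes(self) -> np.ndarray:
        if isinstance(self.group_sizes, (int, np.integer)):
            return np.full(self.n_groups, int(self.group_sizes))
        sizes = np.asarray(self.group_sizes, dtype=int)
        if len(sizes) != self.n_groups:
            raise ValueError("one size per group")
        return sizes

    @property
    def dims(self) -> np.ndarray:
        if self.item_dims is None:
            return np.zeros(self.n_items, dtype=int)
        return np.asarray(self.item_dims, dtype=int)

    @property
    def labels(self) -> list[str]:
        if self.item_labels is not None:
            return list(self.item_labels)
        return [f"item{k + 1}" for k in range(self.n_items)]


def default_spec(n_groups: int = 30, group_size: int = 20, icc: float = 0.3,
                 n_items: int = 6, n_categories: int = 5,
                 discrimination: float = 1.5,
                 two_dimensional: bool = False,
                 dim_correlation: float = 0.4) -> MultilevelGrmSpec:
    """A realistic questionnaire-style spec.

    Defaults mirror common quality-of-life survey conditions: 30 groups of
    20 respondents (classroom-sized clusters), latent ICC 0.3 (mid-range
    of the 0-0.5 band typical for such measures), five-category Likert
    items with moderately strong discrimination 1.5, thresholds evenly
    spread over [-1.5, 1.5] with small per-item offsets.
    """
    m = n_categories - 1
    base = np.linspace(-1.5, 1.5, m)
    thresholds = tuple(tuple(base + 0.2 * ((k % 3) - 1))
                       for k in range(n_items))
    dims = None
    if two_dimensional:
        dims = tuple(int(k >= n_items / 2) for k in range(n_items))
    return MultilevelGrmSpec(
        n_groups=n_groups,
        group_sizes=group_size,
        icc=icc,
        discriminations=tuple([discrimination] * n_items),
        thresholds=thresholds,
        item_dims=dims,
        dim_correlation=dim_correlation if two_dimensional else 1.0,
    )


def _cdf(x: np.ndarray, link: str) -> np.ndarray:
    if link == "logistic":
        return special.expit(x)
    return stats.norm.cdf(x)


def _category_probs(theta: np.ndarray, a: float, b: np.ndarray,
                    link: str) -> np.ndarray:
    """P(X = k | theta) for k = 0..m; theta may be any shape."""
    cum = _cdf(a * (theta[..., None] - b), link)  # P(X >= k+1)
    upper = np.concatenate([np.ones_like(theta[..., None]), cum], axis=-1)
    lower = np.concatenate([cum, np.zeros_like(theta[..., None])], axis=-1)
    return upper - lower


def simulate(spec: MultilevelGrmSpec,
             seed: int | np.random.Generator | None = None
             ) -> tuple[ItemScoreMatrix, GroupDesign]:
    """Draw one clustered sample from the model. Reproducible given seed."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sizes = spec.sizes
    n = int(sizes.sum())
    codes = np.repeat(np.arange(spec.n_groups), sizes)
    rho = spec.icc
    r = spec.dim_correlation
    # lower-triangular factor of [[1, r], [r, 1]]; valid also at |r| = 1
    chol = np.array([[1.0, 0.0], [r, np.sqrt(max(0.0, 1.0 - r * r))]])
    tau = (rng.standard_normal((spec.n_groups, 2)) @ chol.T) * np.sqrt(rho)
    eps = (rng.standard_normal((n, 2)) @ chol.T) * np.sqrt(1.0 - rho)
    theta = tau[codes] + eps  # (n, 2); columns share correlation r
    scores = np.empty((n, spec.n_items), dtype=np.int64)
    dims = spec.dims
    for k in range(spec.n_items):
        b = np.asarray(spec.thresholds[k], dtype=float)
        probs = _category_probs(theta[:, dims[k]], spec.discriminations[k],
                                b, spec.link)
        cum = np.cumsum(probs, axis=-1)
        u = rng.random(n)
        scores[:, k] = (u[:, None] > cum).sum(axis=1)
    matrix = ItemScoreMatrix(
        scores, spec.labels,
        min_score=np.zeros(spec.n_items, dtype=np.int64),
        max_score=np.array([len(b) for b in spec.thresholds],
                           dtype=np.int64),
    )
    return matrix, GroupDesign(codes)


def _quad_1d(n_points: int = 61) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_points)
    return nodes, weights / weights.sum()


def population_H(spec: MultilevelGrmSpec, n_points: int = 61
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Model-implied (population) scalability coefficients.

    Integrates the joint category probabilities of every item pair over
    the latent distribution (probabilist's Gauss-Hermite rule; a tensor
    grid over the correlated bivariate normal when items load on two
    dimensions), then forms population covariances and maximum covariances
    and hence ``H_ij``, ``H_i`` and ``H``.

    Returns ``(h_pair, h_item, h_total)``; raises if the quadrature is too
    coarse for the marginals to be coherent.
    """
    from .scalability import _max_covariance_p

    j = spec.n_items
    dims = spec.dims
    nodes, w = _quad_1d(n_points)
    r = spec.dim_correlation
    # per-item category probabilities at 1-D nodes (own dimension)
    pk_at = [
        _category_probs(nodes, spec.discriminations[k],
                        np.asarray(spec.thresholds[k], float), spec.link)
        for k in range(j)
    ]
    margins = [w @ pk_at[k] for k in range(j)]
    for k, m in enumerate(margins):
        if abs(m.sum() - 1.0) > 1e-8:
            raise ArithmeticError(f"quadrature failed for item {k}")
    mus = [float(np.arange(len(m)) @ m) for m in margins]
    cov = np.full((j, j), np.nan)
    cmax = np.full((j, j), np.nan)
    if (dims != dims[0]).any() and abs(r) < 1.0:
        # 2-D tensor grid: theta2 | theta1 ~ N(r*theta1, 1 - r^2)
        cond = nodes[:, None] * r + np.sqrt(1 - r * r) * nodes[None, :]
        pk_cond = {
            k: _category_probs(cond, spec.discriminations[k],
                               np.asarray(spec.thresholds[k], float),
                               spec.link)
            for k in range(j) if dims[k] == 1
        }
    for x in range(j):
        for y in range(x + 1, j):
            same = dims[x] == dims[y] or abs(r) >= 1.0
            if same:
                e_xy = float(np.einsum(
                    "q,qa,qb,a,b->", w, pk_at[x], pk_at[y],
                    np.arange(pk_at[x].shape[1], dtype=float),
                    np.arange(pk_at[y].shape[1], dtype=float)))
            else:
                first, second = (x, y) if dims[x] == 0 else (y, x)
                # E[X Y] = sum_q w_q X(q) * E_w'[Y(cond(q, q'))]
                ey_cond = np.einsum(
                    "p,qpb,b->q", w, pk_cond[second],
                    np.arange(pk_at[second].shape[1], dtype=float))
                ex_node = pk_at[first] @ np.arange(
                    pk_at[first].shape[1], dtype=float)
                e_xy = float(w @ (ex_node * ey_cond))
            cov[x, y] = cov[y, x] = e_xy - mus[x] * mus[y]
            cmax[x, y] = cmax[y, x] = _max_covariance_p(
                np.clip(margins[x], 0, None) / margins[x].sum(),
                np.clip(margins[y], 0, None) / margins[y].sum())
    h_pair = cov / cmax
    off = ~np.eye(j, dtype=bool)
    h_item = (np.where(off, cov, 0.0).sum(axis=1)
              / np.where(off, cmax, 0.0).sum(axis=1))
    iu = np.triu_indices(j, 1)
    h_total = float(cov[iu].sum() / cmax[iu].sum())
    return h_pair, h_item, h_total
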