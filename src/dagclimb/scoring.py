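"""Z-score standardization and the decomposable linear-Gaussian BIC.

Every node ``X_i`` with parent set ``Pa(X_i)`` is modelled as a linear
regression on its parents with Gaussian residuals,

    X_i = b0 + sum_{X_j in Pa(X_i)} b_j X_j + e,   e ~ N(0, sigma^2),

and scored by the local Bayesian information criterion

    BIC(X_i, Pa(X_i)) = -(n/2) [ln(2 pi) + 1 + ln(RSS/n)] - ((k+2)/2) ln(n)

where ``RSS`` is the residual sum of squares of the fit, ``n`` the sample
size, and ``k = |Pa(X_i)|``.  The ``k+2`` penalty counts the intercept and
the residual-variance parameter alongside the ``k`` slopes.  The score of a
whole DAG is the sum of local scores over nodes; this decomposability is
what makes single-edge hill-climb moves cheap to evaluate (only the
children whose parent sets change need rescoring).

All scoring operates on a column-standardized matrix; standardization uses
the sample standard deviation (divisor n-1).  Perfectly collinear children
drive RSS to zero and the score to +infinity, so RSS is floored at
``RSS_FLOOR_SCALE * n`` (with a logged warning) before the logarithm.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dag import DirectedGraph

__all__ = [
    "StandardizedDataset",
    "LocalFit",
    "ScoreCache",
    "standardize",
    "fit_local",
    "local_bic",
    "graph_score",
    "score_delta",
    "RSS_FLOOR_SCALE",
]

logger = logging.getLogger(__name__)

# floor on RSS (as a multiple of n) guarding ln(RSS/n) against -inf
RSS_FLOOR_SCALE = 1e-10


@dataclass
class StandardizedDataset:
    """An n x p column-standardized numeric matrix with variable names.

    The sole data currency of scoring, search and path-model fitting.
    Construct via :func:`standardize`; direct construction skips validation
    (useful for deliberately non-standard inputs in controlled settings).
    """

    values: np.ndarray
    columns: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.columns = list(self.columns)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values must be n x p with one column per name")
        self._index = {c: i for i, c in enumerate(self.columns)}

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self._index[name]]

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        return self.values[:, [self._index[c] for c in names]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    def validate(self, atol: float = 1e-8) -> None:
        means = self.values.mean(axis=0)
        sds = self.values.std(axis=0, ddof=1)
        bad_mean = np.flatnonzero(np.abs(means) > atol)
        bad_sd = np.flatnonzero(np.abs(sds - 1.0) > atol)
        if bad_mean.size or bad_sd.size:
            offenders = sorted({self.columns[i] for i in np.concatenate([bad_mean, bad_sd])})
            raise ValueError(f"columns not standardized: {offenders}")


def standardize(table, columns: Sequence[str] | None = None) -> StandardizedDataset:
    """Z-score each column: ``(x - mean) / sd`` with sample sd (divisor n-1).

    Accepts a DataFrame or a 2-D array (with ``columns`` names).  Rows with
    missing values must have been removed upstream (listwise deletion);
    remaining NaNs raise.  Constant columns cannot be standardized and
    raise, naming the column.
    """
    if isinstance(table, pd.DataFrame):
        columns = [str(c) for c in table.columns]
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        if columns is None:
            columns = [f"x{i}" for i in range(values.shape[1])]
        columns = list(columns)
    if values.ndim != 2:
        raise ValueError("expected a 2-D table")
    n = values.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 rows to standardize, got {n}")
    if np.isnan(values).any():
        bad = [columns[j] for j in np.flatnonzero(np.isnan(values).any(axis=0))]
        raise ValueError(f"missing values present in columns {bad}; apply listwise deletion first")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    const = np.flatnonzero(sds == 0)
    if const.size:
        raise ValueError(f"constant column cannot be standardized: {columns[const[0]]!r}")
    ds = StandardizedDataset((values - means) / sds, columns)
    if n < ds.p + 3:
        warnings.warn(f"few rows relative to columns (n={n}, p={ds.p}); fits may be unstable")
    return ds


@dataclass
class LocalFit:
    """One node's least-squares regression on its parents.

    ``sigma2 = rss / (n - k - 1)`` is the unbiased residual-variance
    estimate; standard errors, t statistics and two-sided p-values (t
    distribution, ``n - k - 1`` df) are per parent coefficient, aligned
    with ``parents``.
    """

    child: str
    parents: list[str]
    intercept: float
    coefficients: np.ndarray
    rss: float
    sigma2: float
    n: int
    std_errors: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray

    @property
    def k(self) -> int:
        return len(self.parents)

    def coef(self, parent: str) -> float:
        return float(self.coefficients[self.parents.index(parent)])


def fit_local(data: StandardizedDataset, child: str, parents: Sequence[str]) -> LocalFit:
    """OLS of ``child`` on ``parents`` with intercept.

    A rank-deficient design falls back to the minimum-norm pseudoinverse
    solution with a warning; its standard errors use the pseudoinverse of
    X'X and should be interpreted with care.
    """
    parents = list(parents)
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    y = data.column(child)
    n, k = data.n, len(parents)
    if n <= k + 2:
        raise ValueError(f"n={n} too small to regress {child!r} on {k} parents (need n > k + 2)")
    X = np.column_stack([np.ones(n)] + [data.column(p) for p in parents])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(f"singular design for child {child!r}; using pseudoinverse solution")
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - k - 1
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se_all = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    se = se_all[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1:] / se, np.inf * np.sign(beta[1:]))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return LocalFit(
        child=child,
        parents=parents,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        rss=rss,
        sigma2=sigma2,
        n=n,
        std_errors=se,
        t_stats=np.asarray(t, dtype=float),
        p_values=np.asarray(p, dtype=float),
    )


@dataclass
class ScoreCache:
    """Memoizes local scores keyed by ``(child, sorted parent tuple)``.

    Parent order is irrelevant to a least-squares fit, so keys use sorted
    parent tuples.  Purely an optimization: cached values equal
    recomputation to machine precision because they ARE the recomputed
    values, stored.
    """

    _store: dict[tuple[str, tuple[str, ...]], float] = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def get(self, child: str, parents: Sequence[str]):
        key = (child, tuple(sorted(parents)))
        val = self._store.get(key)
        if val is not None:
            self.hits += 1
        return val

    def put(self, child: str, parents: Sequence[str], value: float) -> None:
        self.misses += 1
        self._store[(child, tuple(sorted(parents)))] = value

    def __len__(self) -> int:
        return len(self._store)


def _rss_of(data: StandardizedDataset, child: str, parents: Sequence[str]) -> float:
    y = data.column(child)
    n = data.n
    if not parents:
        mu = y.mean()
        return float(((y - mu) ** 2).sum())
    X = np.column_stack([np.ones(n)] + [data.column(p) for p in parents])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(f"singular design for child {child!r}; using pseudoinverse solution")
    resid = y - X @ beta
    return float(resid @ resid)


def local_bic(
    data: StandardizedDataset,
    child: str,
    parents: Sequence[str] = (),
    cache: ScoreCache | None = None,
) -> float:
    """The local linear-Gaussian BIC of ``child`` given ``parents``.

    Higher is better.  ``RSS`` is floored at ``RSS_FLOOR_SCALE * n`` before
    the logarithm so the score stays finite for perfectly collinear
    children (logged when triggered).
    """
    parents = list(parents)
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    if cache is not None:
        cached = cache.get(child, parents)
        if cached is not None:
            return cached
    n, k = data.n, len(parents)
    if n <= k + 2:
        raise ValueError(f"n={n} too small to score {child!r} with {k} parents (need n > k + 2)")
    rss = _rss_of(data, child, parents)
    floor = RSS_FLOOR_SCALE * n
    if rss < floor:
        logger.warning("RSS %.3e for child %r floored at %.3e", rss, child, floor)
        rss = floor
    score = -(n / 2.0) * (math.log(2.0 * math.pi) + 1.0 + math.log(rss / n)) - (
        (k + 2) / 2.0
    ) * math.log(n)
    if cache is not None:
        cache.put(child, parents, score)
    return score


def graph_score(
    data: StandardizedDataset, g: DirectedGraph, cache: ScoreCache | None = None
) -> float:
    """Sum of local BIC scores over all nodes of ``g``."""
    missing = [v for v in g.nodes if v not in data._index]
    if missing:
        raise KeyError(f"graph nodes not in data: {missing}")
    return sum(local_bic(data, v, g.parents(v), cache) for v in g.nodes)


def score_delta(
    data: StandardizedDataset, g: DirectedGraph, move, cache: ScoreCache | None = None
) -> float:
    """Score change of applying ``move`` to ``g``, via local terms only.

    Exploits decomposability: an add/remove changes only the target node's
    parent set; a reversal changes both endpoints'.  Equal to a full
    rescore difference up to floating-point roundoff.
    """
    u, v = move.edge
    if move.kind == "add":
        if g.has_edge(u, v) or g.has_path(v, u):
            raise ValueError(f"illegal move {move}")
        old = g.parents(v)
        new = sorted(old + [u])
        return local_bic(data, v, new, cache) - local_bic(data, v, old, cache)
    if move.kind == "remove":
        if not g.has_edge(u, v):
            raise ValueError(f"illegal move {move}")
        old = g.parents(v)
        new = [p for p in old if p != u]
        return local_bic(data, v, new, cache) - local_bic(data, v, old, cache)
    if move.kind == "reverse":
        if not g.has_edge(u, v):
            raise ValueError(f"illegal move {move}")
        g.remove_edge(u, v)
        cyclic = g.has_path(u, v)
        g.add_edge(u, v)
        if cyclic:
            raise ValueError(f"illegal move {move}: reversal creates a cycle")
        old_v = g.parents(v)
        new_v = [p for p in old_v if p != u]
        old_u = g.parents(u)
        new_u = sorted(old_u + [v])
        return (
            local_bic(data, v, new_v, cache)
            - local_bic(data, v, old_v, cache)
            + local_bic(data, u, new_u, cache)
            - local_bic(data, u, old_u, cache)
        )
    raise ValueError(f"unknown move kind {move.kind!r}")
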