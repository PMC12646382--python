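"""Predictor curation: correlation screening, regularized + relative-importance
feature selection, and correlation-threshold clustering with first-principal-
component aggregation.

Behavioural questionnaire scales are massively redundant (a dozen T-scores
from one instrument can inter-correlate above 0.8), and score-based DAG
search is notoriously unstable under such multicollinearity: edges between
near-duplicate nodes carry large score gains in either direction.  The
curation stack here addresses that in two moves:

1. *Selection.*  An L1-regularized regression of the outcome on all
   candidate predictors (penalty chosen by cross-validation) keeps strong
   predictors, but the L1 penalty can drop a true cause that is highly
   correlated with a stronger one.  Dropped variables therefore get a
   second chance: any dropped variable that is significant in the full
   multivariate OLS (p < 0.05) AND carries real relative importance
   (LMG share > 0.01) is re-admitted.

2. *Aggregation.*  Average-linkage hierarchical clustering on the
   distance 1 - r groups predictors whose correlation exceeds a threshold;
   each multi-member cluster is replaced by scores on the first principal
   component of its members (correlation-matrix PCA), singletons pass
   through unchanged.

LMG relative importance is the average, over all orderings in which
predictors could enter the model, of the R-squared increment a predictor
contributes when it enters; shares are nonnegative and sum to the full
model's R-squared.  Exact enumeration is feasible up to ~10 predictors via
the subset-sum formulation; beyond that a seeded Monte-Carlo average over
random orderings is used.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.linear_model import LassoCV

from .scoring import StandardizedDataset, fit_local

__all__ = [
    "CorrelationMatrix",
    "AggregatedFactor",
    "SelectionReport",
    "correlation_matrix",
    "lmg_importance",
    "select_features",
    "cluster_and_aggregate",
    "aggregated_dataset",
]

logger = logging.getLogger(__name__)

LMG_EXACT_LIMIT = 10
LMG_MC_ORDERINGS = 2000


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


@dataclass
class AggregatedFactor:
    """One cluster collapsed onto its first principal component.

    ``loadings`` are the unit-norm eigenvector entries of the members'
    correlation submatrix, signed so the member with the largest absolute
    loading loads positively; ``scores`` are the member columns projected
    onto that eigenvector (sample variance equal to the first eigenvalue);
    ``variance_explained`` is eigenvalue / n_members.  Singleton clusters
    pass the original column through (loading 1, variance_explained 1).
    """

    name: str
    members: list[str]
    loadings: np.ndarray
    variance_explained: float
    scores: np.ndarray


@dataclass
class SelectionReport:
    """Per-variable record of the two-stage selection cascade."""

    table: pd.DataFrame  # variable, lasso_coef, ols_coef, ols_se, ols_p, lmg_share, kept, reason
    alpha: float         # cross-validated L1 penalty
    r_squared: float     # full multivariate model R^2
    cv_folds: int
    seed: int

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "variable"])


def correlation_matrix(data: StandardizedDataset) -> CorrelationMatrix:
    if data.n < 3:
        raise ValueError("need n >= 3 for correlations")
    r = np.corrcoef(data.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(data.columns), r)


def _r2(y: np.ndarray, X: np.ndarray | None) -> float:
    """R^2 of OLS of y on X (with intercept); 0 for the empty model."""
    tss = float(((y - y.mean()) ** 2).sum())
    if X is None or X.shape[1] == 0:
        return 0.0
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        warnings.warn("singular design in R^2 computation; using pseudoinverse fit")
    resid = y - Xd @ beta
    return 1.0 - float(resid @ resid) / tss


def lmg_importance(
    data: StandardizedDataset,
    outcome: str,
    predictors: list[str],
    *,
    seed: int = 0,
    n_orderings: int = LMG_MC_ORDERINGS,
) -> dict[str, float]:
    """LMG relative-importance shares of ``predictors`` for ``outcome``.

    Exact (subset-weighted) enumeration for up to 10 predictors; a seeded
    Monte-Carlo average over random entry orderings beyond that.  Shares
    sum to the full-model R-squared in exact mode (and in expectation in
    Monte-Carlo mode, where each sampled ordering's increments sum to it
    exactly as well).
    """
    predictors = list(predictors)
    if outcome in predictors:
        raise ValueError("outcome cannot be one of the predictors")
    y = data.column(outcome)
    X = data.matrix(predictors)
    p = len(predictors)
    if p == 0:
        return {}
    # cache R^2 by predictor subset (frozenset of column indices)
    r2_cache: dict[frozenset, float] = {}

    def r2_of(subset: frozenset) -> float:
        if subset not in r2_cache:
            cols = sorted(subset)
            r2_cache[subset] = _r2(y, X[:, cols] if cols else None)
        return r2_cache[subset]

    shares = dict.fromkeys(predictors, 0.0)
    if p <= LMG_EXACT_LIMIT:
        others = list(range(p))
        fact = math.factorial
        for j in range(p):
            rest = [i for i in others if i != j]
            acc = 0.0
            for s in range(p):
                w = fact(s) * fact(p - 1 - s) / fact(p)
                for sub in itertools.combinations(rest, s):
                    fs = frozenset(sub)
                    acc += w * (r2_of(fs | {j}) - r2_of(fs))
            shares[predictors[j]] = acc
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros(p)
        for _ in range(n_orderings):
            order = rng.permutation(p)
            seen: frozenset = frozenset()
            prev = 0.0
            for j in order:
                cur = r2_of(seen | {j})
                acc[j] += cur - prev
                seen = seen | {j}
                prev = cur
        for j, name in enumerate(predictors):
            shares[name] = float(acc[j] / n_orderings)
    return shares


def select_features(
    data: StandardizedDataset,
    outcome: str,
    *,
    predictors: list[str] | None = None,
    lasso_cutoff: float = 0.03,
    p_cutoff: float = 0.05,
    lmg_cutoff: float = 0.01,
    cv_folds: int = 10,
    seed: int = 0,
) -> SelectionReport:
    """Two-stage predictor selection: L1 screen, then re-admission of
    dropped variables that are significant and important in the full OLS.

    Stage 1 keeps predictors whose cross-validated-L1 coefficient exceeds
    ``lasso_cutoff`` in absolute value.  Stage 2 re-examines only the
    DROPPED predictors in the full multivariate least-squares model and
    re-admits those with p < ``p_cutoff`` and LMG share > ``lmg_cutoff``.
    """
    if predictors is None:
        predictors = [c for c in data.columns if c != outcome]
    if outcome not in data.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    p = len(predictors)
    if p >= data.n:
        raise ValueError(
            f"p={p} >= n={data.n}: the full multivariate re-check is not identifiable; "
            "rely on stronger regularization (reduce the predictor set) instead"
        )
    y = data.column(outcome)
    X = data.matrix(predictors)
    lasso = LassoCV(cv=cv_folds, random_state=seed, alphas=100).fit(X, y)
    lasso_coefs = dict(zip(predictors, lasso.coef_))
    stage1 = {v for v in predictors if abs(lasso_coefs[v]) > lasso_cutoff}

    full = fit_local(data, outcome, predictors)
    ols_coef = dict(zip(full.parents, full.coefficients))
    ols_se = dict(zip(full.parents, full.std_errors))
    ols_p = dict(zip(full.parents, full.p_values))
    lmg = lmg_importance(data, outcome, predictors, seed=seed)
    r_squared = _r2(y, X)

    rows = []
    for v in predictors:
        if v in stage1:
            kept, reason = True, "lasso"
        elif ols_p[v] < p_cutoff and lmg[v] > lmg_cutoff:
            kept, reason = True, "readmitted"
        else:
            kept, reason = False, "dropped"
        rows.append({
            "variable": v, "lasso_coef": float(lasso_coefs[v]),
            "ols_coef": float(ols_coef[v]), "ols_se": float(ols_se[v]),
            "ols_p": float(ols_p[v]), "lmg_share": float(lmg[v]),
            "kept": kept, "reason": reason,
        })
    table = pd.DataFrame(rows)
    return SelectionReport(table=table, alpha=float(lasso.alpha_),
                           r_squared=r_squared, cv_folds=cv_folds, seed=seed)


def cluster_and_aggregate(
    data: StandardizedDataset,
    variables: list[str] | None = None,
    r_threshold: float = 0.7,
    *,
    linkage_method: str = "average",
    absolute: bool = False,
    name_prefix: str = "factor",
) -> list[AggregatedFactor]:
    """Cluster correlated variables and collapse each cluster onto its PC1.

    Hierarchical clustering (``linkage_method``, default average linkage)
    on the distance ``1 - r`` (or ``1 - |r|`` with ``absolute=True``),
    cut so that clusters only merge at distance <= ``1 - r_threshold``.
    Multi-member clusters become first-principal-component scores of the
    members' correlation matrix; singletons pass through unchanged.
    Factors are named ``<prefix>_1 ...`` in order of first member
    appearance; singletons keep their variable name.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError(f"r_threshold must be in (0,1), got {r_threshold}")
    if variables is None:
        variables = list(data.columns)
    m = len(variables)
    if m == 0:
        return []
    sub = StandardizedDataset(data.matrix(variables), variables)
    if m == 1:
        labels = np.array([1])
    else:
        r = correlation_matrix(sub).r
        d = 1.0 - (np.abs(r) if absolute else r)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        Z = linkage(squareform(d, checks=False), method=linkage_method)
        labels = fcluster(Z, t=1.0 - r_threshold, criterion="distance")
    factors: list[AggregatedFactor] = []
    n_multi = 0
    for lab in _labels_in_appearance_order(labels):
        members = [v for v, l in zip(variables, labels) if l == lab]
        if len(members) == 1:
            v = members[0]
            factors.append(AggregatedFactor(
                name=v, members=[v], loadings=np.array([1.0]),
                variance_explained=1.0, scores=sub.column(v).copy(),
            ))
            continue
        n_multi += 1
        factors.append(_pc1_factor(sub, members, f"{name_prefix}_{n_multi}"))
    return factors


def _labels_in_appearance_order(labels: np.ndarray) -> list[int]:
    seen: list[int] = []
    for l in labels:
        if l not in seen:
            seen.append(int(l))
    return seen


def _pc1_factor(sub: StandardizedDataset, members: list[str], name: str) -> AggregatedFactor:
    Zm = sub.matrix(members)
    R = np.corrcoef(Zm, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    lam1 = float(eigvals[-1])
    v1 = eigvecs[:, -1]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
    scores = Zm @ v1
    return AggregatedFactor(
        name=name, members=list(members), loadings=v1.copy(),
        variance_explained=lam1 / len(members), scores=scores,
    )


def aggregated_dataset(
    data: StandardizedDataset,
    factors: list[AggregatedFactor],
    passthrough: list[str] = (),
) -> StandardizedDataset:
    """Re-standardized dataset of factor scores plus untouched columns.

    Factor scores have variance equal to their PC1 eigenvalue, so they are
    re-standardized here to satisfy the preconditions of scoring/search.
    """
    from .scoring import standardize

    cols: dict[str, np.ndarray] = {f.name: f.scores for f in factors}
    for v in passthrough:
        if v in cols:
            raise ValueError(f"column name collision on {v!r}")
        cols[v] = data.column(v)
    frame = pd.DataFrame(cols)
    return standardize(frame)
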