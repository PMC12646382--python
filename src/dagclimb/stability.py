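"""Bootstrap edge-stability analysis and graph comparison.

Greedy structure search is a point estimate of the DAG; resampling shows
which edges are features of the population and which are artifacts of the
draw.  ``bootstrap_dag`` redraws the rows with replacement B times,
re-standardizes each resample, reruns the constrained hill climb and the
path-model fit, and accumulates, per directed edge, its appearance
frequency across replicates and a 95% percentile interval (2.5th / 97.5th)
of its path coefficient.  Edges reaching an appearance frequency of at
least ``min_freq`` are reported, plus every edge of the original full-data
graph regardless of frequency (flagged).  An original edge is *consistent*
when its full-data coefficient falls inside its bootstrap interval.

Replicate randomness comes from per-replicate substreams spawned off one
master seed, so results are reproducible and replicate i's draw does not
depend on B.

``compare_graphs`` is the sensitivity-analysis companion: exact edge-set
arithmetic (shared edges, Jaccard overlap, directional containment
percentages) between two learned graphs, e.g. from two cohort subsets or
two clustering thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dag import ConstraintSet, DirectedGraph, EMPTY_CONSTRAINTS
from .effects import PathModel, fit_path_model
from .scoring import StandardizedDataset, standardize
from .search import SearchResult, hill_climb

__all__ = [
    "BootstrapEdgeStats",
    "BootstrapResult",
    "GraphComparison",
    "bootstrap_dag",
    "consistency_check",
    "compare_graphs",
]

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class BootstrapEdgeStats:
    """Stability record for one directed edge across bootstrap replicates."""

    edge: Edge
    frequency: float          # n_present / B
    n_present: int
    coef_ci: tuple[float, float]  # 2.5th / 97.5th percentile of the coefficient
    in_original: bool
    original_coef: float | None
    consistent: bool | None   # original coefficient inside coef_ci; None if not original


@dataclass
class BootstrapResult:
    stats: list[BootstrapEdgeStats]
    original: SearchResult
    original_model: PathModel
    B: int
    n_failed: int
    seed: int
    min_freq: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": s.edge[0], "target": s.edge[1],
                "frequency": s.frequency, "n_present": s.n_present,
                "ci_low": s.coef_ci[0], "ci_high": s.coef_ci[1],
                "in_original": s.in_original,
                "original_coef": np.nan if s.original_coef is None else s.original_coef,
                "consistent": s.consistent,
            }
            for s in self.stats
        ]
        return pd.DataFrame(
            rows,
            columns=["source", "target", "frequency", "n_present", "ci_low",
                     "ci_high", "in_original", "original_coef", "consistent"],
        )


def bootstrap_dag(
    data: StandardizedDataset,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    *,
    B: int = 100,
    seed: int = 0,
    min_freq: float = 0.40,
    zero_when_absent: bool = False,
    max_failure_rate: float = 0.10,
    search_kwargs: dict | None = None,
    prepare=None,
) -> BootstrapResult:
    """Re-learn the DAG on B row-resamples and summarize edge stability.

    ``zero_when_absent`` switches the coefficient-interval convention: by
    default percentiles pool only the replicates in which the edge was
    present; with the switch on, absent-edge replicates contribute a zero
    coefficient (both conventions are defensible; neither is canonical).

    ``prepare`` enables full-pipeline resampling: a callable mapping a raw
    row-resampled table (2-D array + column names) to a
    :class:`StandardizedDataset`, rerun inside every replicate — use it to
    refit aggregation per replicate.  Without it, replicates simply
    re-standardize the resampled rows of ``data`` (factor definitions, if
    any, stay fixed).

    Replicates whose resample cannot be fit (e.g. a column goes constant)
    are logged and excluded from all denominators; the run aborts if more
    than ``max_failure_rate`` of replicates fail.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    search_kwargs = dict(search_kwargs or {})
    if prepare is None:
        prepare = standardize
    values = np.asarray(data.values, dtype=float)
    columns = [str(c) for c in data.columns]
    analysis = prepare(values, columns)
    original = hill_climb(analysis, constraints, **search_kwargs)
    original_model = fit_path_model(analysis, original.graph)

    n = values.shape[0]
    child_seeds = np.random.SeedSequence(seed).spawn(B)
    edge_coefs: dict[Edge, list[float]] = {}
    edge_count: dict[Edge, int] = {}
    n_ok = 0
    n_failed = 0
    replicate_graphs: list[set[Edge]] = []
    for b in range(B):
        rng = np.random.default_rng(child_seeds[b])
        idx = rng.integers(0, n, size=n)
        try:
            rep = prepare(values[idx], columns)
            res = hill_climb(rep, constraints, **search_kwargs)
            model = fit_path_model(rep, res.graph)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data-driven
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        n_ok += 1
        edges = res.graph.edges
        replicate_graphs.append(edges)
        for u, v in edges:
            edge_count[(u, v)] = edge_count.get((u, v), 0) + 1
            edge_coefs.setdefault((u, v), []).append(model.coefficient(u, v))
    if n_ok == 0 or n_failed > max_failure_rate * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed to fit")

    orig_edges = original.graph.edges
    report_edges = {e for e, c in edge_count.items() if c / n_ok >= min_freq} | orig_edges
    stats: list[BootstrapEdgeStats] = []
    for edge in sorted(report_edges):
        count = edge_count.get(edge, 0)
        coefs = list(edge_coefs.get(edge, []))
        if zero_when_absent:
            coefs = coefs + [0.0] * (n_ok - count)
        if coefs:
            lo, hi = (float(q) for q in np.percentile(coefs, [2.5, 97.5]))
        else:
            lo, hi = (float("nan"), float("nan"))
        in_orig = edge in orig_edges
        orig_coef = original_model.coefficient(*edge) if in_orig else None
        consistent = (lo <= orig_coef <= hi) if (in_orig and coefs) else None
        stats.append(BootstrapEdgeStats(
            edge=edge, frequency=count / n_ok, n_present=count,
            coef_ci=(lo, hi), in_original=in_orig,
            original_coef=orig_coef, consistent=consistent,
        ))
    return BootstrapResult(stats=stats, original=original, original_model=original_model,
                           B=n_ok, n_failed=n_failed, seed=seed, min_freq=min_freq)


def consistency_check(result: BootstrapResult) -> pd.DataFrame:
    """Flag each original edge as consistent/inconsistent with its bootstrap CI.

    Returns the per-edge table restricted to original edges, plus summary
    counts in ``.attrs`` (``n_consistent``, ``n_inconsistent``).
    """
    frame = result.to_frame()
    orig = frame[frame["in_original"]].reset_index(drop=True)
    n_cons = int((orig["consistent"] == True).sum())  # noqa: E712 - may hold None
    orig.attrs["n_consistent"] = n_cons
    orig.attrs["n_inconsistent"] = len(orig) - n_cons
    return orig


@dataclass
class GraphComparison:
    """Edge-set overlap between two learned graphs."""

    edges_a: set[Edge]
    edges_b: set[Edge]
    shared: set[Edge]
    jaccard: float
    pct_a_in_b: float
    pct_b_in_a: float


def compare_graphs(a: DirectedGraph, b: DirectedGraph) -> GraphComparison:
    """Exact edge-set arithmetic between two graphs (nodes may differ).

    ``jaccard`` is |shared| / |union| (1.0 for two empty edge sets);
    ``pct_a_in_b`` is the fraction of a's edges present in b, and vice
    versa.
    """
    ea, eb = a.edges, b.edges
    shared = ea & eb
    union = ea | eb
    jaccard = len(shared) / len(union) if union else 1.0
    return GraphComparison(
        edges_a=ea, edges_b=eb, shared=shared, jaccard=jaccard,
        pct_a_in_b=len(shared) / len(ea) if ea else 1.0,
        pct_b_in_a=len(shared) / len(eb) if eb else 1.0,
    )
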