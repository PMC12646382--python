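"""Greedy hill-climb maximization of the graph BIC under edge blacklists.

Starting from an empty graph, each iteration enumerates every legal
single-edge modification (addition, removal, reversal), scores each via the
decomposable delta, and applies the single best strictly-improving move.
The search stops at a local optimum: no legal move improves the score by
more than the tie tolerance.  Given identical data and configuration the
result is bit-for-bit reproducible (ties break on the deterministic move
ordering of :func:`dagclimb.dag.legal_moves`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .dag import (
    EMPTY_CONSTRAINTS,
    ConstraintSet,
    DirectedGraph,
    EdgeMove,
    apply_move,
    legal_moves,
)
from .scoring import ScoreCache, StandardizedDataset, graph_score, score_delta

__all__ = ["SearchResult", "hill_climb", "local_optimum_certificate", "DEFAULT_TOLERANCE"]

logger = logging.getLogger(__name__)

# minimum score improvement counted as real, against float roundoff
DEFAULT_TOLERANCE = 1e-9


@dataclass
class SearchResult:
    """Outcome of a hill-climb run.

    ``graph`` is a certified local optimum unless ``converged`` is False
    (iteration cap hit); ``score`` equals a from-scratch rescore of
    ``graph``; ``trace`` lists the accepted ``(move, delta)`` pairs in
    order, so cumulative deltas are strictly increasing.
    """

    graph: DirectedGraph
    score: float
    iterations: int
    converged: bool
    trace: list[tuple[EdgeMove, float]] = field(default_factory=list)


def hill_climb(
    data: StandardizedDataset,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    *,
    start: DirectedGraph | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int | None = None,
    max_in_degree: int | None = None,
    cache: ScoreCache | None = None,
) -> SearchResult:
    """Greedy structure search over single-edge moves.

    Parameters
    ----------
    data:
        Standardized dataset; the search runs over all of its columns.
    constraints:
        Edge blacklist; no forbidden edge ever appears in any intermediate
        or final graph.
    start:
        Starting graph (default: empty graph over the data columns).  Must
        already respect the constraints.
    tolerance:
        Strict-improvement threshold; a move is accepted only if its score
        delta exceeds it.
    max_iter:
        Iteration cap, default ``3 * p**2``; hitting it returns the
        best-so-far graph with ``converged=False`` and a logged warning.
    max_in_degree:
        Optional cap on parents per node (additions and reversals that
        would exceed it are skipped).  Unlimited by default.
    """
    bad = [e for e in constraints.forbidden_edges if e[0] not in data._index or e[1] not in data._index]
    if bad:
        raise KeyError(f"constraint edges reference unknown columns: {sorted(bad)[:5]}")
    if start is None:
        g = DirectedGraph(data.columns)
    else:
        viol = constraints.violations(start)
        if viol:
            raise ValueError(f"start graph violates constraints: {sorted(viol)}")
        g = start.copy()
    p = len(g.nodes)
    if max_iter is None:
        max_iter = 3 * p * p
    cache = cache if cache is not None else ScoreCache()
    trace: list[tuple[EdgeMove, float]] = []
    converged = False
    iterations = 0
    while iterations < max_iter:
        best_move, best_delta = _best_move(data, g, constraints, cache, max_in_degree)
        if best_move is None or best_delta <= tolerance:
            converged = True
            break
        apply_move(g, best_move)
        trace.append((best_move, best_delta))
        iterations += 1
        logger.debug("iter %d: %s %s (delta %.6f)", iterations, best_move.kind, best_move.edge, best_delta)
    else:
        # iteration cap: best-so-far graph returned, flagged via converged=False
        logger.warning("hill climb hit max_iter=%d before converging", max_iter)
    score = graph_score(data, g, cache)
    return SearchResult(graph=g, score=score, iterations=iterations, converged=converged, trace=trace)


def _best_move(data, g, constraints, cache, max_in_degree):
    """Single best improving move; ties go to the first in canonical order."""
    best_move, best_delta = None, 0.0
    for move in legal_moves(g, constraints):
        if max_in_degree is not None and move.kind in ("add", "reverse"):
            tgt = move.edge[1] if move.kind == "add" else move.edge[0]
            extra = 1 if move.kind == "add" else 1
            if g.in_degree(tgt) + extra > max_in_degree:
                continue
        delta = score_delta(data, g, move, cache)
        if delta > best_delta:
            best_move, best_delta = move, delta
    return best_move, best_delta


def local_optimum_certificate(
    data: StandardizedDataset,
    g: DirectedGraph,
    constraints: ConstraintSet = EMPTY_CONSTRAINTS,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[bool, EdgeMove | None, float]:
    """Certify that no legal single-edge move improves ``g``'s score.

    Returns ``(is_optimum, counterexample, delta)``: if ``g`` is not a
    local optimum, ``counterexample`` is the best improving move found and
    ``delta`` its score gain; otherwise ``(True, None, 0.0)``.
    """
    viol = constraints.violations(g)
    if viol:
        raise ValueError(f"graph violates constraints: {sorted(viol)}")
    cache = ScoreCache()
    best_move, best_delta = None, tolerance
    for move in legal_moves(g, constraints):
        delta = score_delta(data, g, move, cache)
        if delta > best_delta:
            best_move, best_delta = move, delta
    if best_move is None:
        return True, None, 0.0
    return False, best_move, best_delta
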