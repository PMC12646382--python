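"""Recursive linear path model over a learned DAG: direct, indirect and
total effects.

Once a structure is fixed, each node is regressed (OLS, with intercept) on
its graph parents; the coefficients fill a p x p matrix ``B`` with
``B[i, j]`` the coefficient of variable j in variable i's equation.
Structural zeros are exact: ``B[i, j]`` can be nonzero only when the edge
``(j, i)`` is in the graph, and under a topological ordering ``B`` is
strictly lower triangular.

For a recursive model with independent errors, per-equation least squares
coincides with full-information maximum likelihood, so this is the standard
path-analysis quantification of the DAG without any covariance-structure
machinery.  Effects of a source on an outcome:

* direct   = the source's coefficient in the outcome's equation (0 if no edge);
* total    = sum over all directed paths source -> ... -> outcome of the
             product of edge coefficients, which equals the corresponding
             entry of (I - B)^-1;
* indirect = total - direct.

Both routes (explicit path products and the matrix inverse) are computed
and cross-checked internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dag import DirectedGraph, enumerate_pathways
from .scoring import LocalFit, StandardizedDataset, fit_local

__all__ = ["PathModel", "EffectDecomposition", "fit_path_model", "total_effects", "effect_report"]

_XCHECK_ATOL = 1e-9


@dataclass
class PathModel:
    """A DAG quantified by per-node least-squares fits."""

    graph: DirectedGraph
    fits: dict[str, LocalFit]
    B: pd.DataFrame  # B.loc[child, parent] = coefficient

    def coefficient(self, source: str, target: str) -> float:
        return float(self.B.loc[target, source])


@dataclass
class EffectDecomposition:
    """Direct/indirect/total effect of one source on the outcome.

    ``paths`` lists every directed simple path source -> ... -> outcome
    together with its coefficient product; ``total`` is their sum and
    always equals ``direct + indirect``.
    """

    source: str
    outcome: str
    direct: float
    indirect: float
    total: float
    paths: list[tuple[list[str], float]]


def fit_path_model(data: StandardizedDataset, g: DirectedGraph) -> PathModel:
    """OLS of every node on its graph parents; roots get intercept-only fits.

    The residual sum of squares of each fit is exactly the RSS the BIC
    score used for the same (child, parents) pair on the same data.
    """
    missing = [v for v in g.nodes if v not in data._index]
    if missing:
        raise KeyError(f"graph nodes not in data: {missing}")
    max_par = max((g.in_degree(v) for v in g.nodes), default=0)
    if data.n <= max_par + 2:
        raise ValueError(f"n={data.n} too small for {max_par} parents")
    fits: dict[str, LocalFit] = {}
    B = pd.DataFrame(0.0, index=list(g.nodes), columns=list(g.nodes))
    for v in g.nodes:
        fit = fit_local(data, v, g.parents(v))
        fits[v] = fit
        for p, b in zip(fit.parents, fit.coefficients):
            B.loc[v, p] = b
    return PathModel(graph=g.copy(), fits=fits, B=B)


def _total_effect_matrix(m: PathModel) -> pd.DataFrame:
    """(I - B)^-1; entry [i, j] is the total effect of j on i (diagonal 1)."""
    p = len(m.graph.nodes)
    ident = np.eye(p)
    T = np.linalg.inv(ident - m.B.to_numpy())
    return pd.DataFrame(T, index=m.B.index, columns=m.B.columns)


def total_effects(m: PathModel, outcome: str) -> dict[str, EffectDecomposition]:
    """Decompose the effect of every other node on ``outcome``.

    Path enumeration is exact (a DAG has finitely many simple paths; no
    length cutoff), and the path-product totals are verified against the
    (I - B)^-1 closed form before returning.
    """
    if outcome not in m.graph:
        raise KeyError(f"unknown outcome {outcome!r}")
    T = _total_effect_matrix(m)
    all_paths = enumerate_pathways(m.graph, outcome)
    by_source: dict[str, list[tuple[list[str], float]]] = {v: [] for v in m.graph.nodes if v != outcome}
    for path in all_paths:
        prod = 1.0
        for a, b in zip(path, path[1:]):
            prod *= float(m.B.loc[b, a])
        by_source[path[0]].append((path, prod))
    out: dict[str, EffectDecomposition] = {}
    for source, paths in by_source.items():
        total = float(sum(p for _, p in paths))
        direct = float(m.B.loc[outcome, source])
        closed = float(T.loc[outcome, source])
        if abs(total - closed) > _XCHECK_ATOL * max(1.0, abs(closed)):
            raise AssertionError(
                f"path-sum total {total!r} for {source!r} disagrees with (I-B)^-1 entry {closed!r}"
            )
        out[source] = EffectDecomposition(
            source=source,
            outcome=outcome,
            direct=direct,
            indirect=total - direct,
            total=total,
            paths=paths,
        )
    return out


def effect_report(m: PathModel, outcome: str) -> pd.DataFrame:
    """Tabulate edge coefficients and effect totals as one tidy table.

    Rows with ``kind == "edge"`` carry one graph edge each (direct
    coefficient, standard error, p-value); rows with ``kind == "total"``
    carry the decomposition of each source's effect on ``outcome``, sorted
    by |total| descending.  The table round-trips through TSV exactly
    (``pd.read_csv(..., sep="\\t")``).
    """
    edge_rows = []
    for child in m.graph.nodes:
        fit = m.fits[child]
        for p, b, se, pv in zip(fit.parents, fit.coefficients, fit.std_errors, fit.p_values):
            edge_rows.append(
                {"kind": "edge", "source": p, "target": child,
                 "direct_coef": float(b), "se": float(se), "p_value": float(pv),
                 "indirect": np.nan, "total": np.nan}
            )
    edge_rows.sort(key=lambda r: (r["source"], r["target"]))
    total_rows = []
    for source, dec in total_effects(m, outcome).items():
        total_rows.append(
            {"kind": "total", "source": source, "target": outcome,
             "direct_coef": dec.direct, "se": np.nan, "p_value": np.nan,
             "indirect": dec.indirect, "total": dec.total}
        )
    total_rows.sort(key=lambda r: (-abs(r["total"]), r["source"]))
    cols = ["kind", "source", "target", "direct_coef", "se", "p_value", "indirect", "total"]
    return pd.DataFrame(edge_rows + total_rows, columns=cols)
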