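"""Directed acyclic graphs, expert-knowledge constraints, and edge moves.

The structure-search state is a plain DAG over named variables.  Edges are
ordered ``(source, target)`` name pairs.  Expert knowledge enters as a
blacklist (:class:`ConstraintSet`): a set of directed edges that may never
appear in any candidate graph — e.g. the outcome variable is forbidden from
influencing anything, and an exogenous genetic score is forbidden from
influencing the behavioural predictors.

Also here: breadth-first enumeration of all directed simple paths into an
outcome node, iterative sink pruning, and graph serialization (JSON, DOT,
GraphML) with byte-identical node-name round-tripping.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "CycleError",
    "ConfigError",
    "DirectedGraph",
    "ConstraintSet",
    "EdgeMove",
    "build_constraints",
    "legal_moves",
    "apply_move",
    "invert_move",
    "enumerate_pathways",
    "prune_sinks",
]

Edge = tuple[str, str]


class CycleError(ValueError):
    """Raised when an operation would make (or was given) a cyclic graph."""


class ConfigError(ValueError):
    """Raised for invalid variable roles or run configuration."""


class DirectedGraph:
    """A directed acyclic graph over named variables.

    Parameters
    ----------
    nodes:
        Ordered variable names (order is preserved in serialization and
        topological tie-breaking).
    edges:
        Iterable of ``(source, target)`` pairs.  Self-loops, unknown
        endpoints and cycles raise immediately.
    """

    __slots__ = ("nodes", "_edges", "_children", "_parents")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge] = ()) -> None:
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._children: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._edges: set[Edge] = set()
        for u, v in edges:
            self.add_edge(u, v)

    # -- basic accessors -------------------------------------------------

    @property
    def edges(self) -> set[Edge]:
        return set(self._edges)

    def parents(self, v: str) -> list[str]:
        return sorted(self._parents[v])

    def children(self, v: str) -> list[str]:
        return sorted(self._children[v])

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self._edges

    def out_degree(self, v: str) -> int:
        return len(self._children[v])

    def in_degree(self, v: str) -> int:
        return len(self._parents[v])

    def __contains__(self, v: str) -> bool:
        return v in self._children

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self._edges == other._edges

    def __hash__(self):  # mutable; not hashable
        raise TypeError("DirectedGraph is mutable and unhashable")

    def __repr__(self) -> str:
        return f"DirectedGraph({len(self.nodes)} nodes, {len(self._edges)} edges)"

    def copy(self) -> "DirectedGraph":
        g = DirectedGraph.__new__(DirectedGraph)
        g.nodes = list(self.nodes)
        g._edges = set(self._edges)
        g._children = {v: set(s) for v, s in self._children.items()}
        g._parents = {v: set(s) for v, s in self._parents.items()}
        return g

    # -- mutation --------------------------------------------------------

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if u not in self._children or v not in self._children:
            missing = u if u not in self._children else v
            raise KeyError(f"unknown node {missing!r}")
        if (u, v) in self._edges:
            raise ValueError(f"edge {(u, v)!r} already present")
        if self.has_path(v, u):
            raise CycleError(f"adding edge {(u, v)!r} creates a cycle")
        self._edges.add((u, v))
        self._children[u].add(v)
        self._parents[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        if (u, v) not in self._edges:
            raise KeyError(f"edge {(u, v)!r} not present")
        self._edges.remove((u, v))
        self._children[u].remove(v)
        self._parents[v].remove(u)

    # -- queries ---------------------------------------------------------

    def has_path(self, u: str, v: str) -> bool:
        """True iff a directed path u -> ... -> v exists (including u == v)."""
        if u == v:
            return True
        seen = {u}
        stack = [u]
        while stack:
            w = stack.pop()
            for c in self._children[w]:
                if c == v:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; ties broken by the node declaration order."""
        indeg = {v: len(self._parents[v]) for v in self.nodes}
        order: list[str] = []
        ready = deque(v for v in self.nodes if indeg[v] == 0)
        while ready:
            v = ready.popleft()
            order.append(v)
            for c in sorted(self._children[v], key=self.nodes.index):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            raise CycleError("graph contains a cycle")
        return order

    def is_acyclic(self) -> bool:
        try:
            self.topological_order()
            return True
        except CycleError:
            return False

    # -- conversion / serialization --------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self._edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedGraph":
        return cls(g.nodes, g.edges)

    def to_json_obj(self) -> dict:
        return {"nodes": list(self.nodes), "edges": [list(e) for e in sorted(self._edges)]}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_json_obj(), indent=2) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DirectedGraph":
        """Load from a JSON string, dict, or file path."""
        if isinstance(source, dict):
            obj = source
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                obj = json.loads(text)
            else:
                with open(text, encoding="utf-8") as fh:
                    obj = json.load(fh)
        return cls(obj["nodes"], [tuple(e) for e in obj["edges"]])

    def to_dot(self, path=None) -> str:
        lines = ["digraph {"]
        lines += [f'  "{_dot_escape(v)}";' for v in self.nodes]
        lines += [f'  "{_dot_escape(u)}" -> "{_dot_escape(v)}";' for u, v in sorted(self._edges)]
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dot(cls, source) -> "DirectedGraph":
        """Parse the canonical DOT emitted by :meth:`to_dot`."""
        text = str(source)
        if not text.lstrip().startswith("digraph"):
            with open(text, encoding="utf-8") as fh:
                text = fh.read()
        nodes: list[str] = []
        edges: list[Edge] = []
        edge_re = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*->\s*"((?:[^"\\]|\\.)*)"\s*;')
        node_re = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*;')
        for line in text.splitlines():
            m = edge_re.match(line)
            if m:
                edges.append((_dot_unescape(m.group(1)), _dot_unescape(m.group(2))))
                continue
            m = node_re.match(line)
            if m:
                nodes.append(_dot_unescape(m.group(1)))
        for u, v in edges:
            for w in (u, v):
                if w not in nodes:
                    nodes.append(w)
        return cls(nodes, edges)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_graphml(cls, path) -> "DirectedGraph":
        return cls.from_networkx(nx.read_graphml(path))


def _dot_escape(name: str) -> str:
    return name.replace("\\", "\\\\").replace('"', '\\"')


def _dot_unescape(name: str) -> str:
    return name.replace('\\"', '"').replace("\\\\", "\\")


@dataclass(frozen=True)
class ConstraintSet:
    """Blacklist of directed edges that may never appear in a learned graph."""

    forbidden_edges: frozenset[Edge] = field(default_factory=frozenset)

    def allows(self, edge: Edge) -> bool:
        return edge not in self.forbidden_edges

    def violations(self, g: DirectedGraph) -> set[Edge]:
        return g.edges & set(self.forbidden_edges)

    def __or__(self, other: "ConstraintSet") -> "ConstraintSet":
        return ConstraintSet(self.forbidden_edges | other.forbidden_edges)


EMPTY_CONSTRAINTS = ConstraintSet()


def build_constraints(
    nodes: Sequence[str],
    outcome_vars: Sequence[str] = (),
    exogenous_score_vars: Sequence[str] = (),
    protected_targets: Sequence[str] = (),
) -> ConstraintSet:
    """Translate variable roles into an edge blacklist.

    Two rules, mirroring the temporal/biological logic of the study design:

    * an *outcome* variable may not influence any other variable
      (``(outcome, x)`` forbidden for every other node ``x``);
    * an *exogenous score* (a polygenic-score-like variable) may not
      influence any *protected target* (the aggregated behavioural
      predictors).  Edges INTO the score are deliberately left legal:
      apparent influence of parental behaviour on a child's inherited score
      is an expected consequence of shared parental genetics.

    Idempotent and order-independent in all of its inputs.
    """
    known = set(nodes)
    for role, names in (
        ("outcome", outcome_vars),
        ("exogenous_score", exogenous_score_vars),
        ("protected_target", protected_targets),
    ):
        for name in names:
            if name not in known:
                raise ConfigError(f"unknown variable {name!r} in role {role!r}")
    overlap = set(outcome_vars) & set(exogenous_score_vars)
    if overlap:
        raise ConfigError(f"variables {sorted(overlap)} cannot be both outcome and exogenous score")
    forbidden: set[Edge] = set()
    for o in outcome_vars:
        forbidden.update((o, x) for x in nodes if x != o)
    for s in exogenous_score_vars:
        forbidden.update((s, t) for t in protected_targets if t != s)
    return ConstraintSet(frozenset(forbidden))


@dataclass(frozen=True)
class EdgeMove:
    """A single-edge modification: add, remove, or reverse ``edge``."""

    kind: str  # "add" | "remove" | "reverse"
    edge: Edge

    def __post_init__(self):
        if self.kind not in ("add", "remove", "reverse"):
            raise ValueError(f"unknown move kind {self.kind!r}")


def apply_move(g: DirectedGraph, move: EdgeMove) -> None:
    """Apply ``move`` in place.  ``apply_move(g, invert_move(move))`` undoes it."""
    u, v = move.edge
    if move.kind == "add":
        g.add_edge(u, v)
    elif move.kind == "remove":
        g.remove_edge(u, v)
    else:
        g.remove_edge(u, v)
        g.add_edge(v, u)


def invert_move(move: EdgeMove) -> EdgeMove:
    u, v = move.edge
    if move.kind == "add":
        return EdgeMove("remove", (u, v))
    if move.kind == "remove":
        return EdgeMove("add", (u, v))
    return EdgeMove("reverse", (v, u))


# kinds happen to sort alphabetically in the documented order
_KIND_ORDER = {"add": 0, "remove": 1, "reverse": 2}


def legal_moves(g: DirectedGraph, c: ConstraintSet = EMPTY_CONSTRAINTS) -> list[EdgeMove]:
    """All single-edge moves legal under acyclicity and the blacklist.

    Removals are always legal.  An addition ``(u, v)`` is legal iff the edge
    is absent, not forbidden, and ``v`` cannot already reach ``u``.  A
    reversal of ``(u, v)`` is legal iff ``(v, u)`` is not forbidden and no
    second directed path ``u -> ... -> v`` exists besides the edge itself.

    The returned order is deterministic: by kind (add, remove, reverse),
    then lexicographically by edge — structure search tie-breaks rely on it.
    """
    moves: list[EdgeMove] = []
    nodes = sorted(g.nodes)
    for u in nodes:
        for v in nodes:
            if u == v or g.has_edge(u, v) or not c.allows((u, v)):
                continue
            if not g.has_path(v, u):
                moves.append(EdgeMove("add", (u, v)))
    for u, v in sorted(g.edges):
        moves.append(EdgeMove("remove", (u, v)))
    for u, v in sorted(g.edges):
        if not c.allows((v, u)):
            continue
        g.remove_edge(u, v)
        ok = not g.has_path(u, v)
        g.add_edge(u, v)
        if ok:
            moves.append(EdgeMove("reverse", (u, v)))
    moves.sort(key=lambda m: (_KIND_ORDER[m.kind], m.edge))
    return moves


def enumerate_pathways(g: DirectedGraph, outcome: str) -> list[list[str]]:
    """All directed simple paths terminating at ``outcome``.

    Discovered breadth-first from the outcome over reversed edges, so paths
    surface shortest-first; the final order is deterministic (path length,
    then lexicographic).  Each returned sequence runs source -> ... ->
    outcome.
    """
    if outcome not in g:
        raise KeyError(f"unknown outcome node {outcome!r}")
    paths: list[list[str]] = []
    # queue holds reversed partial paths: outcome ... current-front
    queue: deque[tuple[str, ...]] = deque([(outcome,)])
    while queue:
        partial = queue.popleft()
        front = partial[-1]
        for p in g.parents(front):
            if p in partial:  # simple paths only (DAG makes this redundant)
                continue
            extended = partial + (p,)
            paths.append(list(reversed(extended)))
            queue.append(extended)
    paths.sort(key=lambda p: (len(p), p))
    return paths


def prune_sinks(g: DirectedGraph, keep: Sequence[str]) -> DirectedGraph:
    """Iteratively drop nodes with out-degree 0 that are not in ``keep``.

    Used to discard terminal nodes that absorb edges without lying on any
    pathway into the variables of interest (a variable that only ever acts
    as a sink carries no information about routes into the outcome).
    """
    keep_set = set(keep)
    unknown = keep_set - set(g.nodes)
    if unknown:
        raise KeyError(f"keep list names unknown nodes {sorted(unknown)}")
    h = g.copy()
    while True:
        sinks = [v for v in h.nodes if h.out_degree(v) == 0 and v not in keep_set]
        if not sinks:
            return h
        retained = [v for v in h.nodes if v not in sinks]
        h = DirectedGraph(retained, [e for e in h.edges if e[0] not in sinks and e[1] not in sinks])
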