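"""Edge-attributed undirected graphs: data model, preprocessing, I/O.

The central object is :class:`TypedGraph`, a simple undirected graph in
which every edge carries an integer *type code*.  Type labels (strings such
as social-tie names) are mapped to dense codes ``0..|Te|-1`` by a
:class:`TypeRegistry`; edges with no recorded type carry a reserved
*sentinel* code ``|Te|`` so that downstream counters can include or exclude
them explicitly.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "TypeRegistry",
    "TypedGraph",
    "EgoNetwork",
    "build_registry",
    "load_edgelist",
    "load_graphml",
    "as_ego",
    "write_vector_table",
    "write_edgelist",
    "GraphError",
]


class GraphError(ValueError):
    """Raised for malformed graph input or invariant violations."""


@dataclass(frozen=True)
class TypeRegistry:
    """Bijection between edge-type labels and dense integer codes.

    Codes are exactly ``0..n_types-1``, assigned in lexicographically
    sorted label order so that the same label set always yields the same
    coding regardless of input order.  ``sentinel_code == n_types`` is
    reserved for untyped edges and never collides with a real code.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise GraphError("type registry needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise GraphError("type registry labels must be distinct")

    @property
    def code_of(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_types(self) -> int:
        return len(self.labels)

    @property
    def sentinel_code(self) -> int:
        return len(self.labels)

    def label_of(self, code: int) -> str:
        if code == self.sentinel_code:
            return ""
        return self.labels[code]


def build_registry(raw_labels: Iterable[str]) -> TypeRegistry:
    """Build a :class:`TypeRegistry` from raw (possibly repeated) labels.

    Labels are deduplicated and sorted; codes follow sorted order.
    """
    labels = sorted(set(raw_labels))
    if not labels:
        raise GraphError("cannot build a registry from an empty label list")
    return TypeRegistry(tuple(labels))


class TypedGraph:
    """Simple undirected graph with one type code per edge.

    Thin wrapper around :class:`networkx.Graph`; the networkx graph stores
    the code under the edge attribute ``"type_code"``.  Self-loops and
    parallel edges are rejected.  Node identifiers are opaque (hashable,
    typically strings).
    """

    def __init__(self, registry: TypeRegistry | None = None) -> None:
        self.registry = registry or TypeRegistry(("untyped",))
        self._g = nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, u) -> None:
        self._g.add_node(u)

    def add_edge(self, u, v, type_code: int | None = None) -> None:
        if u == v:
            raise GraphError(f"self-loop on node {u!r} is not allowed")
        if self._g.has_edge(u, v):
            raise GraphError(f"duplicate edge ({u!r}, {v!r})")
        code = self.registry.sentinel_code if type_code is None else int(type_code)
        if not 0 <= code <= self.registry.sentinel_code:
            raise GraphError(f"type code {code} outside registry range")
        self._g.add_edge(u, v, type_code=code)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        registry: TypeRegistry | None = None,
        nodes: Iterable | None = None,
    ) -> "TypedGraph":
        """Build from ``(u, v)`` or ``(u, v, type_code)`` tuples."""
        g = cls(registry)
        for e in edges:
            if len(e) == 2:
                g.add_edge(e[0], e[1])
            else:
                g.add_edge(e[0], e[1], e[2])
        if nodes is not None:
            for u in nodes:
                g.add_node(u)
        return g

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list:
        return list(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> list[tuple]:
        """Edges as ``(u, v, type_code)`` triples."""
        return [(u, v, d["type_code"]) for u, v, d in self._g.edges(data=True)]

    def has_node(self, u) -> bool:
        return self._g.has_node(u)

    def has_edge(self, u, v) -> bool:
        return self._g.has_edge(u, v)

    def type_of(self, u, v) -> int:
        try:
            return self._g.edges[u, v]["type_code"]
        except KeyError:
            raise GraphError(f"no edge ({u!r}, {v!r})") from None

    def neighbors(self, u) -> set:
        return set(self._g.adj[u])

    def degree(self, u) -> int:
        return self._g.degree[u]

    @property
    def adj(self) -> Mapping:
        return self._g.adj

    def subgraph(self, nodes: Iterable) -> "TypedGraph":
        sub = TypedGraph(self.registry)
        sub._g = nx.Graph(self._g.subgraph(nodes))
        return sub

    def __eq__(self, other) -> bool:
        if not isinstance(other, TypedGraph):
            return NotImplemented
        return (
            self.registry == other.registry
            and set(self._g.nodes) == set(other._g.nodes)
            and {frozenset((u, v)): c for u, v, c in self.edges()}
            == {frozenset((u, v)): c for u, v, c in other.edges()}
        )

    def __repr__(self) -> str:
        return (
            f"TypedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges}, "
            f"n_types={self.registry.n_types})"
        )


@dataclass(frozen=True)
class EgoNetwork:
    """A :class:`TypedGraph` with a designated ego adjacent to every alter."""

    graph: TypedGraph
    ego: object

    @property
    def alters(self) -> list:
        return sorted(self.graph.neighbors(self.ego), key=str)


def as_ego(graph: TypedGraph, ego) -> EgoNetwork:
    """Validate the ego-dominance invariant and wrap the graph.

    Every node other than the ego must be a direct neighbour of the ego
    (one-hop reachability); otherwise the node list of the violation is
    reported.
    """
    if not graph.has_node(ego):
        raise GraphError(f"ego {ego!r} not in graph")
    unreachable = sorted(
        (u for u in graph.nodes if u != ego and not graph.has_edge(ego, u)), key=str
    )
    if unreachable:
        raise GraphError(
            f"nodes not adjacent to ego {ego!r}: {unreachable}"
        )
    return EgoNetwork(graph=graph, ego=ego)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    for cand in ("\t", ",", ";"):
        if cand in first_line:
            return cand
    return ","


def load_edgelist(
    source,
    delimiter: str | None = None,
    header: bool = False,
    registry: TypeRegistry | None = None,
) -> TypedGraph:
    """Read a typed edge list: columns (source, target[, type_label]).

    ``source`` may be a path or an open text stream.  Lines starting with
    ``#`` and blank lines are skipped.  A missing third column yields the
    sentinel type.  When ``registry`` is not given it is built from the
    observed labels (sorted order); records with labels outside a given
    registry raise :class:`GraphError`.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    rows: list[tuple[str, str, str | None]] = []
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        g = TypedGraph(registry)
        return g
    delim = _sniff_delimiter(lines[0], delimiter)
    reader = csv.reader(lines, delimiter=delim)
    for i, rec in enumerate(reader):
        if header and i == 0:
            continue
        rec = [c.strip() for c in rec]
        if len(rec) < 2 or not rec[0] or not rec[1]:
            raise GraphError(f"record {i + 1}: need at least two node columns, got {rec}")
        label = rec[2] if len(rec) >= 3 and rec[2] else None
        rows.append((rec[0], rec[1], label))

    if registry is None:
        labels = {lab for _, _, lab in rows if lab is not None}
        registry = build_registry(labels) if labels else TypeRegistry(("untyped",))
    code_of = registry.code_of
    g = TypedGraph(registry)
    for u, v, lab in rows:
        if lab is None:
            code = None
        else:
            if lab not in code_of:
                raise GraphError(f"unknown type label {lab!r} (not in registry)")
            code = code_of[lab]
        g.add_edge(u, v, code)
    return g


def write_edgelist(graph: TypedGraph, sink, delimiter: str = ",") -> None:
    """Write a typed edge list readable by :func:`load_edgelist`.

    Sentinel-typed edges are written with an empty third column; isolated
    nodes are not representable in this format.
    """
    own = not hasattr(sink, "write")
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        w = csv.writer(fh, delimiter=delimiter)
        for u, v, code in sorted(graph.edges(), key=lambda e: (str(e[0]), str(e[1]))):
            w.writerow([u, v, graph.registry.label_of(code)])
    finally:
        if own:
            fh.close()


def load_graphml(source, edge_attr_name: str = "type") -> TypedGraph:
    """Read a GraphML document; the named edge attribute holds type labels.

    Directed graphs are rejected.  Edges missing the attribute get the
    sentinel type.
    """
    g_nx = nx.read_graphml(source)
    if g_nx.is_directed():
        raise GraphError("directed GraphML input is not supported")
    labels = {
        str(d[edge_attr_name]) for _, _, d in g_nx.edges(data=True) if edge_attr_name in d
    }
    registry = build_registry(labels) if labels else TypeRegistry(("untyped",))
    code_of = registry.code_of
    g = TypedGraph(registry)
    for u in g_nx.nodes:
        g.add_node(u)
    for u, v, d in g_nx.edges(data=True):
        code = code_of[str(d[edge_attr_name])] if edge_attr_name in d else None
        g.add_edge(u, v, code)
    return g


# ---------------------------------------------------------------------------
# Vector tables
# ---------------------------------------------------------------------------

def write_vector_table(results: Mapping, layout: str = "long", sink=None):
    """Serialise per-node count vectors to a table.

    ``results`` maps node id to one of the vector types produced by the
    counters (anything exposing ``to_long_records()`` and
    ``flat_labels()/flatten()``).  The long layout emits one row per
    nonzero ``(node, orbit, type, count)`` cell; the wide layout emits one
    row per node with deterministically ordered columns.

    Returns the assembled :class:`pandas.DataFrame`; when ``sink`` is given
    the frame is also written there as CSV.
    """
    if layout not in ("long", "wide"):
        raise GraphError(f"unknown layout {layout!r}")
    kinds = {type(v).__name__ for v in results.values()}
    if len(kinds) > 1:
        raise GraphError(f"mixed vector kinds in one table: {sorted(kinds)}")

    if layout == "long":
        rows = []
        for node in sorted(results, key=str):
            for rec in results[node].to_long_records():
                rows.append((node, *rec))
        df = pd.DataFrame(rows, columns=["node", "orbit", "type", "count"])
    else:
        nodes = sorted(results, key=str)
        if nodes:
            cols = results[nodes[0]].flat_labels()
            data = [results[n].flatten() for n in nodes]
            df = pd.DataFrame(data, index=pd.Index(nodes, name="node"), columns=cols)
            df = df.reset_index()
        else:
            df = pd.DataFrame(columns=["node"])
    if sink is not None:
        df.to_csv(sink, index=False)
    return df


def to_json(results: Mapping, sink=None) -> str:
    """Node -> nested counts as JSON (sparse; orbit -> type/key -> count)."""
    payload = {str(n): v.to_nested() for n, v in sorted(results.items(), key=lambda kv: str(kv[0]))}
    text = json.dumps(payload, indent=1, sort_keys=True)
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text
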