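"""Graphlet counting engines for edge-typed networks.

Six per-node vector families over the 2-4-node graphlets:

``GDV``
    classic graphlet degree vector — frequency of each node orbit the
    node touches (15 orbits sociocentric, 7 egocentric graphlets).
``TyE-GDV``
    typed-edge GDV — an orbit x edge-type matrix; every edge of every
    detected orbit instance contributes +1 to its (orbit, type) cell.
``TyE-EGDV``
    the egocentric TyE-GDV over the seven egocentric graphlets.
``TyE-DV``
    typed-edge degree vector — incident edge counts per type.
``ColoredE-GDV``
    per-orbit counts keyed by the *set* of distinct edge types present in
    an instance.
``HeteroE-GDV``
    per-orbit counts keyed by the sorted *multiset* of all edge types of
    an instance.

All counters enumerate instances through ordered neighbour pair/triple
combinations so no instance is visited twice, and classify each candidate
by its full induced adjacency (a neighbour triple that closes into a
clique is a 4-clique, never additionally a star).  Untyped edges carry the
registry's sentinel code; ``include_sentinel`` controls whether they are
tallied in a dedicated column/key or skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np

from .graph import EgoNetwork, GraphError, TypedGraph, as_ego

__all__ = [
    "GDVector",
    "TypedGDV",
    "TypedDegreeVector",
    "ColoredGDV",
    "HeteroGDV",
    "count_gdv",
    "count_tye_gdv",
    "count_tye_egdv",
    "count_tye_dv",
    "count_colored_gdv",
    "count_hetero_gdv",
    "SOCIO_ORBIT_EDGES",
    "EGO_GRAPHLET_EDGES",
]

# edges in the graphlet owning each sociocentric node orbit 0..14
SOCIO_ORBIT_EDGES = (1, 2, 2, 3, 3, 3, 3, 3, 4, 4, 4, 4, 5, 5, 6)
# edges in each egocentric graphlet 0..6
EGO_GRAPHLET_EDGES = (1, 2, 3, 3, 4, 5, 6)

N_SOCIO_ORBITS = 15
N_EGO_GRAPHLETS = 7


def _orbit_count(mode: str) -> int:
    if mode == "sociocentric":
        return N_SOCIO_ORBITS
    if mode == "egocentric":
        return N_EGO_GRAPHLETS
    raise ValueError(f"unknown mode {mode!r}")


def _edges_per_orbit(mode: str):
    return SOCIO_ORBIT_EDGES if mode == "sociocentric" else EGO_GRAPHLET_EDGES


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class GDVector:
    """Orbit frequencies for one node (classic graphlet degree vector)."""

    counts: np.ndarray
    mode: str = "sociocentric"

    def flatten(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def flat_labels(self) -> list[str]:
        return [f"orbit{o}" for o in range(len(self.counts))]

    def to_long_records(self):
        return [(o, "", int(c)) for o, c in enumerate(self.counts) if c]

    def to_nested(self):
        return {str(o): int(c) for o, c in enumerate(self.counts) if c}


@dataclass
class TypedGDV:
    """Orbit x edge-type count matrix for one node.

    Column ``t`` counts edges of type ``t`` over all instances of the row
    orbit; when ``include_sentinel`` the last column is the sentinel
    (untyped) column and the row sums satisfy
    ``sum_t counts[o, t] == m(o) * GDV[o]`` with ``m(o)`` the edge count
    of orbit ``o``'s graphlet.
    """

    counts: np.ndarray  # shape (n_orbits, width)
    mode: str = "sociocentric"
    include_sentinel: bool = True

    def flatten(self) -> np.ndarray:
        return self.counts.reshape(-1)

    def flat_labels(self) -> list[str]:
        n_orb, width = self.counts.shape
        tail = width - 1 if self.include_sentinel else None
        labels = []
        for o in range(n_orb):
            for t in range(width):
                labels.append(f"o{o}_t{'U' if t == tail else t}")
        return labels

    def to_long_records(self):
        recs = []
        for o in range(self.counts.shape[0]):
            for t in range(self.counts.shape[1]):
                if self.counts[o, t]:
                    recs.append((o, t, int(self.counts[o, t])))
        return recs

    def to_nested(self):
        return {
            str(o): {str(t): int(c) for t, c in enumerate(row) if c}
            for o, row in enumerate(self.counts)
            if row.any()
        }


@dataclass
class TypedDegreeVector:
    """Incident edge counts per type (typed-edge degree vector).

    With the sentinel column included the entries sum to the node degree.
    """

    counts: np.ndarray
    include_sentinel: bool = True

    def flatten(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def flat_labels(self) -> list[str]:
        width = len(self.counts)
        tail = width - 1 if self.include_sentinel else None
        return [f"t{'U' if t == tail else t}" for t in range(width)]

    def to_long_records(self):
        return [(0, t, int(c)) for t, c in enumerate(self.counts) if c]

    def to_nested(self):
        return {str(t): int(c) for t, c in enumerate(self.counts) if c}


@dataclass
class _KeyedGDV:
    """Shared machinery for colored / heterogeneous per-orbit keyed counts."""

    by_orbit: tuple
    mode: str = "sociocentric"
    include_sentinel: bool = True

    def orbit_total(self, o: int) -> int:
        return sum(self.by_orbit[o].values())

    def to_dense(self, indexes) -> np.ndarray:
        """Concatenate per-orbit dense blocks given one DenseTypeIndex per orbit."""
        blocks = []
        for o, index in enumerate(indexes):
            block = np.zeros(len(index), dtype=np.int64)
            for key, c in self.by_orbit[o].items():
                block[index.position(key)] = c
            blocks.append(block)
        return np.concatenate(blocks)

    def to_long_records(self):
        recs = []
        for o, d in enumerate(self.by_orbit):
            for key in sorted(d):
                recs.append((o, "|".join(map(str, key)), d[key]))
        return recs

    def to_nested(self):
        return {
            str(o): {"|".join(map(str, k)): c for k, c in sorted(d.items())}
            for o, d in enumerate(self.by_orbit)
            if d
        }


class ColoredGDV(_KeyedGDV):
    """Per-orbit counts keyed by the set of distinct edge types."""


class HeteroGDV(_KeyedGDV):
    """Per-orbit counts keyed by the sorted multiset of all edge types."""


# ---------------------------------------------------------------------------
# Instance enumeration
# ---------------------------------------------------------------------------

def _sociocentric_instances(graph: TypedGraph, u, stats: dict | None = None):
    """Yield ``(orbit, edges)`` for every 2-4-node induced instance at ``u``.

    ``edges`` lists *all* induced edges of the instance as node pairs.
    Enumeration is by the u-centred combinatorial case analysis: neighbour
    singles/pairs/triples plus controlled reaches outside N(u); each
    connected induced subset containing ``u`` is produced exactly once,
    classified by which edges close among the chosen nodes.
    """
    adj = graph.adj
    nbrs_u = set(adj[u])
    Nu = sorted(nbrs_u, key=str)
    excl = nbrs_u | {u}

    # size 2
    for v in Nu:
        yield 0, [(u, v)]

    # size 3, u adjacent to both others
    for v, w in combinations(Nu, 2):
        if w in adj[v]:
            yield 3, [(u, v), (u, w), (v, w)]
        else:
            yield 2, [(u, v), (u, w)]

    # size 3, u an end of a path
    for v in Nu:
        for w in sorted(set(adj[v]) - excl, key=str):
            yield 1, [(u, v), (v, w)]

    # size 4, all three others adjacent to u
    for v, w, x in combinations(Nu, 3):
        if stats is not None:
            stats["triples"] = stats.get("triples", 0) + 1
        closing = []
        if w in adj[v]:
            closing.append((v, w))
        if x in adj[v]:
            closing.append((v, x))
        if x in adj[w]:
            closing.append((w, x))
        orbit = (7, 11, 13, 14)[len(closing)]
        yield orbit, [(u, v), (u, w), (u, x)] + closing

    # size 4, exactly two others adjacent to u, one outsider
    for v, w in combinations(Nu, 2):
        vw = w in adj[v]
        cand = (set(adj[v]) | set(adj[w])) - excl
        for x in sorted(cand, key=str):
            xv = x in adj[v]
            xw = x in adj[w]
            edges = [(u, v), (u, w)]
            if vw:
                edges.append((v, w))
                orbit = 12 if (xv and xw) else 10
            else:
                orbit = 8 if (xv and xw) else 5
            if xv:
                edges.append((v, x))
            if xw:
                edges.append((w, x))
            yield orbit, edges

    # size 4, one neighbour v, two outsiders hanging off v
    for v in Nu:
        reach = sorted(set(adj[v]) - excl, key=str)
        for w, x in combinations(reach, 2):
            if x in adj[w]:
                yield 9, [(u, v), (v, w), (v, x), (w, x)]
            else:
                yield 6, [(u, v), (v, w), (v, x)]
        for w in reach:
            for x in sorted(set(adj[w]) - excl - set(adj[v]) - {v}, key=str):
                yield 4, [(u, v), (v, w), (w, x)]


def _egocentric_instances(graph: TypedGraph, ego, stats: dict | None = None):
    """Yield ``(ego_gid, edges)`` over the seven egocentric graphlets.

    ``graph`` must be the ego's 1-hop induced subgraph.  Because every
    alter is adjacent to the ego, alter pairs and triples enumerate all
    instances in which the ego dominates; the induced alter-alter edges
    decide the class.
    """
    adj = graph.adj
    alters = sorted(set(adj[ego]), key=str)

    for v in alters:
        yield 0, [(ego, v)]

    for v, w in combinations(alters, 2):
        if w in adj[v]:
            yield 2, [(ego, v), (ego, w), (v, w)]
        else:
            yield 1, [(ego, v), (ego, w)]

    for v, w, x in combinations(alters, 3):
        if stats is not None:
            stats["triples"] = stats.get("triples", 0) + 1
        closing = [
            e for e in ((v, w), (v, x), (w, x)) if e[1] in adj[e[0]]
        ]
        gid = (3, 4, 5, 6)[len(closing)]
        yield gid, [(ego, v), (ego, w), (ego, x)] + closing


def _instances(graph: TypedGraph, target, mode: str, stats: dict | None = None):
    if mode == "sociocentric":
        yield from _sociocentric_instances(graph, target, stats)
    elif mode == "egocentric":
        hood = graph.subgraph(set(graph.neighbors(target)) | {target})
        yield from _egocentric_instances(hood, target, stats)
    else:
        raise ValueError(f"unknown mode {mode!r}")


def _resolve_targets(graph: TypedGraph, targets):
    if targets is None:
        return sorted(graph.nodes, key=str)
    targets = list(targets)
    for t in targets:
        if not graph.has_node(t):
            raise GraphError(f"target node {t!r} not in graph")
    return sorted(targets, key=str)


# ---------------------------------------------------------------------------
# Counters
# ---------------------------------------------------------------------------

def count_gdv(
    graph: TypedGraph,
    targets: Iterable | None = None,
    mode: str = "sociocentric",
    stats: dict | None = None,
) -> dict:
    """Classic graphlet degree vector per target node."""
    n_orb = _orbit_count(mode)
    out = {}
    for u in _resolve_targets(graph, targets):
        vec = np.zeros(n_orb, dtype=np.int64)
        for orbit, _ in _instances(graph, u, mode, stats):
            vec[orbit] += 1
        out[u] = GDVector(counts=vec, mode=mode)
    return out


def _type_width(graph: TypedGraph, include_sentinel: bool) -> int:
    n = graph.registry.n_types
    return n + 1 if include_sentinel else n


def count_tye_gdv(
    graph: TypedGraph,
    targets: Iterable | None = None,
    mode: str = "sociocentric",
    include_sentinel: bool = True,
) -> dict:
    """Typed-edge GDV: every instance edge feeds its (orbit, type) cell."""
    n_orb = _orbit_count(mode)
    width = _type_width(graph, include_sentinel)
    sentinel = graph.registry.sentinel_code
    out = {}
    for u in _resolve_targets(graph, targets):
        vec = np.zeros((n_orb, width), dtype=np.int64)
        for orbit, edges in _instances(graph, u, mode):
            for a, b in edges:
                t = graph.type_of(a, b)
                if t == sentinel and not include_sentinel:
                    continue
                vec[orbit, t] += 1
        out[u] = TypedGDV(counts=vec, mode=mode, include_sentinel=include_sentinel)
    return out


def count_tye_egdv(egonet: EgoNetwork, include_sentinel: bool = True) -> TypedGDV:
    """Typed-edge ego-graphlet degree vector (7 x types) for the ego."""
    result = count_tye_gdv(
        egonet.graph,
        targets=[egonet.ego],
        mode="egocentric",
        include_sentinel=include_sentinel,
    )
    return result[egonet.ego]


def count_tye_dv(
    graph: TypedGraph,
    targets: Iterable | None = None,
    include_sentinel: bool = True,
) -> dict:
    """Typed-edge degree vector: incident edge counts per type."""
    width = _type_width(graph, include_sentinel)
    sentinel = graph.registry.sentinel_code
    out = {}
    for u in _resolve_targets(graph, targets):
        vec = np.zeros(width, dtype=np.int64)
        for v in graph.neighbors(u):
            t = graph.type_of(u, v)
            if t == sentinel and not include_sentinel:
                continue
            vec[t] += 1
        out[u] = TypedDegreeVector(counts=vec, include_sentinel=include_sentinel)
    return out


def _instance_types(graph: TypedGraph, edges, sentinel: int, include_sentinel: bool):
    types = [graph.type_of(a, b) for a, b in edges]
    if not include_sentinel:
        types = [t for t in types if t != sentinel]
    return types


def count_colored_gdv(
    graph: TypedGraph,
    targets: Iterable | None = None,
    mode: str = "sociocentric",
    include_sentinel: bool = True,
) -> dict:
    """Colored variant: instances keyed by the set of distinct edge types.

    With ``include_sentinel=False`` an instance whose edges are all
    untyped has no admissible key and is skipped.
    """
    return _count_keyed(graph, targets, mode, include_sentinel, ColoredGDV, as_set=True)


def count_hetero_gdv(
    graph: TypedGraph,
    targets: Iterable | None = None,
    mode: str = "sociocentric",
    include_sentinel: bool = True,
) -> dict:
    """Heterogeneous variant: instances keyed by the full type multiset."""
    return _count_keyed(graph, targets, mode, include_sentinel, HeteroGDV, as_set=False)


def _count_keyed(graph, targets, mode, include_sentinel, cls, as_set):
    n_orb = _orbit_count(mode)
    sentinel = graph.registry.sentinel_code
    out = {}
    for u in _resolve_targets(graph, targets):
        by_orbit = tuple({} for _ in range(n_orb))
        for orbit, edges in _instances(graph, u, mode):
            types = _instance_types(graph, edges, sentinel, include_sentinel)
            if not types:
                continue
            key = tuple(sorted(set(types))) if as_set else tuple(sorted(types))
            d = by_orbit[orbit]
            d[key] = d.get(key, 0) + 1
        out[u] = cls(by_orbit=by_orbit, mode=mode, include_sentinel=include_sentinel)
    return out
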