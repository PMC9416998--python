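"""Graphlet atlas: canonical graphs, automorphism orbits, combinatorics.

A *graphlet* is a small connected non-isomorphic induced subgraph (2-5
nodes here).  Each graphlet class carries its node orbits and edge orbits
— equivalence classes of positions under the automorphism group — plus an
egocentric flag (does a node adjacent to all others exist).

For sizes 2-4 the numbering follows the classic convention: G0 the edge,
G1 the 3-path, G2 the triangle, G3 the 4-path, G4 the 3-star, G5 the
4-cycle, G6 the tailed triangle, G7 the 4-chordal-cycle (diamond), G8 the
4-clique; node orbits 0-14 in class order with lower-degree positions
first (so orbit 3 is the triangle node and orbit 13 the diamond's
degree-3 node).  Sizes of 5 nodes are enumerated deterministically but
their numbering is library-internal.

The module also houses the key-space combinatorics for edge-typed
graphlet variants: with T types and K typed slots, the colored family
(sets of distinct types) has ``sum_{n=1..min(K,T)} C(T,n)`` keys and the
heterogeneous family (multisets of size K) has ``C(T+K-1, K)`` keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from itertools import combinations, combinations_with_replacement, permutations
from math import comb
from typing import Iterable, Sequence

__all__ = [
    "GraphletClass",
    "Atlas",
    "DenseTypeIndex",
    "build_atlas",
    "egocentric_subatlas",
    "colored_count",
    "hetero_count",
    "dense_index",
    "classify_instance",
    "EGO_GRAPHLET_NAMES",
]

_NAMES_2_4 = {
    0: "2-clique",
    1: "2-path",
    2: "3-clique",
    3: "3-path",
    4: "3-star",
    5: "4-cycle",
    6: "tailed-triangle",
    7: "4-chordal-cycle",
    8: "4-clique",
}

EGO_GRAPHLET_NAMES = (
    "2-clique",
    "2-path",
    "3-clique",
    "3-star",
    "tailed-triangle",
    "4-chordal-cycle",
    "4-clique",
)


Edge = tuple[int, int]


def _canonical_form(k: int, edges: frozenset[Edge]) -> tuple[Edge, ...]:
    """Minimum edge tuple over all relabelings of nodes 0..k-1."""
    best = None
    for perm in permutations(range(k)):
        mapped = tuple(
            sorted(tuple(sorted((perm[u], perm[v]))) for u, v in edges)
        )
        if best is None or mapped < best:
            best = mapped
    return best


def _automorphisms(k: int, edges: frozenset[Edge]):
    eset = {tuple(sorted(e)) for e in edges}
    for perm in permutations(range(k)):
        if all(tuple(sorted((perm[u], perm[v]))) in eset for u, v in eset):
            yield perm


def _orbit_partition(k: int, edges: frozenset[Edge]):
    """Node orbits and edge orbits under the automorphism group.

    Returns (node_orbit_sets, edge_orbit_sets) as lists of frozensets.
    """
    node_parent = list(range(k))

    def find(x, parent):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b, parent):
        ra, rb = find(a, parent), find(b, parent)
        if ra != rb:
            parent[rb] = ra

    elist = sorted(tuple(sorted(e)) for e in edges)
    eidx = {e: i for i, e in enumerate(elist)}
    edge_parent = list(range(len(elist)))
    for perm in _automorphisms(k, edges):
        for u in range(k):
            union(u, perm[u], node_parent)
        for e in elist:
            img = tuple(sorted((perm[e[0]], perm[e[1]])))
            union(eidx[e], eidx[img], edge_parent)
    node_orbits = {}
    for u in range(k):
        node_orbits.setdefault(find(u, node_parent), set()).add(u)
    edge_orbits = {}
    for e in elist:
        edge_orbits.setdefault(find(eidx[e], edge_parent), set()).add(e)
    return (
        [frozenset(s) for s in node_orbits.values()],
        [frozenset(s) for s in edge_orbits.values()],
    )


@dataclass(frozen=True)
class GraphletClass:
    """One isomorphism class with its orbit structure.

    ``canon`` is the class's canonical edge tuple on nodes ``0..n_nodes-1``.
    ``node_orbit_of[i]`` / ``edge_orbit_of[e]`` give *global* orbit ids for
    canonical positions; ``ego_positions`` are the global orbit ids of
    dominating nodes (adjacent to all others), nonempty iff
    ``is_egocentric``.
    """

    gid: int
    n_nodes: int
    n_edges: int
    canon: tuple[Edge, ...]
    node_orbit_of: tuple[int, ...]
    edge_orbit_of: dict
    is_egocentric: bool
    ego_positions: frozenset[int]
    name: str

    @property
    def orbit_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.node_orbit_of)))


@dataclass(frozen=True)
class Atlas:
    """All graphlet classes of 2..max_size nodes under a fixed numbering."""

    max_size: int
    classes: tuple[GraphletClass, ...]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def node_orbit_count(self) -> int:
        return 1 + max(o for c in self.classes for o in c.node_orbit_of)

    @property
    def edge_orbit_count(self) -> int:
        return 1 + max(o for c in self.classes for o in c.edge_orbit_of.values())

    def class_by_canon(self) -> dict:
        return {(c.n_nodes, c.canon): c for c in self.classes}

    def orbit_to_gid(self) -> dict[int, int]:
        return {o: c.gid for c in self.classes for o in c.node_orbit_of}

    def edges_per_orbit(self) -> dict[int, int]:
        """Global node-orbit id -> number of edges of its graphlet."""
        return {o: c.n_edges for c in self.classes for o in c.node_orbit_of}

    def to_json(self) -> str:
        payload = [
            {
                "gid": c.gid,
                "name": c.name,
                "n_nodes": c.n_nodes,
                "edges": [list(e) for e in c.canon],
                "node_orbits": list(c.node_orbit_of),
                "edge_orbits": {f"{u}-{v}": o for (u, v), o in sorted(c.edge_orbit_of.items())},
                "is_egocentric": c.is_egocentric,
                "ego_positions": sorted(c.ego_positions),
            }
            for c in self.classes
        ]
        return json.dumps(payload, indent=1)


def _degree_sequence(k: int, edges: Sequence[Edge]) -> list[int]:
    deg = [0] * k
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return deg


def _connected(k: int, edges: Iterable[Edge]) -> bool:
    adj = {u: set() for u in range(k)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == k


def build_atlas(max_size: int = 4) -> Atlas:
    """Enumerate all connected graphs of 2..max_size nodes with orbits.

    Exhaustive generation over edge subsets with isomorphism rejection by
    canonical form (brute-force permutations; exact at these sizes).
    """
    if not 2 <= max_size <= 5:
        raise ValueError(f"max_size must be in 2..5, got {max_size}")

    reps: list[tuple[int, tuple[Edge, ...]]] = []
    for k in range(2, max_size + 1):
        seen = set()
        all_pairs = list(combinations(range(k), 2))
        for m in range(k - 1, len(all_pairs) + 1):
            for subset in combinations(all_pairs, m):
                if not _connected(k, subset):
                    continue
                canon = _canonical_form(k, frozenset(subset))
                if canon not in seen:
                    seen.add(canon)
                    reps.append((k, canon))

    # Class order: size, then edge count, then descending degree sequence
    # (lexicographic), then canonical edges.  For sizes 2-4 this reproduces
    # the classic G0..G8 numbering.
    def class_key(rep):
        k, canon = rep
        degs = tuple(sorted(_degree_sequence(k, canon), reverse=True))
        return (k, len(canon), degs, canon)

    reps.sort(key=class_key)

    classes: list[GraphletClass] = []
    next_node_orbit = 0
    next_edge_orbit = 0
    for gid, (k, canon) in enumerate(reps):
        node_sets, edge_sets = _orbit_partition(k, frozenset(canon))
        deg = _degree_sequence(k, canon)

        def node_orbit_key(s):
            rep_node = min(s)
            nbr_degs = sorted(
                (deg[v] if u == rep_node else deg[u] for u, v in canon if rep_node in (u, v)),
                reverse=True,
            )
            return (deg[rep_node], tuple(nbr_degs), rep_node)

        node_sets.sort(key=node_orbit_key)
        node_orbit_of = [0] * k
        for s in node_sets:
            for u in s:
                node_orbit_of[u] = next_node_orbit
            next_node_orbit += 1

        def edge_orbit_key(s):
            e = min(s)
            return (tuple(sorted((deg[e[0]], deg[e[1]]))), e)

        edge_sets.sort(key=edge_orbit_key)
        edge_orbit_of = {}
        for s in edge_sets:
            for e in s:
                edge_orbit_of[e] = next_edge_orbit
            next_edge_orbit += 1

        dominating = [u for u in range(k) if deg[u] == k - 1]
        ego_positions = frozenset(node_orbit_of[u] for u in dominating)
        # sizes 2-4 always sort first, so gids 0..8 keep their classic names
        name = _NAMES_2_4.get(gid, f"graphlet-{gid}")
        classes.append(
            GraphletClass(
                gid=gid,
                n_nodes=k,
                n_edges=len(canon),
                canon=canon,
                node_orbit_of=tuple(node_orbit_of),
                edge_orbit_of=edge_orbit_of,
                is_egocentric=bool(dominating),
                ego_positions=ego_positions,
                name=name,
            )
        )
    return Atlas(max_size=max_size, classes=tuple(classes))


def egocentric_subatlas(atlas: Atlas) -> list[GraphletClass]:
    """The classes admitting an ego (a dominating node), in class order.

    For the size-4 atlas these are the seven egocentric graphlets:
    2-clique, 2-path, 3-clique, 3-star, tailed-triangle, 4-chordal-cycle
    and 4-clique; the 3-path and the 4-cycle drop out because no node in
    them reaches every other node in one hop.
    """
    if atlas.max_size != 4:
        raise ValueError("egocentric sub-atlas is defined on the size-4 atlas")
    return [c for c in atlas.classes if c.is_egocentric]


# ---------------------------------------------------------------------------
# Key-space combinatorics
# ---------------------------------------------------------------------------

def colored_count(K: int, T: int) -> int:
    """Number of distinct non-empty type *sets* fitting K slots, T types.

    ``sum_{n=1..min(K,T)} C(T, n)``; collapses to ``2**T - 1`` when
    ``K >= T``.
    """
    if K < 1 or T < 1:
        raise ValueError("K and T must be positive")
    return sum(comb(T, n) for n in range(1, min(K, T) + 1))


def hetero_count(K: int, T: int) -> int:
    """Number of type *multisets* of size exactly K from T types.

    Combinations with repetition: ``C(T + K - 1, K)``.
    """
    if K < 1 or T < 1:
        raise ValueError("K and T must be positive")
    return comb(T + K - 1, K)


@dataclass(frozen=True)
class DenseTypeIndex:
    """Lexicographic dense layout for colored (set) or hetero (multiset) keys.

    ``keys`` enumerates every admissible sorted tuple; ``position`` is a
    total lookup over them.  Lengths match :func:`colored_count` /
    :func:`hetero_count` by construction.
    """

    kind: str
    slot_count: int
    type_count: int
    keys: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.keys)

    def position(self, key: tuple[int, ...], canonicalize: bool = False) -> int:
        if canonicalize:
            key = tuple(sorted(key))
        try:
            return self._lookup[key]
        except KeyError:
            raise KeyError(
                f"key {key!r} not admissible for kind={self.kind!r}, "
                f"K={self.slot_count}, T={self.type_count}"
            ) from None

    @cached_property
    def _lookup(self) -> dict:
        return {k: i for i, k in enumerate(self.keys)}


def dense_index(kind: str, K: int, T: int) -> DenseTypeIndex:
    """Enumerate the admissible key family in lexicographic order."""
    if K < 1 or T < 1:
        raise ValueError("K and T must be positive")
    if kind == "set":
        keys = sorted(
            key
            for n in range(1, min(K, T) + 1)
            for key in combinations(range(T), n)
        )
    elif kind == "multiset":
        keys = list(combinations_with_replacement(range(T), K))
    else:
        raise ValueError(f"unknown index kind {kind!r}")
    return DenseTypeIndex(kind=kind, slot_count=K, type_count=T, keys=tuple(keys))


# ---------------------------------------------------------------------------
# Instance classification (used by the brute-force oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Classified:
    gid: int
    orbit: int
    edge_orbits: dict  # instance edge (sorted pair) -> global edge orbit id


def classify_instance(atlas: Atlas, nodes: Sequence, edges: Iterable[tuple], focal=None) -> Classified:
    """Identify the class of an induced instance and the focal node's orbit.

    ``nodes`` lists the instance nodes; ``edges`` its induced edges as node
    pairs.  The instance must be connected and within the atlas size.
    """
    nodes = list(nodes)
    k = len(nodes)
    if k > atlas.max_size or k < 2:
        raise ValueError(f"instance size {k} outside atlas range")
    idx = {u: i for i, u in enumerate(nodes)}
    int_edges = frozenset(tuple(sorted((idx[u], idx[v]))) for u, v in edges)
    if not _connected(k, int_edges):
        raise ValueError("instance subset induces a disconnected graph")
    by_canon = atlas.class_by_canon()
    eset = {tuple(sorted(e)) for e in int_edges}
    for perm in permutations(range(k)):
        mapped = tuple(sorted(tuple(sorted((perm[u], perm[v]))) for u, v in eset))
        cls = by_canon.get((k, mapped))
        if cls is not None:
            focal_orbit = -1
            if focal is not None:
                focal_orbit = cls.node_orbit_of[perm[idx[focal]]]
            edge_orbits = {}
            for u, v in edges:
                canon_e = tuple(sorted((perm[idx[u]], perm[idx[v]])))
                edge_orbits[tuple(sorted((u, v), key=str))] = cls.edge_orbit_of[canon_e]
            return Classified(gid=cls.gid, orbit=focal_orbit, edge_orbits=edge_orbits)
    raise ValueError("instance matches no atlas class")  # pragma: no cover
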