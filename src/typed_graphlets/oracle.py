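"""Brute-force reference counter: exhaustive subset enumeration.

Deliberately slow and simple — every connected induced subgraph of 2-4
nodes containing a focal node is found by filtering all node subsets, and
classified independently through the atlas's permutation-based
:func:`~typed_graphlets.atlas.classify_instance`.  Serves as the testing
oracle for the fast combinatorial counters; cap input graphs at roughly
twenty nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import counters as _c
from .atlas import Atlas, build_atlas, classify_instance, egocentric_subatlas
from .graph import EgoNetwork, TypedGraph

__all__ = ["InstanceRecord", "enumerate_instances", "oracle_vectors"]


@dataclass(frozen=True)
class InstanceRecord:
    """One connected induced subgraph containing the focal node."""

    nodes: frozenset
    gid: int
    orbit: int  # focal node's orbit (global node-orbit id)
    type_tuple: tuple[int, ...]  # sorted types of all induced edges


def _induced_edges(graph: TypedGraph, subset):
    return [
        (a, b) for a, b in combinations(sorted(subset, key=str), 2) if graph.has_edge(a, b)
    ]


def enumerate_instances(
    graph: TypedGraph, focal, max_size: int = 4, atlas: Atlas | None = None
) -> list[InstanceRecord]:
    """All connected induced instances of sizes 2..max_size containing focal."""
    if max_size > 4:
        raise ValueError("oracle enumeration is limited to 4-node instances")
    if atlas is None:
        atlas = build_atlas(4)
    others = sorted((u for u in graph.nodes if u != focal), key=str)
    records = []
    for k in range(2, max_size + 1):
        for extra in combinations(others, k - 1):
            subset = (focal, *extra)
            edges = _induced_edges(graph, subset)
            try:
                cls = classify_instance(atlas, subset, edges, focal=focal)
            except ValueError:  # disconnected subset
                continue
            types = tuple(sorted(graph.type_of(a, b) for a, b in edges))
            records.append(
                InstanceRecord(
                    nodes=frozenset(subset), gid=cls.gid, orbit=cls.orbit, type_tuple=types
                )
            )
    return records


_SOCIO_KINDS = {"gdv", "tye-gdv", "tye-dv", "colored", "hetero"}


def _ego_records(graph: TypedGraph, focal, atlas: Atlas):
    """Records inside the 1-hop neighbourhood where focal dominates,
    re-labelled with egocentric graphlet ids 0..6."""
    hood = graph.subgraph(set(graph.neighbors(focal)) | {focal})
    gid_to_ego = {c.gid: i for i, c in enumerate(egocentric_subatlas(atlas))}
    out = []
    for rec in enumerate_instances(hood, focal, atlas=atlas):
        if all(u == focal or hood.has_edge(focal, u) for u in rec.nodes):
            if rec.gid in gid_to_ego:
                out.append(
                    InstanceRecord(
                        nodes=rec.nodes,
                        gid=gid_to_ego[rec.gid],
                        orbit=gid_to_ego[rec.gid],
                        type_tuple=rec.type_tuple,
                    )
                )
    return out


def oracle_vectors(
    graph: TypedGraph,
    targets=None,
    which: str = "gdv",
    mode: str = "sociocentric",
    include_sentinel: bool = True,
) -> dict:
    """Tally instance records into the same result shapes as the counters."""
    if which not in _SOCIO_KINDS:
        raise ValueError(f"unknown counter kind {which!r}")
    atlas = build_atlas(4)
    targets = _c._resolve_targets(graph, targets)
    sentinel = graph.registry.sentinel_code
    n_orb = _c.N_SOCIO_ORBITS if mode == "sociocentric" else _c.N_EGO_GRAPHLETS
    width = graph.registry.n_types + (1 if include_sentinel else 0)

    out = {}
    for u in targets:
        if which == "tye-dv":
            vec = np.zeros(width, dtype=np.int64)
            for v in graph.neighbors(u):
                t = graph.type_of(u, v)
                if t == sentinel and not include_sentinel:
                    continue
                vec[t] += 1
            out[u] = _c.TypedDegreeVector(counts=vec, include_sentinel=include_sentinel)
            continue

        if mode == "sociocentric":
            records = enumerate_instances(graph, u, atlas=atlas)
        else:
            records = _ego_records(graph, u, atlas)

        if which == "gdv":
            vec = np.zeros(n_orb, dtype=np.int64)
            for rec in records:
                vec[rec.orbit] += 1
            out[u] = _c.GDVector(counts=vec, mode=mode)
        elif which == "tye-gdv":
            vec = np.zeros((n_orb, width), dtype=np.int64)
            for rec in records:
                for t in rec.type_tuple:
                    if t == sentinel and not include_sentinel:
                        continue
                    vec[rec.orbit, t] += 1
            out[u] = _c.TypedGDV(counts=vec, mode=mode, include_sentinel=include_sentinel)
        else:
            by_orbit = tuple({} for _ in range(n_orb))
            for rec in records:
                types = [t for t in rec.type_tuple if include_sentinel or t != sentinel]
                if not types:
                    continue
                key = (
                    tuple(sorted(set(types))) if which == "colored" else tuple(sorted(types))
                )
                d = by_orbit[rec.orbit]
                d[key] = d.get(key, 0) + 1
            cls = _c.ColoredGDV if which == "colored" else _c.HeteroGDV
            out[u] = cls(by_orbit=by_orbit, mode=mode, include_sentinel=include_sentinel)
    return out
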