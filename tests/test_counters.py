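"""Counting engines: worked examples, closed forms, typed update rules."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from typed_graphlets import (
    GraphError,
    TypedGraph,
    TypeRegistry,
    as_ego,
    count_colored_gdv,
    count_gdv,
    count_hetero_gdv,
    count_tye_dv,
    count_tye_egdv,
    count_tye_gdv,
    generate_random_typed_graph,
)
from typed_graphlets.counters import EGO_GRAPHLET_EDGES, SOCIO_ORBIT_EDGES


def _complete(n, type_code=0, registry=None):
    reg = registry or TypeRegistry(("a", "b", "c"))
    names = [f"n{i}" for i in range(n)]
    return TypedGraph.from_edges(
        [(u, v, type_code) for u, v in combinations(names, 2)], registry=reg
    )


def _star(n_leaves, registry=None):
    reg = registry or TypeRegistry(("a", "b", "c"))
    return TypedGraph.from_edges(
        [("c0", f"l{i}", 0) for i in range(n_leaves)], registry=reg
    )


# ---------------------------------------------------------------------------
# GDV
# ---------------------------------------------------------------------------


def test_gdv_diamond_worked_example(diamond):
    gdv = count_gdv(diamond, ["u"])["u"].counts
    expected = np.zeros(15, dtype=int)
    expected[[0, 2, 3, 13]] = [3, 1, 2, 1]
    assert np.array_equal(gdv, expected)


def test_gdv_k4_node():
    gdv = count_gdv(_complete(4), ["n0"])["n0"].counts
    expected = np.zeros(15, dtype=int)
    expected[[0, 3, 14]] = [3, 3, 1]
    assert np.array_equal(gdv, expected)


def test_gdv_isolated_node():
    g = TypedGraph()
    g.add_node("solo")
    assert count_gdv(g, ["solo"])["solo"].counts.sum() == 0


def test_gdv_unknown_target():
    g = TypedGraph.from_edges([("a", "b")])
    with pytest.raises(GraphError):
        count_gdv(g, ["zz"])


@pytest.mark.parametrize("n", range(4, 11))
def test_gdv_complete_graph_closed_form(n):
    """K_n node: orbit0 = n-1, orbit3 = C(n-1,2), orbit14 = C(n-1,3)."""
    gdv = count_gdv(_complete(n), ["n0"])["n0"].counts
    expected = np.zeros(15, dtype=int)
    expected[[0, 3, 14]] = [n - 1, comb(n - 1, 2), comb(n - 1, 3)]
    assert np.array_equal(gdv, expected)


@pytest.mark.parametrize("n", range(3, 11))
def test_gdv_star_centre_closed_form(n):
    """Star centre: orbit0 = n, orbit2 = C(n,2), orbit7 = C(n,3)."""
    gdv = count_gdv(_star(n), ["c0"])["c0"].counts
    expected = np.zeros(15, dtype=int)
    expected[[0, 2, 7]] = [n, comb(n, 2), comb(n, 3)]
    assert np.array_equal(gdv, expected)


def test_gdv_entry0_is_degree():
    g = generate_random_typed_graph(12, 0.4, 3, seed=5)
    for u, vec in count_gdv(g).items():
        assert vec.counts[0] == g.degree(u)


def test_result_independent_of_target_order():
    g = generate_random_typed_graph(10, 0.3, 3, seed=9)
    fwd = count_gdv(g, sorted(g.nodes))
    rev = count_gdv(g, sorted(g.nodes, reverse=True))
    for u in g.nodes:
        assert np.array_equal(fwd[u].counts, rev[u].counts)


# ---------------------------------------------------------------------------
# TyE-GDV
# ---------------------------------------------------------------------------


def test_tye_gdv_orbit9_update_rule():
    """A tailed triangle seen from the tail (orbit 9) with edge types
    0,1,2,2 must add one to (9,0) and (9,1) and two to (9,2)."""
    reg = TypeRegistry(("a", "b", "c"))
    g = TypedGraph.from_edges(
        # tail t - a; triangle a,b,c
        [("t", "a", 0), ("a", "b", 1), ("a", "c", 2), ("b", "c", 2)],
        registry=reg,
    )
    vec = count_tye_gdv(g, ["t"])["t"].counts
    assert vec[9].tolist() == [1, 1, 2, 0]
    # the same instance: nothing else in any other size-4 orbit row
    assert vec[8:].sum() == 4


def test_tye_gdv_single_type_collapse():
    g = _complete(6, type_code=0)
    gdv = count_gdv(g, ["n0"])["n0"].counts
    tye = count_tye_gdv(g, ["n0"])["n0"].counts
    assert np.array_equal(tye[:, 0], gdv * np.array(SOCIO_ORBIT_EDGES))
    assert tye[:, 1:].sum() == 0


def test_tye_gdv_row_sum_identity():
    g = generate_random_typed_graph(12, 0.35, 3, seed=2)
    for u in g.nodes:
        gdv = count_gdv(g, [u])[u].counts
        tye = count_tye_gdv(g, [u], include_sentinel=True)[u].counts
        assert np.array_equal(tye.sum(axis=1), gdv * np.array(SOCIO_ORBIT_EDGES))


def test_tye_gdv_sentinel_excluded_drops_untyped():
    reg = TypeRegistry(("a", "b"))
    g = TypedGraph.from_edges([("x", "y", 0), ("y", "z", None)], registry=reg)
    with_s = count_tye_gdv(g, ["x"], include_sentinel=True)["x"].counts
    without = count_tye_gdv(g, ["x"], include_sentinel=False)["x"].counts
    assert with_s.shape == (15, 3) and without.shape == (15, 2)
    # the path instance contributes its untyped edge only to the sentinel col
    assert with_s[1, 2] == 1 and without[1].sum() == 1


# ---------------------------------------------------------------------------
# egocentric counting
# ---------------------------------------------------------------------------


def test_tye_egdv_typed_star():
    reg = TypeRegistry(("a", "b", "c"))
    g = TypedGraph.from_edges(
        [("e", "x", 0), ("e", "y", 1), ("e", "z", 2)], registry=reg
    )
    vec = count_tye_egdv(as_ego(g, "e"), include_sentinel=False).counts
    assert vec.shape == (7, 3)
    assert vec[0].tolist() == [1, 1, 1]  # three 2-cliques, one per type
    # one 3-star instance spans all three typed edges
    assert vec[3].tolist() == [1, 1, 1]
    # three 2-paths, each covering two of the three types
    assert vec[1].tolist() == [2, 2, 2]
    assert vec[[2, 4, 5, 6]].sum() == 0


def test_tye_egdv_flat_length_91():
    reg = TypeRegistry(tuple(f"T-{i:02d}" for i in range(1, 14)))
    g = TypedGraph.from_edges([("e", "x", 0), ("e", "y", 5)], registry=reg)
    vec = count_tye_egdv(as_ego(g, "e"), include_sentinel=False)
    assert vec.flatten().shape == (91,)


def test_tye_egdv_single_alter():
    reg = TypeRegistry(("a",))
    g = TypedGraph.from_edges([("e", "x", 0)], registry=reg)
    vec = count_tye_egdv(as_ego(g, "e")).counts
    assert vec[0].sum() == 1 and vec[1:].sum() == 0


def test_egocentric_matches_sociocentric_on_dominated_component():
    """When the 1-hop neighbourhood is the whole component, ego counts
    equal sociocentric counts collapsed onto the 7 ego graphlets."""
    reg = TypeRegistry(("a", "b"))
    # ego-dominated: ego adjacent to all, some alter-alter edges
    g = TypedGraph.from_edges(
        [("e", "p", 0), ("e", "q", 1), ("e", "r", 0), ("p", "q", 1)], registry=reg
    )
    ego_gdv = count_gdv(g, ["e"], mode="egocentric")["e"].counts
    soc_gdv = count_gdv(g, ["e"], mode="sociocentric")["e"].counts
    # socio orbits of the dominating position -> ego graphlet index
    collapse = {0: 0, 2: 1, 3: 2, 7: 3, 11: 4, 13: 5, 14: 6}
    collapsed = np.zeros(7, dtype=int)
    for o, c in enumerate(soc_gdv):
        if c and o in collapse:
            collapsed[collapse[o]] += c
    assert np.array_equal(ego_gdv, collapsed)


# ---------------------------------------------------------------------------
# TyE-DV
# ---------------------------------------------------------------------------


def test_tye_dv_counts_incident_types():
    reg = TypeRegistry(("a", "b", "c"))
    g = TypedGraph.from_edges(
        [("u", "v", 0), ("u", "w", 0), ("u", "x", 2)], registry=reg
    )
    vec = count_tye_dv(g, ["u"])["u"].counts
    assert vec.tolist() == [2, 0, 1, 0]


def test_tye_dv_equals_tye_gdv_row0():
    g = generate_random_typed_graph(10, 0.4, 3, seed=11)
    tye = count_tye_gdv(g)
    dv = count_tye_dv(g)
    for u in g.nodes:
        assert np.array_equal(dv[u].counts, tye[u].counts[0])


def test_tye_dv_isolated():
    g = TypedGraph()
    g.add_node("solo")
    assert count_tye_dv(g, ["solo"])["solo"].counts.sum() == 0


# ---------------------------------------------------------------------------
# colored / heterogeneous
# ---------------------------------------------------------------------------


def test_colored_set_semantics():
    reg = TypeRegistry(("a", "b"))
    g = TypedGraph.from_edges(
        [("u", "v", 0), ("u", "w", 1), ("v", "w", 1)], registry=reg
    )
    col = count_colored_gdv(g, ["u"])["u"]
    assert col.by_orbit[3] == {(0, 1): 1}  # triangle types {0,1,1} -> set {0,1}
    het = count_hetero_gdv(g, ["u"])["u"]
    assert het.by_orbit[3] == {(0, 1, 1): 1}  # full multiset, length 3


def test_keyed_totals_match_gdv_and_key_lengths():
    g = generate_random_typed_graph(11, 0.4, 3, seed=4)
    gdv = count_gdv(g)
    col = count_colored_gdv(g)
    het = count_hetero_gdv(g)
    for u in g.nodes:
        for o in range(15):
            assert col[u].orbit_total(o) == gdv[u].counts[o]
            assert het[u].orbit_total(o) == gdv[u].counts[o]
            for key in het[u].by_orbit[o]:
                assert len(key) == SOCIO_ORBIT_EDGES[o]
            for key in col[u].by_orbit[o]:
                assert key == tuple(sorted(set(key)))


def test_single_type_dense_export_equals_gdv():
    from typed_graphlets import dense_index

    g = generate_random_typed_graph(10, 0.4, 1, seed=7)
    gdv = count_gdv(g)
    col = count_colored_gdv(g)
    het = count_hetero_gdv(g)
    col_idx = [dense_index("set", m, 1) for m in SOCIO_ORBIT_EDGES]
    het_idx = [dense_index("multiset", m, 1) for m in SOCIO_ORBIT_EDGES]
    for u in g.nodes:
        assert np.array_equal(col[u].to_dense(col_idx), gdv[u].counts)
        assert np.array_equal(het[u].to_dense(het_idx), gdv[u].counts)


def test_marginalization_over_types():
    """Collapsing TyE-GDV over types reproduces m(o)-weighted GDV and the
    keyed variants reproduce GDV, sentinel included."""
    reg = TypeRegistry(("a", "b"))
    g = TypedGraph.from_edges(
        [("p", "q", 0), ("q", "r", None), ("p", "r", 1), ("r", "s", 0)], registry=reg
    )
    gdv = count_gdv(g)
    tye = count_tye_gdv(g, include_sentinel=True)
    col = count_colored_gdv(g, include_sentinel=True)
    for u in g.nodes:
        assert np.array_equal(
            tye[u].counts.sum(axis=1), gdv[u].counts * np.array(SOCIO_ORBIT_EDGES)
        )
        for o in range(15):
            assert col[u].orbit_total(o) == gdv[u].counts[o]


# ---------------------------------------------------------------------------
# enumeration budget
# ---------------------------------------------------------------------------


def test_triple_enumeration_budget():
    """The size-4 neighbour-triple loop visits exactly sum_u C(deg u, 3)
    triples — the documented enumeration bound."""
    g = generate_random_typed_graph(13, 0.45, 3, seed=3)
    stats = {}
    count_gdv(g, stats=stats)
    budget = sum(comb(g.degree(u), 3) for u in g.nodes)
    assert stats.get("triples", 0) == budget
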