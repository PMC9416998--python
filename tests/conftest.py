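import pytest

from typed_graphlets import TypedGraph, TypeRegistry, build_atlas


@pytest.fixture(scope="session")
def atlas4():
    return build_atlas(4)


@pytest.fixture(scope="session")
def atlas5():
    return build_atlas(5)


@pytest.fixture
def diamond():
    """4-chordal-cycle; 'u' and 'x' are the degree-3 chord endpoints."""
    return TypedGraph.from_edges(
        [("u", "v"), ("u", "w"), ("u", "x"), ("x", "v"), ("x", "w")]
    )


@pytest.fixture
def typed_registry3():
    return TypeRegistry(("alpha", "beta", "gamma"))
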