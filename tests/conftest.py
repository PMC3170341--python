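import pytest

from mircomplex import (
    ClusterSet,
    ComplexCatalog,
    FamilyMap,
    PPINetwork,
    ProteinComplex,
    SyntheticConfig,
    TargetNetwork,
    generate,
)


@pytest.fixture
def toy_network() -> TargetNetwork:
    return TargetNetwork(
        {
            "m1": {"a", "b", "c", "x"},
            "m2": {"b", "c", "d"},
            "m3": {"x", "y"},
        }
    )


@pytest.fixture
def toy_catalog() -> ComplexCatalog:
    return ComplexCatalog(
        {
            "c1": ProteinComplex("abc complex", {"a", "b", "c"}),
            "c2": ProteinComplex("cd complex", {"c", "d"}),
            "c3": ProteinComplex("yz complex", {"y", "z"}),
        }
    )


@pytest.fixture
def toy_clusters() -> ClusterSet:
    return ClusterSet({"cl1": ["m1", "m2"]})


@pytest.fixture
def toy_families() -> FamilyMap:
    return FamilyMap({"m1": "f1", "m2": "f2", "m3": "f1"})


@pytest.fixture(scope="session")
def planted_bundle():
    """A moderately sized planted scenario shared across read-only tests."""
    return generate(SyntheticConfig(seed=7))
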