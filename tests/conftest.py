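import pytest

from dolloscan import SimConfig, generate_dataset
from dolloscan.tree import SpeciesTree


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated dataset (12 species, 3 genes, 2 stem losses)."""
    return generate_dataset(SimConfig())


@pytest.fixture()
def amniote_toy_tree():
    """(mammals,(squamates,(turtles,(birds,crocs)))) cladogram."""
    return SpeciesTree.from_nested(
        ("mammals", ("squamates", ("turtles", ("birds", "crocs"))))
    )
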