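import numpy as np
import pytest

from caseinlab import synthetic as syn

SPECIES = ("sheep", "goat", "cattle", "buffalo", "camel", "rat")

#: Study-style divergence tree: two shallow cherries, camel on its own deep
#: branch, rat as the distant outgroup (lengths in substitutions/site).
STUDY_TREE = (
    "(((sheep:0.02,goat:0.02):0.06,(cattle:0.02,buffalo:0.02):0.06):0.10,"
    "camel:0.35,rat:0.90);"
)


@pytest.fixture(scope="session")
def species_labels() -> tuple[str, ...]:
    return SPECIES


@pytest.fixture(scope="session")
def study_tree() -> str:
    return STUDY_TREE


@pytest.fixture(scope="session")
def panel_spec() -> syn.PanelSpec:
    return syn.PanelSpec(species_labels=SPECIES, divergence_tree=STUDY_TREE, seed=11)


@pytest.fixture(scope="session")
def panel(panel_spec):
    return syn.make_panel(panel_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def make_protein(rng):
    """Callable: draw a uniform random protein sequence of a given length."""
    from caseinlab.seqio import ALPHABET

    def _make(length: int) -> str:
        return "".join(rng.choice(list(ALPHABET), size=length))

    return _make
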