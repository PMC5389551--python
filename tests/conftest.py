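import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seedtax.taxonomy import TaxonomyTree

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_tree():
    """root(1) -> genus(10) -> species(11, 12); genus(20) -> species(21)."""
    return TaxonomyTree(
        parent={1: 1, 10: 1, 11: 10, 12: 10, 20: 1, 21: 20},
        rank={1: "no rank", 10: "genus", 11: "species", 12: "species",
              20: "genus", 21: "species"},
        name={1: "root", 10: "Genus A", 11: "A one", 12: "A two",
              20: "Genus B", 21: "B one"},
        root=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
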