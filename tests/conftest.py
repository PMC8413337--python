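import pytest

from targetddi.io import DrugTargetMap
from targetddi.profiles import GeneUniverse
from targetddi.synthetic import SynthConfig, generate

# Worked example: Patisiran targets {ALB, ORM1, ORM2}, Bismuth Subsalicylate
# targets {ALB, TF}; the universe is stated in the order (TF, ALB, XDH,
# ORM1, ORM2), with XDH contributed by some third drug.
PATISIRAN = "DB14582"
BISMUTH = "DB01294"
EXAMPLE_UNIVERSE_ORDER = ("TF", "ALB", "XDH", "ORM1", "ORM2")


@pytest.fixture
def example_targets() -> DrugTargetMap:
    return DrugTargetMap({
        PATISIRAN: frozenset({"ALB", "ORM1", "ORM2"}),
        BISMUTH: frozenset({"ALB", "TF"}),
    })


@pytest.fixture
def example_universe() -> GeneUniverse:
    return GeneUniverse(EXAMPLE_UNIVERSE_ORDER)


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted dataset shared across module tests."""
    config = SynthConfig(n_drugs=60, n_genes=80, targets_per_drug=(1, 5),
                         n_pathways=20, n_processes=25,
                         n_positive_pairs=150, n_negative_pairs=150, seed=7)
    return generate(config)
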