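import numpy as np
import pytest

from natpipe.phylo import NeutralModel, parse_newick
from natpipe.synth import SynthConfig, generate_annotation
from natpipe.topology import classify_all

NINE_TAXON_TREE = SynthConfig().tree_newick


@pytest.fixture(scope="session")
def nine_taxon_model() -> NeutralModel:
    return SynthConfig().neutral_model()


@pytest.fixture(scope="session")
def two_leaf_model() -> NeutralModel:
    return NeutralModel.hky(
        parse_newick("(A:0.1,B:0.2);"), np.array([0.3, 0.2, 0.2, 0.3]), 2.0
    )


@pytest.fixture(scope="session")
def demo_world():
    """One mid-sized synthetic world shared across test modules."""
    return generate_annotation(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def demo_records(demo_world):
    return classify_all(demo_world.nats, demo_world.genes, dataset="synthetic")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
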