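import numpy as np
import pytest

from edit_aftermath.genome import AnnotatedGenome, GeneRecord
from edit_aftermath.simulate import generate_genome


@pytest.fixture(scope="session")
def small_genome() -> AnnotatedGenome:
    """Two-chromosome 50 kb genome with 20 annotated genes."""
    return generate_genome(2, [30_000, 20_000], 20, 0.3, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_genome(chrom_seqs: dict[str, str], genes: list[GeneRecord] | None = None):
    """Hand-built genome helper for toy fixtures."""
    return AnnotatedGenome(dict(chrom_seqs), list(genes or [])).validate()
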