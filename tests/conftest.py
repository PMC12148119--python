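import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from kmerprimer import SpeciesSequenceSet

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_species(rng):
    """Three unrelated random species, two contigs each."""
    return [
        SpeciesSequenceSet(f"sp{i + 1}", [
            (f"c{j + 1}", random_seq(rng, 400)) for j in range(2)
        ])
        for i in range(3)
    ]


def make_universe(rng, n_species=3, n_contigs=2, length=400):
    return [
        SpeciesSequenceSet(f"sp{i + 1}", [
            (f"c{j + 1}", random_seq(rng, length)) for j in range(n_contigs)
        ])
        for i in range(n_species)
    ]
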