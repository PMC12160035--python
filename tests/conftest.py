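import numpy as np
import pytest

import panmotif as pm
from panmotif.motif_discovery import AA_ALPHABET
from panmotif.simlib import DEFAULT_FLANK3, DEFAULT_FLANK5


def random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    """n heptapeptides with residues drawn uniformly over the 20 canonical AAs."""
    letters = np.array(list(AA_ALPHABET))
    return ["".join(row) for row in letters[rng.integers(0, 20, size=(n, 7))]]


@pytest.fixture(scope="session")
def screen_library():
    """723 clones of which exactly 16 carry a third-base NNK violation.

    This reconstructs the composition of the modeled screen: 723
    sequenced positive clones, 16 excluded by the codon rule, 707
    heptapeptides surviving.
    """
    spec = pm.SimulationSpec(n_clones=723, rng_seed=101, n_invalid=0)
    reads, truth = pm.generate_nnk_library(spec)
    return pm.corrupt_library(reads, truth, n_invalid=16, n_wildtype=0, seed=102)


@pytest.fixture(scope="session")
def screen_inserts(screen_library):
    reads, _ = screen_library
    return [pm.extract_insert(r, DEFAULT_FLANK5, DEFAULT_FLANK3) for r in reads]


@pytest.fixture(scope="session")
def validated_pool(screen_inserts):
    peptides, report = pm.filter_library(screen_inserts)
    assert report.n_passed == 707
    return pm.dereplicate(peptides)
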