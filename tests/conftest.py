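import warnings

import numpy as np
import pytest

from knapcharge.molgraph import Atom, MolecularGraph
from knapcharge.synthdata import SyntheticCorpusSpec, gen_corpus


@pytest.fixture
def path_xyx() -> MolecularGraph:
    """Symmetric 3-atom path X–Y–X with charges 0.1, −0.2, 0.1 (total 0)."""
    return MolecularGraph(
        [Atom("X", 0.1), Atom("Y", -0.2), Atom("X", 0.1)],
        {(1, 2), (2, 3)},
        0.0,
        "path_xyx",
    )


@pytest.fixture(scope="session")
def small_corpus():
    """50 synthetic molecules (25 structures × 2 copies) with ground truth."""
    spec = SyntheticCorpusSpec(
        n_molecules=50, size_min=5, size_max=15, structure_copies=2, seed=42
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gen_corpus(spec)


def random_connected_molecule(rng: np.random.Generator, n: int, alphabet="CHNO") -> MolecularGraph:
    """Random connected untyped-bond graph: spanning tree plus extra edges."""
    bonds = set()
    for v in range(2, n + 1):
        u = int(rng.integers(1, v))
        bonds.add((u, v))
    n_extra = int(rng.integers(0, max(n // 3, 1)))
    for _ in range(n_extra):
        a, b = rng.choice(np.arange(1, n + 1), size=2, replace=False)
        a, b = int(min(a, b)), int(max(a, b))
        if a != b:
            bonds.add((a, b))
    atoms = [Atom(alphabet[int(rng.integers(len(alphabet)))]) for _ in range(n)]
    return MolecularGraph(atoms, bonds, 0.0, "random")
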