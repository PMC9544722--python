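"""Shared fixtures: hand-built pedigrees and a random-pedigree generator.

The random generator here is deliberately independent of the package's own
colony simulator so that structural oracles (pair counting, ancestor
closure, kinship recursion) are exercised on pedigrees the library code
never produced.
"""

import numpy as np
import pytest

from pedfit import Pedigree


@pytest.fixture
def trio_ped() -> Pedigree:
    """Founder pair with one offspring."""
    return Pedigree(["m", "f", "kid"], [None, None, "f"], [None, None, "m"], [1, 1, 2])


@pytest.fixture
def sib_ped() -> Pedigree:
    """Two founders, two full sibs, one maternal half sib via a third founder."""
    return Pedigree(
        ["f1", "f2", "f3", "c1", "c2", "h1"],
        ["", "", "", "f1", "f1", "f1"],
        ["", "", "", "f2", "f2", "f3"],
    )


def random_pedigree(seed: int, n: int = 60, p_known: float = 0.7) -> Pedigree:
    """A random valid pedigree: each individual may draw parents from its
    predecessors (guaranteeing acyclicity)."""
    rng = np.random.default_rng(seed)
    ids = [f"i{k}" for k in range(n)]
    dam, sire = [], []
    for k in range(n):
        if k < 4 or rng.random() > p_known:
            dam.append(None)
            sire.append(None)
        else:
            d, s = rng.integers(0, k, size=2)
            dam.append(ids[d])
            sire.append(None if rng.random() < 0.2 else ids[s])
    return Pedigree(ids, dam, sire)


@pytest.fixture
def rand_ped() -> Pedigree:
    return random_pedigree(7, n=60)
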