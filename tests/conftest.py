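import numpy as np
import pytest

from idpcircuit.sequence import build_construct, wt_synthetic_construct
from idpcircuit.synth import (
    DimerSpec,
    InteractionSpec,
    make_contact_scaffold,
    make_dimer_pose,
    make_ideal_helix,
)


@pytest.fixture(scope="session")
def wt_construct():
    return wt_synthetic_construct()


@pytest.fixture(scope="session")
def pqe_construct(wt_construct):
    return build_construct(wt_construct, 45, variant_label="pQe")


@pytest.fixture(scope="session")
def ideal_helix_12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def small_scaffold():
    """20-residue scaffold with two planted contacts."""
    return make_contact_scaffold(20, [(2, 18), (10, 16)], seed=1)


@pytest.fixture(scope="session")
def four_type_pose():
    """A dimer realizing one designed interaction of each type."""
    spec = DimerSpec(12, 12, [
        InteractionSpec("salt_bridge", 3, 4),
        InteractionSpec("hydrogen_bond", 6, 7),
        InteractionSpec("pi_cation", 9, 2),
        InteractionSpec("pi_stacking", 11, 10),
    ])
    return make_dimer_pose(spec, seed=1)


def random_contact_map(rng: np.random.Generator, n_residues: int, m: int,
                       exclusion: int = 3) -> set[tuple[int, int]]:
    """Random unordered contact pairs respecting the neighbor-exclusion window."""
    pairs: set[tuple[int, int]] = set()
    attempts = 0
    while len(pairs) < m and attempts < 50 * m:
        i = int(rng.integers(1, n_residues + 1))
        j = int(rng.integers(1, n_residues + 1))
        i, j = min(i, j), max(i, j)
        attempts += 1
        if j - i > exclusion:
            pairs.add((i, j))
    return pairs
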