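import numpy as np
import pytest

from sprotann.structio import chain_from_torsions
from sprotann.synthetic import make_benchmark


@pytest.fixture(scope="session")
def helix30():
    """Ideal 30-residue alpha helix."""
    return chain_from_torsions("A" * 30, [(-57.0, -47.0, 180.0)] * 30)


@pytest.fixture(scope="session")
def hairpin16():
    """Ideal antiparallel beta hairpin (strand-turn-strand)."""
    strand = (-120.0, 120.0, 180.0)
    turn = [(15.0, -105.0, 180.0), (-90.0, 10.0, 180.0)]
    torsions = [strand] * 7 + turn + [strand] * 7
    return chain_from_torsions("A" * 16, torsions)


@pytest.fixture(scope="session")
def bench1():
    """The default synthetic benchmark at seed 1 (shared; read-only)."""
    return make_benchmark(seed=1)


def random_rigid(rng):
    """A uniform random rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(0.0, 15.0, size=3)
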