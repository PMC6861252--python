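import numpy as np
import pytest

from invorigin.alignment import LabeledAlignment
from invorigin.arrangements import Karyotype, canonical_arrangements


@pytest.fixture(scope="session")
def canon():
    return canonical_arrangements()


@pytest.fixture(scope="session")
def het(canon):
    return Karyotype(canon["E_st"], canon["E_1+2"])


def random_alignment(rng, n=6, length=100, p_mut=0.1, p_gap=0.0, regions=None):
    """Star-shaped random alignment: iid mutations off one ancestor."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    anc = rng.integers(0, 4, size=length)
    rows = []
    for _ in range(n):
        row = anc.copy()
        hits = rng.random(length) < p_mut
        row[hits] = (row[hits] + rng.integers(1, 4, size=hits.sum())) % 4
        rows.append(bases[row])
    matrix = np.vstack(rows)
    if p_gap > 0:
        gaps = rng.random(matrix.shape) < p_gap
        matrix[gaps] = b"-"
    return LabeledAlignment(
        ids=[f"s{i}" for i in range(n)],
        matrix=matrix,
        regions=list(regions) if regions is not None else ["R"] * n,
        arrangements=["A"] * n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
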