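import numpy as np
import pytest

from attnsol.model import ModelConfig, build_model
from attnsol.sequence_io import AMINO_ACIDS, ProteinRecord


@pytest.fixture(scope="session")
def default_model():
    """Seeded untrained model with the reference architecture."""
    return build_model(ModelConfig(seed=42))


@pytest.fixture(scope="session")
def tiny_model():
    """Small architecture for gradient checks and brute-force comparisons."""
    return build_model(ModelConfig(hidden_dim=3, seed=11))


def random_records(n, rng, lo=5, hi=30, prefix="r"):
    recs = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        recs.append(ProteinRecord(f"{prefix}{i}", seq))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def some_records(rng):
    return random_records(12, rng)


# --- synthetic 4-residue structure with hand-checkable distances ---------

SYNTHETIC_PDB = """\
HEADER    SYNTHETIC TEST STRUCTURE
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      -0.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       2.000   4.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      6  N   ALA A   3       2.000   4.000  12.000  1.00  0.00           N
ATOM      7  CA  ALA A   3       2.500   4.000  12.000  1.00  0.00           C
ATOM      8  CB  ALA A   3       3.000   4.000  12.000  1.00  0.00           C
ATOM      9  N   SER A   4      -1.000   4.000  12.000  1.00  0.00           N
ATOM     10  CA  SER A   4      -0.500   4.000  12.000  1.00  0.00           C
ATOM     11  CB  SER A   4       0.000   4.000  12.000  1.00  0.00           C
END
"""
# C-beta proxies: (0,0,0), (3,4,0) [GLY C-alpha], (3,4,12), (0,4,12)
# separation 1: 5, 12, 3 -> mean 20/3; separation 2: 13, 12 -> 12.5
# separation 3: sqrt(160)


@pytest.fixture
def synthetic_pdb(tmp_path):
    path = tmp_path / "synthetic.pdb"
    path.write_text(SYNTHETIC_PDB)
    return path
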