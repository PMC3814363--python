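import numpy as np
import pytest

from p4ring.model import Atom, Chain, Residue, StructureModel
from p4ring.synthetic import RingSpec, ca_trace, make_ring


def single_carbon(chain_id: str, pos) -> Chain:
    atom = Atom("CA", "C", np.asarray(pos, dtype=float))
    return Chain(chain_id, [Residue(1, "ALA", atoms=[atom])])


@pytest.fixture
def carbon_at_origin() -> StructureModel:
    return StructureModel("carbon", [single_carbon("A", [0.0, 0.0, 0.0])])


@pytest.fixture
def tube_ring() -> StructureModel:
    """Hexamer of tube templates at 10 Å: pore radius exactly 10 − 1.7 = 8.3."""
    return make_ring(RingSpec(n_subunits=6, ring_radius=10.0,
                              subunit_template="tube"))


@pytest.fixture
def trace60() -> StructureModel:
    return ca_trace(60, seed=11)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.166  -4.943  1.00  0.00           C
ATOM      4  O   ALA A   1      13.339   7.584  -5.898  1.00  0.00           O
ATOM      5  N   GLY A   2      12.840   7.616  -3.704  1.00  0.00           N
ATOM      6  CA  GLY A   2      13.810   8.656  -3.402  1.00  0.00           C
ATOM      7  C   GLY A   2      13.202   9.995  -3.752  1.00  0.00           C
ATOM      8  O   GLY A   2      11.997  10.106  -3.966  1.00  0.00           O
TER       9      GLY A   2
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA ASER A   1      11.000  10.000  10.000  0.60  0.00           C
ATOM      3  CA BSER A   1      11.500  10.000  10.000  0.40  0.00           C
ATOM      4  C   SER A   1      12.000  11.000  10.000  1.00  0.00           C
ATOM      5  O   SER A   1      12.500  11.500  10.000  1.00  0.00           O
END
"""

ALTLOC_TIE_PDB = """\
ATOM      1  N   SER A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA BSER A   1      11.500  10.000  10.000  0.50  0.00           C
ATOM      3  CA ASER A   1      11.000  10.000  10.000  0.50  0.00           C
END
"""
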