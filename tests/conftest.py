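import numpy as np
import pytest

from xdc.structure import read_structure
from xdc.synthetic import make_toy_complex_and_template, make_toy_domain


def pdb_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0, altloc=" ", element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


MINIMAL_PDB = "\n".join(
    [
        pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_line(2, "CA", "GLY", "A", 1, 1.458, 0.0, 0.0),
        pdb_line(3, "C", "GLY", "A", 1, 2.0, 1.42, 0.0),
        "END",
    ]
) + "\n"

ALTLOC_PDB = "\n".join(
    [
        pdb_line(1, "N", "SER", "A", 1, 0.0, 0.0, 0.0),
        pdb_line(2, "CA", "SER", "A", 1, 1.458, 0.0, 0.0, occ=0.6, altloc="A"),
        pdb_line(3, "CA", "SER", "A", 1, 1.458, 0.5, 0.0, occ=0.4, altloc="B"),
        pdb_line(4, "C", "SER", "A", 1, 2.0, 1.42, 0.0),
        "END",
    ]
) + "\n"


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture
def toy_domain():
    return make_toy_domain(10, seed=11)


@pytest.fixture
def close_system():
    """Complex + template whose placed antibody spheres overlap (d = 3 Å)."""
    return make_toy_complex_and_template(protomer_separation=3.0, seed=5)


@pytest.fixture
def wide_system():
    """Complex + template whose placed antibody spheres are far apart."""
    return make_toy_complex_and_template(protomer_separation=200.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
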