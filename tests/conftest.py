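"""Shared fixtures: tiny hand-written PDB texts and synthetic ensembles."""

import numpy as np
import pytest

from tailscope.structio import Atom, Structure
from tailscope.synthdata import PeptideGenSpec, Segment, gen_peptide_trajectory

# Two residues (GLY-ALA), backbone only, chain A.  Coordinates chosen by hand.
TWO_RES_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.989   2.828   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       5.504   2.705   0.000  1.00  0.00           C
ATOM      8  O   ALA A   2       6.065   1.610   0.000  1.00  0.00           O
END
"""


def _one_atom_model(serial: int, z: float) -> str:
    return (
        f"MODEL     {serial:>4d}\n"
        f"ATOM      1  CA  GLY A   1       1.000   2.000{z:8.3f}  1.00  0.00           C\n"
        "ENDMDL\n"
    )


THREE_MODEL_PDB = "".join(_one_atom_model(i + 1, z) for i, z in enumerate((1.0, 2.0, 3.0))) + "END\n"


@pytest.fixture
def two_res_pdb(tmp_path):
    p = tmp_path / "two_res.pdb"
    p.write_text(TWO_RES_PDB)
    return p


@pytest.fixture
def three_model_pdb(tmp_path):
    p = tmp_path / "three_model.pdb"
    p.write_text(THREE_MODEL_PDB)
    return p


@pytest.fixture(scope="session")
def ideal_helix_12():
    """One frame of an ideal 12-residue α-helix (persistence 1, no jitter)."""
    spec = PeptideGenSpec(
        seed=1, n_res=12, segments=(Segment(1, 12, "alpha", 1.0),),
        n_frames=1, coil_dihedral_jitter=0.0,
    )
    return gen_peptide_trajectory(spec)


@pytest.fixture(scope="session")
def planted_tail_2000():
    """Default 43-mer ensemble: tip helix T3-G12 at 0.8, middle L20-A29 at 0.4."""
    return gen_peptide_trajectory(PeptideGenSpec(seed=101, n_frames=2000))


def ca_only_structure(points: np.ndarray, label: str = "ca_trace") -> Structure:
    """A Cα-trace structure from an (n, 3) array, residues numbered 1..n."""
    atoms = [
        Atom("CA", "C", i + 1, "ALA", "A", tuple(float(v) for v in p))
        for i, p in enumerate(np.asarray(points, dtype=float))
    ]
    return Structure(atoms, label=label)
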