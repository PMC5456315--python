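import numpy as np
import pytest

from episurf.structure_io import Atom, Structure

# minimal heavy-atom side chains sufficient for the reduced charge model
SIDE_CHAINS = {
    "ALA": ["CB"],
    "GLY": [],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
}

ONE_TO_THREE_LOCAL = {
    "A": "ALA", "G": "GLY", "R": "ARG", "K": "LYS", "D": "ASP", "E": "GLU",
    "N": "ASN", "L": "LEU", "S": "SER",
}


def build_residue(res_name: str, res_seq: int, chain: str = "A",
                  origin=(0.0, 0.0, 0.0), serial0: int = 1) -> list[Atom]:
    """Toy residue: backbone + side chain laid out on a local lattice."""
    ox, oy, oz = origin
    names = ["N", "CA", "C", "O"] + SIDE_CHAINS.get(res_name, ["CB"])
    atoms = []
    for k, name in enumerate(names):
        coords = np.array([ox + 0.5 * k, oy + (k % 2) * 0.7, oz + 0.3 * k])
        element = name[0] if name[0] in "CNOS" else "C"
        atoms.append(Atom(serial=serial0 + k, name=name, element=element,
                          res_name=res_name, res_seq=res_seq, chain=chain,
                          coords=coords))
    return atoms


def toy_peptide(sequence: str, chain: str = "A", start_res: int = 1,
                spacing: float = 4.0) -> Structure:
    """Peptide of toy residues spaced along x (charge logic only)."""
    atoms: list[Atom] = []
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE_LOCAL[aa]
        atoms.extend(build_residue(res_name, start_res + i, chain,
                                   origin=(spacing * i, 0.0, 0.0),
                                   serial0=len(atoms) + 1))
    return Structure(atoms=atoms, id=f"toy-{sequence}")


@pytest.fixture
def kkd_peptide() -> Structure:
    return toy_peptide("KKD")


@pytest.fixture
def point_charge() -> Structure:
    """Single +1 e pseudo-atom at the origin."""
    return Structure(atoms=[Atom(1, "X", "C", "ALA", 1, "A",
                                 np.zeros(3), charge=1.0, radius=0.1)],
                     id="point")
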