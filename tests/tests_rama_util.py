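"""Test helper: build a poly-Ala backbone with prescribed (phi, psi)."""
import math

import numpy as np

from episurf.structure_io import Atom, Structure
from episurf.synthetic_data import _nerf


def chain_with_dihedrals(phi_psi: list[tuple[float, float]],
                         omega: float = 180.0) -> Structure:
    """n-residue poly-Ala with residue i adopting (phi_i, psi_i)."""
    n = len(phi_psi)
    bb = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    ang = math.radians(111.2)
    c0 = ca0 + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = bb[-1]
        psi_prev = phi_psi[i - 1][1]
        phi_cur = phi_psi[i][0]
        n_new = _nerf(prev["N"], prev["CA"], prev["C"], 1.329, 116.2,
                      psi_prev)
        ca_new = _nerf(prev["CA"], prev["C"], n_new, 1.458, 121.7, omega)
        c_new = _nerf(prev["C"], n_new, ca_new, 1.525, 111.2, phi_cur)
        bb.append({"N": n_new, "CA": ca_new, "C": c_new})
    atoms = []
    serial = 1
    for i, res in enumerate(bb):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            atoms.append(Atom(serial=serial, name=name, element=el,
                              res_name="ALA", res_seq=i + 1, chain="A",
                              coords=res[name]))
            serial += 1
    return Structure(atoms=atoms, id="rama-test")
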