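"""Protein structure parsing, representation, charging and composition.

Reads and writes fixed-column PDB and whitespace-delimited PQR.  Charges
default to a *reduced* model: one net point charge per charged residue at
a canonical side-chain atom (Arg:CZ, Lys:NZ, Asp:CG, Glu:CD); full
per-atom charges enter via PQR with a "keep" table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "ChargeRadiusTable",
    "ParseError",
    "read_structure",
    "write_pdb",
    "write_pqr",
    "assign_charges",
    "net_charge",
    "classify_residues",
    "DEFAULT_TABLE",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BASIC_RESIDUES = {"HIS", "LYS", "ARG"}
ACIDIC_RESIDUES = {"ASP", "GLU"}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Per-element radii (Angstrom); a conventional Bondi-like set.
ELEMENT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90,
}
DEFAULT_RADIUS = 1.60


class ParseError(ValueError):
    """Raised for malformed structure files; carries the line number."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    coords: np.ndarray
    charge: float = 0.0
    radius: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")

    @property
    def is_standard(self) -> bool:
        return self.res_name in THREE_TO_ONE

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Structure:
    """Ordered collection of atoms grouped contiguously by residue."""

    atoms: list[Atom] = field(default_factory=list)
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure(atoms=[a.copy() for a in self.atoms], id=self.id)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residues(self) -> Iterator[tuple[tuple[str, int], list[Atom]]]:
        """Yield ((chain, res_seq), atoms) groups in file order."""
        key = None
        group: list[Atom] = []
        for a in self.atoms:
            k = (a.chain, a.res_seq)
            if k != key:
                if group:
                    yield key, group
                key, group = k, []
            group.append(a)
        if group:
            yield key, group

    def residue(self, chain: str, res_seq: int) -> list[Atom]:
        out = [a for a in self.atoms if a.chain == chain and a.res_seq == res_seq]
        if not out:
            raise KeyError(f"no residue {chain}{res_seq}")
        return out

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence of residues with at least one backbone atom."""
        letters = []
        for (ch, _), atoms in self.residues():
            if chain is not None and ch != chain:
                continue
            if not any(a.name in ("N", "CA", "C") for a in atoms):
                continue
            letters.append(THREE_TO_ONE.get(atoms[0].res_name, "X"))
        return "".join(letters)

    def residue_ids(self, chain: str | None = None) -> list[tuple[str, int]]:
        ids = []
        for (ch, seq), atoms in self.residues():
            if chain is not None and ch != chain:
                continue
            if not any(a.name in ("N", "CA", "C") for a in atoms):
                continue
            ids.append((ch, seq))
        return ids


# default charge-site atoms and net charges of the reduced model
_DEFAULT_SITES = {
    "ARG": ("CZ", +1.0),
    "LYS": ("NZ", +1.0),
    "ASP": ("CG", -1.0),
    "GLU": ("CD", -1.0),
}


@dataclass
class ChargeRadiusTable:
    """Residue-level net charges + per-element radii.

    mode "reduced" zeroes everything and places one net charge per charged
    residue at its site atom; mode "keep" preserves charges already present
    (e.g. read from PQR) and only fills missing radii.
    ``site_fallback_cb`` places the net charge on CB when the canonical
    site atom is absent (used for stub side chains).
    """

    sites: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SITES))
    element_radii: dict[str, float] = field(
        default_factory=lambda: dict(ELEMENT_RADII))
    mode: str = "reduced"
    site_fallback_cb: bool = False

    def residue_charge(self, res_name: str) -> float:
        return self.sites.get(res_name, (None, 0.0))[1]

    def radius_for(self, atom: Atom) -> float:
        return self.element_radii.get(atom.element.upper(), DEFAULT_RADIUS)


DEFAULT_TABLE = ChargeRadiusTable()


def _infer_element(name: str, res_name: str) -> str:
    name = name.strip()
    if not name:
        return ""
    # two-letter elements only in ions / non-standard residues; for amino
    # acids the first alphabetic character is the element
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return name[0].upper()


def _parse_pdb(lines: Iterable[str], include_het: bool) -> list[Atom]:
    atoms: list[Atom] = []
    # (chain, res_seq, name) -> list of (occupancy, altloc, index into atoms)
    alt: dict[tuple, list[tuple[float, str, int]]] = {}
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "ENDMDL":
            break  # first model only
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if rec == "HETATM" and not include_het:
            continue
        try:
            name = line[12:16].strip()
            altloc = line[16]
            res_name = line[17:20].strip()
            chain = line[21].strip() or "A"
            res_seq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_str = line[54:60].strip()
            occ = float(occ_str) if occ_str else 1.0
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed PDB record at line {lineno}: {exc}")
        if res_name in WATER_NAMES and not include_het:
            continue
        if not element:
            element = _infer_element(name, res_name)
        serial_str = line[6:11].strip()
        serial = int(serial_str) if serial_str else len(atoms) + 1
        atom = Atom(serial=serial, name=name, element=element,
                    res_name=res_name, res_seq=res_seq, chain=chain,
                    coords=np.array([x, y, z]))
        key = (chain, res_seq, name)
        if altloc not in (" ", ""):
            candidates = alt.setdefault(key, [])
            if candidates:
                # keep highest occupancy, then lowest altloc letter
                best_occ, best_alt, idx = candidates[0]
                if (occ, ) > (best_occ, ) or (occ == best_occ and altloc < best_alt):
                    atoms[idx] = atom
                    candidates[0] = (occ, altloc, idx)
                continue
            candidates.append((occ, altloc, len(atoms)))
        atoms.append(atom)
    return atoms


def _parse_pqr(lines: Iterable[str], include_het: bool) -> list[Atom]:
    atoms: list[Atom] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if line.startswith("HETATM") and not include_het:
            continue
        fields = line.split()
        if len(fields) == 11:
            (_, serial, name, res_name, chain, res_seq,
             x, y, z, q, r) = fields
        elif len(fields) == 10:
            _, serial, name, res_name, res_seq, x, y, z, q, r = fields
            chain = "A"
        else:
            raise ParseError(
                f"malformed PQR record at line {lineno}: expected 10 or 11 "
                f"fields, got {len(fields)}")
        try:
            atom = Atom(serial=int(serial), name=name,
                        element=_infer_element(name, res_name),
                        res_name=res_name, res_seq=int(res_seq),
                        chain=chain,
                        coords=np.array([float(x), float(y), float(z)]),
                        charge=float(q), radius=float(r))
        except ValueError as exc:
            raise ParseError(f"malformed PQR record at line {lineno}: {exc}")
        if atom.res_name in WATER_NAMES and not include_het:
            continue
        atoms.append(atom)
    return atoms


def read_structure(source, format: str | None = None,
                   include_het: bool = False) -> Structure:
    """Read a structure from a PDB or PQR file path or literal text.

    ``format`` is "pdb" or "pqr"; inferred from the filename suffix when
    omitted.  HETATM records and waters are excluded unless
    ``include_het`` is set.
    """
    label = ""
    text: str
    p = Path(str(source))
    is_path = False
    try:
        is_path = p.is_file()
    except OSError:
        is_path = False
    if is_path:
        text = p.read_text()
        label = p.stem
        if format is None:
            suffix = p.suffix.lower().lstrip(".")
            format = suffix if suffix in ("pdb", "pqr") else "pdb"
    else:
        text = str(source)
        if format is None:
            raise ValueError("format must be given for literal text input")
    format = format.lower()
    lines = text.splitlines()
    if format == "pdb":
        atoms = _parse_pdb(lines, include_het)
    elif format == "pqr":
        atoms = _parse_pqr(lines, include_het)
    else:
        raise ValueError(f"unknown format {format!r}: expected 'pdb' or 'pqr'")
    if not atoms:
        raise ParseError("no ATOM records found")
    return Structure(atoms=atoms, id=label)


def _pdb_atom_line(a: Atom, rec: str = "ATOM") -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (f"{rec:<6s}{a.serial:>5d} {name:<4s}{'':1s}{a.res_name:>3s} "
            f"{a.chain:1s}{a.res_seq:>4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}")


def write_pdb(s: Structure, path) -> None:
    lines = [_pdb_atom_line(a) for a in s.atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pqr(s: Structure, path) -> None:
    lines = []
    for a in s.atoms:
        lines.append(
            f"ATOM {a.serial:>6d} {a.name:<4s} {a.res_name:<3s} {a.chain:1s} "
            f"{a.res_seq:>4d} {a.coords[0]:11.4f} {a.coords[1]:11.4f} "
            f"{a.coords[2]:11.4f} {a.charge:8.4f} {a.radius:7.4f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def assign_charges(s: Structure,
                   table: ChargeRadiusTable = DEFAULT_TABLE) -> Structure:
    """Return a charged copy of ``s`` under the table's charge model.

    Reduced mode: exactly one atom per charged residue carries the
    residue's net charge (at the canonical site atom, or CB when the
    table allows the fallback); all other charges are zeroed.  Keep mode
    preserves existing charges.  Radii are always filled from the table.
    """
    out = s.copy()
    for a in out.atoms:
        a.radius = table.radius_for(a)
        if table.mode == "reduced":
            a.charge = 0.0
    if table.mode != "reduced":
        return out
    for (chain, res_seq), atoms in out.residues():
        res_name = atoms[0].res_name
        if res_name not in table.sites:
            continue
        site, q = table.sites[res_name]
        target = next((a for a in atoms if a.name == site), None)
        if target is None and table.site_fallback_cb:
            target = next((a for a in atoms if a.name == "CB"), None)
        if target is None:
            raise ValueError(
                f"charged residue missing its charge-site atom {site}: "
                f"{res_name} {chain}{res_seq}")
        target.charge = q
    return out


def net_charge(s: Structure) -> float:
    """Sum of atomic partial charges (e). Warns on an all-zero structure."""
    q = s.charges()
    if len(q) and not np.any(q):
        warnings.warn("all charges are zero; did you run assign_charges?",
                      stacklevel=2)
    return float(q.sum()) if len(q) else 0.0


def classify_residues(s: Structure) -> dict[str, int]:
    """Count basic (His/Lys/Arg), acidic (Asp/Glu) and neutral residues."""
    counts = {"basic": 0, "acidic": 0, "neutral": 0, "total": 0}
    for _, atoms in s.residues():
        name = atoms[0].res_name
        counts["total"] += 1
        if name in BASIC_RESIDUES:
            counts["basic"] += 1
        elif name in ACIDIC_RESIDUES:
            counts["acidic"] += 1
        else:
            counts["neutral"] += 1
    return counts
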