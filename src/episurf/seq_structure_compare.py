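"""Sequence divergence, structural superposition and model QC.

p-distance matrices from aligned FASTA (pairwise or complete deletion of
gapped/ambiguous sites), Kabsch least-squares superposition with RMSD,
per-residue Q profiles (Gaussian-weighted CA-CA distance differences,
sigma_ij = |i-j|^0.15), and a coarse Ramachandran phi/psi classifier.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .epsim import DistanceMatrix
from .structure_io import Structure

__all__ = [
    "Alignment",
    "DivergenceMatrix",
    "StructureComparison",
    "RamachandranSummary",
    "read_alignment",
    "p_distance_matrix",
    "kabsch_superpose",
    "qres_profile",
    "dihedral",
    "backbone_dihedrals",
    "ramachandran_summary",
    "DEFAULT_RAMA_REGIONS",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"-", "X"}
AMBIGUOUS = {"-", "X"}


@dataclass
class Alignment:
    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows must have equal length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must all have equal length")
        self.rows = [r.upper() for r in self.rows]
        for lab, row in zip(self.labels, self.rows):
            bad = set(row) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"row {lab!r} has characters outside the amino-acid "
                    f"alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file."""
    aln = AlignIO.read(str(path), "fasta")
    return Alignment(labels=[rec.id for rec in aln],
                     rows=[str(rec.seq) for rec in aln])


@dataclass
class DivergenceMatrix:
    labels: list[str]
    values: np.ndarray        # differences per compared site, in [0, 1]
    n_sites: np.ndarray       # compared-site counts per pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_sites = np.asarray(self.n_sites, dtype=int)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("p-distances must lie in [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(k) for k in pair)
        return float(self.values[i, j])

    def to_distance_matrix(self) -> DistanceMatrix:
        return DistanceMatrix(list(self.labels), self.values.copy(),
                              {"source": "p-distance"})

    def to_csv(self, path) -> None:
        self.to_distance_matrix().to_csv(path)


def p_distance_matrix(a: Alignment,
                      deletion: str = "pairwise") -> DivergenceMatrix:
    """Amino-acid differences per site between all row pairs.

    ``deletion`` is "pairwise" (drop sites gapped/ambiguous in either row
    of a pair) or "complete" (drop columns gapped/ambiguous in any row).
    """
    if len(a) < 2:
        raise ValueError("need at least two sequences")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    rows = [np.array(list(r)) for r in a.rows]
    ok = [~np.isin(r, sorted(AMBIGUOUS)) for r in rows]
    if deletion == "complete":
        keep = np.logical_and.reduce(ok)
        rows = [r[keep] for r in rows]
        ok = [np.ones(keep.sum(), dtype=bool) for _ in rows]
    n = len(a)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = int(ok[i].sum())
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites for pair "
                    f"({a.labels[i]!r}, {a.labels[j]!r})")
            diff = int((rows[i][both] != rows[j][both]).sum())
            values[i, j] = values[j, i] = diff / m
            counts[i, j] = counts[j, i] = m
    return DivergenceMatrix(list(a.labels), values, counts)


@dataclass
class StructureComparison:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # so that mov' = mov @ R.T + t
    rmsd: float
    transformed: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("RMSD must be >= 0")


def kabsch_superpose(ref, mov) -> StructureComparison:
    """Optimal least-squares rigid superposition of paired coordinates.

    Returns the proper rotation R and translation t minimizing
    ||mov @ R.T + t - ref||, plus the RMSD of the superposed pairs.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mov must be (n, 3) arrays of equal shape")
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 paired points")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    if (np.linalg.matrix_rank(ref_c, tol=1e-8) < 2
            or np.linalg.matrix_rank(mov_c, tol=1e-8) < 2):
        raise ValueError("degenerate (collinear) coordinates")
    h = mov_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    t = ref.mean(axis=0) - rot @ mov.mean(axis=0)
    moved = mov @ rot.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum() / n))
    return StructureComparison(rotation=rot, translation=t, rmsd=rmsd,
                               transformed=moved)


def qres_profile(ref, mov, indices=None, min_separation: int = 3) -> np.ndarray:
    """Per-residue structural similarity Q in (0, 1].

    Q_i averages exp(-(d_ij^ref - d_ij^mov)^2 / (2 sigma_ij^2)) over
    partners j with sequence separation |i - j| >= min_separation, where
    sigma_ij = |i - j|**0.15 (Angstrom).  ``indices`` supplies residue
    numbers for separation when the paired lists are non-contiguous.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mov must be (n, 3) arrays of equal shape")
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 paired residues")
    idx = np.arange(n) if indices is None else np.asarray(indices)
    dref = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=2)
    dmov = np.linalg.norm(mov[:, None, :] - mov[None, :, :], axis=2)
    sep = np.abs(idx[:, None] - idx[None, :])
    sep_f = sep.astype(float)
    sigma2 = 2.0 * np.power(sep_f, 0.3, where=sep_f > 0,
                            out=np.ones_like(sep_f))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.exp(-((dref - dmov) ** 2) / sigma2)
    q = np.empty(n)
    for i in range(n):
        mask = sep[i] >= min_separation
        q[i] = terms[i, mask].mean() if mask.any() else 1.0
    return q


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


#: Coarse Ramachandran regions as (phi_min, phi_max, psi_min, psi_max)
#: rectangles.  "favored" holds the alpha and beta cores; "allowed" their
#: 20-degree margins plus the left-handed helix pocket.  User-overridable;
#: no claim of agreement with PROCHECK.
DEFAULT_RAMA_REGIONS = {
    "favored": [(-100.0, -30.0, -77.0, -17.0),    # alpha core
                (-170.0, -50.0, 80.0, 180.0),     # beta core
                (-170.0, -50.0, -180.0, -160.0)], # beta (psi wrap)
    "allowed": [(-120.0, -10.0, -97.0, 3.0),
                (-180.0, -30.0, 60.0, 180.0),
                (-180.0, -30.0, -180.0, -140.0),
                (30.0, 90.0, -20.0, 80.0)],       # left-handed alpha
}


@dataclass
class RamachandranSummary:
    residues: list[dict]       # chain, res_seq, res_name, phi, psi, region
    pct_favored: float
    pct_allowed: float
    pct_disallowed: float
    by_class: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return len(self.residues)


def backbone_dihedrals(s: Structure) -> list[dict]:
    """Per-residue phi/psi (degrees) for residues with full backbone context.

    Chain-terminal residues (no preceding C or following N) are excluded;
    residues with missing backbone atoms are skipped with a warning.
    """
    out: list[dict] = []
    by_chain: dict[str, list[tuple[int, str, dict]] ] = {}
    for (chain, res_seq), atoms in s.residues():
        names = {a.name: a.coords for a in atoms}
        by_chain.setdefault(chain, []).append(
            (res_seq, atoms[0].res_name, names))
    for chain, residues in by_chain.items():
        for k in range(1, len(residues) - 1):
            prev_seq, _, prev = residues[k - 1]
            res_seq, res_name, cur = residues[k]
            next_seq, _, nxt = residues[k + 1]
            need = {"N", "CA", "C"}
            if not (need <= cur.keys() and "C" in prev and "N" in nxt):
                warnings.warn(
                    f"skipping {chain}{res_seq}: missing backbone atoms",
                    stacklevel=2)
                continue
            # require peptide-bond continuity
            if (np.linalg.norm(cur["N"] - prev["C"]) > 2.0
                    or np.linalg.norm(nxt["N"] - cur["C"]) > 2.0):
                continue
            phi = dihedral(prev["C"], cur["N"], cur["CA"], cur["C"])
            psi = dihedral(cur["N"], cur["CA"], cur["C"], nxt["N"])
            out.append({"chain": chain, "res_seq": res_seq,
                        "res_name": res_name, "phi": phi, "psi": psi})
    return out


def _classify(phi: float, psi: float, regions: dict) -> str:
    for name in ("favored", "allowed"):
        for (p0, p1, q0, q1) in regions[name]:
            if p0 <= phi <= p1 and q0 <= psi <= q1:
                return name
    return "disallowed"


def ramachandran_summary(s: Structure,
                         regions: dict | None = None) -> RamachandranSummary:
    """Classify backbone dihedrals into favored/allowed/disallowed.

    Gly and Pro are tabulated separately in ``by_class``; percentages are
    over all classified residues and sum to 100.
    """
    regions = regions or DEFAULT_RAMA_REGIONS
    records = backbone_dihedrals(s)
    counts = {"favored": 0, "allowed": 0, "disallowed": 0}
    by_class: dict[str, dict[str, int]] = {}
    for rec in records:
        region = _classify(rec["phi"], rec["psi"], regions)
        rec["region"] = region
        counts[region] += 1
        cls = {"GLY": "gly", "PRO": "pro"}.get(rec["res_name"], "general")
        by_class.setdefault(cls, {"favored": 0, "allowed": 0,
                                  "disallowed": 0})[region] += 1
    n = len(records)
    pct = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
    return RamachandranSummary(residues=records,
                               pct_favored=pct["favored"],
                               pct_allowed=pct["allowed"],
                               pct_disallowed=pct["disallowed"],
                               by_class=by_class)
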