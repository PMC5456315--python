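"""Electrostatic-potential similarity over protein-skin regions.

The skin is the shell of grid points lying between sigma and sigma+delta
outside the union-of-spheres protein surface.  Similarity uses the
Hodgkin index by default (Carbo optional); the electrostatic distance is
D = sqrt(2 - 2*SI).  Anchored mode intersects the skin with a sphere
(default 35 A) centred on a sequence-motif CA centroid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import KT_TO_KCAL
from .electrostatics import GridSpec, PotentialGrid
from .structure_io import Structure

__all__ = [
    "RegionSpec",
    "RegionMask",
    "SimilarityResult",
    "DistanceMatrix",
    "compute_skin_mask",
    "anchor_from_motif",
    "anchor_sphere_mask",
    "similarity_index",
    "mean_potential_difference",
    "ep_distance_matrix",
]


@dataclass
class RegionSpec:
    sigma: float = 3.0
    delta: float = 4.0
    mode: str = "whole-skin"  # or "anchored"
    anchor: np.ndarray | None = None
    radius: float = 35.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("skin probe sigma must be >= 0")
        if self.delta <= 0:
            raise ValueError("skin thickness delta must be > 0")
        if self.radius <= 0:
            raise ValueError("anchor radius must be > 0")
        if self.mode not in ("whole-skin", "anchored"):
            raise ValueError(f"unknown region mode {self.mode!r}")
        if self.mode == "anchored" and self.anchor is None:
            raise ValueError("anchored mode requires an anchor point")
        if self.anchor is not None:
            self.anchor = np.asarray(self.anchor, dtype=float)


@dataclass
class RegionMask:
    spec: GridSpec
    members: np.ndarray  # boolean field, shape == spec.dims
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)
        if self.members.shape != self.spec.dims:
            raise ValueError("mask shape does not match grid dims")

    @property
    def n_points(self) -> int:
        return int(self.members.sum())

    def intersect(self, other: "RegionMask") -> "RegionMask":
        if not self.spec.same_grid(other.spec):
            raise ValueError("cannot intersect masks on different grids")
        return RegionMask(self.spec, self.members & other.members,
                          {"op": "intersection",
                           "parents": [self.provenance, other.provenance]})


@dataclass
class SimilarityResult:
    si: float
    distance: float
    n_points: int
    kind: str


def compute_skin_mask(s: Structure, g: GridSpec, sigma: float = 3.0,
                      delta: float = 4.0) -> RegionMask:
    """Grid points whose distance to the protein surface lies in
    [sigma, sigma + delta].

    Surface distance at point x is min over atoms of |x - c_i| - r_i.
    """
    if len(s.atoms) == 0:
        raise ValueError("structure has no atoms")
    if delta <= 0:
        raise ValueError("skin thickness delta must be > 0 (empty shell)")
    centers = s.coords()
    radii = s.radii()
    pts = g.point_coords()
    px, py, pz = pts[:, 0], pts[:, 1], pts[:, 2]
    dmin = np.full(len(pts), np.inf)
    # per-atom loop avoids an (n_points, n_atoms, 3) temporary
    for c, r in zip(centers, radii):
        d = np.sqrt((px - c[0]) ** 2 + (py - c[1]) ** 2
                    + (pz - c[2]) ** 2) - r
        np.minimum(dmin, d, out=dmin)
    members = ((dmin >= sigma) & (dmin <= sigma + delta)).reshape(g.dims)
    if not members.any():
        raise ValueError(
            "empty skin mask: enlarge the grid or loosen sigma/delta")
    return RegionMask(g, members, {"structure": s.id, "sigma": sigma,
                                   "delta": delta})


def anchor_sphere_mask(g: GridSpec, anchor, radius: float) -> RegionMask:
    pts = g.point_coords()
    d = np.linalg.norm(pts - np.asarray(anchor, dtype=float), axis=1)
    return RegionMask(g, (d <= radius).reshape(g.dims),
                      {"anchor": list(np.asarray(anchor, float)),
                       "radius": radius})


def anchor_from_motif(s: Structure, motif: str, chain: str) -> np.ndarray:
    """CA centroid of the first occurrence of ``motif`` in a chain sequence."""
    seq = s.sequence(chain)
    ids = s.residue_ids(chain)
    if not seq:
        raise ValueError(f"chain {chain!r} has no residues")
    hits = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            break
        hits.append(i)
        start = i + 1
    if not hits:
        raise ValueError(f"motif {motif!r} not found in chain {chain!r}")
    if len(hits) > 1:
        warnings.warn(f"motif {motif!r} occurs {len(hits)} times in chain "
                      f"{chain!r}; using the first occurrence", stacklevel=2)
    cas = []
    for offset in range(len(motif)):
        ch, res_seq = ids[hits[0] + offset]
        for a in s.residue(ch, res_seq):
            if a.name == "CA":
                cas.append(a.coords)
                break
        else:
            raise ValueError(f"residue {ch}{res_seq} in motif lacks a CA atom")
    return np.mean(cas, axis=0)


def _mask_sums(a: PotentialGrid, b: PotentialGrid,
               m: RegionMask) -> tuple[np.ndarray, np.ndarray]:
    if not (a.spec.same_grid(m.spec) and b.spec.same_grid(m.spec)):
        raise ValueError("potential grids and mask must share one GridSpec")
    if m.n_points == 0:
        raise ValueError("empty region mask")
    return a.values[m.members], b.values[m.members]


def similarity_index(a: PotentialGrid, b: PotentialGrid, m: RegionMask,
                     kind: str = "hodgkin") -> SimilarityResult:
    """Hodgkin or Carbo similarity of two potentials over a mask.

    Hodgkin: 2*sum(ab) / (sum(a^2) + sum(b^2));
    Carbo:   sum(ab) / sqrt(sum(a^2) * sum(b^2));
    both in [-1, 1], with D = sqrt(2 - 2*SI).
    """
    fa, fb = _mask_sums(a, b, m)
    saa = float(fa @ fa)
    sbb = float(fb @ fb)
    sab = float(fa @ fb)
    if saa == 0.0 and sbb == 0.0:
        raise ValueError("similarity undefined: both fields are zero on mask")
    if kind == "hodgkin":
        si = 2.0 * sab / (saa + sbb)
    elif kind == "carbo":
        if saa == 0.0 or sbb == 0.0:
            raise ValueError("Carbo index undefined for a zero field")
        si = sab / np.sqrt(saa * sbb)
    else:
        raise ValueError(f"unknown index kind {kind!r}")
    si = min(1.0, max(-1.0, si))
    return SimilarityResult(si=si, distance=float(np.sqrt(2.0 - 2.0 * si)),
                            n_points=m.n_points, kind=kind)


def mean_potential_difference(a: PotentialGrid, b: PotentialGrid,
                              m: RegionMask) -> float:
    """Mean of (phi_a - phi_b) over the mask, in kcal/mol/e."""
    fa, fb = _mask_sums(a, b, m)
    return float((fa - fb).mean()) * KT_TO_KCAL


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=True):
            raise ValueError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.index], values=df.to_numpy())

    def to_phylip(self, path) -> None:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(f"{lab:<10s} " + " ".join(f"{v:.6f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def ep_distance_matrix(entries: list[tuple[str, Structure, PotentialGrid]],
                       region: RegionSpec | None = None,
                       kind: str = "hodgkin") -> DistanceMatrix:
    """Pairwise electrostatic distances over intersected skin masks.

    All structures must be pre-superposed and all grids share one
    GridSpec.  The pairwise comparison region is the intersection of the
    two members' skins (and the anchor sphere in anchored mode).
    """
    region = region or RegionSpec()
    if not entries:
        raise ValueError("no entries")
    labels = [e[0] for e in entries]
    g = entries[0][2].spec
    for lab, _, grid in entries:
        if not grid.spec.same_grid(g):
            raise ValueError(f"grid for {lab!r} differs from the shared grid")
    masks = [compute_skin_mask(s, g, region.sigma, region.delta)
             for _, s, _ in entries]
    sphere = None
    if region.mode == "anchored":
        sphere = anchor_sphere_mask(g, region.anchor, region.radius)
    n = len(entries)
    d = np.zeros((n, n))
    n_points: dict[str, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            m = masks[i].intersect(masks[j])
            if sphere is not None:
                m = m.intersect(sphere)
            if m.n_points == 0:
                raise ValueError(
                    f"empty pairwise mask for ({labels[i]!r}, {labels[j]!r})")
            res = similarity_index(entries[i][2], entries[j][2], m, kind)
            d[i, j] = d[j, i] = res.distance
            n_points[f"{labels[i]}|{labels[j]}"] = res.n_points
    meta = {"index": kind, "sigma": region.sigma, "delta": region.delta,
            "mode": region.mode, "n_points": n_points}
    if region.mode == "anchored":
        meta["anchor"] = [float(v) for v in region.anchor]
        meta["radius"] = region.radius
    return DistanceMatrix(labels, d, meta)
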