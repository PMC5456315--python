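"""Self-contained synthetic fixtures for the full pipeline.

Ideal alpha-helical scaffolds (backbone + CB at phi=-57, psi=-47,
omega=180) give superposed structure families that differ only in
surface-charge-bearing residues; the qPIPSA benchmark assigns
ln(kcat/Km) values from a linear law on anchored mean potential
differences with configurable slope and Gaussian noise.  All randomness
flows from a single seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import epsim
from .electrostatics import GridSpec, PotentialGrid, SolverParams, solve_lpbe
from .kinetics import KineticRecord
from .mutator import MutantSet, MutationSpec, apply_mutant_set
from .structure_io import (
    Atom,
    ChargeRadiusTable,
    ONE_TO_THREE,
    Structure,
    assign_charges,
)

__all__ = [
    "make_ideal_helix",
    "make_charge_variant_family",
    "make_qpipsa_benchmark",
    "BenchmarkBundle",
    "STUB_TABLE",
    "BASE_BENCHMARK_SEQUENCE",
]

# Charge table for stub (CB-only) side chains: net charges fall back to CB.
STUB_TABLE = ChargeRadiusTable(site_fallback_cb=True)

# Benchmark scaffold: CFT anchor motif flanked by charged positions.
BASE_BENCHMARK_SEQUENCE = "AAKEARKDAACFTAAEKARDKEAA"

# ideal backbone geometry (lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5
PHI_HELIX, PSI_HELIX, OMEGA = -57.0, -47.0, 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
          angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given chain a-b-c, bond |cd|, angle b-c-d, torsion a-b-c-d."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # IUPAC sign convention: negative component along n for positive torsion
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   -bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_ideal_helix(sequence: str, chain: str = "A",
                     start_res: int = 1, id: str = "helix") -> Structure:
    """Build an ideal alpha-helix with N/CA/C/O + CB stub side chains."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    try:
        res_names = [ONE_TO_THREE[aa] for aa in sequence.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid amino-acid letter {exc.args[0]!r}")
    n_res = len(sequence)
    bb: list[dict] = []
    # first residue laid out in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = bb[-1]
        n_new = _nerf(prev["N"], prev["CA"], prev["C"],
                      _B_C_N, _A_CA_C_N, PSI_HELIX)
        ca_new = _nerf(prev["CA"], prev["C"], n_new,
                       _B_N_CA, _A_C_N_CA, OMEGA)
        c_new = _nerf(prev["C"], n_new, ca_new,
                      _B_CA_C, _A_N_CA_C, PHI_HELIX)
        bb.append({"N": n_new, "CA": ca_new, "C": c_new})
    atoms: list[Atom] = []
    serial = 1
    for i, res in enumerate(bb):
        res_name = res_names[i]
        res_seq = start_res + i
        # carbonyl O trans to the next N (psi + 180)
        o = _nerf(res["N"], res["CA"], res["C"],
                  _B_C_O, _A_CA_C_O, PSI_HELIX + 180.0)
        entries = [("N", "N", res["N"]), ("CA", "C", res["CA"]),
                   ("C", "C", res["C"]), ("O", "O", o)]
        if res_name != "GLY":
            cb = _nerf(res["C"], res["N"], res["CA"],
                       _B_CA_CB, _A_N_CA_CB, -122.6)
            entries.append(("CB", "C", cb))
        for name, element, xyz in entries:
            atoms.append(Atom(serial=serial, name=name, element=element,
                              res_name=res_name, res_seq=res_seq,
                              chain=chain, coords=xyz))
            serial += 1
    return Structure(atoms=atoms, id=id)


def make_charge_variant_family(base_sequence: str,
                               variant_specs: list[list[MutationSpec]],
                               seed: int | None = None,
                               chain: str = "A") -> list[Structure]:
    """Superposed helix family differing only in mutated residues.

    Returns one charge-assigned structure per spec list (an empty list
    gives the unmodified base).  ``seed`` is accepted for interface
    symmetry; the construction is deterministic.
    """
    base = make_ideal_helix(base_sequence, chain=chain, id="base")
    out: list[Structure] = []
    for k, specs in enumerate(variant_specs):
        if specs:
            ms = MutantSet(label=f"variant-{k}", specs=list(specs))
            s = apply_mutant_set(base, ms)
        else:
            s = base.copy()
            s.id = f"base-{k}" if k else "base"
        out.append(assign_charges(s, STUB_TABLE))
    return out


@dataclass
class BenchmarkBundle:
    structures: list[Structure]
    grids: list[PotentialGrid]
    records: list[KineticRecord]
    ep_diffs_to_ref: list[float]   # kcal/mol/e, entry i = EP_i - EP_0
    true_slope: float
    noise_sd: float
    seed: int
    region: epsim.RegionSpec
    log: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def pairs(self, mode: str = "all") -> list[tuple[float, float]]:
        """(delta-ln, delta-EP) pairs recomputed from grids and skins.

        mode "all": every unordered enzyme pair; mode "ref": pairs against
        enzyme 0 only.
        """
        g = self.grids[0].spec
        masks = [epsim.compute_skin_mask(s, g, self.region.sigma,
                                         self.region.delta)
                 for s in self.structures]
        sphere = epsim.anchor_sphere_mask(g, self.region.anchor,
                                          self.region.radius)
        lns = [r.ln_kcat_km for r in self.records]
        out = []
        n = len(self.structures)
        pairs_idx = ([(i, j) for i in range(n) for j in range(i + 1, n)]
                     if mode == "all" else [(i, 0) for i in range(1, n)])
        for i, j in pairs_idx:
            m = masks[i].intersect(masks[j]).intersect(sphere)
            dep = epsim.mean_potential_difference(self.grids[i],
                                                  self.grids[j], m)
            out.append((lns[i] - lns[j], dep))
        return out

    def write(self, outdir) -> None:
        """Emit PQR structures, a TSV kinetic table and a JSON manifest."""
        from .structure_io import write_pqr

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.structures:
            write_pqr(s, outdir / f"{s.id.replace(':', '_')}.pqr")
        rows = ["label\tkcat_km\tln_kcat_km"]
        for r in self.records:
            rows.append(f"{r.label}\t{r.kcat_km:.6e}\t{r.ln_kcat_km:.6f}")
        (outdir / "kinetics.tsv").write_text("\n".join(rows) + "\n")
        manifest = {"seed": self.seed, "true_slope": self.true_slope,
                    "noise_sd": self.noise_sd,
                    "ep_diffs_to_ref": self.ep_diffs_to_ref,
                    "labels": self.labels, "log": self.log}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def make_qpipsa_benchmark(n_enzymes: int = 20, true_slope: float = -0.1046,
                          noise_sd: float = 0.05, seed: int = 0,
                          base_sequence: str = BASE_BENCHMARK_SEQUENCE,
                          ref_ln: float = 12.0,
                          h: float = 1.0, pad: float = 12.0,
                          params: SolverParams | None = None,
                          anchor_motif: str = "CFT",
                          radius: float = 35.0) -> BenchmarkBundle:
    """End-to-end synthetic benchmark for slope recovery.

    Builds ``n_enzymes`` charge-variant helices (enzyme 0 is the base),
    solves the LPBE for each on a shared grid, measures anchored mean
    potential differences to the base, and assigns
    ln_i = ref_ln + dEP(i,0)/true_slope + N(0, noise_sd).
    """
    if n_enzymes < 3:
        raise ValueError("need at least 3 enzymes")
    if true_slope == 0:
        raise ValueError("true_slope must be nonzero")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = make_ideal_helix(base_sequence, id="base")
    charged_pos = [(i + 1, aa) for i, aa in enumerate(base_sequence)
                   if aa in "KRDE"]
    variant_specs: list[list[MutationSpec]] = [[]]
    for v in range(n_enzymes - 1):
        # stratified mutation counts so every benchmark spans the full
        # charge range regardless of seed; positions stay random
        k = 1 + v % len(charged_pos)
        chosen = rng.choice(len(charged_pos), size=k, replace=False)
        specs = [MutationSpec("A", charged_pos[c][0], charged_pos[c][1], "A")
                 for c in sorted(chosen)]
        variant_specs.append(specs)
    structures = make_charge_variant_family(base_sequence, variant_specs)
    for i, s in enumerate(structures):
        s.id = f"enz{i:02d}"
    params = params or SolverParams()
    g = GridSpec.from_structure(structures[0], h=h, pad=pad)
    grids = [solve_lpbe(s, g, params) for s in structures]
    anchor = epsim.anchor_from_motif(structures[0], anchor_motif, "A")
    region = epsim.RegionSpec(mode="anchored", anchor=anchor, radius=radius)
    sphere = epsim.anchor_sphere_mask(g, anchor, radius)
    masks = [epsim.compute_skin_mask(s, g, region.sigma, region.delta)
             for s in structures]
    ep_diffs = [0.0]
    for i in range(1, n_enzymes):
        m = masks[i].intersect(masks[0]).intersect(sphere)
        ep_diffs.append(epsim.mean_potential_difference(grids[i], grids[0], m))
    noise = rng.normal(0.0, noise_sd, size=n_enzymes)
    records = [KineticRecord(f"enz{i:02d}",
                             math.exp(ref_ln + ep_diffs[i] / true_slope
                                      + noise[i]))
               for i in range(n_enzymes)]
    log = {
        "base_sequence": base_sequence,
        "n_mutations": [len(v) for v in variant_specs],
        "solver": grids[0].metadata,
        "anchor": [float(v) for v in anchor],
        "radius": radius,
        "ref_ln": ref_ln,
    }
    return BenchmarkBundle(structures=structures, grids=grids,
                           records=records, ep_diffs_to_ref=ep_diffs,
                           true_slope=true_slope, noise_sd=noise_sd,
                           seed=seed, region=region, log=log)
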