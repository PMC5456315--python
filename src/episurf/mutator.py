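"""In-silico point mutagenesis by side-chain truncation.

Every mutation truncates the residue to its CB stub and re-labels it;
charged targets put their table net charge on CB.  This preserves the
charge-deletion signal driving surface-potential comparisons while
avoiding rotamer building.  Neutral-to-neutral swaps change labels only —
a known limitation of the reduced charge model, recorded in metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .structure_io import (
    ChargeRadiusTable,
    DEFAULT_TABLE,
    ONE_TO_THREE,
    THREE_TO_ONE,
    Structure,
)

__all__ = [
    "MutationSpec",
    "MutantSet",
    "MutationError",
    "mutate_residue",
    "apply_mutant_set",
    "load_mutant_sets",
    "bundled_mutant_sets",
]

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "CB"}

_DATA_DIR = Path(__file__).parent / "data"


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpec:
    chain: str
    res_seq: int
    wt_aa: str
    target_aa: str

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.target_aa):
            if aa not in ONE_TO_THREE:
                raise MutationError(f"unknown amino acid code {aa!r}")
        if self.target_aa == "G":
            raise MutationError(
                "target 'G' unsupported: glycine has no CB stub")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.chain}{self.res_seq}{self.target_aa}"


@dataclass
class MutantSet:
    label: str
    specs: list[MutationSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [(m.chain, m.res_seq) for m in self.specs]
        if len(set(positions)) != len(positions):
            raise MutationError(
                f"mutant set {self.label!r} has duplicate positions")


def _check_spec(s: Structure, spec: MutationSpec) -> str | None:
    """Return an error message for ``spec`` against ``s``, or None."""
    try:
        atoms = s.residue(spec.chain, spec.res_seq)
    except KeyError:
        return f"{spec}: no residue at {spec.chain}{spec.res_seq}"
    found = THREE_TO_ONE.get(atoms[0].res_name, "X")
    if found != spec.wt_aa:
        return (f"{spec}: wild-type mismatch at {spec.chain}{spec.res_seq}: "
                f"expected {spec.wt_aa}, found {found}")
    if spec.wt_aa == "G":
        return f"{spec}: glycine source has no CB to truncate to"
    names = {a.name for a in atoms}
    missing = {"N", "CA", "C", "CB"} - names
    if missing:
        return f"{spec}: residue missing backbone atoms {sorted(missing)}"
    return None


def mutate_residue(s: Structure, spec: MutationSpec,
                   table: ChargeRadiusTable = DEFAULT_TABLE) -> Structure:
    """Apply one mutation, returning a new structure (input untouched)."""
    err = _check_spec(s, spec)
    if err:
        raise MutationError(err)
    out = s.copy()
    target3 = ONE_TO_THREE[spec.target_aa]
    kept = []
    for a in out.atoms:
        if a.chain == spec.chain and a.res_seq == spec.res_seq:
            if a.name not in BACKBONE_NAMES:
                continue
            a.res_name = target3
            a.charge = (table.residue_charge(target3)
                        if a.name == "CB" else 0.0)
        kept.append(a)
    out.atoms = kept
    return out


def apply_mutant_set(s: Structure, m: MutantSet,
                     table: ChargeRadiusTable = DEFAULT_TABLE) -> Structure:
    """Apply all mutations of a set; all-or-nothing on validation errors."""
    errors = [e for e in (_check_spec(s, sp) for sp in m.specs) if e]
    if errors:
        raise MutationError(
            f"mutant set {m.label!r} invalid:\n" + "\n".join(errors))
    out = s
    for spec in sorted(m.specs, key=lambda sp: (sp.chain, sp.res_seq)):
        out = mutate_residue(out, spec, table)
    out.id = f"{s.id}:{m.label}" if s.id else m.label
    return out


def load_mutant_sets(path) -> dict[str, MutantSet]:
    """Read mutant sets from TSV with columns label, chain, pos, wt, target."""
    sets: dict[str, list[MutationSpec]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "label":
            continue
        if len(fields) != 5:
            raise MutationError(
                f"{path}:{lineno}: expected 5 tab-separated fields")
        label, chain, pos, wt, target = fields
        if label not in sets:
            sets[label] = []
            order.append(label)
        sets[label].append(MutationSpec(chain, int(pos), wt, target))
    return {lab: MutantSet(lab, sets[lab]) for lab in order}


def bundled_mutant_sets(name: str) -> dict[str, MutantSet]:
    """Bundled panels: "haeiii" (HaeIII variants) or "hdnmt2" (human
    DNMT2 Lys/Arg-to-Ala variants)."""
    fname = {"haeiii": "haeiii_mutants.tsv",
             "hdnmt2": "hdnmt2_mutants.tsv"}.get(name)
    if fname is None:
        raise ValueError(f"unknown bundled panel {name!r}")
    return load_mutant_sets(_DATA_DIR / fname)
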