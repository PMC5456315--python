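"""Linear prediction of ln(kcat/Km) from electrostatic-potential differences.

Pairs of (delta ln(kcat/Km), delta potential in kcal/mol/e) are fitted by
least squares, through the origin by default after antisymmetrizing the
pair set (a zero pair difference must map to zero).  Predictions anchor on
experimentally characterized reference enzymes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "KineticRecord",
    "KineticModel",
    "Prediction",
    "ln_kcat_km",
    "fit_kinetic_model",
    "predict_ln_kcat_km",
    "read_kinetic_table",
    "bundled_kinetic_table",
]

_DATA_DIR = Path(__file__).parent / "data"


def ln_kcat_km(value: float) -> float:
    """Natural log of a catalytic efficiency (M^-1 s^-1)."""
    if value <= 0:
        raise ValueError(f"kcat/Km must be > 0, got {value!r}")
    return math.log(value)


@dataclass(frozen=True)
class KineticRecord:
    label: str
    kcat_km: float

    def __post_init__(self) -> None:
        if self.kcat_km <= 0:
            raise ValueError("kcat/Km must be > 0")

    @property
    def ln_kcat_km(self) -> float:
        return math.log(self.kcat_km)


@dataclass
class KineticModel:
    slope: float                # kcal/mol/e per ln unit
    intercept: float = 0.0
    r2: float = float("nan")
    n_pairs: int = 0
    through_origin: bool = True
    note: str = ""
    provenance: dict = field(default_factory=dict)

    def predict_dln(self, dep: float) -> float:
        """Delta ln implied by a potential difference (kcal/mol/e)."""
        if self.slope == 0:
            raise ValueError("model slope is zero; cannot invert")
        return (dep - self.intercept) / self.slope


def fit_kinetic_model(pairs: list[tuple[float, float]],
                      through_origin: bool = True) -> KineticModel:
    """Least-squares fit of delta-EP (y) on delta-ln (x).

    Each input pair (x, y) is antisymmetrized by adding (-x, -y) before
    fitting, so the fit is invariant to pair orientation.  Through-origin
    (the default): slope = sum(x*y)/sum(x^2).  R^2 is computed on the
    antisymmetrized set and is non-informative for a single pair.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    x = np.concatenate([x, -x])
    y = np.concatenate([y, -y])
    if not np.any(x):
        raise ValueError("degenerate fit: all delta-ln values are zero")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    resid = y - (slope * x + intercept)
    ss_tot = float(y @ y) if through_origin else float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    note = ""
    if len(pairs) == 1:
        note = "single-pair fit: R^2 is non-informative"
    return KineticModel(slope=slope, intercept=intercept, r2=r2,
                        n_pairs=len(pairs), through_origin=through_origin,
                        note=note)


@dataclass
class Prediction:
    label: str
    ln_kcat_km: float
    spread: float
    per_reference: dict[str, float] = field(default_factory=dict)


def predict_ln_kcat_km(model: KineticModel,
                       ep_diffs_to_refs: list[tuple[KineticRecord, float]],
                       label: str = "") -> Prediction:
    """Predict ln(kcat/Km) from potential differences to reference enzymes.

    Each entry is (reference record, EP_target - EP_ref in kcal/mol/e);
    the per-reference estimate is ln_ref + dEP/slope; the returned value is
    their mean, with spread = max - min.
    """
    if model.slope == 0:
        raise ValueError("model slope is zero")
    if not ep_diffs_to_refs:
        raise ValueError("need at least one reference")
    estimates = {ref.label: ref.ln_kcat_km + dep / model.slope
                 for ref, dep in ep_diffs_to_refs}
    values = list(estimates.values())
    return Prediction(label=label, ln_kcat_km=float(np.mean(values)),
                      spread=float(max(values) - min(values)),
                      per_reference=estimates)


def read_kinetic_table(path) -> list[KineticRecord]:
    """Read a TSV with columns label, kcat_km."""
    df = pd.read_csv(path, sep="\t")
    if not {"label", "kcat_km"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'label' and 'kcat_km'")
    return [KineticRecord(str(row.label), float(row.kcat_km))
            for row in df.itertuples()]


def bundled_kinetic_table() -> list[KineticRecord]:
    """The two experimentally characterized anchors (HaeIII, HhaI)."""
    return read_kinetic_table(_DATA_DIR / "kinetic_constants.tsv")
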