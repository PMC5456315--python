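"""Physical constants and unit conversions used across the package.

All electrostatic potentials are computed and stored in thermal units
(kT/e).  Conversion to kcal/mol/e happens exactly once, downstream, using
:data:`KT_TO_KCAL`.
"""

#: e^2 / (4 pi eps0), in kcal * Angstrom / mol  (Coulomb constant in
#: molecular-mechanics units).
COULOMB_KCAL = 332.0637

#: kT expressed in kcal/mol at the reference temperature (298.15 K).
#: This is the single conversion constant between kT/e and kcal/mol/e.
KT_TO_KCAL = 0.5922

#: Reference temperature, Kelvin.
T_REF = 298.15

#: Avogadro's number (1/mol).
N_AVOGADRO = 6.02214076e23


def coulomb_kt(temperature: float = T_REF) -> float:
    """Coulomb prefactor C such that phi = C * q / (eps * r) is in kT/e.

    ``q`` in elementary charges, ``r`` in Angstrom.  At 298.15 K this is
    approximately 560.7 kT/e * Angstrom.
    """
    kt_kcal = KT_TO_KCAL * temperature / T_REF
    return COULOMB_KCAL / kt_kcal


def debye_kappa(ionic_strength: float, eps_out: float,
                temperature: float = T_REF) -> float:
    """Inverse Debye length (1/Angstrom) for a 1:1 electrolyte.

    ``ionic_strength`` in mol/L.  kappa^2 = 8 pi l_B n, with the Bjerrum
    length l_B = C/eps and the ion number density n in 1/A^3.  At 0.15 M
    in water (eps 78.4, 298.15 K) the Debye length is ~7.9 Angstrom.
    """
    import math

    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return 0.0
    l_b = coulomb_kt(temperature) / eps_out
    n_density = ionic_strength * N_AVOGADRO * 1e-27  # ions / A^3
    return math.sqrt(8.0 * math.pi * l_b * n_density)
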