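"""Physical constants and unit bridges.

All energies inside the package are expressed in multiples of k_B*T at the
fixed working temperature of 310 K; forces are in pN and displacements in
Angstrom, so the mechanical work F*delta enters the rate expressions through
the conversion 1 pN*A = 1e-22 J.
"""

# CODATA 2018 exact values
BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23

#: fixed working temperature (K)
TEMPERATURE_K = 310.0

#: thermal energy at 310 K (J); equals 4.28001e-21 J to 6 significant figures
KBT_J = BOLTZMANN_J_PER_K * TEMPERATURE_K

#: 1 pN * 1 Angstrom in J
PN_ANGSTROM_J = 1.0e-22

#: thermochemical calorie
JOULE_PER_KCAL = 4184.0

#: inter-basepair rise along the template (Angstrom)
DELTA_ANGSTROM = 3.4

#: pre-exponential factor of the translocation rates (s^-1)
PREFACTOR_PER_S = 1.0e6


def kcal_per_mol_to_kBT(x: float, temperature_K: float = TEMPERATURE_K) -> float:
    """Convert a molar standard Gibbs energy (kcal/mol) to per-molecule k_B*T units."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return x * JOULE_PER_KCAL / (AVOGADRO_PER_MOL * BOLTZMANN_J_PER_K * temperature_K)


def kBT_to_kcal_per_mol(x: float, temperature_K: float = TEMPERATURE_K) -> float:
    """Inverse of :func:`kcal_per_mol_to_kBT`."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return x * (AVOGADRO_PER_MOL * BOLTZMANN_J_PER_K * temperature_K) / JOULE_PER_KCAL


def force_term_kBT(force_pN: float, displacement_A: float) -> float:
    """Mechanical work F*d expressed in k_B*T (assisting force positive)."""
    return force_pN * displacement_A * PN_ANGSTROM_J / KBT_J
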