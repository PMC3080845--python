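"""Physical constants and unit conventions used package-wide.

Units are fixed throughout: energies in kcal/mol, lengths in Angstrom (A),
times in ns, temperatures in K, charges in elementary charge units (e).
"""

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041

#: Coulomb constant k_e, kcal A / (mol e^2).
COULOMB_K = 332.0636

#: Default solvent (water) dielectric for the generalized Born term.
SOLVENT_DIELECTRIC = 78.5

#: Default interior (solute) dielectric.
INTERIOR_DIELECTRIC = 1.0


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
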