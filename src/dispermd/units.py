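"""Unit conventions and physical constants.

All internal quantities use the nm / ps / kJ·mol⁻¹ / K / e / amu system,
in which 1 amu·nm²·ps⁻² = 1 kJ·mol⁻¹ exactly.  File readers convert at
the boundary (PDB and XYZ are Å; GRO is nm).
"""

# Boltzmann constant, kJ/(mol·K)  (CODATA 2018, exact SI definition)
KB = 0.008_314_462_618_153_24

# Coulomb prefactor f = 1/(4πε0), kJ·mol⁻¹·nm·e⁻²
F_COUL = 138.935_458

# Avogadro constant, mol⁻¹
N_AVOGADRO = 6.022_140_76e23

# Length conversions
ANGSTROM_TO_NM = 0.1
NM_TO_ANGSTROM = 10.0

# 1 kJ·mol⁻¹·nm⁻³ expressed in bar
PRESSURE_KJ_PER_NM3_TO_BAR = 16.605_390_666

# amu/nm³ -> g/cm³  (1 amu/nm³ = 1/N_A g / 1e-21 cm³)
AMU_PER_NM3_TO_G_PER_CC = 1.0 / 602.214_076

# g/mol per Å³ -> g/cm³ when dividing molar mass by N_A·V[Å³]
G_PER_MOL_PER_A3_TO_G_PER_CC = 1.0 / 0.602_214_076


def bar_to_internal(p_bar: float) -> float:
    """Convert pressure in bar to kJ·mol⁻¹·nm⁻³."""
    return p_bar / PRESSURE_KJ_PER_NM3_TO_BAR


def internal_to_bar(p_internal: float) -> float:
    """Convert pressure in kJ·mol⁻¹·nm⁻³ to bar."""
    return p_internal * PRESSURE_KJ_PER_NM3_TO_BAR
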