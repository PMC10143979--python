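"""Literature unit-cell geometries for drug crystals used as worked
examples of the density ↔ lattice-parameter relation.

``*_SIMULATED`` entries hold MD-derived lattice parameters reported in
the force-field validation literature for these drugs;
``*_EXPERIMENTAL`` entries hold the corresponding crystallographic
reference values.  Lengths are Å, angles degrees, molar masses g/mol.
These cells carry no atomic contents (Z and M suffice for density).
"""

from __future__ import annotations

from ..synthetic import UnitCellSpec

__all__ = [
    "NAPROXEN_SIMULATED",
    "NAPROXEN_EXPERIMENTAL",
    "DIMETHYL_FUMARATE_SIMULATED",
    "DIMETHYL_FUMARATE_EXPERIMENTAL",
    "OMEPRAZOLE_SIMULATED",
    "OMEPRAZOLE_EXPERIMENTAL",
    "WORKED_EXAMPLES",
]

# naproxen: C14H14O3, monoclinic P21, Z = 2
NAPROXEN_SIMULATED = UnitCellSpec(
    a=13.30, b=5.76, c=7.87, alpha=90.0, beta=93.9, gamma=90.0,
    z=2, molar_mass=230.26, name="naproxen_sim",
)
NAPROXEN_EXPERIMENTAL = UnitCellSpec(
    a=13.38, b=5.79, c=7.91, alpha=90.0, beta=93.9, gamma=90.0,
    z=2, molar_mass=230.26, name="naproxen_exp",
)

# dimethyl fumarate: C6H8O4, triclinic P-1, Z = 1
DIMETHYL_FUMARATE_SIMULATED = UnitCellSpec(
    a=3.87, b=5.64, c=8.36, alpha=100.8, beta=100.3, gamma=105.7,
    z=1, molar_mass=144.13, name="dimethyl_fumarate_sim",
)
DIMETHYL_FUMARATE_EXPERIMENTAL = UnitCellSpec(
    a=3.87, b=5.64, c=8.36, alpha=100.8, beta=100.3, gamma=105.7,
    z=1, molar_mass=144.13, name="dimethyl_fumarate_exp",
)

# omeprazole: C17H19N3O3S, triclinic, Z = 2
OMEPRAZOLE_SIMULATED = UnitCellSpec(
    a=9.81, b=10.49, c=10.45, alpha=90.0, beta=111.5, gamma=116.5,
    z=2, molar_mass=345.42, name="omeprazole_sim",
)
OMEPRAZOLE_EXPERIMENTAL = UnitCellSpec(
    a=9.70, b=10.29, c=10.62, alpha=90.4, beta=112.1, gamma=115.9,
    z=2, molar_mass=345.42, name="omeprazole_exp",
)

# (drug, simulated cell, literature simulated density g/cc)
WORKED_EXAMPLES = [
    ("naproxen", NAPROXEN_SIMULATED, 1.27),
    ("dimethyl_fumarate", DIMETHYL_FUMARATE_SIMULATED, 1.43),
    ("omeprazole", OMEPRAZOLE_SIMULATED, 1.31),
]
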