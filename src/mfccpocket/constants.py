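"""Physical constants and standard geometric parameters.

Units are Angstrom for lengths and kcal/mol for energies throughout the
package.
"""

# Coulomb constant for q in elementary charges, d in Angstrom, E in kcal/mol.
COULOMB_KCAL: float = 332.0637

# 1 hartree in kcal/mol, used when harvesting external QM single points.
HARTREE_TO_KCAL: float = 627.509474

# Standard X-H bond lengths (Angstrom) for added / saturating hydrogens.
BOND_N_H: float = 1.01
BOND_C_H: float = 1.09
BOND_O_H: float = 0.96
BOND_S_H: float = 1.34

# Water geometry (gas-phase experimental values).
WATER_O_H: float = 0.9572
WATER_H_O_H_DEG: float = 104.52

# A peptide C-N bond longer than this is treated as a chain break.
PEPTIDE_BOND_MAX: float = 2.0

# Default donor-acceptor heavy-atom cutoff for water H-bond assignment.
HBOND_DMAX_DEFAULT: float = 3.5

# Radial shell grid step: spheres at r = n/2, n = 1, 2, 3, ...
SHELL_STEP: float = 0.5

# Default relative-change threshold for shell-energy convergence (10%).
CONVERGENCE_THRESHOLD: float = 0.10

# Dielectric constants evaluated by default (pocket interior vs interface).
DEFAULT_DIELECTRICS: tuple[float, float] = (10.0, 40.0)

# Default pocket radius sweep limit.
DEFAULT_R_MAX: float = 10.0

ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "SC", "TI", "V", "CR", "MN", "FE",
    "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE", "BR", "KR", "RB", "SR",
    "MO", "RU", "PD", "AG", "CD", "I", "XE", "CS", "BA", "W", "PT", "AU",
    "HG", "PB",
}

def x_h_bond_length(element: str) -> float:
    """Standard bond length for a hydrogen attached to `element`."""
    return {
        "N": BOND_N_H,
        "C": BOND_C_H,
        "O": BOND_O_H,
        "S": BOND_S_H,
    }.get(element.upper(), BOND_C_H)
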