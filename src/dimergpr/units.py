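"""Unit conventions and physical constants.

External units are Angstrom (length), kJ/mol (energy), femtosecond (time),
unified atomic mass units (mass) and Kelvin (temperature).  Forces are
kJ/mol/A.  The two derived conversion factors below close the mechanical
unit system: accelerations integrate in A/fs^2 and kinetic energies come
out in kJ/mol.
"""

HARTREE_TO_KJ_MOL = 2625.4996
KCAL_TO_KJ = 4.184
CHEMICAL_ACCURACY_KJ_MOL = 4.184  # 1 kcal/mol

#: Boltzmann constant, kJ/mol/K
KB_KJ_MOL_K = 0.008314462618

#: Coulomb constant e^2/(4 pi eps0), kJ * A / mol / e^2
COULOMB_K = 1389.35457644382

#: (kJ/mol/A) / (g/mol) -> A/fs^2
FORCE_OVER_MASS_TO_ACC = 1.0e-4

#: g/mol * (A/fs)^2 -> kJ/mol
MASS_VEL2_TO_KJ_MOL = 1.0e4

ATOMIC_MASSES = {"O": 15.999, "H": 1.008}


def hartree_to_kj_mol(e_hartree: float) -> float:
    return e_hartree * HARTREE_TO_KJ_MOL


def kj_mol_to_hartree(e_kj_mol: float) -> float:
    return e_kj_mol / HARTREE_TO_KJ_MOL
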