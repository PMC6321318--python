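"""Physical constants in the package's internal unit system.

Internal units follow GROMOS-style molecular-simulation conventions:
length nm, time ps, charge e, energy kJ mol^-1, temperature K.
Electrostatic potentials are then kJ mol^-1 e^-1 and electric fields
kJ mol^-1 nm^-1 e^-1; both carry the Coulomb prefactor ``F_ELEC``.
"""

# Coulomb constant 1/(4 pi eps0) in kJ mol^-1 nm e^-2
F_ELEC = 138.935458

# Hartree energy in kJ mol^-1 and Bohr radius in nm (>= 8 significant digits);
# used to bridge atomic-unit dispersion coefficients to internal units.
HARTREE_KJMOL = 2625.4996
BOHR_NM = 0.052917721

# 1 Debye in e nm
DEBYE_E_NM = 0.020819434

# Molar gas constant, kJ mol^-1 K^-1 (doubles as Boltzmann constant for
# per-mole energies).
R_GAS = 8.31446261815324e-3
KB_KJMOL = R_GAS

# Boltzmann constant in J K^-1 (SI), Avogadro's number
KB_SI = 1.380649e-23
N_AVOGADRO = 6.02214076e23

# Atomic masses (g mol^-1); their sum defines the water molar mass used in
# density conversions.
MASS_O = 15.9994
MASS_H = 1.00795
M_WATER = MASS_O + 2.0 * MASS_H  # 18.0153

# Pressure conversions: 1 kJ mol^-1 nm^-3 in bar / atm
PRESSURE_INTERNAL_TO_BAR = 1.0e3 / (N_AVOGADRO * 1.0e-27) / 1.0e5  # 16.6054...
BAR_PER_ATM = 1.01325

# Bondi van der Waals radii (nm) used for Connolly-style surface grids
BONDI_RADII_NM = {"O": 0.152, "H": 0.120, "N": 0.155, "C": 0.170}
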