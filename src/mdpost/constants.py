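"""Physical constants used project-wide.

All energies are kcal/mol, lengths Angstrom, masses amu, charges in
elementary charge units, temperatures Kelvin.
"""

#: Boltzmann constant, kcal/mol/K.
K_BOLTZMANN = 0.0019872

#: Coulomb prefactor k_e, kcal*A/(mol*e^2): E = K_COULOMB * q1*q2 / r.
K_COULOMB = 332.0637

#: Planck constant, J*s.
PLANCK_H = 6.62607015e-34

#: Boltzmann constant, J/K (for vibrational partition functions).
K_BOLTZMANN_SI = 1.380649e-23

#: Avogadro number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: 1 kcal in J.
KCAL_TO_J = 4184.0

#: 1 amu in kg.
AMU_TO_KG = 1.66053906660e-27

#: Gas constant, kcal/mol/K (identical to K_BOLTZMANN in molar units).
R_GAS = K_BOLTZMANN
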