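"""Physical constants and unit conversions.

All package energies are kJ/mol (per molecule for lattice energies),
lengths in Å, angles in degrees, temperatures in K.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083144621

#: Avogadro's number, mol^-1
N_AVOGADRO = 6.02214076e23

#: Coulomb prefactor e^2/(4 pi eps0), kJ mol^-1 Å e^-2
COULOMB_KC = 1389.35457644382

#: h*c*N_A: converts a wavenumber in cm^-1 to kJ/mol (photon energy hbar*omega)
CM1_TO_KJMOL = 0.011962657277981569

#: Planck constant over 2 pi times N_A, kJ mol^-1 s
HBAR_KJMOL_S = 1.0545718176461565e-34 * 6.02214076e23 / 1000.0
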