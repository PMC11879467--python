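"""Physical constants and unit conversions used throughout the package.

All energetics are carried internally in eV, frequencies in cm^-1, masses in
amu, cross sections in A^2, dipoles in Debye, and polarizability volumes in
A^3.  Every conversion lives here so that the unit chain from state counting
through capture theory is consistent end to end.
"""

# 1 cm^-1 expressed in eV (hc in eV*cm)
CM1_TO_EV = 1.239841984e-4

# Boltzmann constant
KB_EV = 8.617333262e-5  # eV/K
KB_J = 1.380649e-23  # J/K

# Planck constant
H_EV_S = 4.135667696e-15  # eV*s

EV_TO_J = 1.602176634e-19  # J per eV
AMU_TO_KG = 1.66053906660e-27  # kg per amu

# Coulomb constant e^2/(4*pi*eps0) in eV*Angstrom; the natural unit for
# ion-induced-dipole and ion-dipole potentials with alpha in A^3.
COULOMB_EV_ANG = 14.3996

# 1 Debye in e*Angstrom
DEBYE_TO_E_ANG = 0.2081943

# 1 mTorr in Pa
MTORR_TO_PA = 0.13332237

# Gaussian FWHM -> standard deviation: 1/(2*sqrt(2*ln2))
FWHM_TO_SD = 1.0 / 2.3548

# Default temperature for reaction enthalpies (thermochemical convention).
T_ENTHALPY = 298.15  # K

# Default internal temperature of beam-thermalized ions.  Distinct from
# T_ENTHALPY and never conflated with it.
T_ION = 310.0  # K
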