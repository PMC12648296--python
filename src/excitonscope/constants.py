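"""Physical constants and package-wide default parameters.

Internal unit conventions: coordinates in Å, charges in elementary charge e,
energies in eV, spectra in cm^-1, volumetric grids in bohr (cube convention).
"""

# --- unit conversions -------------------------------------------------------
EV_TO_CM = 8065.544           # 1 eV in cm^-1
CM_TO_EV = 1.0 / EV_TO_CM
EANG_TO_DEBYE = 4.80321       # 1 e*Angstrom in Debye
BOHR_TO_ANG = 0.529177210903  # 1 bohr in Angstrom
ANG_TO_BOHR = 1.0 / BOHR_TO_ANG

# Coulomb constant in eV*Angstrom/e^2 (1/(4 pi eps0) in these units)
KE_EV_ANG = 14.39964

# Boltzmann constant
KB_EV = 8.617333262e-5        # eV/K
KB_CM = KB_EV * EV_TO_CM      # cm^-1/K

# Speed of light, used to turn wavenumbers into angular frequencies:
# omega[rad/ps] = 2*pi*C_CM_PS * nu[cm^-1]
C_CM_PS = 0.0299792458        # cm/ps
TWO_PI_C = 2.0 * 3.141592653589793 * C_CM_PS

# --- model defaults ---------------------------------------------------------
DEFAULT_SCREENING = 0.69      # environmental screening of excitonic couplings
DEFAULT_CHARGE_SCALE = 0.724  # transition-charge scaling to the experimental dipole
DEFAULT_BIN_WIDTH_EV = 0.013  # site-energy histogram bin width
COARSE_BIN_WIDTH_EV = 0.245   # coarse variant used for small-sample CT scans
DEFAULT_TEMPERATURE_K = 300.0
DEFAULT_ALIGN_NM = 914.0      # experimental Q_y absorption peak position

# CT-state classification thresholds (dominant NTO weight n, oscillator strength f)
CT_NTO_MIN = 0.94
CT_OSC_MAX = 0.01
MIXED_NTO_MIN = 0.90

# Range-separation parameters (a0^-1) for the underlying LC functional
OMEGA_DEFAULT = 0.30
OMEGA_TUNED = 0.126
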