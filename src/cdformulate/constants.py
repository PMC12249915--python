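"""Physical constants and package-wide defaults.

All internal computation is SI (m²/s, mol/L, Pa·s, K). I/O layers accept the
conventional NMR/pharma units (1e-10 m²/s, mM, G/cm) and convert on ingest.
"""

#: Boltzmann constant, J/K (CODATA exact).
BOLTZMANN_K = 1.380649e-23

#: Gyromagnetic ratio of the proton, rad s⁻¹ T⁻¹.
GAMMA_1H = 2.6752218744e8

#: Default sample temperature: room temperature, K.
ROOM_TEMPERATURE_K = 298.15

#: Dynamic viscosity of D2O at 25 °C, Pa·s.  Used as the default solvent
#: viscosity for Stokes-Einstein radius estimates.
D2O_VISCOSITY_PA_S = 1.09e-3

#: Chemical-shift reference: residual HDO in D2O, ppm.
HDO_REFERENCE_PPM = 4.64

#: Default 1H spectrometer frequency, MHz (600 MHz-class instrument).
SPECTROMETER_FREQ_MHZ = 599.8

#: One-bond 1J(13C-1H) coupling of formate, Hz — satellite doublet spacing.
FORMATE_1JCH_HZ = 210.0

#: Natural abundance of 13C; total fractional area moved into the two
#: satellite lines of a carbon-bound proton signal.
C13_NATURAL_ABUNDANCE = 0.011

#: Water autoionisation constant at 25 °C.
KW = 1e-14

#: Default relative tolerance when comparing diffusion coefficients of
#: non-binding reference species across samples (viscosity matching).
DEFAULT_VISCOSITY_MATCH_TOL = 0.02

#: Maximum fractional overshoot of the observed guest D outside the
#: [D_host, D_free] bracket that is clamped (with a warning) instead of
#: raising.
DEFAULT_D_BRACKET_TOL = 0.01

#: Gradient-strength unit conversion.
GAUSS_PER_CM_TO_T_PER_M = 0.01
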