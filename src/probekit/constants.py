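"""Physical constants and unit conversions used across the package.

All coordinates are Å, energies kJ/mol, densities nm⁻³; every conversion
lives here so no other module carries its own factor.
"""

#: Boltzmann constant in kJ·mol⁻¹·K⁻¹ (CODATA 2018, molar form R/1000).
KB_KJ_PER_MOL_K: float = 8.31446261815324e-3

#: 1 Hartree in kJ/mol.
HARTREE_KJ_PER_MOL: float = 2625.4996

#: 1 Å³ in nm³.
ANG3_TO_NM3: float = 1.0e-3

#: 1 Bohr in Å (CODATA 2018).
BOHR_ANG: float = 0.529177210903

#: Gaussian FWHM → standard deviation factor, 2·sqrt(2·ln 2).
FWHM_TO_SIGMA: float = 2.3548200450309493
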