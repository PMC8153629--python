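"""Physical constants used across the package (SI unless noted).

All constants live here so that resonance arithmetic, dose conversion and
the forward signal models agree on the same values.
"""

#: Planck constant (J*s), CODATA 2018 exact.
PLANCK_H = 6.62607015e-34

#: Bohr magneton (J/T), CODATA 2018.
BOHR_MAGNETON = 9.2740100783e-24

#: Avogadro constant (1/mol), exact.
AVOGADRO = 6.02214076e23

#: Proton gyromagnetic ratio (rad * s^-1 * T^-1).
GAMMA_PROTON = 2.6752218744e8

#: Molar mass of iron (g/mol).
FE_MOLAR_MASS = 55.845

#: Free-electron g-factor (reference value for ESR sanity checks).
G_FREE_ELECTRON = 2.00231930436
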