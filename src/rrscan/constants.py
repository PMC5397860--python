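"""Physical constants in the package's working units (Å, amu, ps, kcal/mol, K).

All numerical routines convert through this table; nothing else hard-codes a
constant.
"""

#: Boltzmann constant, kcal/mol/K (CODATA).
KB_KCAL_MOL_K = 1.9872041e-3

#: 1 kcal/mol expressed in amu·Å²/ps² (exact: 1 amu = 1 g/mol, so
#: 1 amu·Å²/ps² = 10 J/mol and 1 kcal/mol = 4184 J/mol).
KCAL_MOL_TO_AKMA = 418.4

#: Boltzmann constant, amu·Å²/ps²/K.
KB_AKMA = KB_KCAL_MOL_K * KCAL_MOL_TO_AKMA

#: Reduced Planck constant, kcal·ps/mol
#: (1.054571817e-34 J·s × N_A / 4184 J/kcal × 1e12 ps/s).
HBAR_KCAL_PS_MOL = 1.054571817e-34 * 6.02214076e23 / 4184.0 * 1e12

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0
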