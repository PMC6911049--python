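"""Physical constants shared package-wide.

Units convention: energies in kJ mol^-1, temperatures in kelvin,
concentrations in mol L^-1 (M). Every module imports the gas constant
from here so that no two definitions can drift apart.
"""

#: Gas constant, kJ mol^-1 K^-1 (CODATA 2018).
R_GAS: float = 8.314462618e-3

#: Reference temperature used by default for association/binding steps, K.
T_REF_DEFAULT: float = 298.0
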