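"""Physical constants used throughout the package.

All energies are expressed in units of kBT at the working temperature
(25 °C unless stated otherwise); forces in pN; lengths in nm.
"""

#: Boltzmann constant times 298.15 K, in pN·nm.
KBT_PN_NM = 4.114

#: kBT at 298.15 K in kcal/mol (R·T with R = 1.98720425e-3 kcal/mol/K).
KBT_KCAL_MOL = 0.5925

#: Working temperature, K.
T_REF = 298.15
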