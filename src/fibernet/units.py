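"""Unit conventions used throughout the package.

Internal unit system (chosen so typical quantities are O(1)-O(100)):

==============  ==========  =========================================
quantity        unit        conversion
==============  ==========  =========================================
length          µm
force           nN
energy          nN·µm       = 1e-15 J (femtojoule)
spring k        nN/µm       = 1e-3 N/m
stress/modulus  Pa          1 Pa = 1e-3 nN/µm² (conversion at the
                            module boundary; internal stresses are
                            nN/µm²)
density         mg/ml       1 mg/ml = 1e-15 g/µm³
==============  ==========  =========================================

Young's moduli are accepted in Pa in all public parameter objects and
converted internally.
"""

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Multiply a stress in Pa by this to get nN/µm².
PA_TO_NN_PER_UM2 = 1e-3

#: Multiply a stress in nN/µm² by this to get Pa.
NN_PER_UM2_TO_PA = 1e3

#: Multiply a mass density in mg/ml by this to get g/µm³.
MG_PER_ML_TO_G_PER_UM3 = 1e-15
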