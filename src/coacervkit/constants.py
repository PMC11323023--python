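"""Physical constants and default solvent parameters, centralized.

All values are CODATA-2018 SI unless noted. Modules must import constants
from here rather than redefining them, so that every stage of the pipeline
uses one consistent table.
"""

# Fundamental constants (SI)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23  # 1/mol

# Water / solvent defaults at 298.15 K
WATER_RELATIVE_PERMITTIVITY = 78.4
WATER_VISCOSITY = 8.9e-4  # Pa s
WATER_REFRACTIVE_INDEX = 1.33
ROOM_TEMPERATURE = 298.15  # K
KW = 1e-14  # water autoionization product at 25 degC, (mol/L)^2

# Common formulation partners (molar masses in g/mol)
ATP_DISODIUM_MOLAR_MASS = 551.14  # adenosine 5'-triphosphate disodium salt
ATP_FREE_ACID_MOLAR_MASS = 507.18

LN10 = 2.302585092994046
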