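"""Physical and energetic constants used throughout the package.

All gas volumes are expressed at STP (0 degC, 1 atm) unless stated
otherwise.  Energetic constants follow the standard indirect-calorimetry
conventions for monogastric animals; every value can be overridden
through :class:`calorpart.workbench.RunConfig`.
"""

#: Brouwer-type heat production equation, kJ per unit:
#: HP = 16.18*VO2 + 5.02*VCO2 - 2.17*VCH4 - 5.99*N_urine
#: (VO2/VCO2/VCH4 in L STP, urinary N in g, ammonia included).
BROUWER_O2 = 16.18
BROUWER_CO2 = 5.02
BROUWER_CH4 = 2.17
BROUWER_N = 5.99

#: Energy retained per gram of deposited protein / fat (kJ/g).
ENERGY_PER_G_PROTEIN = 23.6
ENERGY_PER_G_FAT = 39.7

#: Protein mass per gram of nitrogen (Kjeldahl factor).
PROTEIN_PER_G_N = 6.25

#: Energy content of methane, kJ per L STP.
CH4_ENERGY_KJ_PER_L = 39.5

#: Exponent of metabolic body size (kg BW ** METABOLIC_EXPONENT).
METABOLIC_EXPONENT = 0.60

#: STP reference conditions.
STP_TEMPERATURE_K = 273.15
STP_PRESSURE_ATM = 1.0

#: Default composition of ingoing (fresh) air as volumetric fractions.
INGOING_O2 = 0.2095
INGOING_CO2 = 0.0004
INGOING_N2 = 1.0 - INGOING_O2 - INGOING_CO2

#: Analyzer-to-chamber transport lag, seconds.
DEFAULT_LAG_S = 70.0

#: Native acquisition resolution, seconds.
TICK_S = 10.0
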