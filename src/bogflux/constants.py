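"""Physical constants and unit-conversion factors used across the package."""

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314

#: Molar mass of carbon, g mol-1.
M_C = 12.011

#: 0 degC in Kelvin.
KELVIN = 273.15

#: Mass ratio CO2 / C (integer molar masses; reproduces published balance tables).
CO2_PER_C = 44.0 / 12.0

#: Mass ratio CH4 / C (integer molar masses).
CH4_PER_C = 16.0 / 12.0

#: Conversion g m-2 -> t ha-1 (x 10^4 m2 ha-1 / 10^6 g t-1).
G_PER_M2_TO_T_PER_HA = 0.01

#: PAR quantum-to-energy conversion, umol photons per J (shortwave PAR band).
PAR_UMOL_PER_W = 4.57

#: 100-year global warming potential of CH4 (mass basis).
DEFAULT_GWP_CH4 = 27.0

#: Seconds in one half-hourly flux integration step.
SECONDS_PER_HALFHOUR = 1800.0

#: Default mean area of a single birch leaf, m2 (one summer leaf-scan campaign).
DEFAULT_MEAN_LEAF_AREA = 0.0012
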