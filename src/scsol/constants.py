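"""Physical constants and solvent (CO2) reference properties.

All quantities are SI: Pa, K, m^3/mol, J/mol. Bar appears only at I/O
boundaries (see :mod:`scsol.datasets`).
"""

from __future__ import annotations

#: Molar gas constant, J mol^-1 K^-1 (CODATA 2018).
R = 8.314462618

#: Molar mass of carbon dioxide, kg mol^-1.
M_CO2 = 44.01e-3

#: CO2 critical temperature, K.
TC_CO2 = 304.13
#: CO2 critical pressure, Pa.
PC_CO2 = 7.3773e6
#: CO2 critical molar volume, m^3 mol^-1.
VC_CO2 = 9.412e-5
#: CO2 acentric factor.
OMEGA_CO2 = 0.2239
#: CO2 critical compressibility, Pc*Vc/(R*Tc).
ZC_CO2 = PC_CO2 * VC_CO2 / (R * TC_CO2)

#: Pressure of one bar, Pa.
BAR = 1.0e5
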