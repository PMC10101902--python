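"""Unit conversion helpers.

Internally the package works in SI-adjacent electrochemical units: volts,
amperes, seconds, and the CGS-molar set (cm, cm^2, cm^2 s^-1, mol cm^-3)
conventional for diffusion problems.  Instrument-facing I/O speaks mV and
uA (macroscopic cells) or nA (micro cells), and concentrations are quoted
in uM; every conversion goes through the constants below so no factor is
ever typed twice.
"""

#: 1 uM expressed in mol cm^-3 (1e-6 mol L^-1 / 1000 cm^3 L^-1).
UM_TO_MOL_CM3 = 1e-9

#: 1 mol L^-1 expressed in mol cm^-3.
MOLAR_TO_MOL_CM3 = 1e-3

MV_TO_V = 1e-3
V_TO_MV = 1e3

UA_TO_A = 1e-6
A_TO_UA = 1e6

NA_TO_A = 1e-9
A_TO_NA = 1e9

PA_TO_A = 1e-12

UM_TO_M = 1e-6  # micromolar to mol/L
M_TO_UM = 1e6

MICRON_TO_CM = 1e-4
CM_TO_MICRON = 1e4

UL_TO_L = 1e-6
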