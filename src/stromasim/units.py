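"""Unit conversions between SI config inputs and internal pN-um-s units.

Internal unit system: force in pN, length in um, time in s.  Derived:
energy pN*um (= 1e-18 J), spring stiffness pN/um, viscosity pN*s/um^2
(numerically equal to Pa*s), stress/pressure pN/um^2 (numerically equal
to Pa).  All SI values from configuration files are converted once, at
the config boundary.
"""

#: N/m -> pN/um  (1 N/m = 1e12 pN / 1e6 um)
N_PER_M = 1.0e6

#: N*m (energy of an angular spring) -> pN*um  (1 J = 1e18 pN*um)
N_M = 1.0e18

#: Pa*s -> pN*s/um^2 (numerically identity)
PA_S = 1.0

#: Pa -> pN/um^2 (numerically identity)
PA = 1.0

#: thermal energy at 300 K in pN*um
KBT_300K = 4.11e-3
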