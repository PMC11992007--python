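"""Unit conversion constants.

All internal computation uses MeV for energy, cm for length, g/cm^3 for
density and protons/cm^2 for fluence.  Conversions to output units are
applied once, at the surface.
"""

#: 1 MeV/g expressed in gray (J/kg); CODATA elementary charge.
MEV_PER_G_TO_GY = 1.602176634e-10

#: 1 MeV/cm expressed in keV/um.
MEV_PER_CM_TO_KEV_PER_UM = 0.1

#: Unit tags used by DepthCurve.
UNIT_DOSE_MEV_G = "MeV/g"
UNIT_DOSE_GY = "Gy"
UNIT_LET = "keV/um"
UNIT_DIMENSIONLESS = "1"
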