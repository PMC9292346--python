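"""Physical constants (CODATA 2018) and the reference ion-cloud conditions.

All quantities are SI. The elementary charge is exact by definition of the SI;
the unified atomic mass unit carries the CODATA 2018 uncertainty, far below
any tolerance relevant to field evaluation.
"""

#: Elementary charge (C), exact.
ELEMENTARY_CHARGE = 1.602176634e-19

#: Unified atomic mass unit (kg), CODATA 2018.
ATOMIC_MASS_UNIT = 1.66053906660e-27

#: Reference magnetic field used throughout the comparative evaluation (T).
DEFAULT_B = 7.0

#: Reference mass-to-charge ratio (Da per elementary charge).
DEFAULT_M_OVER_Z = 500.0

#: Ion-cloud radius (m).
DEFAULT_R_CLOUD = 2e-3

#: Post-excitation cyclotron radius of the cloud centre (m).
DEFAULT_R_EXCITATION = 6e-3

#: Axial half-length of the cloud (m), 4 x cloud radius.
DEFAULT_Z_CLOUD = 8e-3
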