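"""Unit conventions and conversion factors.

All model-layer coordinates are in bohr (atomic units); densities in au
(e/bohr^3).  Presentation-layer exports convert to angstrom, since 3D
authoring tools assume human-scale units.
"""

#: CODATA 2018 Bohr radius in angstrom.
ANGSTROM_PER_BOHR = 0.529177210903
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM
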