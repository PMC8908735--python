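"""Unit conventions and conversions.

Internal coordinates and cutoffs are Å; the pulling CV and covered
distance are quoted in nm.  The toy dynamics engine works in a
GROMACS-like unit system (kJ/mol, nm, amu, ps) while the package-facing
time unit is ns.
"""

ANGSTROM_PER_NM = 10.0
PS_PER_NS = 1000.0

#: Boltzmann constant, kJ/(mol K)
KB = 0.008314462618

ROOM_TEMPERATURE = 300.0  # K


def ang_to_nm(x):
    return x / ANGSTROM_PER_NM


def nm_to_ang(x):
    return x * ANGSTROM_PER_NM
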