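"""Internal unit system and conversion constants.

The simulator works in a mixed micro/SI unit system chosen so that the
cell-scale parameter table can be used verbatim while float magnitudes stay
well away from under/overflow:

========  ==========================  =========================
quantity  internal unit               SI conversion
========  ==========================  =========================
length    micrometre (um)             1 um  = 1e-6 m
time      second (s)                  --
energy    joule (J)                   --
force     J/um                        1 J/um = 1e6 N
drag      J*s/um^2                    1 N*s/m = 1e-12 J*s/um^2
stiffness J/um^2                      1 N/m   = 1e-12 J/um^2
stress    pascal (Pa, at I/O only)    --
========  ==========================  =========================

Per-particle virial stress is kept in energy units (J), i.e. no division by a
per-particle volume.
"""

M_PER_UM = 1e-6
UM_PER_M = 1e6

#: multiply a force in newton to get the internal force unit (J/um)
FORCE_SI_TO_INT = 1e-6
#: multiply a drag coefficient in N*s/m to get J*s/um^2
DRAG_SI_TO_INT = 1e-12
#: multiply a stiffness in N/m to get J/um^2
STIFFNESS_SI_TO_INT = 1e-12

#: nanogram / picogram in kilograms (cytoplasmic particle mass unit flag)
KG_PER_NG = 1e-12
KG_PER_PG = 1e-15


def stress_pa_to_force_int(stress_pa: float, area_um2: float) -> float:
    """Total internal force (J/um) produced by a stress (Pa) over an area (um^2)."""
    force_si = stress_pa * area_um2 * M_PER_UM**2  # N
    return force_si * FORCE_SI_TO_INT
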