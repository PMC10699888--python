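"""Derive the pair-interaction constants of a coarse-grained cell and probe
the potential.

A 10 um cell of stiffness 5e-3 N/m is split into Np = 1000 particles; the
scaling relations give the equilibrium spacing d_eq, the pair stiffness and
the well depth u0 that preserve the cell-level rheology.
"""

import numpy as np

from semcell import CellModelParams, derive_pair_params, pair_force, \
    pair_potential_energy

params = CellModelParams()          # the reference parameter table
pp = derive_pair_params(1000, params)

print(f"d_eq  = {pp.d_eq:.3f} um   (equilibrium pair distance)")
print(f"kappa = {pp.kappa:.3e} N/m (pair stiffness)")
print(f"u0    = {pp.u0:.3e} J    (well depth)")
print(f"R_nuc = {pp.R_nuc:.3f} um  (nucleus radius, 10% of cell volume)")

for frac in (0.8, 1.0, 1.5, 2.5):
    d = frac * pp.d_eq
    V = pair_potential_energy(d, pp)
    F = pair_force(d, pp)
    print(f"d = {frac:>4} d_eq: V/u0 = {V / pp.u0:+.3f},  F = {F:+.2e} J/um "
          f"({'repulsive' if F > 0 else 'attractive' if F < 0 else 'zero'})")

# The minimum sits at d_eq with depth -u0; the force vanishes there and the
# interaction is truncated at 2.5 d_eq.
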