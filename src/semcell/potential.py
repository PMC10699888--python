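"""The intracellular pair potential and its force.

V(d) = u0 exp(2 rho (1 - d'^2/d_eq^2)) - alpha u0 exp(rho (1 - d'^2/d_eq^2))

where d' = d - shift for the pair class: shift = 0 for cytoplasm-cytoplasm,
shift = R_nuc - d_eq/2 for nucleus-cytoplasm.  The potential is truncated
(not shifted to zero) at d' = r_cut = 2.5 d_eq; the residual discontinuity
there is ~u0 * e^{-10.5} and is accepted.

For alpha = 2 the minimum sits at d' = d_eq with V = -u0.  The force is the
analytic -dV/dd, positive = repulsive.

Nucleus-nucleus pairs are not part of the model outside cell division; during
division the daughters' nuclei repel through the first (repulsive) term only,
with shift = 2 R_nuc - d_eq so the severity at equal surface gap matches the
cytoplasmic repulsion.  Request it with ``type_pair="nn"``.
"""

from __future__ import annotations

import numpy as np

from .params import DerivedPairParams, pair_shift

#: floor on the shifted distance so deep overlaps stay strongly repulsive
#: instead of flipping sign (d' <= 0 is geometrically meaningless)
MIN_GAP_FACTOR = 0.05


def _shifted(d, pp: DerivedPairParams, type_pair: str):
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("pair distance must be strictly positive")
    dp = d - pair_shift(pp, type_pair)
    return np.maximum(dp, MIN_GAP_FACTOR * pp.d_eq)


def pair_potential_energy(d, pp: DerivedPairParams, type_pair: str = "cc"):
    """Pair potential energy (J) at separation ``d`` (um; scalar or array)."""
    dp = _shifted(d, pp, type_pair)
    x = 1.0 - dp**2 / pp.d_eq**2
    e1 = np.exp(pp.rho * x)
    if type_pair == "nn":
        v = pp.u0 * e1 * e1
    else:
        v = pp.u0 * e1 * e1 - pp.alpha * pp.u0 * e1
    v = np.where(dp > pp.r_cut, 0.0, v)
    return v if v.shape else float(v)


def pair_force(d, pp: DerivedPairParams, type_pair: str = "cc"):
    """Signed force magnitude -dV/dd (J/um) along the separation axis.

    Positive pushes the particles apart.  Zero beyond the (shifted) cutoff.
    """
    dp = _shifted(d, pp, type_pair)
    x = 1.0 - dp**2 / pp.d_eq**2
    e1 = np.exp(pp.rho * x)
    pref = 2.0 * pp.rho * dp / pp.d_eq**2
    if type_pair == "nn":
        f = 2.0 * pref * pp.u0 * e1 * e1
    else:
        f = pref * pp.u0 * (2.0 * e1 * e1 - pp.alpha * e1)
    f = np.where(dp > pp.r_cut, 0.0, f)
    return f if f.shape else float(f)
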