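"""Active nuclear transport: a spring-like biasing force toward the cell centre.

The nucleus-to-cytoplasm-centroid offset Delta_nc would be closed in a single
step by a particle obeying Newton's law with acceleration a_n:

    Delta_nc = u_n dt + (1/2) a_n dt^2
    F_bias   = S m_nuc a_n = S m_nuc 2 (Delta_nc - u_n dt) / dt^2

with u_n the nucleus velocity of the previous step and S a dimensionless
elastic scaling constant (S = 0 disables the bias).  The force acts on the
nuclear particle only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .params import DerivedPairParams
from .state import ParticleState, NUCLEUS


@dataclass
class BiasSpec:
    """Nuclear biasing configuration.

    ``mode`` is "none" or "com_spring"; ``cells`` restricts applicability
    (None = every cell that has a nucleus).
    """

    S: float = 0.0
    mode: str = "com_spring"
    cells: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("S must be >= 0")
        if self.mode not in ("none", "com_spring"):
            raise ValueError(f"unknown bias mode {self.mode!r}")

    @property
    def active(self) -> bool:
        return self.mode == "com_spring" and self.S > 0


def delta_nc(state: ParticleState, cell: int) -> np.ndarray:
    """Vector (um) from the cell's nucleus to its cytoplasmic centroid."""
    nuc = state.nucleus_index(cell)
    if nuc is None:
        raise ValueError(f"cell {cell} has no nucleus")
    cyto = state.cell_members(cell, cytoplasm_only=True)
    if len(cyto) == 0:
        raise ValueError(f"cell {cell} has no cytoplasmic particles")
    return state.positions[cyto].mean(axis=0) - state.positions[nuc]


def nuclear_bias_force(state: ParticleState, bias: BiasSpec,
                       pp: DerivedPairParams, dt: float) -> np.ndarray:
    """Biasing force (J/um) per particle; nonzero only on nuclei.

    Raises if ``dt <= 0`` or if an applicable cell lacks a nucleus.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    forces = np.zeros((state.n, 3))
    if not bias.active:
        return forces
    cells = bias.cells
    if cells is None:
        cells = np.unique(state.cell_id[state.type_id == NUCLEUS])
    for cell in cells:
        nuc = state.nucleus_index(int(cell))
        if nuc is None:
            raise ValueError(f"bias requested for cell {cell} without a nucleus")
        dvec = delta_nc(state, int(cell))                     # um
        u_n = state.velocities[nuc]                           # um/s
        # Newtonian form in SI, converted to the internal force unit (J/um)
        f_si = bias.S * pp.m_nuc_kg * 2.0 * (dvec - u_n * dt) * units.M_PER_UM / dt**2
        forces[nuc] = f_si * units.FORCE_SI_TO_INT
    return forces
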