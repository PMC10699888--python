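"""Geometric constraints: 9-3 walls, cylindrical indenter, fixed/loaded slabs.

Walls use the integrated Lennard-Jones 9-3 form

    V(z) = eps * [ (2/15) (s/z)^9 - (s/z)^3 ],   z = distance to the plane,

which is mildly adhesive with its minimum at z = (2/5)^(1/6) s; it models the
adhesion of the cell to the fixed and movable plates of a creep experiment.
The cylindrical constraint is a one-sided inward harmonic force beyond its
radius (an indenter).  Slabs are thin particle layers: the bottom slab is
velocity-fixed, the top slab shares a total external load equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state import ParticleState

#: location of the 9-3 potential minimum, in units of sigma
WALL_EQ_FACTOR = (2.0 / 5.0) ** (1.0 / 6.0)


@dataclass
class Wall93:
    """Planar 9-3 wall normal to ``axis`` at ``position``.

    ``side=+1`` keeps particles above the plane (wall below them), ``side=-1``
    keeps them below.  ``epsilon`` in J, ``sigma``/``cutoff`` in um.  A wall
    with ``track_indices`` set is a movable plate: each step its position is
    re-set to ``mean(coordinate of tracked particles) + track_offset``.
    """

    position: float
    side: int = 1
    epsilon: float = 1e-17
    sigma: float = 1.8
    cutoff: float | None = None
    axis: int = 2
    track_indices: np.ndarray | None = None
    track_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.cutoff is None:
            self.cutoff = 2.5 * self.sigma
        if self.cutoff <= 0 or self.sigma <= 0:
            raise ValueError("wall sigma and cutoff (range) must be positive")
        if self.side not in (-1, 1):
            raise ValueError("wall side must be +1 or -1")

    @property
    def z_eq(self) -> float:
        """Distance from the plane where the wall force vanishes (um)."""
        return WALL_EQ_FACTOR * self.sigma

    def update_position(self, state: ParticleState) -> None:
        if self.track_indices is not None and len(self.track_indices):
            coords = state.positions[self.track_indices, self.axis]
            self.position = float(coords.mean()) + self.track_offset

    def force(self, positions: np.ndarray) -> np.ndarray:
        """Per-particle force along ``axis`` (J/um), signed."""
        return _wall_force(self, positions)


def _wall93_force_scalar(eps, sigma, z):
    # V = eps[(2/15)(s/z)^9 - (s/z)^3];  -dV/dz = eps[(6/5) s^9 z^-10 - 3 s^3 z^-4]
    return eps * ((6.0 / 5.0) * sigma**9 / z**10 - 3.0 * sigma**3 / z**4)


@dataclass
class CylinderConstraint:
    """One-sided harmonic shell around ``axis`` (default z): inward force
    ``stiffness * (r - radius)`` for radial distance r beyond ``radius``."""

    radius: float
    stiffness: float      # J/um^2
    axis: int = 2
    center: tuple[float, float] = (0.0, 0.0)

    def force(self, positions: np.ndarray) -> np.ndarray:
        others = [a for a in range(3) if a != self.axis]
        rel = positions[:, others] - np.asarray(self.center)
        r = np.linalg.norm(rel, axis=1)
        out = np.zeros_like(positions)
        beyond = r > self.radius
        if beyond.any():
            unit = rel[beyond] / r[beyond, None]
            # saturate at 0.5 um of overlap so stray initial particles are
            # pushed back stably instead of catapulted
            mag = self.stiffness * np.minimum(r[beyond] - self.radius, 0.5)
            out[np.ix_(beyond, others)] = -mag[:, None] * unit
        return out


@dataclass
class ConstraintSet:
    """Walls + optional cylinder + fixed/loaded slab selections.

    ``fixed_indices`` are velocity-zeroed; each particle of ``loaded_indices``
    receives ``F_ext / N_slab`` along ``load_axis`` (F_ext in J/um, the
    internal force unit).
    """

    walls: list[Wall93] = field(default_factory=list)
    cylinder: CylinderConstraint | None = None
    fixed_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    loaded_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    F_ext: float = 0.0
    load_axis: int = 2

    def __post_init__(self) -> None:
        self.fixed_indices = np.asarray(self.fixed_indices, dtype=np.int64)
        self.loaded_indices = np.asarray(self.loaded_indices, dtype=np.int64)
        if np.intersect1d(self.fixed_indices, self.loaded_indices).size:
            raise ValueError("fixed and loaded slab selections must be disjoint")


class LoadWithoutSlabError(RuntimeError):
    """External force requested but the loaded slab is empty."""


def apply_constraints(state: ParticleState, constraints: ConstraintSet
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Constraint force per particle (J/um) and the velocity-fixed mask."""
    forces = np.zeros((state.n, 3))
    for wall in constraints.walls:
        wall.update_position(state)
        forces[:, wall.axis] += _wall_force(wall, state.positions)
    if constraints.cylinder is not None:
        forces += constraints.cylinder.force(state.positions)
    if constraints.F_ext != 0.0:
        n_slab = len(constraints.loaded_indices)
        if n_slab == 0:
            raise LoadWithoutSlabError("F_ext != 0 but the loaded slab is empty")
        forces[constraints.loaded_indices, constraints.load_axis] += (
            constraints.F_ext / n_slab)
    fixed = np.zeros(state.n, dtype=bool)
    fixed[constraints.fixed_indices] = True
    return forces, fixed


def _wall_force(wall: Wall93, positions: np.ndarray) -> np.ndarray:
    z = wall.side * (positions[:, wall.axis] - wall.position)
    # saturate the repulsion for particles that start on/behind the plane so
    # bad initial packings relax instead of exploding
    z = np.maximum(z, 0.7 * wall.sigma)
    f = np.zeros(len(positions))
    within = z <= wall.cutoff
    zi = z[within]
    f[within] = _wall93_force_scalar(wall.epsilon, wall.sigma, zi)
    return wall.side * f


def select_slab(positions: np.ndarray, axis: int, lo: float, hi: float) -> np.ndarray:
    """Indices of particles whose ``axis`` coordinate lies in [lo, hi]."""
    coord = positions[:, axis]
    return np.flatnonzero((coord >= lo) & (coord <= hi))
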