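"""Discrete biological events layered on the particle dynamics.

Migration is polarity-induced: a cytoplasmic particle is inserted near the
leading edge and the particle with the smallest projection onto the polarity
axis (trailing edge) is removed, so the ensemble translocates while the pair
forces restore rheology in between events.  Growth adds particles without
removal; when a cell's cytoplasmic count doubles to 2 Np_ref the nucleus is
duplicated and every cytoplasmic particle is reassigned to the nearest
nucleus, splitting the mother at its centre.

Event statistics: per step both migration and growth draw
Poisson(dt * Np / T) events, i.e. rates proportional to the (current)
particle count and inversely proportional to the time scale T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import DerivedPairParams
from .state import ParticleState, CYTOPLASM, NUCLEUS


@dataclass
class BehaviorSchedule:
    """Event configuration consulted by the engine every step.

    ``T_m``/``T_p`` in seconds (None disables migration/growth); smaller
    values mean faster migration / proliferation.  ``use_current_np`` selects
    whether event rates follow the growing particle count (exponential
    growth, doubling at T_p ln 2) or the fixed reference count.
    """

    T_m: float | None = None
    T_p: float | None = None
    Np_ref: int = 1000
    Np_min: int = 10
    polarity_mode: str = "fixed_direction"
    polarity_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    persistence: float = 10.0       # 1/persistence = angular step std (rad)
    cells: tuple[int, ...] | None = None
    use_current_np: bool = True
    division_offset_factor: float = 0.1   # new nucleus offset, units of d_eq
    _polarity_state: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.T_m is not None and self.T_m <= 0:
            raise ValueError("T_m must be positive")
        if self.T_p is not None and self.T_p <= 0:
            raise ValueError("T_p must be positive")
        if self.polarity_mode not in ("fixed_direction", "persistent_random"):
            raise ValueError(f"unknown polarity mode {self.polarity_mode!r}")

    # -- engine hook ----------------------------------------------------
    def apply(self, sim) -> bool:
        """Run this step's events on ``sim`` (a Simulation). True if the
        particle set changed."""
        state, pp, rng, dt = sim.state, sim.pp, sim.rng, sim.dt
        changed = False
        cells = self.cells if self.cells is not None else [int(c) for c in state.cells()]
        for cell in cells:
            np_cell = len(state.cell_members(cell, cytoplasm_only=True))
            rate_np = np_cell if self.use_current_np else self.Np_ref
            if self.T_m is not None:
                for _ in range(schedule_events(rate_np, self.T_m, dt, rng)):
                    pol = self.polarity(state, cell, rng)
                    if migration_event(state, cell, pol, pp, rng,
                                       Np_min=self.Np_min, dt=dt) is not None:
                        changed = True
                        sim.events.append({
                            "time": state.time, "event_type": "migration",
                            "cell_id": cell})
            if self.T_p is not None:
                for _ in range(schedule_events(rate_np, self.T_p, dt, rng)):
                    growth_event(state, cell, pp, rng, dt=dt)
                    changed = True
                    sim.events.append({
                        "time": state.time, "event_type": "growth", "cell_id": cell})
                    if len(state.cell_members(cell, cytoplasm_only=True)) >= 2 * self.Np_ref:
                        ev = divide_cell(state, cell, pp, rng,
                                         offset=self.division_offset_factor * pp.d_eq)
                        changed = True
                        sim.events.append({
                            "time": state.time, "event_type": "division",
                            "cell_id": cell, "daughter": ev.daughter_cell})
                        break
        return changed

    def polarity(self, state: ParticleState, cell: int,
                 rng: np.random.Generator) -> np.ndarray:
        prev = self._polarity_state.get(cell)
        pol = cell_polarity(state, cell, self.polarity_mode, rng,
                            axis=self.polarity_axis, prev=prev,
                            persistence=self.persistence)
        self._polarity_state[cell] = pol
        return pol


def cell_polarity(state: ParticleState, cell: int, mode: str,
                  rng: np.random.Generator,
                  axis=(1.0, 0.0, 0.0), prev: np.ndarray | None = None,
                  persistence: float = 10.0) -> np.ndarray:
    """Unit polarity vector of a cell.

    ``fixed_direction`` returns the configured axis.  ``persistent_random``
    rotates the previous polarity by a random angle of standard deviation
    1/persistence radians about a random perpendicular axis (infinite
    persistence keeps the vector constant).
    """
    members = state.cell_members(cell)
    if len(members) < 4:
        raise ValueError(f"cell {cell} has fewer than 4 particles")
    pos = state.positions[members]
    if np.allclose(pos.std(axis=0), 0.0):
        raise ValueError(f"cell {cell} is degenerate (all particles coincident)")
    if mode == "fixed_direction":
        v = np.asarray(axis, dtype=float)
        return v / np.linalg.norm(v)
    if prev is None:
        v = np.asarray(axis, dtype=float)
        prev = v / np.linalg.norm(v)
    if persistence <= 0:
        raise ValueError("persistence must be positive")
    if not np.isfinite(persistence):
        return prev
    sigma = 1.0 / persistence
    # random unit axis perpendicular to prev
    raw = rng.standard_normal(3)
    perp = raw - np.dot(raw, prev) * prev
    nrm = np.linalg.norm(perp)
    if nrm < 1e-12:
        return prev
    perp /= nrm
    angle = rng.normal(0.0, sigma)
    return prev * np.cos(angle) + perp * np.sin(angle)


def schedule_events(Np: int, T: float, dt: float,
                    rng: np.random.Generator) -> int:
    """Number of events this step: Poisson with per-step rate dt * Np / T."""
    if T is None or not np.isfinite(T):
        return 0
    return int(rng.poisson(dt * Np / T))


def _relax_new_particle(state: ParticleState, index: int, pp: DerivedPairParams,
                        n_steps: int = 5, dt: float = 1e-3) -> None:
    """Noise-free local relaxation of a freshly inserted particle: only the
    new particle moves, against its neighbors within the cutoff."""
    from .potential import pair_force
    for _ in range(n_steps):
        rel = state.positions[index] - state.positions
        d = np.linalg.norm(rel, axis=1)
        d[index] = np.inf
        near = np.flatnonzero(d <= pp.r_cut + pp.shift_nuc)
        if not len(near):
            return
        force = np.zeros(3)
        for tp, mask in (("cc", state.type_id[near] == CYTOPLASM),
                         ("nc", state.type_id[near] == NUCLEUS)):
            sel = near[mask]
            if len(sel):
                f = np.atleast_1d(pair_force(d[sel], pp, tp))
                force += ((f / d[sel])[:, None] * rel[sel]).sum(axis=0)
        step = (dt / pp.eta_int) * force
        mag = np.linalg.norm(step)
        if mag > 0.25 * pp.d_eq:       # clamp: relaxation must stay local
            step *= 0.25 * pp.d_eq / mag
        state.positions[index] += step


def _leading_edge_position(state: ParticleState, cell: int, polarity: np.ndarray,
                           pp: DerivedPairParams, rng: np.random.Generator) -> np.ndarray:
    cyto = state.cell_members(cell, cytoplasm_only=True)
    pos = state.positions[cyto]
    centroid = pos.mean(axis=0)
    proj = (pos - centroid) @ polarity
    p_max = proj.max()
    raw = rng.standard_normal(3)
    tang = raw - np.dot(raw, polarity) * polarity
    nrm = np.linalg.norm(tang)
    tang = tang / nrm if nrm > 1e-12 else np.zeros(3)
    return centroid + polarity * (0.9 * p_max) + 0.3 * pp.d_eq * tang


def migration_event(state: ParticleState, cell: int, polarity: np.ndarray,
                    pp: DerivedPairParams, rng: np.random.Generator,
                    Np_min: int = 10, dt: float = 1e-3) -> int | None:
    """One leading-edge insertion + trailing-edge removal.

    Conserves the cell's cytoplasmic count; never removes the nucleus.
    Returns the new particle id, or None if the cell is at Np_min (event
    skipped).
    """
    cyto = state.cell_members(cell, cytoplasm_only=True)
    if len(cyto) <= Np_min:
        return None
    new_pos = _leading_edge_position(state, cell, polarity, pp, rng)
    pid = state.add_particle(new_pos, CYTOPLASM, cell)
    _relax_new_particle(state, state.n - 1, pp, n_steps=5, dt=dt)
    # trailing edge: minimal projection onto polarity (among original members)
    pos = state.positions[cyto]
    proj = pos @ polarity
    victim = cyto[int(np.argmin(proj))]
    state.remove_particle(int(victim))
    return pid


def growth_event(state: ParticleState, cell: int, pp: DerivedPairParams,
                 rng: np.random.Generator, dt: float = 1e-3) -> int:
    """Insert one cytoplasmic particle in a random direction from the cell
    centroid, nestled below the local surface.

    The insertion point lies between the centroid and the outermost particle
    within a cone around the random direction; the local noise-free
    relaxation then opens a pocket for it.  Inserting interstitially (rather
    than stacked onto the surface tip) keeps repeated growth compact --
    tip-stacking makes every protrusion the preferred anchor for later
    insertions and grows dendrites.
    """
    cyto = state.cell_members(cell, cytoplasm_only=True)
    pos = state.positions[cyto]
    centroid = pos.mean(axis=0)
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    rel = pos - centroid
    r = np.linalg.norm(rel, axis=1)
    r = np.maximum(r, 1e-9)
    in_cone = (rel @ u) / r >= 0.7
    anchor_r = r[in_cone].max() if in_cone.any() else r.max()
    raw = rng.standard_normal(3)
    tang = raw - np.dot(raw, u) * u
    nrm = np.linalg.norm(tang)
    tang = tang / nrm if nrm > 1e-12 else np.zeros(3)
    new_pos = centroid + u * 0.6 * anchor_r + 0.3 * pp.d_eq * tang
    pid = state.add_particle(new_pos, CYTOPLASM, cell)
    _relax_new_particle(state, state.n - 1, pp, n_steps=8, dt=dt)
    return pid


@dataclass
class DivisionEvent:
    """Record of one nucleus duplication and cell split."""

    mother_cell: int
    daughter_cell: int
    nucleus_positions: np.ndarray     # (2, 3) at split
    assignment: dict                  # particle_id -> cell_id


class DivisionError(RuntimeError):
    pass


def divide_cell(state: ParticleState, cell: int, pp: DerivedPairParams,
                rng: np.random.Generator, offset: float | None = None,
                min_count: int | None = None) -> DivisionEvent:
    """Duplicate the nucleus and split the mother cell at its centre.

    The second nucleus appears at the first nucleus's position plus a small
    random offset (default 0.1 d_eq) and receives a fresh cell id; every
    cytoplasmic particle is reassigned to the cell of its nearest nucleus.
    The two nuclei then interact through the mild shifted repulsion while the
    per-cell biasing force re-centres each daughter's nucleus.

    Retries the random offset up to 10 times if a daughter would be empty.
    """
    nuc = state.nucleus_index(cell)
    if nuc is None:
        raise DivisionError(f"cell {cell} has no nucleus to duplicate")
    cyto = state.cell_members(cell, cytoplasm_only=True)
    if min_count is None:
        min_count = 2  # structural floor; the 2*Np_ref trigger is checked by the caller
    if len(cyto) < min_count:
        raise DivisionError(
            f"cell {cell} has {len(cyto)} cytoplasmic particles, fewer than {min_count}")
    if offset is None:
        offset = 0.1 * pp.d_eq

    daughter = int(state.cell_id.max()) + 1
    for attempt in range(10):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        new_nuc_pos = state.positions[nuc] + offset * direction
        d_old = np.linalg.norm(state.positions[cyto] - state.positions[nuc], axis=1)
        d_new = np.linalg.norm(state.positions[cyto] - new_nuc_pos, axis=1)
        to_new = d_new < d_old
        if to_new.any() and (~to_new).any():
            state.add_particle(new_nuc_pos, NUCLEUS, daughter)
            moved = cyto[to_new]
            state.cell_id[moved] = daughter
            assignment = {int(state.particle_id[k]): daughter for k in moved}
            assignment.update({int(state.particle_id[k]): cell for k in cyto[~to_new]})
            return DivisionEvent(
                mother_cell=cell, daughter_cell=daughter,
                nucleus_positions=np.vstack([state.positions[nuc], new_nuc_pos]),
                assignment=assignment)
    raise DivisionError(
        f"division of cell {cell} failed: a daughter was empty after 10 offset draws")
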