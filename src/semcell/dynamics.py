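"""Overdamped Brownian time stepping and the simulation driver.

Each free particle moves by

    dx = (dt / eta) (F_pair + F_bias + F_constraint + F_ext) + noise

with per-component Gaussian noise of standard deviation sqrt(2 a dt / eta),
where ``a`` is a temperature-like amplitude in energy units.  Velocities are
previous-step finite differences (zero at t=0), which is what the nuclear
biasing force consumes.  Velocity-fixed (bottom-slab) particles do not move.

The model never states a physical temperature; the scenario default sets
``a`` to a fixed fraction (0.069) of the pair well depth u0, which equals a
per-step RMS displacement of 2 % of d_eq for the reference 1000-particle
cell at dt = 1 ms and keeps the thermal state consistent across particle
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .bias import BiasSpec, nuclear_bias_force
from .constraints import ConstraintSet, apply_constraints
from .forces import PairForceRecord, compute_pair_forces, total_potential_energy
from .neighbors import NeighborList
from .params import DerivedPairParams
from .state import ParticleState, NUCLEUS


class UnstableTimestepError(RuntimeError):
    """A particle moved more than d_eq in a single step."""


@dataclass
class NoiseModel:
    """Thermal fluctuation amplitude (J) plus the RNG seed for the run."""

    amplitude: float      # temperature-like energy, J; 0 disables noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")

    @classmethod
    def from_step_fraction(cls, pp: DerivedPairParams, dt: float,
                           fraction: float = 0.02, seed: int = 0) -> "NoiseModel":
        """Amplitude giving a per-step RMS displacement of ``fraction * d_eq``
        per component for a cytoplasmic particle at timestep ``dt``."""
        rms = fraction * pp.d_eq
        amplitude = rms**2 * pp.eta_int / (2.0 * dt)
        return cls(amplitude=amplitude, seed=seed)

    @classmethod
    def from_well_fraction(cls, pp: DerivedPairParams, ratio: float = 0.069,
                           seed: int = 0) -> "NoiseModel":
        """Amplitude as a fixed fraction of the pair well depth u0.

        The default 0.069 equals the 2%%-of-d_eq-per-step displacement rule
        at the Np = 1000 reference (dt = 1 ms); tying the amplitude to u0
        instead of to d_eq keeps the thermal state (a/u0) identical across
        particle counts, which particle-number invariance requires."""
        return cls(amplitude=ratio * pp.u0, seed=seed)


def eta_per_particle(state: ParticleState, pp: DerivedPairParams) -> np.ndarray:
    """Per-particle drag in internal units (J*s/um^2)."""
    eta = np.full(state.n, pp.eta_int)
    eta[state.type_id == NUCLEUS] = pp.eta_nuc_int
    return eta


def brownian_step(state: ParticleState, forces: np.ndarray, pp: DerivedPairParams,
                  noise: NoiseModel, dt: float, rng: np.random.Generator,
                  fixed_mask: np.ndarray | None = None,
                  eta: np.ndarray | None = None) -> ParticleState:
    """Advance ``state`` in place by one overdamped step; returns it.

    Raises :class:`UnstableTimestepError` if any displacement exceeds d_eq.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if eta is None:
        eta = eta_per_particle(state, pp)
    disp = (dt / eta)[:, None] * forces
    if noise.amplitude > 0:
        std = np.sqrt(2.0 * noise.amplitude * dt / eta)
        disp += std[:, None] * rng.standard_normal((state.n, 3))
    if fixed_mask is not None:
        disp[fixed_mask] = 0.0
    mag = np.linalg.norm(disp, axis=1)
    worst = int(np.argmax(mag))
    if mag[worst] > pp.d_eq:
        raise UnstableTimestepError(
            f"particle {int(state.particle_id[worst])} moved {mag[worst]:.3g} um "
            f"(> d_eq = {pp.d_eq:.3g} um) in one step at t = {state.time:.4g} s")
    state.positions += disp
    state.velocities = disp / dt
    state.time += dt
    return state


@dataclass
class Frame:
    """One stored trajectory frame (positions are copies)."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    type_id: np.ndarray
    cell_id: np.ndarray
    particle_id: np.ndarray
    pair_record: PairForceRecord | None = None

    @classmethod
    def capture(cls, state: ParticleState, pair_record=None) -> "Frame":
        return cls(time=state.time, positions=state.positions.copy(),
                   velocities=state.velocities.copy(), type_id=state.type_id.copy(),
                   cell_id=state.cell_id.copy(), particle_id=state.particle_id.copy(),
                   pair_record=pair_record)


@dataclass
class Trajectory:
    """Time-stamped frame sequence plus the discrete-event log."""

    frames: list[Frame] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    seed: int | None = None

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)


class Simulation:
    """Owns the state, force evaluation, constraints, bias and behaviors.

    Deterministic: one counter-based RNG stream derived from ``noise.seed``
    drives thermal noise and all discrete events.
    """

    def __init__(self, state: ParticleState, pp: DerivedPairParams,
                 constraints: ConstraintSet | None = None,
                 bias: BiasSpec | None = None,
                 noise: NoiseModel | None = None,
                 behaviors=None,
                 dt: float = 1e-3,
                 skin: float = 0.9):
        self.state = state
        self.pp = pp
        self.constraints = constraints
        self.bias = bias if bias is not None else BiasSpec(S=0.0, mode="none")
        self.noise = noise if noise is not None else NoiseModel(0.0, seed=0)
        self.behaviors = behaviors
        self.dt = float(dt)
        self.nlist = NeighborList(pp, skin=skin)
        self.rng = np.random.default_rng(self.noise.seed)
        self.events: list[dict] = []
        self.last_pair_record: PairForceRecord | None = None
        self._forces = np.zeros((state.n, 3))
        self._eta = eta_per_particle(state, self.pp)

    def _buffers(self) -> tuple[np.ndarray, np.ndarray]:
        if len(self._forces) != self.state.n:
            self._forces = np.zeros((self.state.n, 3))
            self._eta = eta_per_particle(self.state, self.pp)
        else:
            self._forces[:] = 0.0
        return self._forces, self._eta

    # -- force assembly -------------------------------------------------
    def compute_forces(self) -> tuple[np.ndarray, np.ndarray]:
        """Total force per particle (J/um) and the velocity-fixed mask."""
        from .forces import compute_pair_forces_into
        table = self.nlist.pairs(self.state)
        forces, _ = self._buffers()
        compute_pair_forces_into(self.state, self.pp, table, forces)
        fixed = None
        if self.constraints is not None:
            cforces, fixed = apply_constraints(self.state, self.constraints)
            forces += cforces
        if fixed is None:
            fixed = np.zeros(self.state.n, dtype=bool)
        if self.bias.active:
            forces += nuclear_bias_force(self.state, self.bias, self.pp, self.dt)
        return forces, fixed

    def potential_energy(self) -> float:
        table = self.nlist.pairs(self.state)
        return total_potential_energy(self.state, self.pp, table)

    # -- stepping --------------------------------------------------------
    def step(self) -> None:
        forces, fixed = self.compute_forces()
        brownian_step(self.state, forces, self.pp, self.noise, self.dt,
                      self.rng, fixed_mask=fixed, eta=self._eta)
        if self.behaviors is not None:
            changed = self.behaviors.apply(self)
            if changed:
                # particle arrays were resized/reordered: all cached
                # per-particle data is stale
                self.nlist.invalidate()
                self._forces = np.zeros((self.state.n, 3))
                self._eta = eta_per_particle(self.state, self.pp)

    def run(self, n_steps: int,
            frame_stride: int | None = None,
            observers: Sequence[Callable[["Simulation"], None]] = (),
            record_pairs: bool = False) -> Trajectory:
        """Advance ``n_steps``; capture every ``frame_stride`` steps (and the
        initial and final states).  ``record_pairs`` attaches per-pair force
        records to captured frames (needed for virial stress)."""
        traj = Trajectory(seed=self.noise.seed)
        traj.frames.append(Frame.capture(self.state, self._fresh_record() if record_pairs else None))
        for obs in observers:
            obs(self)
        for k in range(1, n_steps + 1):
            self.step()
            if (frame_stride and k % frame_stride == 0) or k == n_steps:
                rec = self._fresh_record() if record_pairs else None
                traj.frames.append(Frame.capture(self.state, rec))
                for obs in observers:
                    obs(self)
        traj.events = list(self.events)
        return traj

    def _fresh_record(self) -> PairForceRecord:
        table = self.nlist.pairs(self.state)
        _, record = compute_pair_forces(self.state, self.pp, table)
        return record


def run_simulation(state: ParticleState, pp: DerivedPairParams, n_steps: int,
                   observers: Sequence[Callable[[Simulation], None]] = (),
                   **kwargs) -> Trajectory:
    """Convenience wrapper: build a :class:`Simulation` and run it."""
    frame_stride = kwargs.pop("frame_stride", None)
    record_pairs = kwargs.pop("record_pairs", False)
    sim = Simulation(state, pp, **kwargs)
    return sim.run(n_steps, frame_stride=frame_stride, observers=observers,
                   record_pairs=record_pairs)
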