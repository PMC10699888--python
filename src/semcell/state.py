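"""The evolving world state: positions, velocities, types, cell membership."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CYTOPLASM = 0
NUCLEUS = 1


@dataclass
class ParticleState:
    """All particles of all cells at one instant.

    positions/velocities in um and um/s; ``velocities`` is the previous-step
    finite difference (all-zero at t=0).  ``particle_id`` values are stable
    and never reused within a run; ``next_id`` tracks the allocator.
    """

    positions: np.ndarray                 # (N, 3) float64, um
    velocities: np.ndarray                # (N, 3) float64, um/s
    type_id: np.ndarray                   # (N,) int8: 0 cytoplasm, 1 nucleus
    cell_id: np.ndarray                   # (N,) int32
    particle_id: np.ndarray               # (N,) int64, unique
    time: float = 0.0
    next_id: int = field(default=-1)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.type_id = np.asarray(self.type_id, dtype=np.int8)
        self.cell_id = np.asarray(self.cell_id, dtype=np.int32)
        self.particle_id = np.asarray(self.particle_id, dtype=np.int64)
        if self.next_id < 0:
            self.next_id = int(self.particle_id.max(initial=-1)) + 1
        self.validate()

    @classmethod
    def from_positions(cls, positions, type_id=None, cell_id=None, time=0.0):
        positions = np.asarray(positions, dtype=float)
        n = len(positions)
        return cls(
            positions=positions,
            velocities=np.zeros_like(positions),
            type_id=np.zeros(n, dtype=np.int8) if type_id is None else type_id,
            cell_id=np.zeros(n, dtype=np.int32) if cell_id is None else cell_id,
            particle_id=np.arange(n, dtype=np.int64),
            time=time,
        )

    @property
    def n(self) -> int:
        return len(self.positions)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite particle coordinates")
        ids, counts = np.unique(self.particle_id, return_counts=True)
        if np.any(counts > 1):
            raise ValueError(f"duplicate particle ids: {ids[counts > 1][:5]}")
        nuc = self.type_id == NUCLEUS
        if nuc.any():
            cells, counts = np.unique(self.cell_id[nuc], return_counts=True)
            if np.any(counts > 1):
                raise ValueError(f"more than one nucleus in cell(s) {cells[counts > 1]}")

    def cells(self) -> np.ndarray:
        return np.unique(self.cell_id)

    def cell_members(self, cell: int, cytoplasm_only: bool = False) -> np.ndarray:
        mask = self.cell_id == cell
        if cytoplasm_only:
            mask &= self.type_id == CYTOPLASM
        return np.flatnonzero(mask)

    def nucleus_index(self, cell: int) -> int | None:
        idx = np.flatnonzero((self.cell_id == cell) & (self.type_id == NUCLEUS))
        return int(idx[0]) if len(idx) else None

    def add_particle(self, position, type_id: int, cell: int, velocity=None) -> int:
        """Append one particle; returns its (fresh, never reused) particle id."""
        pid = self.next_id
        self.next_id += 1
        self.positions = np.vstack([self.positions, np.asarray(position, float)])
        v = np.zeros(3) if velocity is None else np.asarray(velocity, float)
        self.velocities = np.vstack([self.velocities, v])
        self.type_id = np.append(self.type_id, np.int8(type_id))
        self.cell_id = np.append(self.cell_id, np.int32(cell))
        self.particle_id = np.append(self.particle_id, np.int64(pid))
        return pid

    def remove_particle(self, index: int) -> int:
        """Remove the particle at array ``index``; returns its particle id."""
        pid = int(self.particle_id[index])
        keep = np.ones(self.n, dtype=bool)
        keep[index] = False
        self.positions = self.positions[keep]
        self.velocities = self.velocities[keep]
        self.type_id = self.type_id[keep]
        self.cell_id = self.cell_id[keep]
        self.particle_id = self.particle_id[keep]
        return pid

    def copy(self) -> "ParticleState":
        return ParticleState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            type_id=self.type_id.copy(),
            cell_id=self.cell_id.copy(),
            particle_id=self.particle_id.copy(),
            time=self.time,
            next_id=self.next_id,
        )
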