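"""Pair-force aggregation with per-pair records for virial stress."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .neighbors import PairTable
from .params import DerivedPairParams
from .state import ParticleState


class CoincidentParticlesError(RuntimeError):
    """Two particles closer than the coincidence tolerance."""


@dataclass
class PairForceRecord:
    """Per-pair force data for one frame, as needed by the virial stress.

    ``f`` is the force on particle ``i`` from particle ``j`` (J/um); the force
    on ``j`` is ``-f``.  ``positions`` is a snapshot so the separation vectors
    can be recomputed exactly.
    """

    i: np.ndarray
    j: np.ndarray
    f: np.ndarray          # (P, 3)
    positions: np.ndarray  # (N, 3) snapshot


def _raise_coincident(state, table, bad):
    a, b = int(table.i[bad]), int(table.j[bad])
    raise CoincidentParticlesError(
        f"particles {int(state.particle_id[a])} and {int(state.particle_id[b])} "
        f"are coincident (d < {kernels.COINCIDENCE_TOL} um)")


def compute_pair_forces(state: ParticleState, pp: DerivedPairParams,
                        table: PairTable) -> tuple[np.ndarray, PairForceRecord]:
    """Net pair force per particle plus the per-pair record.

    Newton's third law holds pair-wise exactly (equal and opposite scatter).

    Raises
    ------
    CoincidentParticlesError
        If any candidate pair is closer than the coincidence tolerance.
    """
    forces = np.zeros((state.n, 3))
    fpair = np.empty((table.n_pairs, 3))
    bad = kernels.accumulate_pair_forces(
        state.positions, table.i, table.j, table.shift, table.rep_only,
        pp.u0, pp.rho, pp.alpha, pp.d_eq, pp.r_cut, forces, fpair)
    if bad >= 0:
        _raise_coincident(state, table, bad)
    record = PairForceRecord(i=table.i, j=table.j, f=fpair,
                             positions=state.positions.copy())
    return forces, record


def compute_pair_forces_into(state: ParticleState, pp: DerivedPairParams,
                             table: PairTable, forces: np.ndarray) -> None:
    """Accumulate net pair forces into a preallocated zeroed buffer, without
    building per-pair records (the per-step hot path)."""
    bad = kernels.accumulate_forces_only(
        state.positions, table.i, table.j, table.shift, table.rep_only,
        pp.u0, pp.rho, pp.alpha, pp.d_eq, pp.r_cut, forces)
    if bad >= 0:
        _raise_coincident(state, table, bad)


def total_potential_energy(state: ParticleState, pp: DerivedPairParams,
                           table: PairTable) -> float:
    return float(kernels.total_pair_energy(
        state.positions, table.i, table.j, table.shift, table.rep_only,
        pp.u0, pp.rho, pp.alpha, pp.d_eq, pp.r_cut))
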