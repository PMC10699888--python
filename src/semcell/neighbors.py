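"""Verlet-style neighbor list over a k-d tree.

Candidate pairs are collected within ``r_cut + skin``; the list is rebuilt
once any particle has moved more than ``skin/2`` since the last build, which
guarantees no true pair within ``r_cut`` is ever missed between rebuilds.

Nucleus pairs use larger (shifted) cutoffs and there are few nuclei, so
nucleus-cytoplasm and nucleus-nucleus candidates are enumerated directly
against all particles of the relevant type instead of through the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .params import DerivedPairParams
from .state import ParticleState, CYTOPLASM, NUCLEUS


@dataclass
class PairTable:
    """Flat candidate-pair arrays consumed by the force kernel.

    ``shift``/``rep_only`` encode the pair class (cc / nc / nn) per pair.
    """

    i: np.ndarray          # (P,) int64 indices into the state arrays
    j: np.ndarray          # (P,) int64
    shift: np.ndarray      # (P,) float64, um
    rep_only: np.ndarray   # (P,) bool (nucleus-nucleus repulsive-only)

    @property
    def n_pairs(self) -> int:
        return len(self.i)


def build_neighbor_list(positions: np.ndarray, r_cut: float, skin: float = 0.0) -> np.ndarray:
    """All index pairs (i < j) with distance <= r_cut + skin.

    Returns an (P, 2) int array; empty systems give an empty array.
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    if len(positions) < 2:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r_cut + skin, output_type="ndarray")
    return pairs.astype(np.int64)


class NeighborList:
    """Rebuild-on-demand pair table for one particle state."""

    def __init__(self, pp: DerivedPairParams, skin: float = 0.9):
        self.pp = pp
        self.skin = float(skin)
        self._ref_positions: np.ndarray | None = None
        self._table: PairTable | None = None

    def invalidate(self) -> None:
        self._table = None
        self._ref_positions = None

    def needs_rebuild(self, state: ParticleState) -> bool:
        if self._table is None or self._ref_positions is None:
            return True
        if len(self._ref_positions) != state.n:
            return True
        disp = state.positions - self._ref_positions
        return bool(np.max(np.einsum("ij,ij->i", disp, disp)) > (self.skin / 2) ** 2)

    def pairs(self, state: ParticleState) -> PairTable:
        if self.needs_rebuild(state):
            self._table = self._build(state)
            self._ref_positions = state.positions.copy()
        return self._table

    def _build(self, state: ParticleState) -> PairTable:
        pp = self.pp
        pos = state.positions
        cyto = np.flatnonzero(state.type_id == CYTOPLASM)
        nuc = np.flatnonzero(state.type_id == NUCLEUS)

        blocks_i, blocks_j, blocks_s, blocks_r = [], [], [], []

        if len(cyto) >= 2:
            local = build_neighbor_list(pos[cyto], pp.r_cut, self.skin)
            if len(local):
                blocks_i.append(cyto[local[:, 0]])
                blocks_j.append(cyto[local[:, 1]])
                blocks_s.append(np.zeros(len(local)))
                blocks_r.append(np.zeros(len(local), dtype=bool))

        if len(nuc) and len(cyto):
            cut_nc = pp.cutoff_for("nc") + self.skin
            for k in nuc:
                d = np.linalg.norm(pos[cyto] - pos[k], axis=1)
                close = cyto[d <= cut_nc]
                if len(close):
                    blocks_i.append(np.full(len(close), k, dtype=np.int64))
                    blocks_j.append(close)
                    blocks_s.append(np.full(len(close), pp.shift_nuc))
                    blocks_r.append(np.zeros(len(close), dtype=bool))

        if len(nuc) >= 2:
            cut_nn = pp.cutoff_for("nn") + self.skin
            for a in range(len(nuc)):
                for b in range(a + 1, len(nuc)):
                    if np.linalg.norm(pos[nuc[a]] - pos[nuc[b]]) <= cut_nn:
                        blocks_i.append(np.array([nuc[a]], dtype=np.int64))
                        blocks_j.append(np.array([nuc[b]], dtype=np.int64))
                        blocks_s.append(np.array([pp.shift_nn]))
                        blocks_r.append(np.array([True]))

        if not blocks_i:
            return PairTable(
                i=np.empty(0, dtype=np.int64), j=np.empty(0, dtype=np.int64),
                shift=np.empty(0), rep_only=np.empty(0, dtype=bool))
        return PairTable(
            i=np.concatenate(blocks_i).astype(np.int64),
            j=np.concatenate(blocks_j).astype(np.int64),
            shift=np.concatenate(blocks_s),
            rep_only=np.concatenate(blocks_r),
        )
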