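"""Mechanics observables from trajectory frames.

Per-particle virial stress (energy units, tension positive), per-particle
Green-Lagrange strain and its von-Mises shear invariant, radial distribution
functions, spatially binned mean volumetric stress, slab contact area, and
cell-level metrics (height, axial strain, hull volume, nucleus offset).

Conventions
-----------
* Virial pair positions are taken relative to the pair midpoint (symmetric
  allocation), so each member of a pair receives sigma_ab = -1/2 r_a F_b with
  r the separation vector and F the pair force on the first member.  Stress
  stays in energy units (J): no per-particle volume division.  The kinetic
  term is omitted: in an overdamped system the contribution is essentially
  all potential.
* The deformation gradient is the standard atomic-strain least-squares fit
  over reference-frame neighbors within a cutoff (default 10 um);
  E = 1/2 (F^T F - I) and
  gamma = sqrt(Exy^2 + Exz^2 + Eyz^2
               + [(Exx-Eyy)^2 + (Exx-Ezz)^2 + (Eyy-Ezz)^2] / 6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree

from .dynamics import Frame, Trajectory
from .state import CYTOPLASM, NUCLEUS


# --------------------------------------------------------------------------
# per-particle virial stress
# --------------------------------------------------------------------------

@dataclass
class MechanicsFrame:
    """Per-particle stress and/or strain results for one frame."""

    time: float
    particle_id: np.ndarray
    virial: np.ndarray | None = None      # (N, 3, 3), J
    sigma_m: np.ndarray | None = None     # (N,), J
    E: np.ndarray | None = None           # (N, 3, 3), dimensionless
    gamma: np.ndarray | None = None       # (N,), dimensionless
    strain_defined: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-particle table; stress columns in J, strain dimensionless."""
        data = {"particle_id": self.particle_id}
        comps = [(0, 0, "xx"), (1, 1, "yy"), (2, 2, "zz"),
                 (0, 1, "xy"), (0, 2, "xz"), (1, 2, "yz")]
        if self.virial is not None:
            for a, b, lbl in comps:
                data[f"sigma_{lbl}"] = self.virial[:, a, b]
            data["sigma_m"] = self.sigma_m
        if self.E is not None:
            for a, b, lbl in comps:
                data[f"E_{lbl}"] = self.E[:, a, b]
            data["gamma"] = self.gamma
            data["strain_defined"] = self.strain_defined
        df = pd.DataFrame(data)
        df.attrs["time_s"] = self.time
        return df


def per_particle_virial(frame: Frame) -> MechanicsFrame:
    """Virial stress tensor per particle from the frame's pair-force records.

    Raises if the frame carries no per-pair records: stress cannot be
    recomputed from positions alone.
    """
    rec = frame.pair_record
    if rec is None:
        raise ValueError("frame has no per-pair force records; "
                         "rerun with record_pairs=True")
    n = len(frame.positions)
    virial = np.zeros((n, 9))
    if rec.i.size:
        r = rec.positions[rec.i] - rec.positions[rec.j]     # um
        f = rec.f                                           # J/um, force on i
        # each pair member receives -1/2 r_a F_b (midpoint allocation)
        contrib = -0.5 * np.einsum("pa,pb->pab", r, f).reshape(len(r), 9)
        np.add.at(virial, rec.i, contrib)
        np.add.at(virial, rec.j, contrib)
    virial = virial.reshape(n, 3, 3)
    virial = 0.5 * (virial + np.transpose(virial, (0, 2, 1)))  # enforce symmetry
    sigma_m = np.trace(virial, axis1=1, axis2=2) / 3.0
    return MechanicsFrame(time=frame.time, particle_id=frame.particle_id,
                          virial=virial, sigma_m=sigma_m)


# --------------------------------------------------------------------------
# per-particle Green-Lagrange strain
# --------------------------------------------------------------------------

def von_mises_shear(E: np.ndarray) -> np.ndarray:
    """Von-Mises shear strain invariant gamma of (..., 3, 3) strain tensors."""
    Exx, Eyy, Ezz = E[..., 0, 0], E[..., 1, 1], E[..., 2, 2]
    Exy, Exz, Eyz = E[..., 0, 1], E[..., 0, 2], E[..., 1, 2]
    return np.sqrt(Exy**2 + Exz**2 + Eyz**2
                   + ((Exx - Eyy)**2 + (Exx - Ezz)**2 + (Eyy - Ezz)**2) / 6.0)


def per_particle_strain(reference: Frame, current: Frame,
                        cutoff: float = 10.0) -> MechanicsFrame:
    """Green-Lagrange strain per particle between two frames.

    Only particles present in both frames (matched by particle id) are
    analyzed; particles with fewer than 3 non-degenerate reference neighbors
    get ``strain_defined = False`` and NaN tensors.
    """
    ref_ids = {int(p): k for k, p in enumerate(reference.particle_id)}
    common = [k for k, p in enumerate(current.particle_id) if int(p) in ref_ids]
    cur_idx = np.array(common, dtype=int)
    ref_idx = np.array([ref_ids[int(current.particle_id[k])] for k in common], dtype=int)

    ref_pos = reference.positions[ref_idx]
    cur_pos = current.positions[cur_idx]
    n = len(cur_idx)
    E = np.full((n, 3, 3), np.nan)
    gamma = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)

    tree = cKDTree(ref_pos)
    neighbor_lists = tree.query_ball_tree(tree, cutoff)
    eye = np.eye(3)
    for k in range(n):
        nbrs = [m for m in neighbor_lists[k] if m != k]
        if len(nbrs) < 3:
            continue
        A = ref_pos[nbrs] - ref_pos[k]        # reference relative vectors
        B = cur_pos[nbrs] - cur_pos[k]        # current relative vectors
        M = A.T @ A
        if np.linalg.matrix_rank(M, tol=1e-10) < 3:
            continue
        Ft = np.linalg.solve(M, A.T @ B)      # B ~ A F^T  ->  F^T
        F = Ft.T
        E[k] = 0.5 * (F.T @ F - eye)
        defined[k] = True
    gamma[defined] = von_mises_shear(E[defined])
    return MechanicsFrame(time=current.time,
                          particle_id=current.particle_id[cur_idx],
                          E=E, gamma=gamma, strain_defined=defined)


# --------------------------------------------------------------------------
# radial distribution function
# --------------------------------------------------------------------------

@dataclass
class RDFResult:
    bin_centers: np.ndarray     # um
    g: np.ndarray               # dimensionless
    time: float
    n_particles: int

    @property
    def peak_distance(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.g))])


def radial_distribution(frame: Frame, bin_width: float = 0.1,
                        r_max: float = 6.0, type_filter: int | None = CYTOPLASM,
                        volume: float | None = None) -> RDFResult:
    """Radial distribution function of the (filtered) particles of one frame.

    Normalized per spherical-shell volume and mean density (an ideal uniform
    gas gives g ~ 1).  ``volume`` defaults to the convex-hull volume of the
    filtered particle set.
    """
    if r_max <= bin_width:
        raise ValueError("r_max must exceed the bin width")
    if type_filter is None:
        pos = frame.positions
    else:
        pos = frame.positions[frame.type_id == type_filter]
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 particles after filtering")
    if volume is None:
        volume = float(ConvexHull(pos).volume)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1) if len(pairs) \
        else np.empty(0)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:]**3 - edges[:-1]**3)
    expected = (n * (n - 1) / 2.0) * shell / volume
    g = np.where(expected > 0, hist / expected, 0.0)
    return RDFResult(bin_centers=centers, g=g, time=frame.time, n_particles=n)


# --------------------------------------------------------------------------
# binned stress fields
# --------------------------------------------------------------------------

@dataclass
class BinnedStressField:
    """Mean volumetric stress in 1D (or flattened 2D) spatial bins."""

    edges: tuple[np.ndarray, ...]
    mean: np.ndarray                  # NaN where empty
    normalized: np.ndarray            # mean / max |mean|, NaN where empty
    axis: tuple[int, ...]

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)


def spatial_bin_stress(frame: Frame, sigma_m: np.ndarray,
                       axis: int | tuple[int, int] = 0,
                       bin_size: float = 2.0,
                       exclude_nucleus: bool = True) -> BinnedStressField:
    """Mean per-particle volumetric stress in 1D or 2D spatial bins.

    The single rigid nucleus particle is excluded by default.  Empty bins are
    NaN-flagged, never zero-filled; the normalization constant is the maximum
    |mean| over non-empty bins.
    """
    keep = np.ones(len(frame.positions), dtype=bool)
    if exclude_nucleus:
        keep = frame.type_id == CYTOPLASM
    pos = frame.positions[keep]
    val = np.asarray(sigma_m)[keep]
    if len(pos) == 0:
        raise ValueError("no particles to bin")
    axes = (axis,) if np.isscalar(axis) else tuple(axis)
    edges = []
    for a in axes:
        lo, hi = pos[:, a].min(), pos[:, a].max() + 1e-9
        nb = max(1, int(np.ceil((hi - lo) / bin_size)))
        edges.append(np.linspace(lo, lo + nb * bin_size, nb + 1))
    coords = [pos[:, a] for a in axes]
    counts, _ = np.histogramdd(np.column_stack(coords), bins=edges)
    sums, _ = np.histogramdd(np.column_stack(coords), bins=edges, weights=val)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not np.isfinite(mean).any():
        raise ValueError("all bins are empty")
    norm = np.nanmax(np.abs(mean))
    normalized = mean / norm if norm > 0 else mean
    return BinnedStressField(edges=tuple(edges), mean=mean,
                             normalized=normalized, axis=axes)


# --------------------------------------------------------------------------
# slab contact area
# --------------------------------------------------------------------------

def slab_contact_area(positions: np.ndarray, slab_indices: np.ndarray,
                      load_axis: int = 2, margin: float = 0.0) -> float:
    """Projected contact area (um^2) of a slab of particles.

    Area of the 2D convex hull of the slab particles projected onto the plane
    perpendicular to the load axis, dilated by ``margin`` (Minkowski sum with
    a disk: A + P*m + pi m^2), typically margin = d_eq/2 for the particle
    radius.  Used to convert an applied stress to a total slab force.
    """
    if len(slab_indices) == 0:
        raise ValueError("slab selection is empty")
    others = [a for a in range(3) if a != load_axis]
    proj = positions[np.asarray(slab_indices)][:, others]
    if len(proj) < 3:
        raise ValueError("need at least 3 slab particles for a projected hull")
    try:
        hull = ConvexHull(proj)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate (collinear) slab projection: {exc}") from exc
    area = hull.volume          # 2D: volume = area
    perimeter = hull.area       # 2D: area = perimeter
    return float(area + perimeter * margin + np.pi * margin**2)


# --------------------------------------------------------------------------
# cell-level metrics
# --------------------------------------------------------------------------

def frame_cell_metrics(frame: Frame, d_eq: float, cell: int | None = None) -> dict:
    """Centroid, nucleus position, Delta_nc, height and hull volume of one
    cell (or of all particles when ``cell`` is None) in one frame."""
    if cell is None:
        mask = np.ones(len(frame.positions), dtype=bool)
    else:
        mask = frame.cell_id == cell
    pos = frame.positions[mask]
    types = frame.type_id[mask]
    cyto = pos[types == CYTOPLASM]
    centroid = cyto.mean(axis=0) if len(cyto) else pos.mean(axis=0)
    nuc = pos[types == NUCLEUS]
    nucleus = nuc[0] if len(nuc) else None
    dnc = float(np.linalg.norm(centroid - nucleus)) if nucleus is not None else np.nan
    height = float(pos[:, 2].max() - pos[:, 2].min() + d_eq)
    vol = np.nan
    if len(pos) >= 4:
        try:
            vol = float(ConvexHull(pos).volume)
        except Exception:
            pass
    return {"time": frame.time, "cell_id": -1 if cell is None else cell,
            "centroid_x": centroid[0], "centroid_y": centroid[1],
            "centroid_z": centroid[2], "delta_nc": dnc,
            "height": height, "hull_volume": vol,
            "n_particles": int(mask.sum())}


def cell_level_metrics(traj: Trajectory, d_eq: float,
                       reference_index: int = 0,
                       per_cell: bool = False) -> pd.DataFrame:
    """Per-frame metric series with strains relative to a reference frame.

    Axial strain eps_z(t) = (z(t) - z0)/z0 with z(t) = max z - min z + d_eq
    measured over the member particles; volumetric strain
    (V(t) - V0)/V0 from convex-hull volumes.
    """
    if not 0 <= reference_index < len(traj.frames):
        raise ValueError("reference frame index out of range")
    rows = []
    for frame in traj.frames:
        if per_cell:
            for cell in np.unique(frame.cell_id):
                rows.append(frame_cell_metrics(frame, d_eq, int(cell)))
        else:
            rows.append(frame_cell_metrics(frame, d_eq, None))
    df = pd.DataFrame(rows)
    ref = df[df["time"] == traj.frames[reference_index].time]
    out = []
    for cell, grp in df.groupby("cell_id"):
        r = ref[ref["cell_id"] == cell]
        if len(r):
            z0 = float(r["height"].iloc[0])
            v0 = float(r["hull_volume"].iloc[0])
        else:   # cell born after the reference frame
            z0 = float(grp["height"].iloc[0])
            v0 = float(grp["hull_volume"].iloc[0])
        grp = grp.copy()
        grp["eps_z"] = (grp["height"] - z0) / z0
        grp["volumetric_strain"] = (grp["hull_volume"] - v0) / v0
        out.append(grp)
    return pd.concat(out).sort_values(["time", "cell_id"]).reset_index(drop=True)
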