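"""Scenario builders: single-cell creep, free-space migration, proliferation.

These reproduce the canonical coarse-grained cell experiments:

* **creep** -- a cylindrical cell adhered between two 9-3 plates (bottom slab
  velocity-fixed, top slab force-loaded per a piecewise-constant stress
  protocol, radial indenter around the z axis), reporting axial strain vs
  time.  The applied stress is converted to a total slab force through the
  projected contact area of the top slab, computed once at each load onset.
* **migration** -- a free-space cell with a nucleus, polarity-induced
  particle turnover at migration time T_m, optional nuclear-centring bias.
* **proliferation** -- growth events until the cytoplasmic count doubles,
  then nucleus duplication and splitting; optionally inside a cylindrical
  channel (organ-on-chip central section).

All randomness flows from a single integer seed per run; identical seed and
configuration give bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviors import BehaviorSchedule
from .bias import BiasSpec, delta_nc
from .constraints import ConstraintSet, CylinderConstraint, Wall93, select_slab
from .dynamics import Frame, NoiseModel, Simulation, Trajectory
from .mechanics import slab_contact_area
from .params import CellModelParams, DerivedPairParams, derive_pair_params
from .state import ParticleState, CYTOPLASM, NUCLEUS
from . import units


# --------------------------------------------------------------------------
# load protocol
# --------------------------------------------------------------------------

@dataclass
class LoadProtocol:
    """Piecewise-constant applied-stress schedule: [(start_s, end_s, Pa)]."""

    segments: list[tuple[float, float, float]]
    axis: int = 2

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        prev_end = None
        for t0, t1, stress in self.segments:
            if t0 < 0 or t1 <= t0:
                raise ValueError(f"bad protocol segment ({t0}, {t1})")
            if stress < 0:
                raise ValueError("stress must be >= 0")
            if prev_end is not None and not math.isclose(t0, prev_end):
                raise ValueError("protocol segments must be contiguous")
            prev_end = t1
        if not math.isclose(self.segments[0][0], 0.0):
            raise ValueError("protocol must start at t = 0")

    @property
    def total_time(self) -> float:
        return self.segments[-1][1]

    @property
    def load_onset(self) -> float | None:
        for t0, _, stress in self.segments:
            if stress > 0:
                return t0
        return None


#: short small-stress protocol: 3 s hold, 5 Pa for 7 s
PROTOCOL_5PA = LoadProtocol([(0.0, 3.0, 0.0), (3.0, 10.0, 5.0)])
#: large-strain protocol: 10 s hold, 30 s at 20 Pa, 30 s unload
PROTOCOL_20PA = LoadProtocol([(0.0, 10.0, 0.0), (10.0, 40.0, 20.0), (40.0, 70.0, 0.0)])


# --------------------------------------------------------------------------
# initial packing
# --------------------------------------------------------------------------

class PackingError(RuntimeError):
    pass


def _rejection_sample(n: int, sampler, min_dist: float, rng,
                      keepout_center=None, keepout_radius: float = 0.0,
                      max_tries_factor: int = 2000) -> np.ndarray:
    """Uniform points from ``sampler`` with pairwise spacing >= min_dist,
    via a hash-grid rejection loop."""
    cell = min_dist
    grid: dict[tuple, int] = {}
    pts = np.empty((n, 3))
    placed = 0
    tries = 0
    max_tries = max_tries_factor * n
    while placed < n:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"placed only {placed}/{n} particles after {max_tries} tries; "
                "use a larger geometry or smaller Np")
        p = sampler(rng)
        if keepout_center is not None and \
                np.linalg.norm(p - keepout_center) < keepout_radius:
            continue
        key = tuple((p // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    k = (key[0] + dx, key[1] + dy, key[2] + dz)
                    idx = grid.get(k)
                    if idx is not None:
                        for q in idx:
                            if np.linalg.norm(p - pts[q]) < min_dist:
                                ok = False
                                break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid.setdefault(key, []).append(placed)
            placed += 1
    return pts


def _fcc_lattice(spacing: float, half_extent: float) -> np.ndarray:
    """FCC lattice points with nearest-neighbor distance ``spacing`` covering
    a cube [-half_extent, half_extent]^3 around the origin."""
    a = spacing * math.sqrt(2.0)        # conventional cubic cell edge
    n = int(math.ceil(2.0 * half_extent / a)) + 2
    k = np.arange(-n, n + 1)
    base = np.array(np.meshgrid(k, k, k, indexing="ij")).reshape(3, -1).T * a
    offsets = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0],
                        [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]) * a
    pts = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    keep = np.all(np.abs(pts) <= half_extent + a, axis=1)
    return pts[keep]


def generate_initial_cell(Np: int, geometry: str, pp: DerivedPairParams,
                          seed: int, with_nucleus: bool = False,
                          R_cell: float = 10.0,
                          cylinder_height: float | None = None,
                          cylinder_radius: float | None = None,
                          relax_steps: int = 200, dt: float = 1e-3,
                          constraints: ConstraintSet | None = None,
                          method: str = "lattice",
                          jitter: float = 0.04,
                          spacing_factor: float = 1.0,
                          cell_id: int = 0) -> ParticleState:
    """Deterministic initial packing of one cell, noise-free relaxed.

    ``sphere``: ball centred at the origin.  ``cylinder``: tube around the z
    axis (radius defaulting to the volume-matched
    sqrt((4/3) R_cell^3 / h) at height h = 1.5 R_cell), plug grown from
    z = 0 upward.  The optional nucleus sits at the centroid with a
    keep-out at its shifted equilibrium distance.

    Two construction methods:

    * ``lattice`` (default): jittered FCC lattice at spacing d_eq -- the
      nominal close-packed density the parameter-scaling relations assume
      ("densely packed particles connected by springs").  During
      equilibration the ensemble relaxes elastically a few percent toward
      the slightly denser bulk minimum of the truncated potential;
      volume-ratio features of the preparation (e.g. the nuclear excluded
      volume) survive that uniform relaxation.
    * ``rejection``: uniform rejection sampling at minimum spacing
      0.8 d_eq, which lands well below nominal density (sequential
      rejection saturates around 38 % fill); useful for sparse/loose test
      configurations.
    """
    if Np < 10:
        raise ValueError("Np must be >= 10")
    rng = np.random.default_rng(seed)
    keepout = (pp.shift_nuc + 0.9 * pp.d_eq) if with_nucleus else 0.0
    if geometry == "sphere":
        center = np.zeros(3)
    elif geometry == "cylinder":
        h = cylinder_height if cylinder_height is not None else 1.5 * R_cell
        r_cyl = cylinder_radius if cylinder_radius is not None else \
            math.sqrt((4.0 / 3.0) * R_cell**3 / h)
        center = np.array([0.0, 0.0, h / 2.0])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    if method == "lattice":
        pts = _fcc_lattice(spacing_factor * pp.d_eq, half_extent=2.2 * R_cell + 5.0)
        pts = pts + rng.uniform(-0.2, 0.2, 3) * pp.d_eq   # random lattice phase
        if with_nucleus:
            pts = pts[np.linalg.norm(pts - center, axis=1) >= keepout]
        if geometry == "sphere":
            order = np.argsort(np.linalg.norm(pts, axis=1))
        else:
            radial = np.linalg.norm(pts[:, :2], axis=1)
            inside = radial <= r_cyl - 0.3 * pp.d_eq
            pts = pts[inside]
            # grow the plug upward from z = 0 (ranked by |z - z_layer|)
            order = np.argsort(np.abs(pts[:, 2] - center[2]))
        if len(order) < Np:
            raise PackingError(f"lattice yields only {len(order)} sites for "
                               f"Np={Np}; use a larger geometry")
        pos = pts[order[:Np]]
        pos = pos + rng.normal(0.0, jitter * pp.d_eq, pos.shape)
        if geometry == "cylinder":
            pos[:, 2] -= pos[:, 2].min()      # rest the plug on the bottom plate
    elif method == "rejection":
        min_dist = 0.8 * pp.d_eq
        if geometry == "sphere":
            def sampler(rng):
                while True:
                    p = rng.uniform(-R_cell, R_cell, 3)
                    if np.linalg.norm(p) <= R_cell:
                        return p
        else:
            def sampler(rng):
                while True:
                    x, y = rng.uniform(-r_cyl, r_cyl, 2)
                    if x * x + y * y <= r_cyl * r_cyl:
                        return np.array([x, y, rng.uniform(0.0, h)])
        pos = _rejection_sample(Np, sampler, min_dist, rng,
                                keepout_center=center if with_nucleus else None,
                                keepout_radius=keepout)
    else:
        raise ValueError(f"unknown packing method {method!r}")

    types = np.zeros(Np, dtype=np.int8)
    if with_nucleus:
        nuc_pos = pos.mean(axis=0) if geometry == "sphere" else \
            np.array([0.0, 0.0, 0.5 * (pos[:, 2].min() + pos[:, 2].max())])
        pos = np.vstack([pos, nuc_pos])
        types = np.append(types, np.int8(NUCLEUS))
    state = ParticleState.from_positions(
        pos, type_id=types, cell_id=np.full(len(pos), cell_id, dtype=np.int32))
    if relax_steps > 0:
        sim = Simulation(state, pp, constraints=constraints,
                         noise=NoiseModel(0.0, seed=seed), dt=dt)
        sim.run(relax_steps)
        state.velocities[:] = 0.0
        state.time = 0.0
    return state


def rotate_about_axis(positions: np.ndarray, angle: float, axis: int = 2,
                      center=None) -> np.ndarray:
    """Proper rotation of a point cloud about a coordinate axis."""
    c, s = math.cos(angle), math.sin(angle)
    others = [a for a in range(3) if a != axis]
    out = positions.copy()
    if center is None:
        center = positions.mean(axis=0)
    u = positions[:, others[0]] - center[others[0]]
    v = positions[:, others[1]] - center[others[1]]
    out[:, others[0]] = center[others[0]] + c * u - s * v
    out[:, others[1]] = center[others[1]] + s * u + c * v
    return out


# --------------------------------------------------------------------------
# scenario container
# --------------------------------------------------------------------------

@dataclass
class Scenario:
    """A fully specified experiment: kind + configuration, run via
    :func:`run_scenario` with a seed."""

    kind: str                      # 'creep' | 'migration' | 'proliferation'
    params: CellModelParams
    Np: int
    options: dict = field(default_factory=dict)
    replicates: int = 3

    def describe(self) -> dict:
        d = {"kind": self.kind, "Np": self.Np, "replicates": self.replicates,
             "params": self.params.to_dict()}
        d["options"] = {k: (v if not isinstance(v, LoadProtocol) else v.segments)
                        for k, v in self.options.items()}
        return d


def build_creep_scenario(params: CellModelParams | None = None, Np: int = 1000,
                         protocol: LoadProtocol = PROTOCOL_20PA,
                         with_nucleus: bool = False, replicates: int = 3,
                         **options) -> Scenario:
    params = params if params is not None else CellModelParams()
    if protocol.segments and min(t0 for t0, _, _ in protocol.segments) < 0:
        raise ValueError("protocol references negative times")
    opts = dict(protocol=protocol, with_nucleus=with_nucleus)
    opts.update(options)
    return Scenario(kind="creep", params=params, Np=Np, options=opts,
                    replicates=replicates)


def build_migration_scenario(params: CellModelParams | None = None, Np: int = 1000,
                             T_m: float = 100.0, T_sim: float = 100.0,
                             S: float = 0.0, replicates: int = 3,
                             **options) -> Scenario:
    params = params if params is not None else CellModelParams()
    opts = dict(T_m=T_m, T_sim=T_sim, S=S)
    opts.update(options)
    return Scenario(kind="migration", params=params, Np=Np, options=opts,
                    replicates=replicates)


def build_proliferation_scenario(params: CellModelParams | None = None,
                                 Np: int = 1000, rounds: int = 3,
                                 T_p: float = 50.0, constrained: bool = False,
                                 channel_radius: float | None = None,
                                 S: float = 1.0, replicates: int = 1,
                                 **options) -> Scenario:
    params = params if params is not None else CellModelParams()
    if constrained:
        if channel_radius is None:
            channel_radius = 1.2 * params.R_cell
        if channel_radius < params.R_cell:
            raise ValueError("channel radius smaller than the cell radius")
    opts = dict(rounds=rounds, T_p=T_p, constrained=constrained,
                channel_radius=channel_radius, S=S)
    opts.update(options)
    return Scenario(kind="proliferation", params=params, Np=Np, options=opts,
                    replicates=replicates)


# --------------------------------------------------------------------------
# runners
# --------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    metrics: pd.DataFrame
    trajectory: Trajectory
    info: dict = field(default_factory=dict)


def run_scenario(scenario: Scenario, seed: int, **overrides) -> ScenarioResult:
    opts = dict(scenario.options)
    opts.update(overrides)
    if scenario.kind == "creep":
        return run_creep(scenario.params, scenario.Np, seed=seed, **opts)
    if scenario.kind == "migration":
        return run_migration(scenario.params, scenario.Np, seed=seed, **opts)
    if scenario.kind == "proliferation":
        return run_proliferation(scenario.params, scenario.Np, seed=seed, **opts)
    raise ValueError(f"unknown scenario kind {scenario.kind!r}")


def _cell_height(positions: np.ndarray, d_eq: float) -> float:
    return float(positions[:, 2].max() - positions[:, 2].min() + d_eq)


def run_creep(params: CellModelParams, Np: int, seed: int,
              protocol: LoadProtocol = PROTOCOL_20PA,
              with_nucleus: bool = False, dt: float = 1e-3,
              temperature_ratio: float = 0.069, frame_stride_s: float = 0.1,
              rotation_angle: float = 0.0, relax_steps: int = 2000,
              jitter: float = 0.18,
              tube_radius_factor: float | None = None,
              record_pairs: bool = False, keep_frames: bool = False
              ) -> ScenarioResult:
    """One creep run: equilibrate/load/unload per the stress protocol.

    The cell is a plug inside a cylindrical tube (the pipette wall, a
    one-sided radial indenter) resting on an adhesive fixed bottom plate,
    with a movable top plate tracking the loaded slab.  The default tube
    radius is volume-matched (sqrt((4/3) R_cell^3 / h0)): the nominal-
    density plug exactly fills it, so the radial constraint is engaged and
    the nuclear excluded volume must be accommodated axially.

    Returns per-frame metrics: time, height (um), applied stress (Pa) and
    axial strain eps_z relative to the height at load onset.
    """
    pp = derive_pair_params(Np, params)
    h0 = 1.5 * params.R_cell
    r_cyl = tube_radius_factor * params.R_cell if tube_radius_factor \
        else math.sqrt((4.0 / 3.0) * params.R_cell**3 / h0)
    z_eq = (2.0 / 5.0) ** (1.0 / 6.0) * pp.d_eq

    cylinder = CylinderConstraint(radius=r_cyl, stiffness=10.0 * pp.kappa_int)
    bottom_wall = Wall93(position=-z_eq, side=1, epsilon=pp.u0, sigma=pp.d_eq)
    pack_constraints = ConstraintSet(walls=[bottom_wall], cylinder=cylinder)
    state = generate_initial_cell(
        Np, "cylinder", pp, seed=seed, with_nucleus=with_nucleus,
        R_cell=params.R_cell, cylinder_radius=r_cyl,
        relax_steps=relax_steps, dt=dt, jitter=jitter,
        constraints=pack_constraints)
    if rotation_angle:
        state.positions = rotate_about_axis(state.positions, rotation_angle, axis=2)

    slab_t = 0.1 * h0  # 1.5 um at the reference geometry (~10 % of cell height)
    z = state.positions[:, 2]
    # quantile-referenced faces so single stray surface particles do not
    # shift the slab window off the contact layer
    zlo = float(np.quantile(z, 0.02))
    zhi = float(np.quantile(z, 0.98))
    cyto_mask = state.type_id == CYTOPLASM
    bottom = select_slab(state.positions, 2, -np.inf, zlo + slab_t)
    top = select_slab(state.positions, 2, zhi - slab_t, np.inf)
    zmax = z.max()
    bottom = bottom[cyto_mask[bottom]]
    top = np.setdiff1d(top[cyto_mask[top]], bottom)

    top_wall = Wall93(position=zmax + z_eq, side=-1, epsilon=pp.u0, sigma=pp.d_eq,
                      track_indices=top,
                      track_offset=float(zmax + z_eq - state.positions[top, 2].mean()))
    constraints = ConstraintSet(walls=[bottom_wall, top_wall], cylinder=cylinder,
                                fixed_indices=bottom, loaded_indices=top,
                                F_ext=0.0, load_axis=2)

    noise = NoiseModel.from_well_fraction(pp, temperature_ratio, seed=seed)
    sim = Simulation(state, pp, constraints=constraints, noise=noise, dt=dt)

    frame_stride = max(1, int(round(frame_stride_s / dt)))
    metrics_rows: list[dict] = []
    current_stress = {"value": 0.0}

    def observer(s: Simulation) -> None:
        z = s.state.positions[:, 2]
        # plate separation: slab means are robust to individual stragglers
        # pulled out of the bulk in the flow regime, unlike max-min extent
        metrics_rows.append({
            "time": s.state.time,
            "height": float(z[top].mean() - z[bottom].mean()) + pp.d_eq,
            "extent": _cell_height(s.state.positions, pp.d_eq),
            "stress_pa": current_stress["value"],
        })

    traj = Trajectory(seed=seed)
    info: dict = {"Np": Np, "with_nucleus": with_nucleus, "seed": seed,
                  "d_eq": pp.d_eq, "r_cyl": r_cyl, "N_slab": int(len(top))}
    for t0, t1, stress in protocol.segments:
        current_stress["value"] = stress
        if stress > 0:
            area = slab_contact_area(state.positions, top, load_axis=2,
                                     margin=pp.d_eq / 2.0)
            constraints.F_ext = units.stress_pa_to_force_int(stress, area)
            info.setdefault("A_slab", area)
            info.setdefault("F_ext_int", constraints.F_ext)
        else:
            constraints.F_ext = 0.0
        n_steps = int(round((t1 - t0) / dt))
        seg = sim.run(n_steps, frame_stride=frame_stride, observers=[observer],
                      record_pairs=record_pairs)
        if keep_frames or record_pairs:
            start = 1 if traj.frames else 0
            traj.frames.extend(seg.frames[start:])
        else:
            traj.frames = seg.frames[-1:]
    traj.events = list(sim.events)

    metrics = pd.DataFrame(metrics_rows).drop_duplicates("time").reset_index(drop=True)
    onset = protocol.load_onset
    if onset is not None:
        at_onset = metrics[metrics["time"] <= onset + 1e-9]
        z0 = float(at_onset["height"].iloc[-1])
        info["z0"] = z0
        metrics["eps_z"] = (metrics["height"] - z0) / z0
    else:
        metrics["eps_z"] = 0.0
    return ScenarioResult(metrics=metrics, trajectory=traj, info=info)


def run_migration(params: CellModelParams, Np: int, seed: int,
                  T_m: float = 100.0, T_sim: float = 100.0, S: float = 0.0,
                  dt: float = 1e-3, temperature_ratio: float = 0.069,
                  frame_stride_s: float = 0.1, polarity_axis=(1.0, 0.0, 0.0),
                  polarity_mode: str = "persistent_random",
                  persistence: float = 5.0,
                  keep_frames: bool = False) -> ScenarioResult:
    """Free-space migration with a nucleus; reports Delta_nc and centroid."""
    pp = derive_pair_params(Np, params)
    state = generate_initial_cell(Np, "sphere", pp, seed=seed, with_nucleus=True,
                                  R_cell=params.R_cell, dt=dt)
    schedule = BehaviorSchedule(T_m=T_m, Np_ref=Np,
                                polarity_mode=polarity_mode,
                                polarity_axis=tuple(polarity_axis),
                                persistence=persistence)
    bias = BiasSpec(S=S, mode="com_spring" if S > 0 else "none")
    noise = NoiseModel.from_well_fraction(pp, temperature_ratio, seed=seed)
    sim = Simulation(state, pp, bias=bias, noise=noise, behaviors=schedule, dt=dt)

    rows: list[dict] = []

    def observer(s: Simulation) -> None:
        cell = int(s.state.cells()[0])
        cyto = s.state.cell_members(cell, cytoplasm_only=True)
        centroid = s.state.positions[cyto].mean(axis=0)
        rows.append({"time": s.state.time,
                     "delta_nc": float(np.linalg.norm(delta_nc(s.state, cell))),
                     "centroid_x": centroid[0], "centroid_y": centroid[1],
                     "centroid_z": centroid[2],
                     "n_cyto": len(cyto)})

    frame_stride = max(1, int(round(frame_stride_s / dt)))
    traj = sim.run(int(round(T_sim / dt)), frame_stride=frame_stride,
                   observers=[observer])
    if not keep_frames:
        traj.frames = traj.frames[-1:]
    metrics = pd.DataFrame(rows).drop_duplicates("time").reset_index(drop=True)
    path = metrics[["centroid_x", "centroid_y", "centroid_z"]].to_numpy()
    info = {"Np": Np, "T_m": T_m, "S": S, "seed": seed,
            "path_length": float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum()),
            "net_displacement": float(np.linalg.norm(path[-1] - path[0]))}
    return ScenarioResult(metrics=metrics, trajectory=traj, info=info)


def run_proliferation(params: CellModelParams, Np: int, seed: int,
                      rounds: int = 3, T_p: float = 50.0,
                      constrained: bool = False, channel_radius: float | None = None,
                      S: float = 1.0, dt: float = 1e-3,
                      temperature_ratio: float = 0.069, frame_stride_s: float = 0.2,
                      max_time: float | None = None,
                      keep_frames: bool = False) -> ScenarioResult:
    """Growth/division rounds from a single mother cell (2^rounds cells)."""
    pp = derive_pair_params(Np, params)
    state = generate_initial_cell(Np, "sphere", pp, seed=seed, with_nucleus=True,
                                  R_cell=params.R_cell, dt=dt)
    constraints = None
    if constrained:
        if channel_radius is None:
            channel_radius = 1.2 * params.R_cell
        if channel_radius < params.R_cell:
            raise ValueError("channel radius smaller than the cell radius")
        constraints = ConstraintSet(
            cylinder=CylinderConstraint(radius=channel_radius,
                                        stiffness=10.0 * pp.kappa_int))
    schedule = BehaviorSchedule(T_p=T_p, Np_ref=Np)
    bias = BiasSpec(S=S, mode="com_spring" if S > 0 else "none")
    noise = NoiseModel.from_well_fraction(pp, temperature_ratio, seed=seed)
    sim = Simulation(state, pp, constraints=constraints, bias=bias,
                     noise=noise, behaviors=schedule, dt=dt)

    rows: list[dict] = []

    def observer(s: Simulation) -> None:
        pos = s.state.positions
        rows.append({"time": s.state.time,
                     "n_cells": len(s.state.cells()),
                     "n_particles": s.state.n,
                     "extent_z": float(pos[:, 2].max() - pos[:, 2].min() + pp.d_eq),
                     "extent_x": float(pos[:, 0].max() - pos[:, 0].min() + pp.d_eq)})

    target_cells = 2**rounds
    frame_stride = max(1, int(round(frame_stride_s / dt)))
    # expected time for `rounds` doublings at the current-count rate: T_p ln2 each
    budget = max_time if max_time is not None else (rounds + 1.0) * T_p * math.log(2.0)
    traj = Trajectory(seed=seed)
    traj.frames.append(Frame.capture(state))
    observer(sim)
    chunk = max(frame_stride, 1)
    steps_done = 0
    total_steps = int(round(budget / dt))
    while steps_done < total_steps and len(state.cells()) < target_cells:
        seg = sim.run(chunk, frame_stride=chunk, observers=[observer])
        if keep_frames:
            traj.frames.extend(seg.frames[1:])
        else:
            traj.frames[-1:] = seg.frames[-1:]
        steps_done += chunk
    traj.events = list(sim.events)
    metrics = pd.DataFrame(rows).drop_duplicates("time").reset_index(drop=True)
    info = {"Np": Np, "rounds": rounds, "constrained": constrained,
            "final_cells": int(len(state.cells())), "seed": seed,
            "T_p": T_p}
    return ScenarioResult(metrics=metrics, trajectory=traj, info=info)
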