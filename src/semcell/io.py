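"""Trajectory, event-log, config and manifest I/O.

Trajectories are written as LAMMPS-style text dumps with columns
``id type cell x y z`` (type 1 = cytoplasm, 2 = nucleus, matching the usual
1-based dump convention) and optionally as XYZ.  Coordinates are in um.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import Frame, Trajectory
from .state import ParticleState

DUMP_COLUMNS = "id type cell x y z"


def write_lammps_dump(traj: Trajectory | list[Frame], path) -> None:
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            pos = frame.positions
            lo = pos.min(axis=0) - 1.0
            hi = pos.max(axis=0) + 1.0
            fh.write("ITEM: TIMESTEP\n%d\n" % k)
            fh.write("ITEM: TIME\n%.6f\n" % frame.time)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(pos))
            fh.write("ITEM: BOX BOUNDS ff ff ff\n")
            for a in range(3):
                fh.write("%.6f %.6f\n" % (lo[a], hi[a]))
            fh.write(f"ITEM: ATOMS {DUMP_COLUMNS}\n")
            for i in range(len(pos)):
                fh.write("%d %d %d %.6f %.6f %.6f\n" % (
                    frame.particle_id[i], frame.type_id[i] + 1, frame.cell_id[i],
                    pos[i, 0], pos[i, 1], pos[i, 2]))


def read_lammps_dump(path) -> list[Frame]:
    """Read a dump written by :func:`write_lammps_dump` (columns id type cell
    x y z; TIME item optional)."""
    frames: list[Frame] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ValueError(f"malformed dump at line {i + 1}")
        i += 2
        time = 0.0
        if lines[i].startswith("ITEM: TIME"):
            time = float(lines[i + 1])
            i += 2
        if not lines[i].startswith("ITEM: NUMBER OF ATOMS"):
            raise ValueError(f"malformed dump at line {i + 1}")
        n = int(lines[i + 1])
        i += 2
        if lines[i].startswith("ITEM: BOX BOUNDS"):
            i += 4
        header = lines[i]
        if not header.startswith("ITEM: ATOMS"):
            raise ValueError(f"malformed dump at line {i + 1}")
        cols = header.split()[2:]
        idx = {c: j for j, c in enumerate(cols)}
        i += 1
        rows = np.array([lines[i + j].split() for j in range(n)], dtype=float)
        i += n
        frames.append(Frame(
            time=time,
            positions=rows[:, [idx["x"], idx["y"], idx["z"]]].astype(float),
            velocities=np.zeros((n, 3)),
            type_id=rows[:, idx["type"]].astype(np.int8) - 1,
            cell_id=rows[:, idx["cell"]].astype(np.int32) if "cell" in idx
            else np.zeros(n, dtype=np.int32),
            particle_id=rows[:, idx["id"]].astype(np.int64),
        ))
    return frames


def frame_to_state(frame: Frame) -> ParticleState:
    return ParticleState(positions=frame.positions.copy(),
                         velocities=frame.velocities.copy(),
                         type_id=frame.type_id.copy(),
                         cell_id=frame.cell_id.copy(),
                         particle_id=frame.particle_id.copy(),
                         time=frame.time)


def write_xyz(traj: Trajectory | list[Frame], path) -> None:
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    names = {0: "C", 1: "N"}  # cytoplasm / nucleus
    with open(path, "w") as fh:
        for frame in frames:
            fh.write("%d\n" % len(frame.positions))
            fh.write("t=%.6f s, coordinates in um\n" % frame.time)
            for i, p in enumerate(frame.positions):
                fh.write("%s %.6f %.6f %.6f\n" % (names[int(frame.type_id[i])],
                                                  p[0], p[1], p[2]))


def write_event_log(events: list[dict], path) -> None:
    cols = ["time", "event_type", "cell_id", "particle_id_added",
            "particle_id_removed", "daughter"]
    df = pd.DataFrame(events)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df[cols].to_csv(path, index=False)


class ConfigError(ValueError):
    pass


_TOP_KEYS = {"scenario", "params", "options", "integrator", "seed", "out"}
_INTEGRATOR_KEYS = {"dt", "temperature_ratio", "frame_stride_s"}


def load_config(path) -> dict:
    """Load and validate a run configuration YAML.

    Unknown keys raise :class:`ConfigError` listing them, so a misspelled
    option can never fall back to a silent default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    integ = raw.get("integrator", {})
    unknown = set(integ) - _INTEGRATOR_KEYS
    if unknown:
        raise ConfigError(f"unknown integrator keys: {sorted(unknown)}")
    raw.setdefault("options", {})
    raw.setdefault("integrator", {})
    raw.setdefault("seed", 0)
    if "scenario" not in raw:
        raise ConfigError("config must name a scenario")
    return raw


def write_manifest(path, config: dict, seed: int, derived: dict | None = None) -> None:
    import semcell
    manifest = {
        "package": "semcell",
        "version": getattr(semcell, "__version__", "unknown"),
        "seed": seed,
        "config": config,
        "derived": derived or {},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
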