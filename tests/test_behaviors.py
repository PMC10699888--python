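"""Migration, growth and division events: conservation laws, oracles,
statistics."""

import numpy as np
import pytest

from semcell import (BehaviorSchedule, BiasSpec, NoiseModel, ParticleState,
                     Simulation, cell_polarity, divide_cell, growth_event,
                     migration_event, schedule_events)
from semcell.behaviors import DivisionError
from semcell.bias import delta_nc, nuclear_bias_force
from semcell.state import CYTOPLASM, NUCLEUS


def test_fixed_polarity(small_cell):
    rng = np.random.default_rng(0)
    for _ in range(3):
        v = cell_polarity(small_cell, 0, "fixed_direction", rng, axis=(1, 0, 0))
        assert np.allclose(v, [1, 0, 0])


def test_persistent_random_limit_and_dispersion(small_cell):
    """Infinite persistence keeps the vector constant; finite persistence
    gives angular steps whose mean matches the configured dispersion."""
    rng = np.random.default_rng(1)
    prev = np.array([1.0, 0, 0])
    v = cell_polarity(small_cell, 0, "persistent_random", rng, prev=prev,
                      persistence=np.inf)
    assert np.allclose(v, prev)

    persistence = 20.0          # angular step std = 0.05 rad
    angles = []
    v = prev
    for _ in range(10000):
        w = cell_polarity(small_cell, 0, "persistent_random", rng, prev=v,
                          persistence=persistence)
        angles.append(np.arccos(np.clip(np.dot(v, w), -1, 1)))
        v = w
        assert np.linalg.norm(w) == pytest.approx(1.0)
    # folded-normal mean: sigma * sqrt(2/pi)
    expect = (1 / persistence) * np.sqrt(2 / np.pi)
    assert np.mean(angles) == pytest.approx(expect, rel=0.05)


def test_polarity_errors(pp):
    rng = np.random.default_rng(0)
    tiny = ParticleState.from_positions(np.zeros((3, 3)) + np.arange(3)[:, None])
    with pytest.raises(ValueError, match="fewer than 4"):
        cell_polarity(tiny, 0, "fixed_direction", rng)
    degenerate = ParticleState.from_positions(np.zeros((5, 3)))
    with pytest.raises(ValueError, match="degenerate"):
        cell_polarity(degenerate, 0, "fixed_direction", rng)


def test_schedule_events_poisson_counting():
    """Expected event count over T_sim is T_sim * Np / T (Poisson oracle:
    Np=1000, T=100 s, T_sim=100 s -> 1000 +- 3 sqrt(1000))."""
    rng = np.random.default_rng(3)
    dt, T, Np, T_sim = 1e-2, 100.0, 1000, 100.0
    total = sum(schedule_events(Np, T, dt, rng)
                for _ in range(int(T_sim / dt)))
    assert abs(total - 1000) <= 3 * np.sqrt(1000)
    assert schedule_events(1000, np.inf, dt, rng) == 0


def test_schedule_events_boundary_rate():
    """dt*Np/T = 1: one event per step in expectation."""
    rng = np.random.default_rng(4)
    draws = [schedule_events(100, 100.0, 1.0, rng) for _ in range(4000)]
    assert np.mean(draws) == pytest.approx(1.0, rel=0.1)


def test_migration_conserves_count_and_removes_trailing(pp_small, small_cell):
    state = small_cell.copy()
    rng = np.random.default_rng(5)
    pol = np.array([1.0, 0.0, 0.0])
    before = state.cell_members(0, cytoplasm_only=True)
    n_before = len(before)
    # brute-force trailing-edge oracle on the pre-event configuration
    trailing_id = int(state.particle_id[before[np.argmin(
        state.positions[before] @ pol)]])
    migration_event(state, 0, pol, pp_small, rng)
    after_ids = set(state.particle_id[state.cell_members(0, cytoplasm_only=True)])
    assert len(after_ids) == n_before
    assert trailing_id not in after_ids
    assert state.nucleus_index(0) is not None


def test_migration_skipped_below_minimum(pp_small):
    pos = np.vstack([np.random.default_rng(0).uniform(0, 3, (5, 3)),
                     [[1.5, 1.5, 1.5]]])
    types = np.array([0] * 5 + [1], dtype=np.int8)
    state = ParticleState.from_positions(pos, type_id=types,
                                         cell_id=np.zeros(6, dtype=np.int32))
    out = migration_event(state, 0, np.array([1.0, 0, 0]), pp_small,
                          np.random.default_rng(1), Np_min=10)
    assert out is None and state.n == 6


def test_growth_increments_count(pp_small, small_cell):
    state = small_cell.copy()
    n0 = state.n
    pid = growth_event(state, 0, pp_small, np.random.default_rng(6))
    assert state.n == n0 + 1
    assert pid == state.particle_id.max()
    # new particle near the surface: at least d_eq * 0.5 from all others
    d = np.linalg.norm(state.positions[:-1] - state.positions[-1], axis=1)
    assert d.min() > 0.4 * pp_small.d_eq


def test_particle_ids_never_reused(pp_small, small_cell):
    state = small_cell.copy()
    rng = np.random.default_rng(7)
    seen_removed = set()
    for _ in range(30):
        before = set(state.particle_id.tolist())
        migration_event(state, 0, np.array([1.0, 0, 0]), pp_small, rng)
        now = set(state.particle_id.tolist())
        removed = before - now
        assert not (now & seen_removed)       # removed ids never reappear
        seen_removed |= removed


def test_division_conservation_and_nearest_nucleus_oracle(pp_small, small_cell):
    state = small_cell.copy()
    rng = np.random.default_rng(8)
    cyto_before = len(state.cell_members(0, cytoplasm_only=True))
    ev = divide_cell(state, 0, pp_small, rng)
    d0 = state.cell_members(0, cytoplasm_only=True)
    d1 = state.cell_members(ev.daughter_cell, cytoplasm_only=True)
    assert len(d0) + len(d1) == cyto_before
    assert len(d0) > 0 and len(d1) > 0
    assert len(state.cells()) == 2
    # brute-force nearest-nucleus reclassification
    n0 = state.positions[state.nucleus_index(0)]
    n1 = state.positions[state.nucleus_index(ev.daughter_cell)]
    for idx in np.concatenate([d0, d1]):
        p = state.positions[idx]
        nearer = 0 if np.linalg.norm(p - n0) < np.linalg.norm(p - n1) \
            else ev.daughter_cell
        assert state.cell_id[idx] == nearer


def test_division_requires_nucleus(pp_small):
    state = ParticleState.from_positions(np.random.default_rng(0).uniform(
        0, 5, (20, 3)))
    with pytest.raises(DivisionError, match="no nucleus"):
        divide_cell(state, 0, pp_small, np.random.default_rng(0))


def test_bias_force_zero_at_centroid(pp_small):
    """Nucleus exactly at the cytoplasm centroid with zero velocity feels no
    bias force."""
    pos = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0],
                    [0, 0, 0]])
    types = np.array([0, 0, 0, 0, 1], dtype=np.int8)
    state = ParticleState.from_positions(pos, type_id=types,
                                         cell_id=np.zeros(5, dtype=np.int32))
    f = nuclear_bias_force(state, BiasSpec(S=1.0), pp_small, 1e-3)
    assert np.allclose(f, 0.0)


def test_bias_force_substitution(pp_small):
    """Direct substitution: Delta_nc = (1,0,0) um, u_n = 0, S = 1 gives
    F = 2 m_nuc / dt^2 (in SI) along +x on the nucleus only."""
    pos = np.array([[2.0, 0, 0], [0.0, 0, 0]])
    types = np.array([0, 1], dtype=np.int8)
    state = ParticleState.from_positions(pos, type_id=types,
                                         cell_id=np.zeros(2, dtype=np.int32))
    dt = 1e-3
    f = nuclear_bias_force(state, BiasSpec(S=1.0), pp_small, dt)
    expect_si = 1.0 * pp_small.m_nuc_kg * 2.0 * (2.0e-6) / dt**2   # N
    assert f[1, 0] == pytest.approx(expect_si * 1e-6)              # J/um
    assert np.allclose(f[0], 0.0)
    with pytest.raises(ValueError):
        nuclear_bias_force(state, BiasSpec(S=1.0), pp_small, 0.0)


def test_division_trigger_in_schedule(pp_small, small_cell):
    """Growth events trigger exactly one division when the cytoplasmic count
    doubles."""
    state = small_cell.copy()
    noise = NoiseModel.from_step_fraction(pp_small, 1e-3, 0.02, seed=9)
    schedule = BehaviorSchedule(T_p=0.4, Np_ref=100)
    sim = Simulation(state, pp_small, bias=BiasSpec(S=1.0), noise=noise,
                     behaviors=schedule)
    sim.run(1200)
    divisions = [e for e in sim.events if e["event_type"] == "division"]
    assert len(state.cells()) == len(divisions) + 1
    if divisions:
        growths = [e for e in sim.events if e["event_type"] == "growth"
                   and e["time"] <= divisions[0]["time"]]
        assert len(growths) >= 100        # doubled before the first split
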