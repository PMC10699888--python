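"""Scenario builders: packing determinism, protocol validation, small
end-to-end runs (scaled-down particle counts keep these fast; the
full-scale study conditions live in the acceptance tests)."""

import numpy as np
import pytest

from semcell import (CellModelParams, LoadProtocol, derive_pair_params,
                     generate_initial_cell, radial_distribution,
                     rotate_about_axis, run_creep, run_migration,
                     run_proliferation)
from semcell.dynamics import Frame
from semcell.scenarios import (PackingError, build_proliferation_scenario,
                               build_creep_scenario)


def test_protocol_validation():
    LoadProtocol([(0.0, 3.0, 0.0), (3.0, 10.0, 5.0)])
    with pytest.raises(ValueError, match="contiguous"):
        LoadProtocol([(0.0, 3.0, 0.0), (4.0, 10.0, 5.0)])
    with pytest.raises(ValueError):
        LoadProtocol([(0.0, 3.0, -5.0)])
    with pytest.raises(ValueError):
        LoadProtocol([(-1.0, 3.0, 0.0)])
    assert LoadProtocol([(0.0, 2.0, 0.0), (2.0, 4.0, 7.0)]).load_onset == 2.0


def test_packing_spacing_and_determinism(pp_small):
    """Rejection packing honors the 0.8 d_eq minimum spacing and is
    deterministic per seed; the default lattice packing is deterministic
    too."""
    a = generate_initial_cell(30, "sphere", pp_small, seed=1, R_cell=10.0,
                              relax_steps=0, method="rejection")
    d = np.linalg.norm(a.positions[:, None] - a.positions[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 0.8 * pp_small.d_eq
    b = generate_initial_cell(30, "sphere", pp_small, seed=1, R_cell=10.0,
                              relax_steps=0, method="rejection")
    assert np.array_equal(a.positions, b.positions)
    c = generate_initial_cell(30, "sphere", pp_small, seed=2, R_cell=10.0,
                              relax_steps=0, method="rejection")
    assert not np.array_equal(a.positions, c.positions)


def test_packing_failure_suggests_larger_geometry(pp_small):
    with pytest.raises(PackingError, match="larger geometry"):
        generate_initial_cell(500, "sphere", pp_small, seed=1, R_cell=2.0,
                              relax_steps=0, method="rejection")


def test_packing_relaxed_cell_rdf_peak_stable(pp):
    """Relaxed packing: rdf peak near the bulk equilibrium spacing of the
    potential (compressed below d_eq by the attractive tail; see methods)."""
    state = generate_initial_cell(400, "sphere", pp, seed=3, R_cell=10.0)
    r = radial_distribution(Frame.capture(state), bin_width=0.1)
    assert 0.8 * pp.d_eq < r.peak_distance < 1.1 * pp.d_eq


def test_rotation_is_proper(pp):
    rng = np.random.default_rng(0)
    pos = rng.uniform(0, 5, (40, 3))
    rot = rotate_about_axis(pos, 2 * np.pi / 3, axis=2)
    d0 = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    d1 = np.linalg.norm(rot[:, None] - rot[None, :], axis=-1)
    assert np.allclose(d0, d1)                       # isometry
    assert not np.allclose(pos, rot)


def test_creep_zero_stress_strain_stays_small():
    """Hold-only protocol: axial strain stays within noise of zero."""
    params = CellModelParams()
    res = run_creep(params, 150, seed=2,
                    protocol=LoadProtocol([(0.0, 2.0, 0.0), (2.0, 4.0, 0.0)]),
                    relax_steps=200)
    tail = res.metrics[res.metrics.time >= 2.0]["eps_z"]
    assert np.abs(tail).max() < 0.05


def test_creep_load_stretches():
    params = CellModelParams()
    res = run_creep(params, 150, seed=2,
                    protocol=LoadProtocol([(0.0, 1.0, 0.0), (1.0, 4.0, 20.0)]))
    m = res.metrics
    assert m["eps_z"].iloc[-1] > 0.05                # clearly stretched
    assert res.info["N_slab"] > 0 and res.info["A_slab"] > 0


def test_migration_no_events_limit():
    """T_m -> infinity: no turnover events, centroid stays put (diffusion
    only)."""
    params = CellModelParams()
    res = run_migration(params, 100, seed=4, T_m=1e12, T_sim=2.0, S=0.0)
    assert len(res.trajectory.events) == 0
    assert res.info["net_displacement"] < 1.0


def test_migration_moves_cell_along_polarity():
    params = CellModelParams()
    res = run_migration(params, 100, seed=4, T_m=2.0, T_sim=6.0, S=1.0,
                        polarity_mode="fixed_direction")
    m = res.metrics
    assert len(res.trajectory.events) > 50
    assert m["centroid_x"].iloc[-1] - m["centroid_x"].iloc[0] > 2.0
    # drift is along +x, not the other axes
    assert abs(m["centroid_y"].iloc[-1] - m["centroid_y"].iloc[0]) < \
        0.5 * (m["centroid_x"].iloc[-1] - m["centroid_x"].iloc[0])


def test_proliferation_rounds_and_conservation():
    """One round: growth doubles the count, division splits into 2 cells and
    conserves cytoplasmic particles."""
    params = CellModelParams()
    res = run_proliferation(params, 60, seed=5, rounds=1, T_p=2.0, S=2.0,
                            max_time=12.0)
    assert res.info["final_cells"] == 2
    ev = [e for e in res.trajectory.events if e["event_type"] == "division"]
    assert len(ev) == 1
    last = res.trajectory.frames[-1]
    assert (last.type_id == 0).sum() >= 120          # grown past 2 Np_ref


def test_proliferation_channel_validation():
    with pytest.raises(ValueError, match="channel radius"):
        build_proliferation_scenario(CellModelParams(), Np=60, constrained=True,
                                     channel_radius=5.0)
    scn = build_creep_scenario(CellModelParams(), Np=100)
    assert scn.kind == "creep"
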