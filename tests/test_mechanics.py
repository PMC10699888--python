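"""Virial stress, Green-Lagrange strain, rdf, binned stress, contact area,
cell metrics."""

import numpy as np
import pytest

from semcell import (NoiseModel, ParticleState, Simulation, Trajectory,
                     cell_level_metrics, pair_force, per_particle_strain,
                     per_particle_virial, radial_distribution,
                     slab_contact_area, spatial_bin_stress, von_mises_shear)
from semcell.dynamics import Frame
from semcell.mechanics import RDFResult
from semcell.neighbors import NeighborList
from semcell.forces import compute_pair_forces


def _frame_with_records(positions, pp, type_id=None):
    state = ParticleState.from_positions(np.asarray(positions, float),
                                         type_id=type_id)
    table = NeighborList(pp).pairs(state)
    _, rec = compute_pair_forces(state, pp, table)
    return Frame.capture(state, pair_record=rec)


# ---------------------------------------------------------------- virial

def test_virial_isolated_and_equilibrium_pairs(pp):
    frame = _frame_with_records([[0.0, 0, 0], [50.0, 0, 0]], pp)
    mf = per_particle_virial(frame)
    assert np.allclose(mf.virial, 0.0)                # no neighbors
    frame = _frame_with_records([[0.0, 0, 0], [pp.d_eq, 0, 0]], pp)
    mf = per_particle_virial(frame)
    assert np.allclose(mf.virial, 0.0, atol=1e-30)    # zero force at d_eq


def test_virial_compressed_pair_hand_evaluated(pp):
    """Pair at 0.8 d_eq along x: sigma_xx = -1/2 r F < 0 for both members,
    other components zero; sigma_m = trace/3 exactly."""
    d = 0.8 * pp.d_eq
    frame = _frame_with_records([[0.0, 0, 0], [d, 0, 0]], pp)
    mf = per_particle_virial(frame)
    f = pair_force(d, pp)                 # repulsive > 0
    expect_xx = -0.5 * d * f
    for k in (0, 1):
        assert mf.virial[k, 0, 0] == pytest.approx(expect_xx)
        assert mf.virial[k, 1, 1] == 0 and mf.virial[k, 2, 2] == 0
        assert mf.virial[k, 0, 0] < 0     # compression negative
        assert mf.sigma_m[k] == pytest.approx(np.trace(mf.virial[k]) / 3)


def test_virial_stretched_pair_tension_positive(pp):
    d = 1.3 * pp.d_eq
    frame = _frame_with_records([[0.0, 0, 0], [d, 0, 0]], pp)
    mf = per_particle_virial(frame)
    assert mf.virial[0, 0, 0] > 0         # tension positive


def test_virial_requires_pair_records(pp):
    state = ParticleState.from_positions(np.zeros((2, 3)) + [[0, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="pair"):
        per_particle_virial(Frame.capture(state))


def test_virial_sign_under_uniform_scaling(pp, equilibrated_cell):
    """Sum of sigma_m turns negative under uniform compression of a relaxed
    cell and positive under dilation."""
    base = equilibrated_cell
    out = {}
    for name, s in (("compressed", 0.94), ("dilated", 1.10)):
        scaled = base.copy()
        centroid = scaled.positions.mean(axis=0)
        scaled.positions = centroid + s * (scaled.positions - centroid)
        pp_ = pp
        table = NeighborList(pp_).pairs(scaled)
        _, rec = compute_pair_forces(scaled, pp_, table)
        mf = per_particle_virial(Frame.capture(scaled, pair_record=rec))
        cyto = scaled.type_id == 0
        out[name] = mf.sigma_m[cyto].sum()
    assert out["compressed"] < 0 < out["dilated"]


# ---------------------------------------------------------------- strain

def test_strain_identity_and_rigid_motion(pp):
    rng = np.random.default_rng(0)
    pos = rng.uniform(0, 8, (60, 3))
    ref = Frame.capture(ParticleState.from_positions(pos.copy()))
    cur = Frame.capture(ParticleState.from_positions(pos.copy()))
    mf = per_particle_strain(ref, cur)
    assert np.allclose(mf.E[mf.strain_defined], 0.0, atol=1e-12)
    assert np.allclose(mf.gamma[mf.strain_defined], 0.0, atol=1e-12)

    # rigid rotation + translation: finite-strain objectivity, E = 0
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = pos @ R.T + np.array([5.0, -2.0, 1.0])
    cur = Frame.capture(ParticleState.from_positions(moved))
    mf = per_particle_strain(ref, cur)
    assert np.allclose(mf.E[mf.strain_defined], 0.0, atol=1e-9)
    assert np.allclose(mf.gamma[mf.strain_defined], 0.0, atol=1e-9)


def test_strain_uniaxial_stretch_closed_form(pp):
    """x -> lam x gives E = diag((lam^2-1)/2, 0, 0) and gamma = |E_xx|/sqrt(3)
    for every particle with enough neighbors."""
    rng = np.random.default_rng(1)
    pos = rng.uniform(0, 10, (80, 3))
    lam = 1.25
    stretched = pos * np.array([lam, 1.0, 1.0])
    ref = Frame.capture(ParticleState.from_positions(pos))
    cur = Frame.capture(ParticleState.from_positions(stretched))
    mf = per_particle_strain(ref, cur, cutoff=10.0)
    exx = (lam**2 - 1) / 2
    sel = mf.strain_defined
    assert sel.sum() > 70
    assert np.allclose(mf.E[sel, 0, 0], exx, atol=1e-10)
    assert np.allclose(mf.E[sel, 1, 1], 0.0, atol=1e-10)
    assert np.allclose(mf.gamma[sel], abs(exx) / np.sqrt(3), atol=1e-10)


def test_strain_undefined_for_isolated_particle(pp):
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0],
                    [100.0, 100, 100]])
    ref = Frame.capture(ParticleState.from_positions(pos.copy()))
    cur = Frame.capture(ParticleState.from_positions(pos.copy()))
    mf = per_particle_strain(ref, cur, cutoff=5.0)
    assert not mf.strain_defined[4]
    assert np.isnan(mf.gamma[4])


def test_strain_matches_only_shared_ids(pp):
    """Particles added between frames (migration) are excluded from the
    analyzed set."""
    pos = np.random.default_rng(2).uniform(0, 6, (30, 3))
    ref = Frame.capture(ParticleState.from_positions(pos))
    st = ParticleState.from_positions(pos)
    st.add_particle([3.0, 3.0, 3.0], 0, 0)
    cur = Frame.capture(st)
    mf = per_particle_strain(ref, cur)
    assert len(mf.particle_id) == 30


def test_von_mises_formula_direct():
    E = np.zeros((3, 3))
    E[0, 1] = E[1, 0] = 0.2
    assert von_mises_shear(E) == pytest.approx(0.2)
    E = np.diag([0.3, 0.0, 0.0])
    assert von_mises_shear(E) == pytest.approx(0.3 / np.sqrt(3))


# ------------------------------------------------------------------- rdf

def test_rdf_two_particles_single_bin(pp):
    state = ParticleState.from_positions(np.array([[0.0, 0, 0], [2.04, 0, 0]]))
    r = radial_distribution(Frame.capture(state), bin_width=0.1, r_max=4.0,
                            volume=100.0)
    nz = np.flatnonzero(r.g)
    assert len(nz) == 1
    assert r.bin_centers[nz[0]] == pytest.approx(2.05)


def test_rdf_ideal_gas_is_unity():
    """Uniform random points: g(r) = 1 within a few percent at mid-range r
    (shell normalization oracle)."""
    rng = np.random.default_rng(3)
    L = 60.0
    pos = rng.uniform(0, L, (20000, 3))
    state = ParticleState.from_positions(pos)
    r = radial_distribution(Frame.capture(state), bin_width=0.2, r_max=1.6,
                            type_filter=None, volume=L**3)
    mid = (r.bin_centers > 0.55) & (r.bin_centers < 1.45)
    assert np.allclose(r.g[mid], 1.0, atol=0.05)


def test_rdf_validation(pp):
    state = ParticleState.from_positions(np.zeros((1, 3)))
    with pytest.raises(ValueError):
        radial_distribution(Frame.capture(state))
    state2 = ParticleState.from_positions(np.random.default_rng(0).uniform(0, 5, (10, 3)))
    with pytest.raises(ValueError):
        radial_distribution(Frame.capture(state2), bin_width=2.0, r_max=1.0)


# -------------------------------------------------------- binned stress

def test_binned_stress_single_bin_normalization(pp):
    pos = np.random.default_rng(4).uniform(0, 1.5, (20, 3))
    frame = Frame.capture(ParticleState.from_positions(pos))
    field = spatial_bin_stress(frame, np.full(20, -3.0e-18), axis=0, bin_size=2.0)
    assert field.mean.shape == (1,)
    assert field.mean[0] == pytest.approx(-3.0e-18)
    assert field.normalized[0] == pytest.approx(-1.0)   # sign preserved


def test_binned_stress_empty_bins_flagged(pp):
    pos = np.array([[0.5, 0, 0], [8.5, 0, 0], [8.6, 0.2, 0.1]])
    frame = Frame.capture(ParticleState.from_positions(pos))
    field = spatial_bin_stress(frame, np.array([1.0e-18, 2e-18, 2e-18]),
                               axis=0, bin_size=1.0)
    assert np.isnan(field.mean[2])                      # gap bin flagged
    assert np.nanmax(np.abs(field.normalized)) == pytest.approx(1.0)


def test_binned_stress_excludes_nucleus(pp):
    pos = np.array([[0.1, 0, 0], [0.2, 0, 0], [0.3, 0, 0]])
    types = np.array([0, 0, 1], dtype=np.int8)
    frame = Frame.capture(ParticleState.from_positions(pos, type_id=types))
    field = spatial_bin_stress(frame, np.array([1e-18, 3e-18, 100e-18]),
                               axis=0, bin_size=1.0)
    assert field.mean[0] == pytest.approx(2e-18)        # nucleus value ignored


def test_binned_stress_2d(pp):
    pos = np.random.default_rng(5).uniform(0, 4, (200, 3))
    frame = Frame.capture(ParticleState.from_positions(pos))
    field = spatial_bin_stress(frame, np.ones(200) * 1e-18, axis=(0, 1),
                               bin_size=2.0)
    assert field.mean.shape == (2, 2)
    assert np.allclose(field.normalized[np.isfinite(field.normalized)], 1.0)


# ---------------------------------------------------------- contact area

def test_contact_area_square_and_dilation(pp):
    pos = np.array([[0.0, 0, 5], [10.0, 0, 5], [10.0, 10, 5], [0.0, 10, 5]])
    area = slab_contact_area(pos, np.arange(4), load_axis=2, margin=0.0)
    assert area == pytest.approx(100.0)
    m = pp.d_eq / 2
    dilated = slab_contact_area(pos, np.arange(4), load_axis=2, margin=m)
    assert dilated == pytest.approx(100.0 + 40.0 * m + np.pi * m**2)


def test_contact_area_errors(pp):
    with pytest.raises(ValueError):
        slab_contact_area(np.zeros((4, 3)), np.array([], dtype=int))
    collinear = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
    with pytest.raises(ValueError):
        slab_contact_area(collinear, np.arange(4), load_axis=2)


def test_contact_area_cylindrical_plug_sanity(pp):
    """Top slab of a dense cylindrical plug: projected hull area within 20 %
    of the disk pi R_contact^2 spanned by the slab particles."""
    rng = np.random.default_rng(11)
    n = 2000
    r = 8.0 * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([r * np.cos(th), r * np.sin(th),
                           rng.uniform(0, 15.0, n)])
    slab = np.flatnonzero(pos[:, 2] >= 13.5)
    area = slab_contact_area(pos, slab, load_axis=2, margin=pp.d_eq / 2)
    r_contact = np.linalg.norm(pos[slab, :2], axis=1).max() + pp.d_eq / 2
    assert area == pytest.approx(np.pi * r_contact**2, rel=0.20)


# ----------------------------------------------------------- cell metrics

def _traj_from_positions(list_of_pos, pp, type_id=None):
    traj = Trajectory()
    for k, pos in enumerate(list_of_pos):
        st = ParticleState.from_positions(np.asarray(pos, float),
                                          type_id=type_id, time=float(k))
        traj.frames.append(Frame.capture(st))
    return traj


def test_cell_metrics_reference_and_rigid_shift(pp):
    rng = np.random.default_rng(6)
    pos = rng.uniform(0, 9, (50, 3))
    traj = _traj_from_positions([pos, pos + np.array([2.0, 1.0, -3.0])], pp)
    df = cell_level_metrics(traj, d_eq=pp.d_eq, reference_index=0)
    first, second = df.iloc[0], df.iloc[1]
    assert first["eps_z"] == pytest.approx(0.0)
    assert first["volumetric_strain"] == pytest.approx(0.0)
    assert second["eps_z"] == pytest.approx(0.0, abs=1e-12)   # rigid shift
    assert second["volumetric_strain"] == pytest.approx(0.0, abs=1e-9)


def test_cell_metrics_isotropic_scaling(pp):
    rng = np.random.default_rng(7)
    pos = rng.uniform(0, 9, (80, 3))
    s = 1.3
    centroid = pos.mean(axis=0)
    scaled = centroid + s * (pos - centroid)
    traj = _traj_from_positions([pos, scaled], pp)
    df = cell_level_metrics(traj, d_eq=pp.d_eq, reference_index=0)
    assert df.iloc[1]["volumetric_strain"] == pytest.approx(s**3 - 1, rel=1e-9)


def test_cell_metrics_delta_nc(pp):
    pos = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 2.0, 0], [0, -2.0, 0],
                    [0.5, 0.5, 0.0]])
    types = np.array([0, 0, 0, 0, 1], dtype=np.int8)
    traj = _traj_from_positions([pos], pp, type_id=types)
    df = cell_level_metrics(traj, d_eq=pp.d_eq, reference_index=0)
    assert df.iloc[0]["delta_nc"] == pytest.approx(np.sqrt(0.5))
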