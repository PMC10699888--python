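"""Cell growth and division, free or inside a microfluidic channel.

A small mother cell (Np_ref = 60 for speed) grows by particle addition;
when its cytoplasmic count doubles, the nucleus duplicates and every
cytoplasmic particle is reassigned to the nearest nucleus, splitting the
cell.  The constrained variant confines growth to a cylindrical channel so
the forming tissue elongates axially.
"""

from semcell import CellModelParams, run_proliferation

params = CellModelParams()
for constrained in (False, True):
    res = run_proliferation(params, Np=60, seed=3, rounds=1, T_p=8.0,
                            constrained=constrained, channel_radius=12.0,
                            S=2.0, max_time=30.0)
    m = res.metrics.iloc[-1]
    label = "channel" if constrained else "free"
    print(f"{label:>8}: final cells = {res.info['final_cells']}, "
          f"particles = {int(m['n_particles'])}, "
          f"extent z = {m['extent_z']:.1f} um, x = {m['extent_x']:.1f} um")
    for ev in res.trajectory.events:
        if ev["event_type"] == "division":
            print(f"          division of cell {ev['cell_id']} at "
                  f"t = {ev['time']:.2f} s -> daughter {ev['daughter']}")
# Each division conserves cytoplasmic particles and increments the cell
# count; the channel steers the growing pair along its axis.
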