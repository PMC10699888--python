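"""Cell migration with and without active nuclear transport.

A 300-particle cell migrates by particle turnover (insert at the leading
edge, remove at the trailing edge).  Without a biasing force the nucleus
lags toward the trailing edge and Delta_nc (nucleus-to-centroid distance)
grows; with a strong centring spring (S) it stays near zero and the cell
travels further.
"""

import numpy as np

from semcell import CellModelParams, run_migration

params = CellModelParams()
for S, label in ((0.0, "no bias"), (3.0, "strong bias")):
    res = run_migration(params, Np=300, seed=2, T_m=20.0, T_sim=20.0, S=S)
    m = res.metrics
    tail = m[m.time >= 15.0]["delta_nc"].mean()
    print(f"{label:>12}: events={len(res.trajectory.events):4d}  "
          f"mean Delta_nc(15-20 s) = {tail:5.2f} um  "
          f"net displacement = {res.info['net_displacement']:5.1f} um  "
          f"path length = {res.info['path_length']:5.1f} um")
# Delta_nc saturates near the cell radius without bias; the biased nucleus
# stays centred and the cell covers more ground.
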