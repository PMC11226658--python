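"""Mobility subsets of a supercooled vertex-model tissue.

Runs one long thermal vertex-model trajectory, finds the cage time t* from
the peak of the non-Gaussian parameter, splits cells into the 10% most and
least mobile per t*-window, and compares the two subsets' shape statistics
against the universal scaling line.  (One seed; the test suite pools three.)
"""

import warnings

import numpy as np

from shapejam import dynamics as dy
from shapejam import shape_stats as ss
from shapejam import vertex_model as vm

curve = ss.universal_line()
p0, T, seed = 3.85, 0.015, 1
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    state = vm.init_tissue(100, seed=seed, params=vm.VMParams(T=0.0, p0=p0))
    state = vm.run(state, 1500, snapshot_stride=1500, seed=74).final_state
    state.params = vm.VMParams(T=T, p0=p0)
    state = vm.run(state, 6000, snapshot_stride=6000, seed=75).final_state
    vt = vm.run(state, 40000, snapshot_stride=50, seed=76)
    traj = vt.trajectory()
    lags = np.unique(np.geomspace(2, traj.n_frames * 0.6, 40).astype(int))
    cage = dy.cage_time(traj, lags=lags)
    fast, slow, window = dy.windowed_mobility_shape_stats(
        traj, vt.polygons, cage.t_star, fraction=0.10
    )

print(f"cage time t* = {cage.t_star:.1f}  (window of {window} snapshots)")
for name, (mean_ar, sd_ar) in (("fast", fast), ("slow", slow)):
    resid = sd_ar - curve.predict(mean_ar)
    print(f"{name}: AR-bar={mean_ar:.3f}  SD(AR)={sd_ar:.3f}  line residual={resid:+.4f}")
print(
    "\nFast cells are more elongated than slow ones and their shape\n"
    "variability sits below the universal line; at this desk scale the\n"
    "fast-slow residual difference itself is within noise (see the methods\n"
    "note), while the confinement mechanism behind it is demonstrated\n"
    "directly by examples/frozen_cluster.py."
)
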