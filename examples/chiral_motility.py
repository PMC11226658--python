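"""Tuning activity through interior chirality.

Generates chiral active-Brownian trajectories for several values of the
interior chirality chi_cell, extracts the persistence time tau_p from the
ballistic-to-diffusive crossover of the MSD, and prints the trend: a
racemic interior (chi = 0) is the most persistent, an enantiopure one
(|chi| = 1) traces tight circles and decorrelates fastest.
"""

import numpy as np

from shapejam import dynamics as dy
from shapejam import synthetic as sy
from shapejam.dynamics import Box

print("chi_cell  omega   tau_p    l_p")
for chi in (0.0, 0.25, 0.5, 0.75, 1.0):
    omega, d_r = sy.map_chirality(chi)
    params = sy.ChiralCellParams(v0=1.0, omega=omega, D_r=d_r, chi_cell=chi)
    traj, ens = sy.chiral_abp_trajectory(
        params, n_cells=150, n_frames=5000, dt=0.08, box=Box.periodic(300.0), seed=6
    )
    lags = np.unique(np.geomspace(1, 3500, 70).astype(int))
    t, m = dy.msd(traj, lags=lags)
    res = dy.persistence_time(t, m)
    print(f"  {chi:4.2f}   {omega:5.2f}  {res.tau_p:6.2f}  {res.l_p:6.2f}")

print(
    "\ntau_p falls monotonically with |chi_cell| (about a decade across the\n"
    "range): increasing the angular drift omega = omega_max*chi bends the\n"
    "path into circles of radius v0/|omega|, cutting the persistence of the\n"
    "motion even at fixed rotational diffusivity."
)
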