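import math
import warnings

import numpy as np
import pandas as pd
import pytest

from shapejam import dynamics as dy
from shapejam import shape_stats as ss
from shapejam import vertex_model as vm


@pytest.fixture(scope="session")
def small_tissue():
    """64-cell disordered tissue shared by read-only vertex-model tests."""
    return vm.init_tissue(64, seed=3, params=vm.VMParams(T=0.01))


@pytest.fixture(scope="session")
def hexagonal_tissue():
    """Perfect hexagonal tiling (disorder = 0)."""
    return vm.init_tissue(64, seed=0, disorder=0.0)


@pytest.fixture(scope="session")
def temperature_sweep():
    """Thermal vertex-model sweep: quench → thermalize → produce at four
    temperatures, two seeds each; pooled (AR̄, SD) and end-of-run MSD per T.

    Shared between the vertex-model unit tests (AR̄ monotone in T,
    two-temperature relaxation contrast) and the acceptance checks (points
    track the universal scaling line).
    """
    rows = []
    for T in (0.002, 0.005, 0.009, 0.02):
        pool = []
        msd_ends = []
        for seed in (1, 2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                st = vm.init_tissue(64, seed=seed, params=vm.VMParams(T=0.0))
                st = vm.run(st, 1500, snapshot_stride=1500, seed=seed * 17 + 1).final_state
                st.params = vm.VMParams(T=T)
                st = vm.run(st, 4000, snapshot_stride=4000, seed=seed * 17 + 2).final_state
                vt = vm.run(st, 4000, snapshot_stride=50, seed=seed * 17 + 3)
            pool.extend(
                ss.aspect_ratio(p, check_simple=False)
                for fr in vt.polygons.frames
                for p in fr.values()
            )
            traj = vt.trajectory()
            _, m = dy.msd(traj, lags=[traj.n_frames - 1])
            msd_ends.append(m[0])
        pool = np.asarray(pool)
        rows.append({
            "T": T,
            "mean_ar": float(pool.mean()),
            "sd_ar": float(pool.std(ddof=0)),
            "msd_end": float(np.mean(msd_ends)),
        })
    return pd.DataFrame(rows)


@pytest.fixture
def regular_polygon():
    def make(n: int, radius: float = 1.0) -> np.ndarray:
        a = 2 * math.pi * np.arange(n) / n
        return radius * np.column_stack([np.cos(a), np.sin(a)])

    return make
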