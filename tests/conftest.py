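import numpy as np
import pytest

from sptfit import (
    AcquisitionSettings,
    benchmark_config,
    build_histograms,
    compute_displacements,
    load_default_table,
    simulate_dataset,
)
from sptfit.empirical import TrajectorySet


@pytest.fixture(scope="session")
def coeffs():
    """Shipped defocalization-coefficient table (auto-calibrates off-grid)."""
    table = load_default_table()
    table.auto_calibrate = True
    table.calibration.n_particles = 20_000
    return table


def make_ts(records, dt=0.01):
    """TrajectorySet from [(traj, frame, x, y), ...] tuples."""
    if not records:
        return TrajectorySet(
            codes=np.array([], dtype=np.int64),
            frames=np.array([], dtype=np.int64),
            x=np.array([]), y=np.array([]), dt=dt,
        )
    arr = np.array(records, dtype=float)
    ids = arr[:, 0].astype(np.int64)
    uniq, codes = np.unique(ids, return_inverse=True)
    return TrajectorySet(
        codes=codes, frames=arr[:, 1].astype(np.int64),
        x=arr[:, 2], y=arr[:, 3], dt=dt, labels=uniq,
    )


@pytest.fixture(scope="session")
def sim_reference(coeffs):
    """Reference benchmark condition: D_free=2, F_bound=0.7, 7 ms frames.

    Simulated once per session and shared; 20,000 in-focus trajectories.
    """
    cfg = benchmark_config(2.0, 0.70, 0.007, target_trajectories=20_000, seed=42)
    res = simulate_dataset(cfg)
    ts = res.trajectories
    disp = compute_displacements(ts, 7, jumps_per_traj=None)
    hist = build_histograms(disp, bin_width=0.01, r_max=6.0, dt=0.007)
    settings = AcquisitionSettings(dt=0.007, dz=0.7, gaps=1, n_lags=7)
    return {"result": res, "ts": ts, "hist": hist, "settings": settings,
            "d_free": 2.0, "f_bound": 0.70}


def mc_p_remaining(dt_total, dz, d, n=100_000, substeps=100, seed=0):
    """Continuous-absorption Monte Carlo oracle for the slab survival.

    Walkers take Gaussian substeps; absorption uses the exact Brownian-bridge
    boundary-crossing probability between substeps, so the discretization
    bias of naive position checks (which overestimates survival) is removed.
    Independent of the erfc-series implementation under test.
    """
    rng = np.random.default_rng(seed)
    half = dz / 2
    z = rng.uniform(-half, half, n)
    w = np.ones(n)
    sub = dt_total / substeps
    var = 2 * d * sub
    for _ in range(substeps):
        z1 = z + rng.normal(0, np.sqrt(var), n)
        dead = np.abs(z1) > half
        w[dead] = 0.0
        inside = ~dead
        for bnd in (half, -half):
            p_cross = np.exp(-2 * np.clip((bnd - z) * (bnd - z1), 0, None) / var)
            w[inside] *= 1 - p_cross[inside]
        z = z1
    return float(w.mean())
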