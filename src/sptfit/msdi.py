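"""Per-trajectory MSD analysis: the classic baseline the jump-model fit is
compared against.

Each trajectory of at least ``min_len`` localizations gets a time-averaged
mean-square displacement curve over the first few lags; a straight line
``MSD(tau) = 4 D tau + c`` fitted to it yields one diffusion-constant
estimate per trajectory. The population is then summarized by fitting a
two-component Gaussian mixture to ``log10(D_hat)``: the weight of the
slower component estimates the bound fraction, the mean of the faster
component the free diffusion constant. An optional R^2 filter on the MSD
line fit reproduces the commonly used quality threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .empirical import TrajectorySet

__all__ = [
    "MsdEstimate",
    "MsdiPopulationFit",
    "msd_per_trajectory",
    "msdi_population_fit",
]

#: floor applied to per-trajectory D before taking logs (um^2/s)
D_FLOOR = 1e-5


@dataclass
class MsdEstimate:
    trajectory: int
    d_hat: float
    r2: float
    n_points: int


@dataclass
class MsdiPopulationFit:
    """Two-component summary of the per-trajectory D distribution."""

    f_bound: float
    d_free: float
    n_used: int
    frac_used: float
    degenerate: bool
    means_log10: tuple = (np.nan, np.nan)
    weights: tuple = (np.nan, np.nan)
    method: str = "gmm"


def msd_per_trajectory(
    ts: TrajectorySet,
    min_len: int = 5,
    n_msd_lags: int = 4,
) -> list[MsdEstimate]:
    """Time-averaged MSD line fits per qualifying trajectory.

    Trajectories shorter than ``min_len`` localizations are skipped. The MSD
    at lag ``k`` averages squared displacements over all record pairs with
    frame difference ``k``; the line fit uses lags ``1..n_msd_lags`` (those
    with data). ``d_hat`` is slope/4, floored at a small positive value.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3 for a meaningful line fit")
    if ts.n_localizations == 0:
        return []
    codes, frames, x, y = ts.codes, ts.frames, ts.x, ts.y
    n_traj = int(codes.max()) + 1
    lengths = np.bincount(codes, minlength=n_traj)
    qualify = lengths >= min_len

    sums = np.zeros((n_traj, n_msd_lags))
    counts = np.zeros((n_traj, n_msd_lags), dtype=np.int64)
    for k in range(1, n_msd_lags + 1):
        for j in range(1, k + 1):
            if j >= codes.size:
                break
            m = (codes[j:] == codes[:-j]) & (frames[j:] - frames[:-j] == k)
            if not np.any(m):
                continue
            i = np.flatnonzero(m)
            sq = (x[i + j] - x[i]) ** 2 + (y[i + j] - y[i]) ** 2
            np.add.at(sums[:, k - 1], codes[i], sq)
            np.add.at(counts[:, k - 1], codes[i], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        msd = sums / counts  # (n_traj, L)
    taus = ts.dt * np.arange(1, n_msd_lags + 1)

    # vectorized weighted (mask) linear regression msd = s*tau + c per traj
    mask = (counts > 0) & qualify[:, None]
    w = mask.astype(float)
    nw = w.sum(axis=1)
    ok = qualify & (nw >= 2)
    tx = np.where(mask, taus[None, :], 0.0)
    ty = np.where(mask, np.nan_to_num(msd), 0.0)
    sx = tx.sum(axis=1)
    sy = ty.sum(axis=1)
    sxx = (tx * tx).sum(axis=1)
    sxy = (tx * ty).sum(axis=1)
    denom = nw * sxx - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (nw * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / nw
        pred = slope[:, None] * tx + intercept[:, None]
        ss_res = (w * (ty - pred) ** 2).sum(axis=1)
        ss_tot = (w * (ty - (sy / nw)[:, None]) ** 2).sum(axis=1)
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot <= 0, np.where(ss_res <= 1e-30, 1.0, -np.inf), r2)

    estimates = []
    for t in np.flatnonzero(ok):
        estimates.append(
            MsdEstimate(
                trajectory=int(t),
                d_hat=float(max(slope[t] / 4.0, D_FLOOR)),
                r2=float(r2[t]),
                n_points=int(lengths[t]),
            )
        )
    return estimates


def msdi_population_fit(
    estimates: list[MsdEstimate],
    r2_min: float | None = None,
    d_split_init: float = 0.1,
    seed: int = 0,
    method: str = "gmm",
) -> MsdiPopulationFit:
    """Summarize per-trajectory D estimates as (F_bound, D_free).

    ``r2_min=None`` is the "(all)" variant; otherwise only estimates with
    ``r2 >= r2_min`` survive. The default fit is a two-component Gaussian
    mixture on ``log10(D_hat)`` initialized around ``d_split_init``; a
    threshold split at ``d_split_init`` is available as ``method='threshold'``.
    """
    n_total = len(estimates)
    if n_total == 0:
        raise ValueError("no MSD estimates supplied")
    kept = [e for e in estimates if r2_min is None or e.r2 >= r2_min]
    n_used = len(kept)
    if n_used < 2:
        raise ValueError(
            f"fewer than 2 estimates survive the R^2 filter ({n_used}/{n_total})"
        )
    logd = np.log10(np.maximum([e.d_hat for e in kept], D_FLOOR))

    if method == "threshold":
        split = np.log10(d_split_init)
        low = logd < split
        f_bound = float(low.mean())
        d_free = float(10 ** logd[~low].mean()) if np.any(~low) else np.nan
        return MsdiPopulationFit(
            f_bound=f_bound, d_free=d_free, n_used=n_used,
            frac_used=n_used / n_total, degenerate=not np.any(~low),
            method="threshold",
        )

    from sklearn.mixture import GaussianMixture

    split = np.log10(d_split_init)
    init = np.array([[split - 1.5], [split + 1.5]])
    gm = GaussianMixture(
        n_components=2, random_state=seed, means_init=init, n_init=1,
        covariance_type="full", reg_covar=1e-4,
    ).fit(logd[:, None])
    means = gm.means_.ravel()
    weights = gm.weights_.ravel()
    slow = int(np.argmin(means))
    fast = 1 - slow
    degenerate = abs(means[fast] - means[slow]) < 0.2 or weights.min() < 1e-3
    return MsdiPopulationFit(
        f_bound=float(weights[slow]),
        d_free=float(10 ** means[fast]),
        n_used=n_used,
        frac_used=n_used / n_total,
        degenerate=bool(degenerate),
        means_log10=(float(means[slow]), float(means[fast])),
        weights=(float(weights[slow]), float(weights[fast])),
        method="gmm",
    )
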