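"""Steady-state Brownian trajectory simulator for SPT benchmarking.

Emulates a typical nuclear SPT experiment under highly inclined (HiLo)
illumination: a mixture of diffusing subpopulations inside a reflecting
sphere (the nucleus), a laser slab that sets the photobleaching rate (mean
lifetime ``life_in`` frames inside the beam, ``life_out`` outside), an axial
detection window of thickness ``dz`` with Gaussian edges, localization noise
on every detected position, and a tracker that bridges up to ``gaps`` missed
frames. Detected runs of at least ``min_traj_len`` localizations become
output trajectories, until ``target_trajectories`` in-focus trajectories
have been collected.

Default geometry matches the 2-state benchmark conditions: 4 um nucleus
radius, 4 um beam width (2 um half-width), 0.7 um detection range, lifetimes
4/40 frames, 25 nm localization error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .empirical import TrajectorySet

__all__ = [
    "SimConfig",
    "SimResult",
    "axial_detection_probability",
    "reflect_sphere",
    "simulate_dataset",
    "benchmark_config",
]

#: lifetimes are truncated at this many mean lifetimes (survival ~ e^-30)
LIFETIME_CAP_FACTOR = 30


@dataclass
class SimConfig:
    """Simulator settings; all lengths in um, times in seconds or frames."""

    populations: list  # (diffusion um^2/s, fraction) pairs
    dt: float
    radius: float = 4.0
    beam_halfwidth: float = 2.0
    dz: float = 0.7
    edge_sigma: float = 0.02
    life_in: float = 4.0  # mean lifetime (frames) inside the beam
    life_out: float = 40.0  # mean lifetime (frames) outside the beam
    sigma_loc: float = 0.025
    gaps: int = 1
    target_trajectories: int = 100_000
    min_traj_len: int = 2
    lifetime_mode: str = "hazard"  # 'hazard': per-frame bleaching hazard
    # re-evaluated from the current beam occupancy; 'birth': drawn once at
    # birth from the mean set by the birth position
    max_frames: int | None = None  # truncate every particle's history at
    # this frame count (diagnostics); None uses the lifetime-based cap
    seed: int = 0

    def __post_init__(self) -> None:
        fr = sum(f for _, f in self.populations)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"population fractions must sum to 1, got {fr}")
        if any(d < 0 or f < 0 for d, f in self.populations):
            raise ValueError("diffusion constants and fractions must be >= 0")
        if self.radius <= self.dz / 2:
            raise ValueError("radius must exceed dz/2")
        if min(self.dt, self.life_in, self.life_out) <= 0:
            raise ValueError("dt and lifetimes must be positive")
        if self.sigma_loc < 0 or self.edge_sigma < 0:
            raise ValueError("sigma_loc and edge_sigma must be >= 0")
        if self.min_traj_len < 1 or self.target_trajectories < 1:
            raise ValueError("min_traj_len and target_trajectories must be >= 1")
        if self.lifetime_mode not in ("birth", "hazard"):
            raise ValueError("lifetime_mode must be 'birth' or 'hazard'")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = [[float(a), float(b)] for a, b in self.populations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["populations"] = [tuple(p) for p in d["populations"]]
        return cls(**d)


@dataclass
class SimResult:
    """Detected in-focus trajectories plus per-trajectory ground truth."""

    trajectories: TrajectorySet
    ground_truth: pd.DataFrame  # trajectory, population, d_true
    config: SimConfig
    n_particles_simulated: int = 0
    n_particle_frames: int = 0
    n_detections: int = 0

    def write(self, traj_path, truth_path, meta_path=None) -> None:
        self.trajectories.to_csv(traj_path)
        self.ground_truth.to_csv(truth_path, index=False)
        if meta_path is not None:
            meta = {
                "config": self.config.as_dict(),
                "n_particles_simulated": self.n_particles_simulated,
                "n_trajectories": self.trajectories.n_trajectories,
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def benchmark_config(
    d_free: float,
    f_bound: float,
    dt: float,
    d_bound: float = 0.001,
    **overrides,
) -> SimConfig:
    """2-state benchmark condition with the standard nuclear geometry."""
    return SimConfig(
        populations=[(d_bound, f_bound), (d_free, 1.0 - f_bound)],
        dt=dt,
        **overrides,
    )


def axial_detection_probability(z, dz: float, edge_sigma: float):
    """Detection probability profile: 1 inside the slab, Gaussian edges outside.

    ``edge_sigma = 0`` reduces to a step profile.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if edge_sigma < 0:
        raise ValueError("edge_sigma must be >= 0")
    z = np.asarray(z, dtype=float)
    excess = np.abs(z) - dz / 2.0
    if edge_sigma == 0:
        return np.where(excess <= 0, 1.0, 0.0)
    pos_excess = np.maximum(excess, 0.0)
    return np.exp(-(pos_excess**2) / (2.0 * edge_sigma**2))


def reflect_sphere(p, radius: float):
    """Mirror positions outside a sphere across its boundary (radially).

    ``p`` has shape (..., 3). Displacements are assumed small relative to the
    radius; a warning is emitted if any point lies beyond 2x the radius
    (where a single specular reflection is no longer geometrically sensible).
    """
    p = np.asarray(p, dtype=float)
    r = np.sqrt(np.sum(p * p, axis=-1))
    outside = r > radius
    if not np.any(outside):
        return p
    if np.any(r > 2 * radius):
        warnings.warn("displacement comparable to sphere radius; reflection crude")
    scale = np.ones_like(r)
    rs = r[outside]
    scale[outside] = np.clip(2 * radius - rs, 1e-12, None) / rs
    return p * scale[..., None]


def _uniform_in_ball(rng, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * np.cbrt(rng.random(n))
    return v * r[:, None]


def _simulate_batch(cfg: SimConfig, rng, n: int):
    """Simulate n particles; return (pid, frame, x, y, pop) of detections."""
    d_vals = np.array([d for d, _ in cfg.populations])
    fracs = np.array([f for _, f in cfg.populations])
    pop = rng.choice(len(d_vals), size=n, p=fracs)
    pos = _uniform_in_ball(rng, n, cfg.radius)
    sd = np.sqrt(2.0 * d_vals[pop] * cfg.dt)  # per-coordinate step SD

    idx = np.arange(n)  # global particle index of the alive set
    t_cap = int(LIFETIME_CAP_FACTOR * max(cfg.life_in, cfg.life_out))
    if cfg.max_frames is not None:
        t_cap = min(t_cap, cfg.max_frames - 1)
    rec_pid, rec_frame, rec_x, rec_y = [], [], [], []

    if cfg.lifetime_mode == "birth":
        # lifetime (frames) drawn once, mean set by the birth position
        mean_life = np.where(np.abs(pos[:, 2]) <= cfg.beam_halfwidth,
                             cfg.life_in, cfg.life_out)
        life = np.minimum(
            rng.geometric(1.0 / mean_life), t_cap
        )
    else:
        life = None

    frame = 0
    n_particle_frames = 0
    n_detections = 0
    while idx.size and frame <= t_cap:
        z = pos[:, 2]
        n_particle_frames += idx.size
        # detection draw at the current frame
        pdet = axial_detection_probability(z, cfg.dz, cfg.edge_sigma)
        det = rng.random(idx.size) < pdet
        n_detections += int(det.sum())
        if np.any(det):
            rec_pid.append(idx[det].copy())
            rec_frame.append(np.full(det.sum(), frame, dtype=np.int32))
            rec_x.append(pos[det, 0].copy())
            rec_y.append(pos[det, 1].copy())
        if cfg.lifetime_mode == "birth":
            survive = life > frame + 1
        else:
            # per-frame hazard from the current beam occupancy
            hazard = np.where(np.abs(z) <= cfg.beam_halfwidth,
                              1.0 / cfg.life_in, 1.0 / cfg.life_out)
            survive = rng.random(idx.size) >= hazard
        idx, pos, sd = idx[survive], pos[survive], sd[survive]
        if life is not None:
            life = life[survive]
        if not idx.size:
            break
        # Brownian step with specular reflection at the nuclear envelope
        pos = pos + rng.standard_normal(pos.shape) * sd[:, None]
        pos = reflect_sphere(pos, cfg.radius)
        frame += 1

    counters = (n_particle_frames, n_detections)
    if not rec_pid:
        empty = np.array([], dtype=np.int64)
        return empty, empty, np.array([]), np.array([]), pop, counters
    pid = np.concatenate(rec_pid).astype(np.int64)
    frames = np.concatenate(rec_frame).astype(np.int64)
    xs = np.concatenate(rec_x)
    ys = np.concatenate(rec_y)
    if cfg.sigma_loc > 0:
        xs = xs + rng.normal(0.0, cfg.sigma_loc, xs.size)
        ys = ys + rng.normal(0.0, cfg.sigma_loc, ys.size)
    # order by (particle, frame); frames were appended in time order
    order = np.lexsort((frames, pid))
    return pid[order], frames[order], xs[order], ys[order], pop, counters


def _split_runs(pid, frames, gaps: int):
    """Run id per detection; a gap longer than ``gaps`` frames splits a run."""
    if pid.size == 0:
        return np.array([], dtype=np.int64)
    new_run = np.r_[
        True,
        (pid[1:] != pid[:-1]) | (frames[1:] - frames[:-1] > gaps + 1),
    ]
    return np.cumsum(new_run) - 1


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Run the simulator until ``cfg.target_trajectories`` in-focus
    trajectories (detected runs of >= ``min_traj_len`` localizations) are
    collected. Fully reproducible for a fixed config + seed.
    """
    rng = np.random.default_rng(cfg.seed)
    batch = max(20_000, cfg.target_trajectories)
    parts = []  # (codes, frames, x, y, pop_per_run)
    total_runs = 0
    total_particles = 0
    stalled = 0
    total_frames = 0
    total_detections = 0
    while total_runs < cfg.target_trajectories:
        pid, frames, xs, ys, pop, counters = _simulate_batch(cfg, rng, batch)
        total_particles += batch
        total_frames += counters[0]
        total_detections += counters[1]
        run = _split_runs(pid, frames, cfg.gaps)
        if run.size:
            counts = np.bincount(run)
            keep_run = counts >= cfg.min_traj_len
            keep = keep_run[run]
            run_kept, codes = np.unique(run[keep], return_inverse=True)
            n_new = run_kept.size
        else:
            n_new = 0
        if n_new == 0:
            stalled += 1
            if stalled >= 5:
                raise RuntimeError(
                    "simulation makes no progress: no detected runs of length "
                    f">= {cfg.min_traj_len} after {total_particles} particles; "
                    "check the geometry (dz vs radius) and detection settings"
                )
            continue
        stalled = 0
        first_det = np.r_[True, np.diff(run[keep]) != 0]
        run_pop = pop[pid[keep][first_det]]
        parts.append((codes, frames[keep], xs[keep], ys[keep], run_pop))
        total_runs += n_new
        # size the next batch from the observed yield
        if total_runs < cfg.target_trajectories:
            yield_rate = total_runs / total_particles
            need = cfg.target_trajectories - total_runs
            batch = int(np.clip(need / max(yield_rate, 1e-6) * 1.15,
                                10_000, 2_000_000))

    # concatenate and truncate to exactly the target, in generation order
    offset = 0
    codes_all, frames_all, x_all, y_all, pop_all = [], [], [], [], []
    for codes, frames, xs, ys, run_pop in parts:
        codes_all.append(codes + offset)
        frames_all.append(frames)
        x_all.append(xs)
        y_all.append(ys)
        pop_all.append(run_pop)
        offset += run_pop.size
    codes = np.concatenate(codes_all)
    keep = codes < cfg.target_trajectories
    codes = codes[keep]
    ts = TrajectorySet(
        codes=codes,
        frames=np.concatenate(frames_all)[keep],
        x=np.concatenate(x_all)[keep],
        y=np.concatenate(y_all)[keep],
        dt=cfg.dt,
    )
    pop_per_run = np.concatenate(pop_all)[: cfg.target_trajectories]
    d_vals = np.array([d for d, _ in cfg.populations])
    truth = pd.DataFrame(
        {
            "trajectory": np.arange(cfg.target_trajectories),
            "population": pop_per_run,
            "d_true": d_vals[pop_per_run],
        }
    )
    return SimResult(
        trajectories=ts,
        ground_truth=truth,
        config=cfg,
        n_particles_simulated=total_particles,
        n_particle_frames=total_frames,
        n_detections=total_detections,
    )
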