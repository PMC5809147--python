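# sptfit

Kinetic modeling of single-particle tracking (SPT) data: infer the bound
fraction and diffusion constants of molecular subpopulations from pooled 2D
trajectories by fitting defocalization-corrected jump-length distribution
models, together with a steady-state trajectory simulator and a
per-trajectory MSD baseline for benchmarking.

## The problem

Live-cell SPT follows individual fluorescently labeled molecules — for
example transcription factors that alternate between a chromatin-bound,
quasi-immobile state and free 3D diffusion. Pooling the 2D displacements
`r` between localizations separated by lag `kΔτ` gives jump-length
histograms whose shape encodes the subpopulation mix. For Brownian motion
with diffusion constant `D` and static localization error `σ`, the
jump-length density at lag `t` is Rayleigh,

    p(r) = r / (2u) · exp(−r²/4u),   u = D·t + σ²,

and the 2-state model is

    P₂(r, kΔτ) = F_bound · p_bound(r) + Z_k · (1 − F_bound) · p_free(r),

renormalized per lag. The factor `Z_k` is the crux: fast molecules diffuse
out of the finite axial detection range `Δz` (~700 nm in HiLo microscopy),
so later lags are depleted of free molecules, and without a correction the
bound fraction is grossly overestimated. `Z_k` is the absorbing-slab
survival probability (an erfc series averaged over the slab) evaluated at a
Monte Carlo-calibrated corrected slab thickness
`Δz_corr = Δz + a·√D + b`, which accounts for molecules that briefly
defocalize and re-enter within the tracker's gap tolerance `g`. A shipped
coefficient table covers Δz 0.5–1.0 µm, Δτ 1–30 ms, g 0–2; other settings
are calibrated on the fly. Full model details: [docs/methods.md](docs/methods.md).

The package provides, as importable modules and a `sptfit` command:

- `model_core` — the semi-analytical 2-/3-state models and slab survival;
- `defocal` — Monte Carlo calibration of `(a, b)` and the coefficient table;
- `empirical` — trajectory CSV I/O, displacement histograms, dataset metadata;
- `fitting` — constrained multi-start least squares (PDF or CDF mode),
  optional localization-error inference;
- `simulate` — a steady-state simulator of nuclear SPT experiments
  (reflecting spherical nucleus, HiLo beam-dependent photobleaching,
  Gaussian-edged axial detection, localization noise, gap-tolerant tracking);
- `msdi` — the per-trajectory MSD baseline;
- `cli` — the command-line interface and the simulation-benchmark harness.

## Worked example

Simulate a benchmark-style experiment — 70% bound molecules
(D = 0.001 µm²/s) and 30% free at D = 2 µm²/s, 7 ms frames, 20,000
in-focus trajectories in a 4 µm nucleus — then fit the 2-state model:

```sh
$ cat demo.yaml
populations:
- [0.001, 0.7]
- [2.0, 0.3]
dt: 0.007
radius: 4.0
target_trajectories: 20000
seed: 7

$ sptfit simulate demo.yaml -o demo_sim --seed 7
wrote 20000 trajectories (91676 localizations) to demo_sim

$ sptfit fit demo_sim/trajectories.csv --sigma 0.025 --jumps-per-traj 999 -o demo_fit
sptfit 0.1.0 fit report
inputs: demo_sim/trajectories.csv
frame interval: 7.000 ms; lags: 1..7
dataset: 20000 trajectories, 91676 localizations, mean length 4.58 frames
jumps per lag: [70449, 51555, 37572, 27460, 20140, 14803, 10855]
model: 2-state, CDF fit
D_bound = 0.00095 um^2/s
D_free = 1.9258 um^2/s
F_bound = 67.50 %
sigma = 25.0 nm (fixed)
objective (RSS) = 0.00173744
```

The fit recovers the planted bound fraction within 2.5 points and the free
diffusion constant within 4% (the small underestimate is the apparent-
diffusion effect of nuclear confinement). `demo_fit/` also contains the
full fit JSON (parameters, restarts, settings, seed) and per-lag
empirical/model histogram curves as CSV. `sptfit validate` runs grids of
such conditions and summarizes bias/std/iqr per method, including the MSD
baselines (`--methods jld,msd_all,msd_r2`).

Typical library use mirrors the CLI:

```python
from sptfit import (TrajectorySet, AcquisitionSettings, FitSpec,
                    compute_displacements, build_histograms, fit_model,
                    load_default_table)

ts = TrajectorySet.from_csv("demo_sim/trajectories.csv", dt=0.007)
hist = build_histograms(compute_displacements(ts, n_lags=7, jumps_per_traj=None),
                        bin_width=0.01, r_max=6.0, dt=ts.dt)
fit = fit_model(hist, AcquisitionSettings(dt=0.007, dz=0.7, gaps=1, n_lags=7),
                FitSpec(mode="cdf", fixed_sigma=0.025), load_default_table())
print(fit.params.f_bound, fit.params.d_free)
```

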