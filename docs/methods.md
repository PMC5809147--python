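# Methods

## The model

`sptfit` infers the composition of a mixed molecular population — a
quasi-immobile ("bound") fraction and one or two freely diffusing
fractions — from pooled single-particle tracking (SPT) trajectories. The
data enter as histograms of 2D jump lengths `r` at increasing lag times
`Δτ, 2Δτ, …`. For ideal Brownian motion with diffusion constant `D`,
localization error `σ` (per coordinate) inflates the apparent scale, and
the jump-length density at lag `t` is the Rayleigh form

    p(r) = r / (2u) · exp(−r² / 4u),    u = D·t + σ².

The 2-state model is a weighted sum of a bound term (`D_bound`, weight
`F_bound`) and a free term (`D_free`, weight `1 − F_bound`); the 3-state
model adds a second mobile term with the convention `D_slow ≤ D_fast`.

### Defocalization correction

Fast molecules leave the finite axial detection range `Δz` (they
"defocalize"), so later lags are progressively depleted of free molecules.
Treating the detection slab as absorbing at `±Δz/2` and averaging over a
uniform initial axial position gives the surviving fraction

    P_remaining(t, Δz, D) = 1/Δz ∫ dz [1 − Σₙ (−1)ⁿ (erfc(((2n+1)Δz/2 − z)/√(4Dt))
                                             + erfc(((2n+1)Δz/2 + z)/√(4Dt)))].

Pure absorption is pessimistic: a molecule that briefly leaves the slab can
re-enter before the tracker terminates the trajectory (the tracker bridges
up to `g` missed frames). This is absorbed into a *corrected* slab
thickness

    Δz_corr = Δz + a·√D + b,

with `(a, b)` estimated per `(Δz, Δτ, g)` by Monte Carlo: molecules are
placed uniformly in the slab, take Euler–Maruyama steps of per-frame
variance `2DΔτ`, and survive delay `k` if they never spent more than `g`
consecutive observation frames outside the slab and are inside at frame
`k`; `(a, b)` minimize the squared difference between
`P_remaining(kΔτ, Δz_corr, D)` and the simulated fractions jointly over
`D = 1..12 µm²/s` and delays `1..15`. The `√D` form is dimensionally
forced: axial excursions scale as `√(DΔτ)`, and for the gapless case the
fitted `a` agrees with the classical discrete-observation boundary-shift
`2·0.5826·√(2Δτ)` within a few percent.

Each diffusive mixture term at lag `k` is multiplied by
`Z_k = P_remaining(kΔτ, Δz_corr(D), D)`; the bound term carries no factor
(its axial motion over ≤15 frames is negligible). Both the model and the
empirical histograms are renormalized per lag, so the correction acts as a
lag-dependent reweighting of bound vs free — the information that makes the
bound fraction identifiable even when absolute counts are unusable
(photobleaching affects all lags). A joint-across-lags normalization is
implemented (`renormalize="joint"`) but not used by default.

### Accuracy of the correction family

The single-`(a, b)` absorbing family is an approximation with a known
structural limit: at delay 1 the true gap-tolerant survival is a free
two-point probability (no absorption can have occurred yet), which no
absorbing-slab curve can match simultaneously with the later delays. The
joint fit residual is 1–4% RMS over the calibration grid (stored per entry
in the shipped table), smallest at short frame intervals and growing with
`√(2DΔτ)/Δz`. Consequences for inference are quantified under
*Limitations*.

## Numerical choices

- The `z` integral uses midpoint quadrature with 200 nodes; the alternating
  erfc series is summed in pairs until the largest pair falls below 1e-10,
  with a hard cap of 1e4 terms.
- Per-bin model mass is the density at the bin midpoint times the bin
  width; at the default 10 nm bins the difference from exact integration is
  negligible.
- Fits minimize unweighted least squares over all lags and bins, either on
  per-bin mass (PDF mode) or its running sum (CDF mode, default). Bounded
  trust-region least squares (`scipy.optimize.least_squares`, `trf`) with
  ftol = xtol = 1e-8 and at most 1000 evaluations; initial guesses are
  drawn uniformly from the parameter ranges and the best of `n_restarts`
  (default 3) converged restarts is reported. Fractions live on the simplex
  by construction: the 2-state model fits `F_bound ∈ [0, 1]`, the 3-state
  model uses stick-breaking `F_slow = (1 − F_bound)·u, u ∈ [0, 1]`, and
  3-state labels are swapped after fitting if needed so `D_slow ≤ D_fast`.
- The shipped coefficient table covers Δz 0.5–1.0 µm (step 0.05), Δτ 1–30 ms
  (step 1 ms), g ∈ {0, 1, 2}, calibrated with 20,000 walkers per condition
  (fit noise well below the family's structural residual); off-grid settings
  are calibrated on the fly (50,000 walkers) and cached. The `(a, b)`
  objective has a single basin over the bounded region, so one start is
  used (verified against multi-start).
- The localization error can be fitted as one shared parameter
  (bounds 5–100 nm). The estimate reflects the *static* error of the bound
  subpopulation and is flagged unreliable when the fitted bound fraction is
  below 5% or converged restarts disagree by more than 5 nm.

## The trajectory simulator

The generator emulates a nuclear spaSPT experiment under HiLo illumination
at steady state. Defaults are the benchmark conditions used throughout:

| parameter | default | meaning |
|---|---|---|
| radius | 4 µm | reflecting spherical nucleus |
| beam_halfwidth | 2 µm | illumination slab half-thickness (z) |
| dz | 0.7 µm | axial detection range |
| edge_sigma | 0.02 µm | Gaussian fall-off of detection beyond ±dz/2 |
| life_in / life_out | 4 / 40 frames | mean lifetime inside/outside the beam |
| sigma_loc | 25 nm | localization error per coordinate |
| d_bound | 0.001 µm²/s | bound-state diffusion (benchmark helper) |
| gaps | 1 | missed frames the tracker bridges |
| min_traj_len | 2 | localizations needed to emit a trajectory |

Particles are assigned to populations by their fractions, initialized
uniformly in the sphere (the steady-state law), stepped with per-coordinate
Gaussian increments `N(0, 2DΔτ)`, and mirrored back across the boundary
when they leave the sphere. Detection each frame is Bernoulli with
probability 1 inside the slab and a Gaussian tail of scale `edge_sigma`
outside; localization noise is added per detected position. Photobleaching
is a per-frame hazard `1/life_in` or `1/life_out` by current beam
occupancy. Detected runs (with gap bridging) of at least `min_traj_len`
localizations become trajectories, until the target count is reached;
everything is reproducible from the seed.

Decisions where the geometry was under-determined:

- *Edge scale.* Only "Gaussian edges" on a 700 nm window is specified.
  The default is 0.02 µm: it keeps the effective (integrated) detection
  window within 3% of the nominal `Δz` that the fit assumes. With soft
  edges of 0.1 µm the effective window is ~0.95 µm and the fitted bound
  fraction is biased by −6 to −9 points purely by the detection/model
  mismatch — a mismatch experiment, not a benchmark of the estimator.
- *Lifetime semantics.* The per-frame hazard reproduces both stated mean
  lifetimes and handles beam crossings. Drawing one lifetime at birth from
  the birth-position mean was implemented (`lifetime_mode="birth"`) and
  rejected as a default: molecules born outside the beam then live ~40
  frames regardless of where they travel, and the pooled statistics
  over-represent free molecules by tens of points.
- *Confinement relaxation.* When the nuclear radius is scaled up to isolate
  confinement effects, the validation harness scales the beam half-width
  with it (beam = radius/2). Keeping a 2 µm beam inside a 20 µm nucleus
  changes the bleaching geometry instead: free molecules park outside the
  beam, pause their bleach clock, and re-enter, inflating the free pair
  counts (−11 points on `F_bound` at the fast extreme).

What the generator does **not** emulate: camera/PSF image formation, motion
blur during exposure, tracking errors from high densities, anomalous
diffusion, and state transitions. Passing benchmarks on these synthetic
data therefore show correctness of the estimator under the model's own
assumptions plus confinement, detection edges, and bleaching — not
robustness to every experimental pathology.

## Validation harness

`sptfit.cli.run_condition` simulates one benchmark condition and estimates
it with any of: the defocalization-corrected 2-state CDF fit (`jld`), the
same fit without the correction (`jld_nocorr`), and the per-trajectory MSD
baseline with or without an `R² > 0.8` filter (`msd_all`, `msd_r2`).
Errors follow the benchmark convention: relative for `D_free`, absolute
(percentage points) for `F_bound`; summaries report bias (mean), std, and
iqr (p75 − p25, linear/type-7 interpolation). Harness-specific choices:

- all jumps per trajectory enter the histograms (no per-trajectory cap).
  The cap of 4, appropriate for experimental data with long immobile
  trajectories, truncates bound trajectories preferentially in these short
  simulated tracks and shifts `F_bound` by −4 to −5 points;
- histogram range 6 µm (10 nm bins) so the fastest conditions are not
  truncated;
- `σ` fixed at the simulation ground truth (25 nm);
- lag counts follow the published frame-rate mapping (timepoints 9/9/8/6/4
  at 1/4/7/13/20 ms; histograms at lags 1..timepoints−1).

The MSD baseline computes, per trajectory of ≥5 frames, the time-averaged
MSD at lags 1–4, a straight-line fit `MSD = 4D̂τ + c` (`D̂` floored at
1e-5 µm²/s), and summarizes `log₁₀ D̂` with a two-component Gaussian
mixture: the slower component's weight estimates `F_bound`, the faster
component's mean gives `D_free`.

## Problem sizes

The test suite and the acceptance script run the benchmark at desk scale:
40 grid-sampled conditions × 20,000 in-focus trajectories (the full suite
is 3,480 conditions × 100,000 trajectories; a `sptfit validate` run with
`--n-conditions` / `--n-traj` reproduces any intermediate scale). The
axial-survival worked number uses 1e5 walkers with 20 substeps per frame;
the survival-vs-Monte-Carlo oracle uses 1e5 walkers with Brownian-bridge
boundary-crossing corrections (naive position checks at substeps
overestimate survival by 1–2 points at these step sizes).

## Limitations

- **Fast diffusion at slow frame rates.** When `√(2DΔτ)` approaches `Δz`
  the correction family's shape error (see above) is no longer negligible:
  the model overestimates lag-1 free survival and underestimates it at
  later lags. The fit converts this into an extra −10..−15% underestimate
  of `D_free` at the fastest benchmark cells (e.g. D = 14 µm²/s at 20 ms)
  even without confinement, on top of the genuine confinement bias
  (−8..−10% in a 4 µm nucleus at those conditions). Averaged over the full
  benchmark grid this yields a mean relative `D_free` bias near −9% with a
  spread of ~6 points, while `F_bound` stays accurate (bias ≈ −2 points,
  spread ≈ 1.2). Estimates of `F_bound` are therefore trustworthy across
  the whole regime; `D_free` from data with `√(2DΔτ) ≳ Δz/2` should be read
  as a lower bound, and a faster frame rate is the proper fix.
- Diffusion constants measured in confined nuclei are *apparent*: the
  reflecting boundary compresses long jumps, and relaxing the confinement
  (20 µm radius) removes that share of the bias.
- The model ignores state transitions within a trajectory and assumes ideal
  Brownian motion with a static localization error.
- The MSD baseline's absolute biases depend strongly on its thresholds;
  only the signs (overestimation without filtering, underestimation with
  the `R²` filter) and the ordering against the jump-distribution fit are
  stable observations.
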