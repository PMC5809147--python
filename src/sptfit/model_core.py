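"""Semi-analytical jump-length distribution models for single-particle tracking.

Pooled SPT displacement histograms are modeled as mixtures of Brownian
subpopulations. Each subpopulation with diffusion constant ``D`` contributes a
Rayleigh-form density of 2D jump lengths over a lag ``dt``, with the static
localization error ``sigma`` inflating the apparent variance,

    p(r) = r / (2 (D dt + sigma^2)) * exp(-r^2 / (4 (D dt + sigma^2))).

Freely diffusing molecules additionally leave the axial detection slab of
thickness ``dz``; their contribution at lag ``k dt`` is down-weighted by the
fraction still in focus, computed from the absorbing-slab survival probability
evaluated at a Monte Carlo-calibrated corrected slab thickness
``dz_corr = dz + a sqrt(D) + b`` (see :mod:`sptfit.defocal`). The bound
(quasi-immobile) term carries no defocalization factor: its axial excursions
over the fitted lag range are negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

__all__ = [
    "AcquisitionSettings",
    "ModelParams2",
    "ModelParams3",
    "ModelCurve",
    "free_propagator_pdf",
    "p_remaining",
    "zcorr_axial_range",
    "model_distribution",
    "model_cdf",
]

#: series terms are added in erfc pairs until the pair magnitude drops below this
SERIES_TOL = 1e-10
#: hard cap on series terms (guards pathological dz / D / dt combinations)
SERIES_MAX_TERMS = 10_000
#: number of midpoint-quadrature nodes for the axial average
ZQUAD_POINTS = 200
#: delay range (in frame units) the correction coefficients are calibrated for
CALIBRATED_MAX_DELAYS = 15


@dataclass(frozen=True)
class AcquisitionSettings:
    """Acquisition descriptors shared by the model and the empirical histograms.

    Parameters
    ----------
    dt : float
        Frame interval (lag unit) in seconds.
    dz : float
        Axial detection range in micrometers.
    gaps : int
        Number of gap frames the tracker may bridge.
    n_lags : int
        Number of lag multiples: histograms/models at ``1*dt .. n_lags*dt``.
    """

    dt: float
    dz: float = 0.7
    gaps: int = 1
    n_lags: int = 7

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.dz <= 0:
            raise ValueError(f"dz must be positive, got {self.dz}")
        if self.gaps < 0:
            raise ValueError(f"gaps must be >= 0, got {self.gaps}")
        if self.n_lags < 1:
            raise ValueError(f"n_lags must be >= 1, got {self.n_lags}")


@dataclass(frozen=True)
class ModelParams2:
    """2-state (bound + free) mixture parameters.

    ``f_free = 1 - f_bound`` is always derived, never stored.
    """

    d_bound: float
    d_free: float
    f_bound: float
    sigma: float = 0.035

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_bound <= 1.0:
            raise ValueError(f"f_bound must be in [0, 1], got {self.f_bound}")
        if self.d_bound < 0 or self.d_free < 0 or self.sigma < 0:
            raise ValueError("diffusion constants and sigma must be >= 0")

    @property
    def f_free(self) -> float:
        return 1.0 - self.f_bound

    def components(self) -> list[tuple[float, float, bool]]:
        """(weight, D, is_bound) triples; the bound state is listed first."""
        return [
            (self.f_bound, self.d_bound, True),
            (self.f_free, self.d_free, False),
        ]


@dataclass(frozen=True)
class ModelParams3:
    """3-state (bound + slow + fast) mixture parameters.

    ``f_fast = 1 - f_bound - f_slow``; reported with ``d_slow <= d_fast``.
    """

    d_bound: float
    d_slow: float
    d_fast: float
    f_bound: float
    f_slow: float
    sigma: float = 0.035

    def __post_init__(self) -> None:
        for name in ("f_bound", "f_slow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.f_bound + self.f_slow > 1.0 + 1e-12:
            raise ValueError("f_bound + f_slow must not exceed 1")
        if min(self.d_bound, self.d_slow, self.d_fast, self.sigma) < 0:
            raise ValueError("diffusion constants and sigma must be >= 0")
        if self.d_slow > self.d_fast:
            raise ValueError("label convention requires d_slow <= d_fast")

    @property
    def f_fast(self) -> float:
        return 1.0 - self.f_bound - self.f_slow

    def components(self) -> list[tuple[float, float, bool]]:
        return [
            (self.f_bound, self.d_bound, True),
            (self.f_slow, self.d_slow, False),
            (self.f_fast, self.d_fast, False),
        ]


@dataclass
class ModelCurve:
    """Binned model distribution per lag.

    ``density_per_lag[k - 1, i]`` is the model probability mass in bin ``i``
    at lag ``k * dt`` (mass, not density: midpoint density times bin width).
    """

    bin_edges: np.ndarray
    density_per_lag: np.ndarray
    cdf_per_lag: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_lags(self) -> int:
        return self.density_per_lag.shape[0]


def free_propagator_pdf(r, d: float, dt: float, sigma: float = 0.0):
    """Probability density of 2D jump lengths for free diffusion.

    Rayleigh form with scale ``u = D dt + sigma^2`` (per-coordinate variance
    ``2u``): ``p(r) = r/(2u) exp(-r^2/(4u))``, normalized over r >= 0.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if d < 0 or sigma < 0:
        raise ValueError("d and sigma must be >= 0")
    u = d * dt + sigma * sigma
    if u <= 0:
        raise ValueError(
            "degenerate distribution: d*dt + sigma^2 must be positive"
        )
    r = np.asarray(r, dtype=float)
    return r / (2.0 * u) * np.exp(-(r * r) / (4.0 * u))


def _survival_series(dt_total, dz, d):
    """Absorbing-slab survival, averaged over uniform initial z.

    Broadcasts over array arguments. Midpoint quadrature over ``ZQUAD_POINTS``
    nodes; the alternating erfc series is summed in pairs until the largest
    remaining pair magnitude falls below ``SERIES_TOL``.
    """
    dt_total, dz, d = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (dt_total, dz, d))
    )
    out = np.ones(dt_total.shape, dtype=float)
    active = (d > 0) & (dt_total > 0)
    if not np.any(active):
        return out

    t = dt_total[active]
    dzc = dz[active]
    dd = d[active]
    # quadrature nodes: z_j = -dz/2 + (j + 1/2) dz / N, on the last axis
    j = (np.arange(ZQUAD_POINTS) + 0.5) / ZQUAD_POINTS  # (N,)
    z = (j[None, :] - 0.5) * dzc[..., None]  # (M, N)
    s = np.sqrt(4.0 * dd * t)[..., None]  # (M, 1)
    half = (dzc / 2.0)[..., None]

    loss = np.zeros_like(z)
    sign = 1.0
    for n in range(SERIES_MAX_TERMS):
        edge = (2 * n + 1) * half
        pair = erfc((edge - z) / s) + erfc((edge + z) / s)
        loss += sign * pair
        sign = -sign
        if pair.max() < SERIES_TOL:
            break
    else:  # pragma: no cover - pathological inputs only
        warnings.warn("survival series hit the term cap before converging")

    surv = 1.0 - loss.mean(axis=-1)
    out[active] = np.clip(surv, 0.0, 1.0)
    return out


def p_remaining(dt_total: float, dz: float, d: float) -> float:
    """Fraction of molecules with diffusion constant ``d`` still inside an
    absorbing axial slab of thickness ``dz`` after time ``dt_total``.

    Initial positions are uniform across the slab; molecules touching either
    face at ``+-dz/2`` are permanently lost. Result is in [0, 1],
    nonincreasing in ``d`` and ``dt_total``.
    """
    if dz <= 0:
        raise ValueError(f"dz must be positive, got {dz}")
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    if dt_total < 0:
        raise ValueError(f"dt_total must be >= 0, got {dt_total}")
    return float(_survival_series(dt_total, dz, d))


def p_remaining_grid(dt_total, dz, d) -> np.ndarray:
    """Vectorized :func:`p_remaining`; arguments broadcast elementwise."""
    return _survival_series(dt_total, dz, d)


def zcorr_axial_range(dz: float, dt: float, d: float, gaps: int, coeffs) -> float:
    """Corrected axial detection range ``dz + a sqrt(D) + b``.

    ``coeffs`` must expose ``lookup(dz, dt, gaps) -> (a, b)`` (see
    :class:`sptfit.defocal.DefocalCoefficients`). The correction widens the
    slab to account for molecules that briefly leave the detection range and
    re-enter within the tracker's gap tolerance.
    """
    a, b = coeffs.lookup(dz, dt, gaps)
    return dz + a * np.sqrt(d) + b


def _component_mass(
    centers: np.ndarray,
    widths: np.ndarray,
    lags: np.ndarray,
    dt: float,
    d: float,
    sigma: float,
) -> np.ndarray:
    """Per-bin mass of a single Rayleigh component at each lag: (K, B)."""
    u = d * dt * lags[:, None] + sigma * sigma  # (K, 1)
    r = centers[None, :]
    dens = r / (2.0 * u) * np.exp(-(r * r) / (4.0 * u))
    return dens * widths[None, :]


def model_distribution(
    params: ModelParams2 | ModelParams3,
    settings: AcquisitionSettings,
    bin_edges,
    coeffs,
    renormalize: bool | str = "per_lag",
    apply_zcorr: bool = True,
) -> ModelCurve:
    """Evaluate the mixture model on histogram bins at lags ``1..n_lags``.

    Per-bin mass is the mixture density at the bin midpoint times the bin
    width. Each diffusive component with constant ``D`` is weighted at lag
    ``k`` by ``Z_k = p_remaining(k dt, dz_corr(D), D)``; the bound component
    carries no defocalization factor. With ``renormalize`` each lag's mass
    vector is divided by its total, so the defocalization information
    survives as the lag-dependent reweighting of bound vs mobile terms.
    ``renormalize`` accepts ``"per_lag"`` (default; alias ``True``),
    ``"joint"`` (one total across all lags), or ``False``.

    Setting ``apply_zcorr=False`` evaluates the uncorrected mixture (used for
    diagnosing the defocalization bias).
    """
    if renormalize is True:
        renormalize = "per_lag"
    if renormalize not in ("per_lag", "joint", False):
        raise ValueError(f"unknown renormalize mode: {renormalize!r}")
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2:
        raise ValueError("bin_edges must be a 1D array with >= 2 entries")
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    if bin_edges[0] != 0.0:
        raise ValueError("bin_edges must start at 0")
    if settings.n_lags > CALIBRATED_MAX_DELAYS:
        warnings.warn(
            f"n_lags={settings.n_lags} exceeds the calibrated delay range "
            f"(1..{CALIBRATED_MAX_DELAYS}); reusing the same (a, b) pair",
            stacklevel=2,
        )

    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    widths = np.diff(bin_edges)
    lags = np.arange(1, settings.n_lags + 1, dtype=float)

    mass = np.zeros((settings.n_lags, centers.size))
    for weight, d, is_bound in params.components():
        if weight == 0.0:
            continue
        comp = _component_mass(centers, widths, lags, settings.dt, d, params.sigma)
        if apply_zcorr and not is_bound and d > 0:
            dz_corr = zcorr_axial_range(
                settings.dz, settings.dt, d, settings.gaps, coeffs
            )
            zk = p_remaining_grid(lags * settings.dt, dz_corr, d)  # (K,)
            comp = comp * zk[:, None]
        mass += weight * comp

    if renormalize == "per_lag":
        totals = mass.sum(axis=1, keepdims=True)
        np.divide(mass, totals, out=mass, where=totals > 0)
    elif renormalize == "joint":
        total = mass.sum()
        if total > 0:
            mass /= total  # unit mass across all lags combined

    curve = ModelCurve(
        bin_edges=bin_edges,
        density_per_lag=mass,
        meta={
            "renormalized": bool(renormalize),
            "zcorr": bool(apply_zcorr),
            "dt": settings.dt,
            "dz": settings.dz,
            "gaps": settings.gaps,
        },
    )
    return model_cdf(curve)


def model_cdf(curve: ModelCurve) -> ModelCurve:
    """Fill ``cdf_per_lag`` as the running sum of per-bin mass along bins."""
    curve.cdf_per_lag = np.cumsum(curve.density_per_lag, axis=1)
    return curve
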