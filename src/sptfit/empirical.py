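"""Pooled-trajectory handling: displacement extraction, histograms, metadata.

Trajectories are stored column-wise (flat arrays of trajectory code, frame,
x, y) which keeps displacement extraction vectorized even for 1e5+
trajectories. The on-disk dialect is a plain CSV with header
``trajectory,frame,t,x,y`` (frame integer, t seconds, x/y micrometers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet",
    "JumpHistogram",
    "DatasetMetadata",
    "compute_displacements",
    "build_histograms",
    "dataset_metadata",
    "merge_datasets",
]

CSV_COLUMNS = ["trajectory", "frame", "t", "x", "y"]


@dataclass
class TrajectorySet:
    """Pooled per-particle localization sequences.

    ``codes`` holds a 0-based trajectory index per record; ``labels[codes]``
    recovers the original trajectory ids. Records are sorted by
    (trajectory, frame) and frames are strictly increasing within a
    trajectory.
    """

    codes: np.ndarray
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.labels is None:
            n = self.codes.max() + 1 if self.codes.size else 0
            self.labels = np.arange(n)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.codes.size:
            order_ok = np.all(
                (np.diff(self.codes) > 0)
                | ((np.diff(self.codes) == 0) & (np.diff(self.frames) > 0))
            )
            if not order_ok:
                order = np.lexsort((self.frames, self.codes))
                self.codes = self.codes[order]
                self.frames = self.frames[order]
                self.x = self.x[order]
                self.y = self.y[order]
                same = np.diff(self.codes) == 0
                if np.any(same & (np.diff(self.frames) <= 0)):
                    raise ValueError(
                        "frames must be strictly increasing within a trajectory"
                    )

    # -- basic accessors ----------------------------------------------

    @property
    def n_localizations(self) -> int:
        return int(self.codes.size)

    @property
    def n_trajectories(self) -> int:
        return int(np.unique(self.codes).size)

    def lengths(self) -> np.ndarray:
        """Localization count per trajectory (over trajectories present)."""
        if not self.codes.size:
            return np.array([], dtype=np.int64)
        return np.bincount(self.codes, minlength=len(self.labels))[
            np.unique(self.codes)
        ]

    def __len__(self) -> int:
        return self.n_trajectories

    # -- construction / IO --------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float) -> "TrajectorySet":
        codes, labels = pd.factorize(df["trajectory"], sort=True)
        return cls(
            codes=codes,
            frames=df["frame"].to_numpy(dtype=np.int64),
            x=df["x"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
            dt=dt,
            labels=np.asarray(labels),
        )

    @classmethod
    def from_csv(cls, path, dt: float | None = None) -> "TrajectorySet":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"empty trajectory file: {path}") from exc
        missing = [c for c in ("trajectory", "frame", "x", "y") if c not in df]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        bad = df[["frame", "x", "y"]].isna().any(axis=1)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed row at line {line}")
        if dt is None:
            if "t" not in df or len(df) < 2:
                raise ValueError(f"{path}: cannot infer dt; pass it explicitly")
            tt = df.sort_values(["trajectory", "frame"])
            dts = tt.groupby("trajectory", sort=False).apply(
                lambda g: np.diff(g["t"]) / np.maximum(np.diff(g["frame"]), 1),
                include_groups=False,
            )
            vals = np.concatenate([v for v in dts if len(v)]) if len(dts) else []
            if len(vals) == 0:
                raise ValueError(f"{path}: cannot infer dt; pass it explicitly")
            dt = float(np.median(vals))
        return cls.from_dataframe(df, dt=dt)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trajectory": self.labels[self.codes],
                "frame": self.frames,
                "t": self.frames * self.dt,
                "x": self.x,
                "y": self.y,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class JumpHistogram:
    """Binned displacement distributions per lag time.

    ``pdf_per_lag`` is probability mass per bin (sums to 1 per lag);
    lags with zero jumps have NaN pdf/cdf and are flagged in ``empty_lags``.
    """

    bin_edges: np.ndarray
    counts_per_lag: np.ndarray
    pdf_per_lag: np.ndarray
    cdf_per_lag: np.ndarray
    n_jumps_per_lag: np.ndarray
    dt: float
    settings: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_lags(self) -> int:
        return self.counts_per_lag.shape[0]

    @property
    def empty_lags(self) -> np.ndarray:
        return np.flatnonzero(self.n_jumps_per_lag == 0) + 1


@dataclass
class DatasetMetadata:
    """Quality metadata for a pooled dataset."""

    n_trajectories: int
    n_localizations: int
    mean_length: float
    median_length: float
    localizations_per_frame: float
    n_jumps_per_lag: np.ndarray | None = None

    def as_dict(self) -> dict:
        d = {
            "n_trajectories": self.n_trajectories,
            "n_localizations": self.n_localizations,
            "mean_length": self.mean_length,
            "median_length": self.median_length,
            "localizations_per_frame": self.localizations_per_frame,
        }
        if self.n_jumps_per_lag is not None:
            d["n_jumps_per_lag"] = [int(n) for n in self.n_jumps_per_lag]
        return d


def compute_displacements(
    ts: TrajectorySet,
    n_lags: int,
    jumps_per_traj: int | None = 4,
) -> list[np.ndarray]:
    """Per-lag 2D displacement lengths (um).

    For lag ``k`` the pairs are records of the same trajectory whose frame
    difference is exactly ``k`` (pairs spanning a tracking gap contribute to
    the lag equal to their frame difference). At most ``jumps_per_traj``
    displacements per trajectory per lag are kept, taken from the trajectory
    start; ``None`` disables the cap.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if jumps_per_traj is not None and jumps_per_traj < 1:
        raise ValueError("jumps_per_traj must be >= 1 or None")
    if ts.n_localizations == 0:
        warnings.warn("empty trajectory set: no displacements")
        return [np.array([]) for _ in range(n_lags)]

    codes, frames, x, y = ts.codes, ts.frames, ts.x, ts.y
    out: list[np.ndarray] = []
    for k in range(1, n_lags + 1):
        ds, cs, starts = [], [], []
        # frames are strictly increasing, so a frame difference of k can only
        # occur at record offsets 1..k
        for j in range(1, k + 1):
            if j >= codes.size:
                break
            m = (codes[j:] == codes[:-j]) & (frames[j:] - frames[:-j] == k)
            if not np.any(m):
                continue
            i = np.flatnonzero(m)
            ds.append(np.hypot(x[i + j] - x[i], y[i + j] - y[i]))
            cs.append(codes[i])
            starts.append(i)
        if not ds:
            out.append(np.array([]))
            continue
        d = np.concatenate(ds)
        c = np.concatenate(cs)
        s = np.concatenate(starts)
        order = np.lexsort((s, c))
        d, c = d[order], c[order]
        if jumps_per_traj is not None:
            # rank within trajectory (candidates sorted by start record)
            firsts = np.flatnonzero(np.r_[True, np.diff(c) != 0])
            counts = np.diff(np.r_[firsts, c.size])
            rank = np.arange(c.size) - np.repeat(firsts, counts)
            d = d[rank < jumps_per_traj]
        out.append(d)
    return out


def build_histograms(
    displacements: list[np.ndarray],
    bin_width: float = 0.01,
    r_max: float = 3.0,
    dt: float = np.nan,
    settings: dict | None = None,
) -> JumpHistogram:
    """Bin per-lag displacements into half-open bins ``[i w, (i+1) w)``.

    Displacements at or beyond ``r_max`` accumulate in the final bin. The
    per-lag pdf is counts over total (mass per bin); the cdf its running sum.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max <= bin_width:
        raise ValueError("r_max must exceed bin_width")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros((len(displacements), n_bins), dtype=np.int64)
    for row, d in enumerate(displacements):
        d = np.asarray(d, dtype=float)
        if d.size == 0:
            continue
        idx = np.minimum((d / bin_width).astype(np.int64), n_bins - 1)
        counts[row] = np.bincount(idx, minlength=n_bins)
    n_jumps = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pdf = counts / n_jumps[:, None]
    pdf[n_jumps == 0] = np.nan
    cdf = np.where(np.isnan(pdf), np.nan, np.nancumsum(pdf, axis=1))
    if np.any(n_jumps == 0):
        warnings.warn(
            f"lags with zero jumps: {list(np.flatnonzero(n_jumps == 0) + 1)}; "
            "pdf/cdf undefined there"
        )
    return JumpHistogram(
        bin_edges=edges,
        counts_per_lag=counts,
        pdf_per_lag=pdf,
        cdf_per_lag=cdf,
        n_jumps_per_lag=n_jumps,
        dt=dt,
        settings=dict(settings or {}, bin_width=bin_width, r_max=r_max),
    )


def dataset_metadata(
    ts: TrajectorySet,
    n_lags: int | None = None,
    jumps_per_traj: int | None = None,
) -> DatasetMetadata:
    """Counts and averages describing a pooled dataset."""
    lengths = ts.lengths()
    if lengths.size == 0:
        return DatasetMetadata(0, 0, 0.0, 0.0, 0.0)
    span = int(ts.frames.max() - ts.frames.min() + 1)
    n_jumps = None
    if n_lags is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            disp = compute_displacements(ts, n_lags, jumps_per_traj)
        n_jumps = np.array([d.size for d in disp])
    return DatasetMetadata(
        n_trajectories=int(lengths.size),
        n_localizations=int(lengths.sum()),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        localizations_per_frame=float(lengths.sum() / span),
        n_jumps_per_lag=n_jumps,
    )


def merge_datasets(sets: list[TrajectorySet]) -> TrajectorySet:
    """Concatenate replicate datasets with re-keyed unique trajectory ids."""
    sets = [s for s in sets if s is not None]
    if not sets:
        raise ValueError("nothing to merge")
    dts = {round(s.dt, 12) for s in sets}
    if len(dts) > 1:
        raise ValueError(f"cannot merge datasets with different dt: {sorted(dts)}")
    nonempty = [s for s in sets if s.n_localizations > 0]
    if not nonempty:
        return TrajectorySet(
            codes=np.array([], dtype=np.int64), frames=np.array([], dtype=np.int64),
            x=np.array([]), y=np.array([]), dt=sets[0].dt,
        )
    codes_parts, labels = [], []
    offset = 0
    for i, s in enumerate(nonempty):
        uniq, local = np.unique(s.codes, return_inverse=True)
        codes_parts.append(local + offset)
        labels.extend(f"set{i}:{s.labels[u]}" for u in uniq)
        offset += uniq.size
    return TrajectorySet(
        codes=np.concatenate(codes_parts),
        frames=np.concatenate([s.frames for s in nonempty]),
        x=np.concatenate([s.x for s in nonempty]),
        y=np.concatenate([s.y for s in nonempty]),
        dt=nonempty[0].dt,
        labels=np.array(labels, dtype=object),
    )
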