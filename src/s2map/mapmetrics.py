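"""Two-dimensional composites of the 1-D inequality machinery.

A 2D intensity map is reduced to its two axis projections (column sums for
the x-axis, row sums for the y-axis); the signal inequality index (SII) and
signal coverage index (SCI) are the Euclidean norms of the per-axis degrees
of inequality and center-weighted SNRs respectively:

    SII = sqrt(DIx^2 + DIy^2)       SCI = sqrt(CWSNRx^2 + CWSNRy^2)

SII measures dissymmetry of the map about its center (0 for centrally
symmetric maps, up to sqrt(2) when mass piles onto a corner); SCI measures
how much above-average signal sits near the projection centers.  Both are
exactly invariant under 90-degree grid rotations and transposition, since
those operations permute/swap the projections.

``metric_series`` evaluates both indices along a time series, either on the
cumulative frames or on per-step delta frames (current minus previous,
negatives clipped, small entries suppressed by a noise cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .inequality import AxisDecomposition, InvalidSignalError, cwsnr

__all__ = [
    "MapMetrics",
    "MetricSeries",
    "SignalMatrix",
    "SignalSeries",
    "map_metrics",
    "metric_series",
    "project",
    "sci",
    "sii",
]


@dataclass(frozen=True)
class SignalMatrix:
    """A non-negative 2D intensity grid for one time point.

    ``center`` is the (row, col) coordinate the center-weighting refers to;
    it defaults to the geometric center ``((H-1)/2, (W-1)/2)``.
    """

    grid: NDArray[np.float64]
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2 or grid.size == 0:
            raise InvalidSignalError(f"grid must be 2-D and non-empty, got {grid.shape}")
        if not np.all(np.isfinite(grid)):
            raise InvalidSignalError("grid contains non-finite values")
        if np.any(grid < 0):
            raise InvalidSignalError("grid values must be non-negative")
        object.__setattr__(self, "grid", grid)
        center = self.center
        if center is None:
            center = ((grid.shape[0] - 1) / 2.0, (grid.shape[1] - 1) / 2.0)
        else:
            center = (float(center[0]), float(center[1]))
            if not (0 <= center[0] <= grid.shape[0] - 1 and 0 <= center[1] <= grid.shape[1] - 1):
                raise InvalidSignalError(f"center {center} outside grid {grid.shape}")
        object.__setattr__(self, "center", center)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def total(self) -> float:
        return float(self.grid.sum())


@dataclass
class SignalSeries:
    """Time-ordered stack of same-shape frames with time stamps in minutes."""

    frames: list[SignalMatrix]
    times: NDArray[np.float64] | None = None
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise InvalidSignalError("series needs at least one frame")
        self.frames = [
            f if isinstance(f, SignalMatrix) else SignalMatrix(np.asarray(f, dtype=float))
            for f in self.frames
        ]
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise InvalidSignalError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.size != len(self.frames):
                raise InvalidSignalError("times must match frame count")
            if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
                raise InvalidSignalError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def stack(self) -> NDArray[np.float64]:
        """Frames as a (T, H, W) array."""
        return np.stack([f.grid for f in self.frames])


@dataclass(frozen=True)
class MapMetrics:
    """SII/SCI of one map plus the two axis decompositions behind them."""

    sii: float
    sci: float
    axis_x: AxisDecomposition
    axis_y: AxisDecomposition


@dataclass
class MetricSeries:
    """Per-time-point SII and SCI values for one sample."""

    sample_id: str
    timepoints: NDArray[np.float64]
    sii_values: NDArray[np.float64]
    sci_values: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.sii_values = np.asarray(self.sii_values, dtype=float)
        self.sci_values = np.asarray(self.sci_values, dtype=float)
        if not (len(self.timepoints) == len(self.sii_values) == len(self.sci_values)):
            raise InvalidSignalError("metric series vectors must share length")
        if not (np.all(np.isfinite(self.sii_values)) and np.all(np.isfinite(self.sci_values))):
            raise InvalidSignalError("metric values must be finite")

    def values(self, metric: str) -> NDArray[np.float64]:
        if metric == "sii":
            return self.sii_values
        if metric == "sci":
            return self.sci_values
        raise InvalidSignalError(f"unknown metric {metric!r}; expected 'sii' or 'sci'")


def _as_matrix(m: SignalMatrix | ArrayLike) -> SignalMatrix:
    return m if isinstance(m, SignalMatrix) else SignalMatrix(np.asarray(m, dtype=float))


def project(m: SignalMatrix | ArrayLike, axis: str) -> NDArray[np.float64]:
    """Axis projection of a map: ``'x'`` -> column sums, ``'y'`` -> row sums.

    Total mass is conserved: ``sum(projection) == grid.sum()``.
    """
    mat = _as_matrix(m)
    if axis == "x":
        return mat.grid.sum(axis=0)
    if axis == "y":
        return mat.grid.sum(axis=1)
    raise InvalidSignalError(f"axis must be 'x' or 'y', got {axis!r}")


def map_metrics(m: SignalMatrix | ArrayLike) -> MapMetrics:
    """Evaluate SII, SCI and both axis decompositions for one map."""
    mat = _as_matrix(m)
    ax = cwsnr(project(mat, "x"))
    ay = cwsnr(project(mat, "y"))
    return MapMetrics(
        sii=math.hypot(ax.di, ay.di),
        sci=math.hypot(ax.cwsnr, ay.cwsnr),
        axis_x=ax,
        axis_y=ay,
    )


def sii(m: SignalMatrix | ArrayLike) -> float:
    """Signal inequality index: Euclidean norm of the two projection DIs."""
    return map_metrics(m).sii


def sci(m: SignalMatrix | ArrayLike) -> float:
    """Signal coverage index: Euclidean norm of the two projection CWSNRs."""
    return map_metrics(m).sci


def delta_frames(s: SignalSeries, cutoff: float = 0.0) -> list[NDArray[np.float64]]:
    """Per-step increments of a series: frame_t - frame_{t-1}, clipped at 0.

    The first frame is differenced against zero.  Entries <= ``cutoff`` are
    suppressed to 0 (noise floor).
    """
    if cutoff < 0:
        raise InvalidSignalError("cutoff must be >= 0")
    stack = s.stack()
    deltas = np.diff(stack, axis=0, prepend=np.zeros((1,) + stack.shape[1:]))
    deltas = np.clip(deltas, 0.0, None)
    deltas[deltas <= cutoff] = 0.0
    return list(deltas)


def metric_series(
    s: SignalSeries,
    mode: str = "delta",
    cutoff: float = 0.0,
) -> MetricSeries:
    """SII/SCI along a time series.

    ``mode='delta'`` evaluates the clipped per-step increments (secretion
    added since the previous frame) after suppressing entries <= ``cutoff``;
    ``mode='cumulative'`` evaluates the frames as given.
    """
    if mode == "delta":
        frames = delta_frames(s, cutoff=cutoff)
    elif mode == "cumulative":
        frames = [f.grid for f in s.frames]
    else:
        raise InvalidSignalError(f"mode must be 'delta' or 'cumulative', got {mode!r}")
    center = s.frames[0].center
    results = [map_metrics(SignalMatrix(f, center=center)) for f in frames]
    return MetricSeries(
        sample_id=s.sample_id,
        timepoints=s.times,
        sii_values=np.array([r.sii for r in results]),
        sci_values=np.array([r.sci for r in results]),
    )
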