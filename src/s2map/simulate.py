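"""Signal-diffusion simulators and the synthetic scalability harness.

Two families of ground-truth patterns are generated here:

* ten one-dimensional 5-pixel scenarios in four models — signal shifting,
  shaping, spreading and propagating — used to probe what the (DI, CWSNR)
  pair can and cannot distinguish;
* four two-dimensional diffusion models on an odd square grid (default
  51x51, center (25, 25)) — circular propagation, circular propagation with
  direction, circular sector and translation — with a point source of
  amplitude 5000 at t=1 that spreads or moves outward in steps of 4 grid
  units per time point, its amplitude decaying as 5000 / outer-distance.

The translation model is the stress case for one-dimensional metrics: a
point signal moving off-center along x.  Its displacement at time t is
``(step+1) + step*(t-2)`` for t >= 2 (the first move lands on the outer
edge of the inner-4/outer-5 band, each later move adds ``step``).

``rotate_map`` rotates a pattern about the designated center.  Multiples of
90 degrees are exact index permutations; other angles forward-splat every
nonzero cell onto the rotated grid, with bilinear weights by default (mass
and mass-center are preserved exactly while the pattern stays on-grid) or
nearest-neighbor rounding.  ``rotation_sweep`` tabulates DIx, CWSNRx, SII
and SCI over the twelve 30-degree rotations, the experiment demonstrating
that the 2D composites are rotation-robust while per-axis DI is not.

``random_matrix`` and ``benchmark`` provide the reproducible random grids
and timing/memory harness for scalability testing.
"""

from __future__ import annotations

import time
import tracemalloc
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .inequality import InvalidSignalError, cwsnr
from .mapmetrics import SignalMatrix, SignalSeries, map_metrics

__all__ = [
    "MODELS_1D",
    "MODELS_2D",
    "Scenario1D",
    "SimulationSpec2D",
    "benchmark",
    "random_matrix",
    "rotate_map",
    "rotation_sweep",
    "scenario_catalog",
    "simulate_1d",
    "simulate_2d",
    "simulate_series",
]

MODELS_1D = ("shifting", "shaping", "spreading", "propagating")
MODELS_2D = (
    "circular_propagation",
    "circular_with_direction",
    "circular_sector",
    "translation",
)

ROTATION_ANGLES = tuple(range(0, 360, 30))


@dataclass(frozen=True)
class Scenario1D:
    """One stage of a one-dimensional signal model on an odd pixel axis."""

    model: str
    stage: int
    length: int = 5

    def __post_init__(self) -> None:
        if self.model not in MODELS_1D:
            raise InvalidSignalError(f"unknown 1D model {self.model!r}")
        if self.length < 1 or self.length % 2 == 0:
            raise InvalidSignalError("length must be odd and >= 1")
        if not 1 <= self.stage <= 3:
            raise InvalidSignalError(f"stage must be 1..3, got {self.stage}")


@dataclass(frozen=True)
class SimulationSpec2D:
    """Parameters of the 2D diffusion models.

    Defaults are the reference study conditions: a 51x51 grid with center
    (25, 25), a point source of amplitude 5000, a step of 4 grid units per
    time point and four time points.  Signal falling off-grid is dropped.
    """

    model: str
    grid_size: int = 51
    center: tuple[int, int] | None = None
    initial_amplitude: float = 5000.0
    step: int = 4
    timepoints: int = 4
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS_2D:
            raise InvalidSignalError(f"unknown 2D model {self.model!r}")
        if self.grid_size < 1:
            raise InvalidSignalError("grid_size must be >= 1")
        if self.initial_amplitude <= 0:
            raise InvalidSignalError("initial_amplitude must be positive")
        if self.step < 1 or self.timepoints < 1:
            raise InvalidSignalError("step and timepoints must be >= 1")

    @property
    def center_rc(self) -> tuple[int, int]:
        if self.center is not None:
            return (int(self.center[0]), int(self.center[1]))
        return ((self.grid_size - 1) // 2, (self.grid_size - 1) // 2)


def simulate_1d(sc: Scenario1D) -> NDArray[np.float64]:
    """Generate the 1D profile of one scenario stage.

    shifting: a unit signal stepping rightward from the center pixel.
    shaping: mass over the right half (center..end) with decreasing (stage 1,
    the densities 3,2,1 case at length 5), uniform (stage 2) or increasing
    (stage 3) density.
    spreading: mass widening from the center pixel to the central 3 pixels
    to the whole axis.
    propagating: two units moving symmetrically outward from the center.
    """
    n, c = sc.length, sc.length // 2
    x = np.zeros(n)
    if sc.model == "shifting":
        pos = c + (sc.stage - 1)
        if pos >= n:
            raise InvalidSignalError(f"stage {sc.stage} shifts off the axis")
        x[pos] = 1.0
    elif sc.model == "shaping":
        m = n - c  # right half including the center pixel
        if sc.stage == 1:
            x[c:] = np.arange(m, 0, -1)
        elif sc.stage == 2:
            x[c:] = 1.0
        else:
            x[c:] = np.arange(1, m + 1)
    elif sc.model == "spreading":
        if sc.stage == 1:
            x[c] = 1.0
        elif sc.stage == 2:
            x[c - 1 : c + 2] = 1.0
        else:
            x[:] = 1.0
    else:  # propagating
        off = sc.stage - 1
        if sc.stage == 3:
            off = c  # final stage reaches both endpoints
        x[c - off] = 1.0
        x[c + off] = 1.0
    return x


def scenario_catalog(length: int = 5) -> dict[str, NDArray[np.float64]]:
    """The ten distinct 1D scenarios (the shared center-unit initial stage of
    the shifting/spreading/propagating models is counted once)."""
    cat: dict[str, NDArray[np.float64]] = {
        "center": simulate_1d(Scenario1D("shifting", 1, length))
    }
    for model, tag in (("shifting", "a"), ("shaping", "b"),
                       ("spreading", "c"), ("propagating", "d")):
        for stage in (1, 2, 3):
            x = simulate_1d(Scenario1D(model, stage, length))
            name = f"{tag}{stage}"
            if model != "shaping" and stage == 1:
                continue  # identical to the shared center scenario
            cat[name] = x
    return cat


def _annulus(
    shape: tuple[int, int],
    center: tuple[float, float],
    inner: float,
    outer: float,
) -> NDArray[np.bool_]:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(rows - center[0], cols - center[1])
    return (dist >= inner) & (dist <= outer)


def simulate_2d(spec: SimulationSpec2D, t: int) -> SignalMatrix:
    """One frame of a 2D diffusion model at time point ``t`` (1-based).

    At t=1 every model is the point source at the center.  For t >= 2 the
    annulus models place uniform amplitude ``A / outer`` on cells with
    center distance in ``[step*(t-1), (step+1)*(t-1)]`` (shifted right by
    ``step*(t-1)`` for the directional variant, masked to the right-pointing
    sector ``dx >= dy`` and ``dx >= -(dy+1)`` for the sector variant); the
    translation model moves the point source right with the same decay.
    """
    if not 1 <= t <= spec.timepoints:
        raise InvalidSignalError(
            f"t must be in 1..{spec.timepoints}, got {t}"
        )
    g = spec.grid_size
    cy, cx = spec.center_rc
    grid = np.zeros((g, g))
    if t == 1:
        grid[cy, cx] = spec.initial_amplitude
    else:
        inner = spec.step * (t - 1)
        outer = (spec.step + 1) * (t - 1)
        amp = spec.initial_amplitude / outer
        if spec.model == "translation":
            # first move lands at the outer edge of the step..step+1 band,
            # each later move advances by `step`
            disp = (spec.step + 1) + spec.step * (t - 2)
            col = cx + disp
            if 0 <= col < g:
                grid[cy, col] = amp
        else:
            shift = spec.step * (t - 1) if spec.model == "circular_with_direction" else 0
            mask = _annulus((g, g), (cy, cx + shift), inner, outer)
            if spec.model == "circular_sector":
                rows, cols = np.mgrid[0:g, 0:g]
                dx = cols - cx
                dy = rows - cy
                mask &= (dx >= dy) & (dx >= -(dy + 1))
            grid[mask] = amp
    m = SignalMatrix(grid, center=(cy, cx))
    if spec.rotation_deg % 360 != 0:
        m = rotate_map(m, spec.rotation_deg)
    return m


def simulate_series(spec: SimulationSpec2D) -> SignalSeries:
    """All time points of a 2D model as a SignalSeries (times in minutes)."""
    frames = [simulate_2d(spec, t) for t in range(1, spec.timepoints + 1)]
    return SignalSeries(frames, times=np.arange(spec.timepoints, dtype=float),
                        sample_id=spec.model)


def rotate_map(
    m: SignalMatrix,
    angle_deg: float,
    method: str = "linear",
) -> SignalMatrix:
    """Rotate a square map about its designated center.

    Multiples of 90 degrees are exact index permutations.  Other angles
    forward-map every nonzero cell to its rotated offset and splat its mass
    onto the grid — bilinearly (default; conserves mass and mass-center
    exactly while on-grid) or to the nearest cell (``method='nearest'``,
    discrete mass units).  Cells rotated off-grid are dropped.
    """
    if m.grid.shape[0] != m.grid.shape[1]:
        raise InvalidSignalError("rotation requires a square grid")
    if method not in ("linear", "nearest"):
        raise InvalidSignalError(f"method must be 'linear' or 'nearest', got {method!r}")
    angle = angle_deg % 360.0
    if angle == 0.0:
        return SignalMatrix(m.grid.copy(), center=m.center)
    cy, cx = m.center
    if angle % 90.0 == 0.0 and cy == cx == (m.grid.shape[0] - 1) / 2.0:
        return SignalMatrix(np.rot90(m.grid, int(angle // 90)).copy(), center=m.center)

    theta = np.deg2rad(angle)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rows, cols = np.nonzero(m.grid)
    vals = m.grid[rows, cols]
    dy = rows - cy
    dx = cols - cx
    # rotate offsets in the (x, y) plane; y follows the row axis
    ndx = dx * cos_t - dy * sin_t
    ndy = dx * sin_t + dy * cos_t
    out = np.zeros_like(m.grid)
    n = m.grid.shape[0]
    if method == "nearest":
        rr = np.floor(ndy + cy + 0.5).astype(int)
        cc = np.floor(ndx + cx + 0.5).astype(int)
        ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        np.add.at(out, (rr[ok], cc[ok]), vals[ok])
    else:
        fy = ndy + cy
        fx = ndx + cx
        r0 = np.floor(fy).astype(int)
        c0 = np.floor(fx).astype(int)
        wy = fy - r0
        wx = fx - c0
        for dr, dc, wgt in (
            (0, 0, (1 - wy) * (1 - wx)),
            (0, 1, (1 - wy) * wx),
            (1, 0, wy * (1 - wx)),
            (1, 1, wy * wx),
        ):
            rr = r0 + dr
            cc = c0 + dc
            ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n) & (wgt > 0)
            np.add.at(out, (rr[ok], cc[ok]), vals[ok] * wgt[ok])
    return SignalMatrix(out, center=m.center)


def rotation_sweep(
    spec: SimulationSpec2D,
    t: int,
    angles: tuple[int, ...] = ROTATION_ANGLES,
    method: str = "linear",
) -> pd.DataFrame:
    """Tabulate DIx, CWSNRx, SII and SCI across rotation angles.

    Returns a DataFrame with one row per angle plus ``mean`` and
    ``variance`` rows (sample variance over the angles).  The SII/SCI rows
    demonstrate rotation robustness of the 2D composites; the DIx row shows
    the one-dimensional failure mode (mean ~ 0 under rotation).
    """
    base = simulate_2d(replace(spec, rotation_deg=0.0), t)
    records = {}
    for angle in angles:
        frame = rotate_map(base, angle, method=method)
        mm = map_metrics(frame)
        records[angle] = {
            "DIx": mm.axis_x.di,
            "CWSNRx": mm.axis_x.cwsnr,
            "SII": mm.sii,
            "SCI": mm.sci,
        }
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "rotation_deg"
    df.loc["mean"] = df.mean()
    df.loc["variance"] = df.iloc[: len(angles)].var(ddof=1)
    return df


def random_matrix(dim: int, seed: int) -> SignalMatrix:
    """Reproducible non-negative random grid for the scalability harness."""
    if dim < 1:
        raise InvalidSignalError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    return SignalMatrix(rng.random((dim, dim)))


def benchmark(
    dims: tuple[int, ...] = (400, 800, 1600, 3200),
    reps: int = 5,
    seed0: int = 0,
    track_memory: bool = False,
) -> pd.DataFrame:
    """Time (and optionally peak-memory) SII+SCI evaluation per grid size.

    Each repetition r uses seed ``seed0 + r``.  Returns one row per
    (dim, rep) with the elapsed wall time in seconds; timings characterise
    scaling trends only and are never meaningful as absolute values.
    """
    rows = []
    for dim in dims:
        for rep in range(reps):
            m = random_matrix(dim, seed0 + rep)
            if track_memory:
                tracemalloc.start()
            t0 = time.perf_counter()
            mm = map_metrics(m)
            elapsed = time.perf_counter() - t0
            peak = np.nan
            if track_memory:
                _, peak = tracemalloc.get_traced_memory()
                tracemalloc.stop()
                peak = peak / 1024.0  # KiB
            rows.append(
                {"dim": dim, "rep": rep, "seconds": elapsed,
                 "peak_kib": peak, "sii": mm.sii, "sci": mm.sci}
            )
    return pd.DataFrame(rows)
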