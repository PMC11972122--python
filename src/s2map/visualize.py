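"""Multi-layer secretion-signal map rendering.

One time point of a cell's secretion signal is drawn as a stacked figure:

* a radial-basis-function (RBF) interpolated heatmap of the delta signal
  (smooth surface through the grid samples, Gaussian kernel by default);
* contour-line layers for the delta and/or cumulative signal, the latter
  honouring a user cutoff so sub-noise structure is not contoured;
* a velocity layer: arrows seeded at the strongest signal peaks and
  following the negative gradient of the smoothed surface, depicting the
  direction of signal flow from peaks towards valleys;
* two small 3D panels: the cumulative surface (grey baseline with the red
  delta increment stacked on top) and the delta surface alone.

Rendering never mutates the input matrices; figures are written as PNG and
SVG files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; no display required

import matplotlib.pyplot as plt
import numpy as np
from numpy.typing import NDArray
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import maximum_filter

from .inequality import InvalidSignalError
from .mapmetrics import SignalMatrix

__all__ = [
    "KERNELS",
    "RenderConfig",
    "find_hotspots",
    "interpolate_surface",
    "render_map",
]

# user-facing kernel names -> scipy RBFInterpolator kernels
KERNELS = {
    "gaussian": "gaussian",
    "multiquadric": "multiquadric",
    "inverse": "inverse_multiquadric",
    "linear": "linear",
    "cubic": "cubic",
    "quintic": "quintic",
    "thin_plate": "thin_plate_spline",
}


@dataclass(frozen=True)
class RenderConfig:
    """Appearance and layer options of the secretion-signal map.

    ``n_hotspots`` seeds at most that many velocity arrows at the strongest
    surface peaks (0 disables the layer); ``contour_layers`` selects which
    contour sets are drawn; ``cumulative_cutoff`` suppresses cumulative
    contour levels at or below the cutoff; ``color_range`` clamps the
    heatmap color scale.
    """

    kernel: str = "gaussian"
    n_hotspots: int = 5
    show_arrows: bool = True
    arrow_density: float = 1.0
    contour_layers: str = "both"  # delta | cumulative | both | none
    cumulative_cutoff: float = 0.0
    color_range: tuple[float, float] | None = None
    dpi: int = 100
    label_size: int = 9
    upscale: int = 4  # interpolation refinement factor per axis

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise InvalidSignalError(
                f"unknown kernel {self.kernel!r}; expected one of {sorted(KERNELS)}"
            )
        if self.n_hotspots < 0:
            raise InvalidSignalError("n_hotspots must be >= 0")
        if self.arrow_density <= 0:
            raise InvalidSignalError("arrow_density must be positive")
        if self.contour_layers not in ("delta", "cumulative", "both", "none"):
            raise InvalidSignalError(f"bad contour_layers {self.contour_layers!r}")
        if self.upscale < 1:
            raise InvalidSignalError("upscale must be >= 1")


def interpolate_surface(
    m: SignalMatrix,
    kernel: str = "gaussian",
    upscale: int = 4,
    epsilon: float = 1.0,
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """RBF-smooth a grid onto a finer sampling grid.

    Returns ``(xs, ys, surface)`` where ``surface[j, i]`` samples the
    interpolant at ``(xs[i], ys[j])`` in original grid coordinates.  The
    surface passes through the input samples at the grid nodes (interpolating
    RBF, zero smoothing); ``epsilon`` is the kernel shape parameter in grid
    units for the scale-dependent kernels.
    """
    if kernel not in KERNELS:
        raise InvalidSignalError(
            f"unknown kernel {kernel!r}; expected one of {sorted(KERNELS)}"
        )
    h, w = m.shape
    yy, xx = np.mgrid[0:h, 0:w]
    nodes = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    values = m.grid.ravel()
    neighbors = min(64, nodes.shape[0])
    interp = RBFInterpolator(
        nodes, values, kernel=KERNELS[kernel], epsilon=epsilon,
        neighbors=neighbors, degree=1,
    )
    xs = np.linspace(0, w - 1, (w - 1) * upscale + 1)
    ys = np.linspace(0, h - 1, (h - 1) * upscale + 1)
    gx, gy = np.meshgrid(xs, ys)
    surface = interp(np.column_stack([gx.ravel(), gy.ravel()])).reshape(gy.shape)
    return xs, ys, surface


def find_hotspots(
    surface: NDArray[np.float64], n_hotspots: int
) -> NDArray[np.float64]:
    """Top-n surface peaks with 3x3 non-maximum suppression.

    Returns an (k, 2) array of (row, col) indices into ``surface``,
    strongest first, with k <= n_hotspots.
    """
    if n_hotspots == 0:
        return np.empty((0, 2))
    local_max = surface == maximum_filter(surface, size=3, mode="nearest")
    rows, cols = np.nonzero(local_max)
    if rows.size == 0:
        return np.empty((0, 2))
    order = np.argsort(surface[rows, cols])[::-1][:n_hotspots]
    return np.column_stack([rows[order], cols[order]]).astype(float)


def render_map(
    m_delta: SignalMatrix,
    m_cumulative: SignalMatrix,
    cfg: RenderConfig | None = None,
    out: str | Path = "secretion_map",
) -> list[Path]:
    """Write the stacked secretion-signal map for one time point.

    ``out`` is the output path stem; ``<out>.png`` and ``<out>.svg`` are
    written and their paths returned.
    """
    cfg = cfg or RenderConfig()
    if m_delta.shape != m_cumulative.shape:
        raise InvalidSignalError(
            f"delta {m_delta.shape} and cumulative {m_cumulative.shape} shapes differ"
        )
    xs, ys, surf_delta = interpolate_surface(m_delta, cfg.kernel, cfg.upscale)
    _, _, surf_cum = interpolate_surface(m_cumulative, cfg.kernel, cfg.upscale)
    baseline = np.clip(m_cumulative.grid - m_delta.grid, 0.0, None)

    fig = plt.figure(figsize=(8, 9), dpi=cfg.dpi)
    gs = fig.add_gridspec(2, 2, height_ratios=(1, 2))
    ax3d_cum = fig.add_subplot(gs[0, 0], projection="3d")
    ax3d_delta = fig.add_subplot(gs[0, 1], projection="3d")
    ax_map = fig.add_subplot(gs[1, :])

    h, w = m_delta.shape
    gyy, gxx = np.mgrid[0:h, 0:w]
    # cumulative panel: grey baseline surface with the red delta on top
    ax3d_cum.plot_surface(gxx, gyy, baseline, color="0.6", alpha=0.7,
                          linewidth=0, antialiased=False)
    ax3d_cum.plot_surface(gxx, gyy, baseline + m_delta.grid, color="crimson",
                          alpha=0.5, linewidth=0, antialiased=False)
    ax3d_cum.set_title("cumulative signal", fontsize=cfg.label_size)
    ax3d_delta.plot_surface(gxx, gyy, m_delta.grid, cmap="Reds",
                            linewidth=0, antialiased=False)
    ax3d_delta.set_title("delta change", fontsize=cfg.label_size)
    for ax in (ax3d_cum, ax3d_delta):
        ax.tick_params(labelsize=cfg.label_size - 2)

    vmin, vmax = cfg.color_range or (float(surf_delta.min()), float(surf_delta.max()))
    im = ax_map.imshow(
        surf_delta, origin="upper", cmap="viridis",
        extent=(xs[0], xs[-1], ys[-1], ys[0]), vmin=vmin, vmax=vmax,
    )
    fig.colorbar(im, ax=ax_map, shrink=0.8).ax.tick_params(labelsize=cfg.label_size)

    if cfg.contour_layers in ("delta", "both") and np.ptp(surf_delta) > 0:
        ax_map.contour(xs, ys, surf_delta, levels=6, colors="white",
                       linewidths=0.7, alpha=0.8)
    if cfg.contour_layers in ("cumulative", "both"):
        levels = np.linspace(surf_cum.min(), surf_cum.max(), 8)[1:-1]
        levels = levels[levels > cfg.cumulative_cutoff]
        if levels.size:
            ax_map.contour(xs, ys, surf_cum, levels=levels, colors="orange",
                           linewidths=0.7, linestyles="dashed", alpha=0.8)

    if cfg.show_arrows and cfg.n_hotspots > 0:
        hot = find_hotspots(surf_delta, cfg.n_hotspots)
        if hot.size:
            gy_, gx_ = np.gradient(surf_delta, ys, xs)
            # negative gradient: flow from peaks down towards valleys
            start = np.column_stack([xs[hot[:, 1].astype(int)],
                                     ys[hot[:, 0].astype(int)]])
            ax_map.streamplot(
                xs, ys, -gx_, -gy_,
                start_points=start, density=cfg.arrow_density,
                color="black", linewidth=0.8, arrowsize=0.9,
            )
            ax_map.plot(start[:, 0], start[:, 1], "r^", markersize=4)

    ax_map.set_xlabel("x (grid units)", fontsize=cfg.label_size)
    ax_map.set_ylabel("y (grid units)", fontsize=cfg.label_size)
    ax_map.tick_params(labelsize=cfg.label_size - 1)
    fig.suptitle("secretion-signal map", fontsize=cfg.label_size + 2)

    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for ext in ("png", "svg"):
        target = out.with_suffix(f".{ext}")
        fig.savefig(target, dpi=cfg.dpi)
        written.append(target)
    plt.close(fig)
    return written
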