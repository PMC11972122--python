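"""One-dimensional position-aware inequality metrics.

The degree of inequality (DI) scores how far a non-negative 1D intensity
profile deviates from the uniform profile.  Unlike the classic Gini
coefficient it does *not* sort the values first: the Lorenz curve is built in
pixel order, so the index is signed — positive when mass concentrates at low
indices, negative at high indices — and carries position information.  For a
profile ``x`` of length ``n`` with prefix shares ``L(k) = sum(x[:k]) / sum(x)``,

    DI = (2 / n) * sum_{k=1..n} (L(k) - k / n),

which lies in ``[-(n-1)/n, (n-1)/n] ⊂ [-1, 1]`` and is 0 for any uniform
profile.

The center-weighted signal-to-noise ratio (CWSNR) builds on the discrete
derivative of the DI prefix terms,

    dDI(k) = x(k) / sum(x) - 1 / n,

whose sign splits pixels into signal (``dDI > 0``, above-average intensity)
and noise (``dDI <= 0``).  CWSNR multiplies the signal/noise count ratio by
the semicircle-weighted sum of the positive derivative units, so it is large
when above-average signal sits near the axis center:

    CWSNR = SNR * sum_i V(i) * W(i),

with ``V = max(dDI, 0)`` and ``W`` a semicircular weight profile (1 at the
center pixel, 0 at both endpoints).

Five comparator concentration indices (Shannon entropy, Theil, HHI, Simpson,
Atkinson) are provided for benchmarking; none of them is position-aware.

Formulas are documented 1-based (the field's convention); storage is 0-based
NumPy; the conversion is confined to this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "AxisDecomposition",
    "AltMetricParams",
    "DegenerateSignalWarning",
    "InvalidSignalError",
    "alternative_metric",
    "center_weights",
    "cwsnr",
    "degree_of_inequality",
    "di_derivative",
    "signal_noise_ratio",
]

ALT_METHODS = ("shannon", "theil", "hhi", "simpson", "atkinson")


class InvalidSignalError(ValueError):
    """Raised for signals that violate the non-negativity/shape contract."""


class DegenerateSignalWarning(UserWarning):
    """Emitted when a degenerate input (e.g. all-zero) triggers a convention."""


@dataclass(frozen=True)
class AxisDecomposition:
    """All per-axis intermediates behind a CWSNR evaluation.

    Attributes
    ----------
    di : float
        Degree of inequality of the profile, in [-1, 1].
    d_di : ndarray
        Discrete derivative of the DI prefix terms, length n, sums to 0
        whenever the profile has positive total mass.
    c_signal, c_noise : int
        Counts of pixels with positive / non-positive derivative.
    snr : float
        ``c_signal / c_noise`` (see :func:`signal_noise_ratio` for the
        degenerate conventions).
    v : ndarray
        Positive part of ``d_di`` (the retained signal units).
    w : ndarray
        Semicircular center weights, in [0, 1].
    cwsnr : float
        ``snr * sum(v * w)``, always >= 0.
    """

    di: float
    d_di: NDArray[np.float64]
    c_signal: int
    c_noise: int
    snr: float
    v: NDArray[np.float64]
    w: NDArray[np.float64]
    cwsnr: float


@dataclass(frozen=True)
class AltMetricParams:
    """Parameters of the comparator concentration indices.

    ``theil_epsilon`` is the additive guard that keeps the Theil log finite
    on zero pixels; ``atkinson_aversion`` is the inequality-aversion exponent
    (must differ from 1).
    """

    method: str = "shannon"
    theil_epsilon: float = 0.01
    atkinson_aversion: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ALT_METHODS:
            raise InvalidSignalError(
                f"unknown method {self.method!r}; expected one of {ALT_METHODS}"
            )
        if self.theil_epsilon <= 0:
            raise InvalidSignalError("theil_epsilon must be positive")
        if not (0 < self.atkinson_aversion < 1):
            raise InvalidSignalError("atkinson_aversion must lie in (0, 1)")


def _as_signal(x: ArrayLike) -> NDArray[np.float64]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidSignalError(f"signal must be 1-D, got shape {arr.shape}")
    if arr.size == 0:
        raise InvalidSignalError("signal must contain at least one pixel")
    if not np.all(np.isfinite(arr)):
        raise InvalidSignalError("signal contains non-finite values")
    if np.any(arr < 0):
        raise InvalidSignalError("signal values must be non-negative")
    return arr


def degree_of_inequality(x: ArrayLike) -> float:
    """Signed, unsorted Lorenz deviation of a non-negative profile.

    Returns 0 for an all-zero profile (the scale-consistent limit).  The
    result is invariant under positive rescaling of ``x`` and is negated when
    ``x`` is reversed.
    """
    arr = _as_signal(x)
    n = arr.size
    total = arr.sum()
    if total == 0:
        return 0.0
    lorenz = np.cumsum(arr) / total
    k = np.arange(1, n + 1)
    return float(2.0 * np.sum(lorenz - k / n) / n)


def di_derivative(x: ArrayLike) -> NDArray[np.float64]:
    """Discrete derivative of the DI prefix terms: ``x(k)/sum(x) - 1/n``.

    Sums to 0 whenever ``sum(x) > 0``; the all-zero profile maps to the
    all-zero derivative.
    """
    arr = _as_signal(x)
    n = arr.size
    total = arr.sum()
    if total == 0:
        return np.zeros(n)
    return arr / total - 1.0 / n


def signal_noise_ratio(d_di: ArrayLike) -> tuple[int, int, float]:
    """Split derivative units into signal/noise counts and form their ratio.

    Pixels with ``d_di > 0`` count as signal, the rest as noise.  Returns
    ``(c_signal, c_noise, snr)`` with ``snr = c_signal / c_noise``.  When no
    noise unit exists the ratio is capped at ``c_signal`` (finite, ordering
    preserved) and a :class:`DegenerateSignalWarning` is emitted.
    """
    arr = np.asarray(d_di, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidSignalError("d_di must be a non-empty 1-D vector")
    c_signal = int(np.count_nonzero(arr > 0))
    c_noise = arr.size - c_signal
    if c_noise == 0:
        warnings.warn(
            "no noise units (all derivative entries positive); "
            "capping SNR at c_signal",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        return c_signal, 0, float(c_signal)
    return c_signal, c_noise, c_signal / c_noise


def center_weights(n: int) -> NDArray[np.float64]:
    """Semicircular weight profile: 1 at the axis center, 0 at both endpoints.

    Pixel ``i`` (1-based) sits at offset ``o = i - (n+1)/2`` from the center
    and receives ``sqrt(max(0, 1 - (o/h)^2))`` with half-span ``h = (n-1)/2``.
    For even ``n`` the two central pixels share ``sqrt(1 - (1/(n-1))^2)``.
    """
    if n < 1:
        raise InvalidSignalError("n must be >= 1")
    if n == 1:
        return np.ones(1)
    offsets = np.arange(1, n + 1) - (n + 1) / 2.0
    h = (n - 1) / 2.0
    return np.sqrt(np.clip(1.0 - (offsets / h) ** 2, 0.0, 1.0))


def cwsnr(x: ArrayLike) -> AxisDecomposition:
    """Full center-weighted SNR decomposition of a 1-D profile.

    All intermediates (DI, derivative, counts, SNR, positive units, weights)
    are returned alongside the scalar CWSNR; the scalar is always >= 0 and is
    0 for uniform and all-zero profiles.
    """
    arr = _as_signal(x)
    n = arr.size
    di = degree_of_inequality(arr)
    d_di = di_derivative(arr)
    w = center_weights(n)
    v = np.maximum(d_di, 0.0)
    if arr.sum() == 0:
        return AxisDecomposition(
            di=0.0, d_di=d_di, c_signal=0, c_noise=n, snr=0.0,
            v=v, w=w, cwsnr=0.0,
        )
    c_signal, c_noise, snr = signal_noise_ratio(d_di)
    value = float(snr * np.sum(v * w))
    return AxisDecomposition(
        di=di, d_di=d_di, c_signal=c_signal, c_noise=c_noise, snr=snr,
        v=v, w=w, cwsnr=value,
    )


def alternative_metric(x: ArrayLike, params: AltMetricParams | str = "shannon") -> float:
    """Evaluate one of the five comparator concentration indices.

    ``params`` may be an :class:`AltMetricParams` or a bare method name.
    Proportion-based indices (shannon, hhi, simpson) normalise ``x`` to
    ``p_i = x_i / sum(x)`` internally; an all-zero profile returns 0 with a
    :class:`DegenerateSignalWarning`.
    """
    if isinstance(params, str):
        params = AltMetricParams(method=params)
    arr = _as_signal(x)
    n = arr.size
    total = arr.sum()
    if total == 0:
        warnings.warn(
            "all-zero signal; returning 0 for the degenerate input",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        return 0.0

    if params.method == "shannon":
        p = arr / total
        p = p[p > 0]  # 0 * log 0 := 0
        return float(-np.sum(p * np.log2(p)))
    if params.method == "hhi":
        p = arr / total
        return float(np.sum(p**2))
    if params.method == "simpson":
        p = arr / total
        return float(1.0 - np.sum(p**2))
    if params.method == "theil":
        shifted = arr + params.theil_epsilon
        mu = shifted.mean()
        ratio = shifted / mu
        return float(np.mean(ratio * np.log(ratio)))
    # atkinson
    eps = params.atkinson_aversion
    mu = arr.mean()
    inner = np.mean((arr / mu) ** (1.0 - eps))
    return float(1.0 - inner ** (1.0 / (1.0 - eps)))
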