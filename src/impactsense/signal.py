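"""Acceleration traces, unit conversion, DC suppression, and windowed energy.

The processing chain mirrors the embedded firmware of a waist-worn smart
accelerometer sensor: raw multi-axis samples (uniformly sampled, 3 or 4
axes) are passed through a two-tap FIR DC suppressor,

    a_AC(t) = (a(t) - a(t - t_s)) / 2,

and the "energy" of the motion is accumulated as the sliding sum of
``|a_AC|`` over the last ``tau`` milliseconds (``N_w = round(tau / t_s)``
samples).  Absolute values stand in for squares so the accumulator fits an
8-bit integer pipeline.  All user-facing energy thresholds are expressed on
the *E_avg* scale — the accumulated energy divided by ``N_w``, i.e. the
per-sample mean absolute AC acceleration in g — which keeps thresholds in
acceleration units regardless of the window width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AccelSeries",
    "QuantizationSpec",
    "EnergyTrace",
    "dc_suppress",
    "window_energy",
    "n_window",
    "g_to_counts",
    "counts_to_g",
]

#: Default sampling period of the study hardware, ms (36.4 samples/s).
DEFAULT_T_S_MS = 27.5
#: Default energy window width, ms (24 samples at the default rate).
DEFAULT_TAU_MS = 660.0

_VALID_UNITS = ("g", "counts")


@dataclass
class AccelSeries:
    """Uniformly sampled multi-axis acceleration trace.

    Parameters
    ----------
    data : ndarray of shape (n_samples, n_axes)
        Acceleration samples, in ``unit``.
    axes : tuple of str
        Axis labels; the study layout uses ``x1`` (horizontal, sagittal),
        ``y1`` (vertical), ``y2`` (lateral) and optionally ``x2`` (the
        sagittal bisectrix, a redundant fourth direction).
    t_s : float
        Sampling period, ms.
    unit : {"g", "counts"}
    start_time : float
        Time offset of sample 0, ms.
    """

    data: np.ndarray
    axes: tuple = ("x1", "y1", "y2")
    t_s: float = DEFAULT_T_S_MS
    unit: str = "g"
    start_time: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_samples, n_axes) array")
        self.axes = tuple(self.axes)
        if len(self.axes) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.axes)} axis labels for {self.data.shape[1]} columns"
            )
        if len(set(self.axes)) != len(self.axes):
            raise ValueError("axis labels must be unique")
        if self.data.shape[0] < 1:
            raise ValueError("series must contain at least one sample")
        if not self.t_s > 0:
            raise ValueError("t_s must be positive")
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_axes(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times, ms."""
        return self.start_time + self.t_s * np.arange(self.n_samples)

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms."""
        return int(round((t_ms - self.start_time) / self.t_s))


@dataclass(frozen=True)
class QuantizationSpec:
    """ADC coding of accelerations. Study hardware: 128 counts = 2 g,
    full range 4 g = 256 counts."""

    counts_per_g: float = 64.0
    full_range_counts: int = 256

    def __post_init__(self):
        if not self.counts_per_g > 0:
            raise ValueError("counts_per_g must be positive")
        if not self.full_range_counts > 0:
            raise ValueError("full_range_counts must be positive")


@dataclass
class EnergyTrace:
    """Per-axis windowed energy of a DC-suppressed trace.

    ``e_ac[t]`` is the sum of ``|a_AC|`` over the ``N_w`` samples ending at
    ``t`` (fewer during warm-up); ``e_avg = e_ac / n_w`` is the same
    quantity on the per-sample (g) scale.
    """

    e_ac: np.ndarray
    axes: tuple
    t_s: float
    tau: float
    n_w: int
    start_time: float = 0.0

    def __post_init__(self):
        self.e_ac = np.asarray(self.e_ac, dtype=float)
        self.axes = tuple(self.axes)
        if self.n_w < 1:
            raise ValueError("n_w must be >= 1")

    @property
    def e_avg(self) -> np.ndarray:
        return self.e_ac / self.n_w

    @property
    def n_samples(self) -> int:
        return self.e_ac.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.t_s * np.arange(self.n_samples)

    def index_at(self, t_ms: float) -> int:
        return int(round((t_ms - self.start_time) / self.t_s))


def n_window(tau_ms: float, t_s_ms: float) -> int:
    """Number of samples in the energy window, ``round(tau / t_s)``.

    With the study values (660 ms, 27.5 ms) this is exactly 24.
    """
    if tau_ms < t_s_ms:
        raise ValueError(f"tau ({tau_ms} ms) must be >= t_s ({t_s_ms} ms)")
    return int(round(tau_ms / t_s_ms))


def dc_suppress(series: AccelSeries, first_output_zero: bool = False) -> AccelSeries:
    """Remove the DC (gravity/posture) component with the two-tap FIR
    ``a_AC(t) = (a(t) - a(t - t_s)) / 2``.

    The filter state starts at zero, so the first output is ``a[0] / 2``
    (streaming-friendly, no lookahead); pass ``first_output_zero=True`` to
    force the first output sample to zero instead.
    """
    a = series.data
    out = np.empty_like(a)
    out[0] = 0.0 if first_output_zero else a[0] / 2.0
    if a.shape[0] > 1:
        out[1:] = (a[1:] - a[:-1]) / 2.0
    return replace(series, data=out)


def window_energy(series_ac: AccelSeries, tau_ms: float = DEFAULT_TAU_MS) -> EnergyTrace:
    """Sliding-window energy: per axis, the sum of ``|a_AC|`` over the last
    ``N_w = round(tau / t_s)`` samples.

    During warm-up (the first ``N_w - 1`` samples) the sum runs over the
    samples available so far, matching an embedded accumulator that starts
    empty.  ``e_avg`` is always ``e_ac / N_w``, warm-up included.
    """
    n_w = n_window(tau_ms, series_ac.t_s)
    absa = np.abs(series_ac.data)
    c = np.cumsum(absa, axis=0)
    e = c.copy()
    if absa.shape[0] > n_w:
        e[n_w:] = c[n_w:] - c[:-n_w]
    return EnergyTrace(
        e_ac=e,
        axes=series_ac.axes,
        t_s=series_ac.t_s,
        tau=tau_ms,
        n_w=n_w,
        start_time=series_ac.start_time,
    )


def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def g_to_counts(
    value_g,
    spec: QuantizationSpec = QuantizationSpec(),
    scale: str = "amplitude",
    n_w: int = 1,
):
    """Convert a g-scale quantity to integer ADC counts.

    ``scale="amplitude"`` converts an acceleration: ``counts = g * counts_per_g``.
    ``scale="e_avg"`` converts an E_avg-scale energy to raw accumulated
    counts: ``counts = g * N_w * counts_per_g`` (e.g. 0.02 g with N_w = 24
    and 64 counts/g gives 30.72, rounded to 31).

    Rounding is half-away-from-zero to the nearest integer count.
    """
    value_g = np.asarray(value_g, dtype=float)
    if np.any(value_g < 0):
        raise ValueError("value_g must be non-negative")
    if scale == "amplitude":
        raw = value_g * spec.counts_per_g
    elif scale == "e_avg":
        if n_w < 1:
            raise ValueError("n_w must be >= 1 for the e_avg scale")
        raw = value_g * n_w * spec.counts_per_g
    else:
        raise ValueError("scale must be 'amplitude' or 'e_avg'")
    out = _round_half_away(raw)
    if out.ndim == 0:
        return int(out)
    return out.astype(int)


def counts_to_g(
    counts,
    spec: QuantizationSpec = QuantizationSpec(),
    scale: str = "amplitude",
    n_w: int = 1,
):
    """Inverse of :func:`g_to_counts` (up to one quantization step)."""
    counts = np.asarray(counts, dtype=float)
    if scale == "amplitude":
        return counts / spec.counts_per_g
    if scale == "e_avg":
        if n_w < 1:
            raise ValueError("n_w must be >= 1 for the e_avg scale")
        return counts / (n_w * spec.counts_per_g)
    raise ValueError("scale must be 'amplitude' or 'e_avg'")
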