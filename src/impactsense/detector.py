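"""Impact detectors: amplitude+energy isotropic, energy-only isotropic,
and energy-based anisotropic, with temporal-hold flag logic.

A detector watches per-axis binary flags.  An amplitude flag ``af_i``
activates when ``|a_i|`` exceeds the threshold ``A``; an energy flag
``ef_i`` activates when the windowed energy of axis ``i`` exceeds the
energy threshold (a scalar ``E`` shared by all axes in the isotropic
modes, a per-axis vector ``E_i`` in the anisotropic mode).  Each
activation keeps the flag true for the hold time ``t_h`` — energy and
amplitude maxima of a real impact do not coincide in time, so the hold
lets non-simultaneous crossings jointly assert an impact.  The output is

* ``isotropic_full``:    h = (OR_i af_i) AND (OR_i ef_i)
* ``isotropic_energy``:  h = OR_i ef_i            (scalar E)
* ``anisotropic``:       h = OR_i ef_i            (per-axis E_i)

and an :class:`ImpactEvent` is emitted at every rising edge of ``h``.
Energy thresholds are given on the E_avg scale (g); amplitudes in g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .signal import (
    DEFAULT_T_S_MS,
    DEFAULT_TAU_MS,
    AccelSeries,
    dc_suppress,
    n_window,
    window_energy,
)

__all__ = ["ImpactEvent", "ImpactDetector", "detect", "MODES"]

MODES = ("isotropic_full", "isotropic_energy", "anisotropic")

#: Study value of the hold time, ms (≈ 2.5 τ separation between maxima).
DEFAULT_HOLD_MS = 1760.0


@dataclass(frozen=True)
class ImpactEvent:
    """A detected impact: first sample where the detector output rose."""

    t_ms: float
    index: int
    contributing_axes: tuple


def _held_flags(cross: np.ndarray, n_h: int, refresh: str) -> np.ndarray:
    """Per-axis boolean flags held ``n_h`` samples past each activation.

    ``cross`` is (n_samples, n_axes) boolean.  ``refresh='latest'`` lets a
    re-crossing restart the hold window; ``'first'`` ignores crossings that
    occur while the flag is already active.
    """
    n, k = cross.shape
    if refresh == "latest":
        idx = np.arange(n)[:, None]
        last = np.where(cross, idx, -(n_h + 1))
        last = np.maximum.accumulate(last, axis=0)
        return (idx - last) <= n_h
    if refresh == "first":
        flags = np.zeros_like(cross)
        for j in range(k):
            expiry = -1
            rows = np.flatnonzero(cross[:, j])
            for r in rows:
                if r > expiry:
                    expiry = r + n_h
                    flags[r : min(expiry, n - 1) + 1, j] = True
        return flags
    raise ValueError("refresh must be 'latest' or 'first'")


class ImpactDetector(BaseEstimator):
    """Threshold-based impact detector over acceleration traces.

    Presented as a scikit-learn style classifier: ``predict`` maps a list
    of :class:`~impactsense.signal.AccelSeries` to 0/1 labels (1 = at
    least one impact event anywhere in the trace, which is how a labeled
    activity is scored), while :meth:`detect` returns the individual
    events of a single trace.

    Parameters
    ----------
    mode : {"isotropic_full", "isotropic_energy", "anisotropic"}
    amplitude_threshold : float
        ``A``, g; used only by ``isotropic_full``.
    energy_threshold : float or sequence of float
        ``E`` on the E_avg scale (g); scalar for the isotropic modes,
        one value per axis for ``anisotropic``.
    hold_ms : float
        Hold time ``t_h``, ms.
    tau_ms : float
        Energy window width, ms.
    refractory_ms : float
        Minimum spacing between emitted events (0 = rising edges only).
    refresh : {"latest", "first"}
        Whether a re-crossing restarts a flag's hold window.
    amplitude_on : {"ac", "raw"}
        Signal the amplitude comparison uses: DC-suppressed (default) or
        the raw trace.
    """

    def __init__(
        self,
        mode: str = "anisotropic",
        amplitude_threshold: float = 1.0,
        energy_threshold=0.115,
        hold_ms: float = DEFAULT_HOLD_MS,
        tau_ms: float = DEFAULT_TAU_MS,
        refractory_ms: float = 0.0,
        refresh: str = "latest",
        amplitude_on: str = "ac",
    ):
        self.mode = mode
        self.amplitude_threshold = amplitude_threshold
        self.energy_threshold = energy_threshold
        self.hold_ms = hold_ms
        self.tau_ms = tau_ms
        self.refractory_ms = refractory_ms
        self.refresh = refresh
        self.amplitude_on = amplitude_on

    # -- validation -----------------------------------------------------

    def _energy_vector(self, n_axes: int) -> np.ndarray:
        e = self.energy_threshold
        if self.mode == "anisotropic":
            e = np.atleast_1d(np.asarray(e, dtype=float))
            if e.size != n_axes:
                raise ValueError(
                    f"anisotropic mode needs {n_axes} per-axis energy "
                    f"thresholds, got {e.size}"
                )
        else:
            if np.ndim(e) != 0:
                raise ValueError(f"{self.mode} mode takes a scalar energy threshold")
            e = np.full(n_axes, float(e))
        if np.any(e < 0):
            raise ValueError("energy thresholds must be >= 0")
        return e

    def _validate(self, series: AccelSeries) -> np.ndarray:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "isotropic_full":
            if self.amplitude_threshold is None or self.amplitude_threshold < 0:
                raise ValueError("isotropic_full needs an amplitude threshold >= 0")
        if self.hold_ms < 0 or self.refractory_ms < 0:
            raise ValueError("hold_ms and refractory_ms must be >= 0")
        if self.amplitude_on not in ("ac", "raw"):
            raise ValueError("amplitude_on must be 'ac' or 'raw'")
        return self._energy_vector(series.n_axes)

    # -- sklearn surface ------------------------------------------------

    def fit(self, X=None, y=None):
        """Stateless validation; thresholds are parameters, not learned here
        (see :class:`~impactsense.learning.ThresholdLearner`)."""
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.is_fitted_ = True
        return self

    def predict(self, X):
        """Binary impact prediction per trace: 1 iff >= 1 event."""
        return np.array([1 if self.detect(s) else 0 for s in X], dtype=int)

    # -- core streaming evaluation --------------------------------------

    def detect(self, series: AccelSeries):
        """Run the detector over one trace; return the list of events."""
        e_thr = self._validate(series)
        ac = dc_suppress(series)
        energy = window_energy(ac, self.tau_ms)
        n_h = int(round(self.hold_ms / series.t_s))

        cross_e = energy.e_avg > e_thr[None, :]
        ef = _held_flags(cross_e, n_h, self.refresh)
        ef_any = ef.any(axis=1)

        if self.mode == "isotropic_full":
            amp = np.abs(ac.data if self.amplitude_on == "ac" else series.data)
            cross_a = amp > float(self.amplitude_threshold)
            af = _held_flags(cross_a, n_h, self.refresh)
            h = af.any(axis=1) & ef_any
        else:
            af = None
            h = ef_any

        rising = np.flatnonzero(h & ~np.concatenate(([False], h[:-1])))
        events = []
        n_refr = int(round(self.refractory_ms / series.t_s))
        last_emit = None
        for idx in rising:
            if last_emit is not None and idx - last_emit < n_refr:
                continue
            active = ef[idx]
            if af is not None:
                active = active | af[idx]
            axes = tuple(a for a, on in zip(series.axes, active) if on)
            events.append(
                ImpactEvent(
                    t_ms=series.start_time + idx * series.t_s,
                    index=int(idx),
                    contributing_axes=axes,
                )
            )
            last_emit = idx
        return events


def detect(series: AccelSeries, **params):
    """Functional wrapper: ``detect(series, mode=..., energy_threshold=...)``."""
    return ImpactDetector(**params).detect(series)


# -- threshold-free per-trace summaries (used by the ROC sweep) ---------


@dataclass
class DetectionSummary:
    """Everything a grid sweep needs to know about one trace.

    ``peak_e_avg`` decides the energy-only modes exactly: with latest-
    refresh hold semantics a single crossing emits an event, so the trace
    is positive iff some axis' peak E_avg exceeds its threshold.  For the
    full isotropic mode the trace is positive iff an amplitude crossing
    and an energy crossing fall within ``t_h`` of each other; that is
    encoded by sorting the per-sample amplitude maxima ``M_a[t]``
    descending and prefix-maximising the hold-window energy envelope
    ``R_e[t] = max_{|m - t| <= n_h} max_i e_avg_i[m]``.
    """

    peak_e_avg: np.ndarray  # (n_axes,)
    amp_sorted: np.ndarray  # M_a sorted descending
    env_prefmax: np.ndarray  # prefix max of R_e in that order

    def fires_energy(self, e_thr: np.ndarray) -> bool:
        return bool(np.any(self.peak_e_avg > e_thr))

    def best_energy_given_amplitude(self, a_thr):
        """max R_e over samples whose amplitude exceeds ``a_thr``
        (-inf when none); vectorised over an array of thresholds."""
        a_thr = np.asarray(a_thr, dtype=float)
        # amp_sorted is descending; count of amp strictly > a_thr
        cnt = np.searchsorted(-self.amp_sorted, -a_thr, side="left")
        out = np.where(cnt > 0, self.env_prefmax[np.maximum(cnt, 1) - 1], -np.inf)
        return out

    def fires_full(self, a_thr: float, e_thr: float) -> bool:
        return bool(self.best_energy_given_amplitude(a_thr) > e_thr)


def detection_summary(
    series: AccelSeries,
    tau_ms: float = DEFAULT_TAU_MS,
    hold_ms: float = DEFAULT_HOLD_MS,
    amplitude_on: str = "ac",
) -> DetectionSummary:
    """Precompute the threshold-independent sweep summary of a trace."""
    from scipy.ndimage import maximum_filter1d

    ac = dc_suppress(series)
    energy = window_energy(ac, tau_ms)
    n_h = int(round(hold_ms / series.t_s))

    e_avg = energy.e_avg
    peak = e_avg.max(axis=0)
    m_e = e_avg.max(axis=1)
    # hold-window envelope; e_avg >= 0 so a zero pad cannot inflate it
    r_e = maximum_filter1d(m_e, size=2 * n_h + 1, mode="constant", cval=0.0)
    amp = np.abs(ac.data if amplitude_on == "ac" else series.data).max(axis=1)
    order = np.argsort(-amp, kind="stable")
    return DetectionSummary(
        peak_e_avg=peak,
        amp_sorted=amp[order],
        env_prefmax=np.maximum.accumulate(r_e[order]),
    )
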