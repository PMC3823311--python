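"""Unsupervised threshold learning from activity energies.

The premise: for a given subject, each type of physical activity has a
characteristic mean energy ``E_m`` — the windowed energy ``E_avg``
averaged over the activity's duration, sampled once per window ``tau``.
Setting the energy threshold to the *largest* ``E_m`` reached by any
non-impact activity places the detector inside the optimal operating
region (all impacts caught, bounded false-positive rate), and because
``E_m`` is a running mean it can be maintained incrementally on an 8-bit
processor, giving a continuous, unsupervised, per-subject adaptation.

The pieces here:

* :func:`segment_activity` — find activity bouts in an energy trace (the
  energy level rises above / falls back to the local baseline by more
  than a factor ``e``).
* :func:`mean_energy` / :class:`RunningMean` — the batch and the exactly
  equivalent incremental form of the per-segment mean energy.
* :class:`ThresholdLearner` — fit / partial_fit estimator implementing
  the per-axis-max (and the vector-magnitude alternative) threshold
  strategies, with the optional fixed window count n = 30.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .signal import DEFAULT_TAU_MS, AccelSeries, EnergyTrace, dc_suppress, window_energy
from .study import IMPACT, NON_IMPACT

__all__ = [
    "ActivitySegment",
    "LearnedThreshold",
    "segment_activity",
    "mean_energy",
    "RunningMean",
    "ThresholdLearner",
    "learn_threshold",
    "continuous_update",
]


@dataclass
class ActivitySegment:
    """One activity bout: boundaries, window count, per-axis mean energy."""

    t_i_ms: float
    t_f_ms: float
    n: int
    e_m: np.ndarray  # per-axis, E_avg scale (g)
    label: str | None = None
    activity_type: str = ""
    #: per-window, per-axis E_avg subsamples inside the segment (n, n_axes);
    #: kept so the fixed-n strategy can re-average without the raw trace.
    window_e_avg: np.ndarray | None = None

    def __post_init__(self):
        self.e_m = np.atleast_1d(np.asarray(self.e_m, dtype=float))
        if not self.t_f_ms > self.t_i_ms:
            raise ValueError("t_f must exceed t_i")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if np.any(self.e_m < 0):
            raise ValueError("E_m must be non-negative")


@dataclass
class LearnedThreshold:
    e_vec: np.ndarray  # per-axis, E_avg scale (g)
    strategy: str = "per_axis_max"
    n_mode: str = "adaptive"

    def __post_init__(self):
        self.e_vec = np.atleast_1d(np.asarray(self.e_vec, dtype=float))
        if np.any(self.e_vec < 0):
            raise ValueError("threshold components must be >= 0")


def window_subsamples(energy: EnergyTrace) -> np.ndarray:
    """E_avg sampled once per window: the accumulated value at the last
    sample of each whole window (shape: n_windows x n_axes)."""
    n_w = energy.n_w
    n_full = energy.n_samples // n_w
    idx = np.arange(1, n_full + 1) * n_w - 1
    return energy.e_avg[idx]


def segment_activity(
    energy: EnergyTrace,
    edge_factor: float = math.e,
    baseline_buffer: int = 5,
    baseline_floor: float = 1e-4,
):
    """Detect activity bouts in an energy trace.

    The trace is reduced to one E_avg value per window ``tau`` (across-axes
    maximum); a trailing median over the last ``baseline_buffer``
    out-of-segment windows serves as the local baseline.  A segment opens
    when the level exceeds ``edge_factor`` times the baseline (default: a
    factor e change) and closes when it falls back below the same level;
    boundaries are therefore whole-``tau`` multiples, giving the window
    count ``n`` directly.  Returns a list of :class:`ActivitySegment` with
    per-axis ``E_m`` computed over each segment's windows.
    """
    sub = window_subsamples(energy)  # (n_windows, n_axes)
    if sub.shape[0] == 0:
        return []
    level = sub.max(axis=1)
    tau = energy.n_w * energy.t_s

    segments = []
    buf = deque(maxlen=baseline_buffer)
    in_seg = False
    seg_start = 0
    gate = np.inf
    for j, x in enumerate(level):
        if not in_seg:
            base = max(float(np.median(buf)) if buf else x, baseline_floor)
            if x > edge_factor * base:
                in_seg = True
                seg_start = j
                gate = edge_factor * base
            else:
                buf.append(x)
        else:
            if x <= gate:  # fell back towards baseline: close
                segments.append(_make_segment(energy, sub, seg_start, j, tau))
                in_seg = False
                buf.append(x)
    if in_seg:
        segments.append(_make_segment(energy, sub, seg_start, sub.shape[0], tau))
    return segments


def _make_segment(energy, sub, j0, j1, tau):
    rows = sub[j0:j1]
    return ActivitySegment(
        t_i_ms=energy.start_time + j0 * tau,
        t_f_ms=energy.start_time + j1 * tau,
        n=j1 - j0,
        e_m=rows.mean(axis=0),
        window_e_avg=rows.copy(),
    )


def mean_energy(energy: EnergyTrace, t_i_ms: float, n: int) -> np.ndarray:
    """Per-axis mean energy of the window (t_i, t_i + n*tau).

    ``E_m = (1/n) sum_{k=1..n} E_avg(t_i + k*tau)``, each term read at the
    last sample of the k-th whole window after ``t_i``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i0 = energy.index_at(t_i_ms)
    idx = i0 + np.arange(1, n + 1) * energy.n_w - 1
    if i0 < 0 or idx[-1] >= energy.n_samples:
        raise ValueError(
            f"window (t_i={t_i_ms} ms, n={n}) overruns the trace "
            f"({energy.n_samples} samples)"
        )
    return energy.e_avg[idx].mean(axis=0)


class RunningMean:
    """Incremental mean: m_k = m_{k-1} + (x_k - m_{k-1}) / k, m_0 = 0.

    The unique incremental form of the batch mean — after n updates the
    value equals :func:`mean_energy` over the same n window samples to
    floating tolerance.  Works on scalars or per-axis vectors.
    """

    def __init__(self):
        self.k = 0
        self.value = 0.0

    def update(self, x):
        x = np.asarray(x, dtype=float)
        self.k += 1
        self.value = self.value + (x - self.value) / self.k
        return self.value


def _segment_e_m(seg: ActivitySegment, n_mode: str, fixed_n: int) -> np.ndarray:
    if n_mode == "adaptive":
        return seg.e_m
    if n_mode == "fixed":
        if seg.window_e_avg is None:
            raise ValueError(
                "fixed-n threshold learning needs segments carrying their "
                "per-window energies (window_e_avg)"
            )
        return seg.window_e_avg[:fixed_n].mean(axis=0)
    raise ValueError("n_mode must be 'adaptive' or 'fixed'")


class ThresholdLearner(BaseEstimator):
    """Unsupervised learner of the per-axis energy threshold vector.

    ``fit`` accepts either raw traces (:class:`AccelSeries`; they are
    filtered, windowed and segmented internally) or ready
    :class:`ActivitySegment` objects.  Only non-impact material may shape
    the threshold: pass ``y`` labels to filter, or pre-filter yourself.
    ``partial_fit`` consumes one confirmed segment at a time, which is the
    continuous operating mode (the upper processing layer confirms
    impacts, everything else raises the running maximum).

    Parameters
    ----------
    strategy : {"per_axis_max", "vector_magnitude"}
        Per-axis running maximum (each axis independent), or the single
        E_m vector with the largest Euclidean magnitude.
    n_mode : {"adaptive", "fixed"}
        Average each segment over its own n windows, or over at most
        ``fixed_n`` (default 30) leading windows.
    tau_ms, edge_factor, baseline_buffer
        Segmentation parameters (see :func:`segment_activity`).
    forgetting : float or None
        Optional exponential forgetting factor in (0, 1]: the current
        threshold is multiplied by it before each update so the maximum
        can track a subject whose energies drift downward.  ``None``
        (default) keeps the pure running max.

    Attributes
    ----------
    e_vec_ : ndarray
        Learned per-axis threshold, E_avg scale (g).
    segments_ : list of ActivitySegment
        Non-impact segments used by the last ``fit``.
    """

    def __init__(
        self,
        strategy: str = "per_axis_max",
        n_mode: str = "adaptive",
        fixed_n: int = 30,
        tau_ms: float = DEFAULT_TAU_MS,
        edge_factor: float = math.e,
        baseline_buffer: int = 5,
        forgetting: float | None = None,
    ):
        self.strategy = strategy
        self.n_mode = n_mode
        self.fixed_n = fixed_n
        self.tau_ms = tau_ms
        self.edge_factor = edge_factor
        self.baseline_buffer = baseline_buffer
        self.forgetting = forgetting

    # -------------------------------------------------------------- fit

    def _extract_segments(self, x):
        if isinstance(x, ActivitySegment):
            return [x]
        if isinstance(x, EnergyTrace):
            energy = x
        elif isinstance(x, AccelSeries):
            energy = window_energy(dc_suppress(x), self.tau_ms)
        else:
            raise TypeError(
                "fit inputs must be AccelSeries, EnergyTrace or ActivitySegment"
            )
        return segment_activity(
            energy,
            edge_factor=self.edge_factor,
            baseline_buffer=self.baseline_buffer,
        )

    @staticmethod
    def _is_non_impact(label) -> bool:
        if label in (NON_IMPACT, 0, False, "negative"):
            return True
        if label in (IMPACT, 1, True, "positive"):
            return False
        raise ValueError(f"unrecognized label {label!r}")

    def fit(self, X, y=None):
        if self.strategy not in ("per_axis_max", "vector_magnitude"):
            raise ValueError("strategy must be 'per_axis_max' or 'vector_magnitude'")
        items = list(X)
        if y is not None:
            labels = list(y)
            if len(labels) != len(items):
                raise ValueError("X and y length mismatch")
            items = [x for x, lab in zip(items, labels) if self._is_non_impact(lab)]
        segments = []
        for x in items:
            segments.extend(self._extract_segments(x))
        if not segments:
            raise ValueError("no non-impact segments to learn from")
        self.segments_ = segments
        e_rows = np.vstack([_segment_e_m(s, self.n_mode, self.fixed_n) for s in segments])
        if self.strategy == "per_axis_max":
            self.e_vec_ = e_rows.max(axis=0)
        else:
            self.e_vec_ = e_rows[np.argmax(np.linalg.norm(e_rows, axis=1))].copy()
        self.n_axes_ = self.e_vec_.size
        return self

    def partial_fit(self, segment: ActivitySegment, confirmed_non_impact: bool = True):
        """Continuous update with one new characterized segment."""
        if not confirmed_non_impact:
            return self  # confirmed impacts never move the threshold
        e_m = _segment_e_m(segment, self.n_mode, self.fixed_n)
        if not hasattr(self, "e_vec_"):
            self.e_vec_ = np.atleast_1d(e_m).astype(float).copy()
            self.segments_ = [segment]
            self.n_axes_ = self.e_vec_.size
            return self
        current = self.e_vec_
        if self.forgetting is not None:
            current = current * float(self.forgetting)
        if self.strategy == "per_axis_max":
            self.e_vec_ = np.maximum(current, e_m)
        else:
            if np.linalg.norm(e_m) > np.linalg.norm(current):
                self.e_vec_ = np.atleast_1d(e_m).astype(float).copy()
            else:
                self.e_vec_ = current
        self.segments_.append(segment)
        return self

    # -------------------------------------------------- conveniences

    @property
    def threshold_(self) -> LearnedThreshold:
        return LearnedThreshold(self.e_vec_, self.strategy, self.n_mode)

    def to_detector(self, **overrides):
        """Anisotropic detector configured with the learned threshold."""
        from .detector import ImpactDetector

        params = dict(mode="anisotropic", energy_threshold=self.e_vec_.copy())
        params.update(overrides)
        return ImpactDetector(**params)


def learn_threshold(
    segments, strategy: str = "per_axis_max", n_mode: str = "adaptive", fixed_n: int = 30
) -> LearnedThreshold:
    """Batch threshold from non-impact segments (functional form)."""
    learner = ThresholdLearner(strategy=strategy, n_mode=n_mode, fixed_n=fixed_n)
    learner.fit(list(segments))
    return learner.threshold_


def continuous_update(
    current: LearnedThreshold,
    new_segment: ActivitySegment,
    confirmed_non_impact: bool,
    forgetting: float | None = None,
) -> LearnedThreshold:
    """One step of the continuous learning rule (pure function)."""
    learner = ThresholdLearner(
        strategy=current.strategy, n_mode=current.n_mode, forgetting=forgetting
    )
    learner.e_vec_ = current.e_vec.copy()
    learner.segments_ = []
    learner.n_axes_ = current.e_vec.size
    learner.partial_fit(new_segment, confirmed_non_impact=confirmed_non_impact)
    return LearnedThreshold(learner.e_vec_, current.strategy, current.n_mode)
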