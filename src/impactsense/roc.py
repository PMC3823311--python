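"""ROC-space evaluation of impact detectors.

A detector configuration is scored against a labeled activity study:
an impact activity counts as a true positive when the detector fires at
least once anywhere in its trace, a non-impact activity as a false
positive when it fires.  Sweeping the threshold parameters maps the
parameter space into ROC space; the enveloping (Pareto) curve and its
area (AUC) summarise the detector family, and the optimal region

    R_opt = { thresholds : tpr = 1 and fpr < alpha }

captures the operating points that miss no impact while keeping the
false-alarm rate below ``alpha``.  Robustness of R_opt is reported as the
half-widths of the largest axis-aligned box inscribed in the region,
both in g and in ADC counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .detector import (
    DEFAULT_HOLD_MS,
    ImpactDetector,
    detection_summary,
)
from .signal import DEFAULT_TAU_MS, QuantizationSpec, g_to_counts, n_window
from .study import IMPACT, NON_IMPACT, LabeledStudy

__all__ = [
    "ROCPoint",
    "ROCSurface",
    "OptRegion",
    "evaluate",
    "sweep",
    "envelope_auc",
    "extract_ropt",
    "objective_f",
    "compare_personalization",
    "PersonalizationReport",
]


@dataclass(frozen=True)
class ROCPoint:
    thresholds: tuple
    tpr: float
    fpr: float
    tp: int
    fp: int


@dataclass
class ROCSurface:
    points: list
    envelope: np.ndarray  # (m, 2) [fpr, tpr] vertices, anchors included
    auc: float
    mode: str = ""
    param_names: tuple = ()
    param_grids: tuple = ()
    tpr_grid: np.ndarray | None = None
    fpr_grid: np.ndarray | None = None
    tau_ms: float = DEFAULT_TAU_MS
    hold_ms: float = DEFAULT_HOLD_MS
    t_s_ms: float = 27.5
    p: int = 0
    n: int = 0


@dataclass
class OptRegion:
    alpha: float
    thresholds: list
    min_fpr_at_tpr1: float
    center: tuple | None = None
    robustness_g: dict = field(default_factory=dict)
    robustness_counts: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return len(self.thresholds) == 0


def evaluate(detector: ImpactDetector, study: LabeledStudy) -> ROCPoint:
    """Score one configuration by running the streaming detector on every
    activity of the study (the slow, reference route)."""
    study.validate()
    tp = fp = 0
    for act in study:
        fired = len(detector.detect(act.series)) > 0
        if act.label == IMPACT and fired:
            tp += 1
        elif act.label == NON_IMPACT and fired:
            fp += 1
    thr = detector.energy_threshold
    if detector.mode == "isotropic_full":
        thresholds = (float(detector.amplitude_threshold), float(thr))
    elif detector.mode == "anisotropic":
        thresholds = tuple(float(v) for v in np.atleast_1d(thr))
    else:
        thresholds = (float(thr),)
    return ROCPoint(thresholds, tp / study.p, fp / study.n, tp, fp)


def envelope_auc(points):
    """Pareto-maximal staircase of ROC points and its trapezoidal area.

    The anchors (0, 0) and (1, 1) are always part of the construction;
    dominated points (another point with fpr <= and tpr >=, strictly
    better somewhere) never affect the envelope or the AUC.
    """
    pts = sorted(
        {(float(p.fpr), float(p.tpr)) for p in points}, key=lambda q: (q[0], -q[1])
    )
    env = []
    best = -np.inf
    for f, t in pts:
        if t > best:
            env.append((f, t))
            best = t
    # anchors: the all-negative and all-positive classifiers always exist,
    # so the staircase starts at (0, 0) and ends at (1, 1) even when they
    # are dominated (the segments they add are vertical/horizontal)
    if not env or env[0] != (0.0, 0.0):
        env.insert(0, (0.0, 0.0))
    if env[-1] != (1.0, 1.0):
        env.append((1.0, 1.0))
    env = np.asarray(env)
    auc = float(np.trapezoid(env[:, 1], env[:, 0]))
    return env, auc


def _default_grid(lo, hi, n):
    return np.linspace(lo, hi, n)


def sweep(
    study: LabeledStudy,
    mode: str = "anisotropic",
    energy_grid=None,
    amplitude_grid=None,
    tau_ms: float = DEFAULT_TAU_MS,
    hold_ms: float = DEFAULT_HOLD_MS,
    amplitude_on: str = "ac",
    n_grid_2d: int = 64,
    n_grid_nd: int = 24,
    max_evals: int = 1_000_000,
) -> ROCSurface:
    """Grid sweep of the threshold space against a labeled study.

    Each activity trace is reduced once to a threshold-independent
    detection summary (per-axis peak E_avg; for the full isotropic mode
    additionally the amplitude/hold-window-energy Pareto structure), after
    which every grid point is evaluated by exact vectorised comparisons —
    the result is identical, activity by activity, to running the
    streaming detector at that grid point.

    Grids default to ``n_grid_2d`` (scalar modes) or ``n_grid_nd``
    (per-axis mode) linearly spaced values from 0 to just above the
    largest value observed in the study, so both ROC corners are reached.
    """
    study.validate()
    summaries = [
        detection_summary(a.series, tau_ms, hold_ms, amplitude_on) for a in study
    ]
    is_pos = np.array([a.label == IMPACT for a in study])
    p, n = study.p, study.n
    n_axes = study.activities[0].series.n_axes
    peaks = np.vstack([s.peak_e_avg for s in summaries])  # (n_act, n_axes)

    if mode == "isotropic_energy":
        if energy_grid is None:
            energy_grid = _default_grid(0.0, 1.05 * peaks.max(), n_grid_2d)
        e = np.asarray(energy_grid, dtype=float)
        _check_cap(e.size, max_evals)
        fires = peaks.max(axis=1)[None, :] > e[:, None]  # (n_cfg, n_act)
        thr_tuples = [(float(v),) for v in e]
        param_names, param_grids, shape = ("E",), (e,), (e.size,)

    elif mode == "anisotropic":
        if energy_grid is None:
            energy_grid = [
                _default_grid(0.0, 1.05 * peaks[:, i].max(), n_grid_nd)
                for i in range(n_axes)
            ]
        elif isinstance(energy_grid, np.ndarray) and energy_grid.ndim == 1:
            energy_grid = [np.asarray(energy_grid, float)] * n_axes
        grids = [np.asarray(g, dtype=float) for g in energy_grid]
        if len(grids) != n_axes:
            raise ValueError(f"need one energy grid per axis ({n_axes})")
        shape = tuple(g.size for g in grids)
        n_cfg = int(np.prod(shape))
        _check_cap(n_cfg, max_evals)
        mesh = np.stack(
            [m.ravel() for m in np.meshgrid(*grids, indexing="ij")], axis=1
        )  # (n_cfg, n_axes)
        fires = np.empty((n_cfg, len(study)), dtype=bool)
        chunk = max(1, 4_000_000 // (len(study) * n_axes))
        for i0 in range(0, n_cfg, chunk):
            blk = mesh[i0 : i0 + chunk]
            fires[i0 : i0 + blk.shape[0]] = (
                peaks[None, :, :] > blk[:, None, :]
            ).any(axis=2)
        thr_tuples = [tuple(row) for row in mesh]
        param_names = tuple(f"E{i + 1}" for i in range(n_axes))
        param_grids = tuple(grids)

    elif mode == "isotropic_full":
        amax = max(s.amp_sorted[0] if s.amp_sorted.size else 0.0 for s in summaries)
        if amplitude_grid is None:
            amplitude_grid = _default_grid(0.0, 1.05 * amax, n_grid_2d)
        if energy_grid is None:
            energy_grid = _default_grid(0.0, 1.05 * peaks.max(), n_grid_2d)
        a = np.asarray(amplitude_grid, dtype=float)
        e = np.asarray(energy_grid, dtype=float)
        _check_cap(a.size * e.size, max_evals)
        best = np.vstack(
            [s.best_energy_given_amplitude(a) for s in summaries]
        )  # (n_act, nA)
        fires = (best[:, :, None] > e[None, None, :]).transpose(1, 2, 0)
        fires = fires.reshape(a.size * e.size, len(study))
        thr_tuples = [(float(av), float(ev)) for av, ev in product(a, e)]
        param_names, param_grids, shape = ("A", "E"), (a, e), (a.size, e.size)

    else:
        raise ValueError(f"unknown mode {mode!r}")

    tp = fires[:, is_pos].sum(axis=1)
    fp = fires[:, ~is_pos].sum(axis=1)
    tpr = tp / p
    fpr = fp / n
    pts = [
        ROCPoint(thr_tuples[i], float(tpr[i]), float(fpr[i]), int(tp[i]), int(fp[i]))
        for i in range(len(thr_tuples))
    ]
    env, auc = envelope_auc(pts)
    t_s = study.activities[0].series.t_s
    return ROCSurface(
        points=pts,
        envelope=env,
        auc=auc,
        mode=mode,
        param_names=param_names,
        param_grids=param_grids,
        tpr_grid=tpr.reshape(shape),
        fpr_grid=fpr.reshape(shape),
        tau_ms=tau_ms,
        hold_ms=hold_ms,
        t_s_ms=t_s,
        p=p,
        n=n,
    )


def _check_cap(n_cfg, max_evals):
    if n_cfg > max_evals:
        raise ValueError(
            f"grid has {n_cfg} configurations, above the cap of {max_evals}; "
            "coarsen the grid or raise max_evals"
        )
    if n_cfg < 1:
        raise ValueError("empty grid")


# ----------------------------------------------------------- R_opt


def _largest_box(mask: np.ndarray):
    """Chebyshev center and per-dimension half-widths (in grid steps) of
    the largest axis-aligned box of True cells inside ``mask``.

    The box must lie inside the grid: region touching the swept border is
    not extrapolated.  The cube radius is found by iterative erosion; the
    cube at the Chebyshev center is then greedily stretched one dimension
    at a time.
    """
    from scipy.ndimage import binary_erosion

    if not mask.any():
        return None, None
    radius = np.zeros(mask.shape, dtype=int)
    cur = mask.copy()
    structure = np.ones((3,) * mask.ndim, dtype=bool)
    r = 0
    while cur.any():
        radius[cur] = r
        cur = binary_erosion(cur, structure=structure, border_value=0)
        r += 1

    def box_ok(center, h):
        sl = []
        for c, w, size in zip(center, h, mask.shape):
            if c - w < 0 or c + w >= size:
                return False
            sl.append(slice(c - w, c + w + 1))
        return bool(mask[tuple(sl)].all())

    def grow(center):
        half = [int(radius[tuple(center)])] * mask.ndim
        grew = True
        while grew:  # round-robin per-dimension stretching
            grew = False
            for d in range(mask.ndim):
                trial = list(half)
                trial[d] += 1
                if box_ok(center, trial):
                    half[d] = trial[d]
                    grew = True
        return half

    candidates = np.argwhere(radius == radius.max())
    if len(candidates) > 128:
        candidates = candidates[:: max(1, len(candidates) // 128)]
    best = None
    for cand in map(tuple, candidates):
        half = grow(cand)
        vol = float(np.prod([2 * w + 1 for w in half]))
        if best is None or vol > best[0]:
            best = (vol, cand, half)
    return best[1], best[2]


def extract_ropt(
    surface: ROCSurface,
    alpha: float,
    quant: QuantizationSpec = QuantizationSpec(),
) -> OptRegion:
    """Optimal parameter region: tpr = 1 (exact count equality) and
    fpr < alpha, with robustness half-widths in g and in counts."""
    if surface.tpr_grid is None:
        raise ValueError("surface carries no grid; run it through sweep()")
    mask = (surface.tpr_grid >= 1.0) & (surface.fpr_grid < alpha)
    tpr1 = surface.fpr_grid[surface.tpr_grid >= 1.0]
    min_fpr = float(tpr1.min()) if tpr1.size else float("inf")

    thresholds = []
    if mask.any():
        idx = np.argwhere(mask)
        for row in idx:
            thresholds.append(
                tuple(float(g[i]) for g, i in zip(surface.param_grids, row))
            )

    region = OptRegion(alpha=alpha, thresholds=thresholds, min_fpr_at_tpr1=min_fpr)
    center, half = _largest_box(mask)
    if center is not None:
        region.center = tuple(
            float(g[i]) for g, i in zip(surface.param_grids, center)
        )
        n_w = n_window(surface.tau_ms, surface.t_s_ms)
        for name, grid, c, w in zip(
            surface.param_names, surface.param_grids, center, half
        ):
            hw_g = float((grid[c + w] - grid[c - w]) / 2.0) if w > 0 else 0.0
            region.robustness_g[name] = hw_g
            scale = "amplitude" if name.startswith("A") else "e_avg"
            region.robustness_counts[name] = int(
                g_to_counts(hw_g, quant, scale=scale, n_w=n_w)
            )
    return region


def objective_f(tpr: float, fpr: float, p: int, n: int) -> float:
    """Objective F = N (3 tpr - 1) - P fpr; maximising it does not
    guarantee tpr = 1, which is why R_opt replaces it."""
    return n * (3.0 * tpr - 1.0) - p * fpr


# ------------------------------------------- personalization comparison


@dataclass
class PersonalizationReport:
    mean_auc: float
    auc_avg: float
    gap: float
    combo_aucs: list
    unit_aucs: list


def compare_personalization(
    study: LabeledStudy,
    n_units_per_combo: int = 8,
    n_combos: int = 10,
    seed=None,
    **sweep_kwargs,
) -> PersonalizationReport:
    """Quantify how far a detector family run on grouped data sits from
    its per-set ceiling.

    ``n_combos`` random groups of ``n_units_per_combo`` (subject, set)
    units are drawn; the mean of their sweep AUCs is compared with
    ``AUC_avg``, the average of single-unit AUCs (the easiest controlled
    classification each unit admits).  The gap ``AUC_avg - mean AUC``
    shrinks as the activity energies become consistent across the grouped
    units — i.e. it measures the price of sharing thresholds.
    """
    units = study.units()
    if len(units) < n_units_per_combo:
        raise ValueError(
            f"study has {len(units)} units, fewer than {n_units_per_combo}"
        )
    rng = np.random.default_rng(seed)
    combo_aucs = []
    for _ in range(n_combos):
        pick = rng.choice(len(units), size=n_units_per_combo, replace=False)
        sub = study.subset([units[i] for i in pick])
        combo_aucs.append(sweep(sub, **sweep_kwargs).auc)
    unit_aucs = [sweep(study.subset([u]), **sweep_kwargs).auc for u in units]
    mean_auc = float(np.mean(combo_aucs))
    auc_avg = float(np.mean(unit_aucs))
    return PersonalizationReport(
        mean_auc=mean_auc,
        auc_avg=auc_avg,
        gap=auc_avg - mean_auc,
        combo_aucs=combo_aucs,
        unit_aucs=unit_aucs,
    )
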