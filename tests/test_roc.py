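import numpy as np
import pytest

import impactsense as ims
from impactsense.roc import ROCPoint, ROCSurface
from impactsense.study import ActivityRecord, LabeledStudy

from conftest import constant_ac_series

T_S = 27.5


def level_study(impact_levels, non_impact_levels, n=80):
    """Study of constant-|a_AC| traces: labels separable by energy level."""
    acts = []
    for i, lv in enumerate(impact_levels):
        acts.append(
            ActivityRecord(constant_ac_series(lv, n=n, n_axes=3), "impact",
                           activity_type="jump", subject_id="s0", set_id=str(i))
        )
    for i, lv in enumerate(non_impact_levels):
        acts.append(
            ActivityRecord(constant_ac_series(lv, n=n, n_axes=3), "non_impact",
                           activity_type="walk", subject_id="s0", set_id=str(i))
        )
    return LabeledStudy(acts)


def point(fpr, tpr):
    return ROCPoint((0.0,), tpr, fpr, 0, 0)


class TestEvaluate:
    def test_zero_thresholds_catch_everything(self):
        study = level_study([0.3] * 2, [0.1] * 3)
        det = ims.ImpactDetector(mode="isotropic_energy", energy_threshold=0.0)
        pt = ims.evaluate(det, study)
        assert (pt.tpr, pt.fpr) == (1.0, 1.0)

    def test_infinite_thresholds_catch_nothing(self):
        study = level_study([0.3] * 2, [0.1] * 3)
        det = ims.ImpactDetector(mode="isotropic_energy", energy_threshold=np.inf)
        pt = ims.evaluate(det, study)
        assert (pt.tpr, pt.fpr) == (0.0, 0.0)

    def test_hand_counted_rates(self):
        # 4 impacts at 0.3; non-impacts at 0.05 x4 and 0.2 x2; threshold
        # 0.1 catches all impacts and exactly the two energetic negatives
        study = level_study([0.3] * 4, [0.05] * 4 + [0.2] * 2)
        det = ims.ImpactDetector(mode="isotropic_energy", energy_threshold=0.1)
        pt = ims.evaluate(det, study)
        assert pt.tpr == 1.0
        assert pt.fpr == pytest.approx(1 / 3)
        assert (pt.tp, pt.fp) == (4, 2)

    def test_degenerate_study_rejected(self):
        study = level_study([0.3], [])
        det = ims.ImpactDetector(mode="isotropic_energy", energy_threshold=0.1)
        with pytest.raises(ValueError):
            ims.evaluate(det, study)


class TestEnvelopeAUC:
    def test_perfect_classifier(self):
        env, auc = ims.envelope_auc([point(0.0, 1.0)])
        assert auc == pytest.approx(1.0)

    def test_single_midpoint_staircase(self):
        env, auc = ims.envelope_auc([point(0.5, 0.5)])
        assert auc == pytest.approx(0.5)
        np.testing.assert_allclose(env, [[0, 0], [0.5, 0.5], [1, 1]])

    def test_dominated_points_do_not_change_auc(self):
        base = [point(0.2, 0.8), point(0.6, 0.9)]
        _, auc0 = ims.envelope_auc(base)
        _, auc1 = ims.envelope_auc(base + [point(0.3, 0.5), point(0.7, 0.7)])
        assert auc0 == pytest.approx(auc1)

    def test_order_invariance(self):
        pts = [point(0.1, 0.4), point(0.5, 0.8), point(0.3, 0.6)]
        _, a = ims.envelope_auc(pts)
        _, b = ims.envelope_auc(pts[::-1])
        assert a == pytest.approx(b)

    def test_envelope_monotone_and_anchored(self):
        pts = [point(0.4, 0.2), point(0.2, 0.7), point(0.8, 0.9)]
        env, _ = ims.envelope_auc(pts)
        assert tuple(env[0]) == (0.0, 0.0) and tuple(env[-1]) == (1.0, 1.0)
        assert np.all(np.diff(env[:, 0]) >= 0)
        assert np.all(np.diff(env[:, 1]) >= 0)


class TestSweep:
    def test_separable_study_reaches_auc_one(self):
        study = level_study([0.30, 0.35, 0.4], [0.05, 0.08, 0.1, 0.12])
        surf = ims.sweep(study, mode="isotropic_energy")
        assert surf.auc == pytest.approx(1.0)

    def test_single_point_grid(self):
        study = level_study([0.3] * 2, [0.1] * 2)
        surf = ims.sweep(study, mode="isotropic_energy", energy_grid=[0.2])
        assert len(surf.points) == 1
        assert surf.points[0].tpr == 1.0 and surf.points[0].fpr == 0.0

    def test_grid_cap_refused_with_guidance(self):
        study = level_study([0.3], [0.1])
        with pytest.raises(ValueError, match="cap"):
            ims.sweep(study, mode="isotropic_energy",
                      energy_grid=np.linspace(0, 1, 50), max_evals=10)

    def test_sweep_matches_streaming_evaluate_on_every_grid_point(
        self, personalized_study
    ):
        # dual route: vectorised grid reduction vs per-config streaming
        study, _ = personalized_study
        sub = LabeledStudy(study.activities[:22])  # 2 sets, keeps it quick
        grids = [np.linspace(0, 0.25, 4)] * 3
        surf = ims.sweep(sub, mode="anisotropic", energy_grid=grids)
        for pt in surf.points:
            det = ims.ImpactDetector(mode="anisotropic",
                                     energy_threshold=list(pt.thresholds))
            ref = ims.evaluate(det, sub)
            assert (pt.tp, pt.fp) == (ref.tp, ref.fp), pt.thresholds

    def test_full_mode_sweep_matches_streaming(self, personalized_study):
        study, _ = personalized_study
        sub = LabeledStudy(study.activities[:22])
        surf = ims.sweep(sub, mode="isotropic_full",
                         amplitude_grid=np.linspace(0, 1.2, 4),
                         energy_grid=np.linspace(0, 0.25, 4))
        for pt in surf.points:
            det = ims.ImpactDetector(mode="isotropic_full",
                                     amplitude_threshold=pt.thresholds[0],
                                     energy_threshold=pt.thresholds[1])
            ref = ims.evaluate(det, sub)
            assert (pt.tp, pt.fp) == (ref.tp, ref.fp), pt.thresholds

    def test_rates_monotone_in_each_threshold(self, personalized_study):
        study, _ = personalized_study
        surf = ims.sweep(study, mode="anisotropic",
                         energy_grid=[np.linspace(0, 0.3, 8)] * 3)
        for axis in range(3):
            assert np.all(np.diff(surf.tpr_grid, axis=axis) <= 1e-12)
            assert np.all(np.diff(surf.fpr_grid, axis=axis) <= 1e-12)


class TestOptRegion:
    def _surface(self, fpr_at_tpr1):
        # 1-D grid: tpr = 1 below some index, fpr decreasing
        e = np.linspace(0, 1, 11)
        tpr = np.where(e < 0.85, 1.0, 0.5)
        fpr = np.maximum(fpr_at_tpr1, 1.0 - e)
        pts = [ROCPoint((float(v),), float(t), float(f), 0, 0)
               for v, t, f in zip(e, tpr, fpr)]
        return ROCSurface(points=pts, envelope=np.zeros((2, 2)), auc=0.9,
                          mode="isotropic_energy", param_names=("E",),
                          param_grids=(e,), tpr_grid=tpr, fpr_grid=fpr)

    def test_region_empty_when_min_fpr_exceeds_alpha(self):
        reg = ims.extract_ropt(self._surface(0.46), alpha=0.4)
        assert reg.empty
        assert reg.min_fpr_at_tpr1 == pytest.approx(0.46)

    def test_region_bounds_when_min_fpr_below_alpha(self):
        reg = ims.extract_ropt(self._surface(0.25), alpha=0.4)
        assert not reg.empty
        fprs = []
        surf = self._surface(0.25)
        for thr in reg.thresholds:
            i = int(np.argmin(np.abs(surf.param_grids[0] - thr[0])))
            fprs.append(surf.fpr_grid[i])
        assert min(fprs) >= 0.25 and max(fprs) < 0.4

    def test_alpha_one_takes_all_perfect_sensitivity_points(self):
        surf = self._surface(0.25)
        reg = ims.extract_ropt(surf, alpha=1.0)
        expect = int(((surf.tpr_grid >= 1.0) & (surf.fpr_grid < 1.0)).sum())
        assert len(reg.thresholds) == expect

    def test_robustness_box_lies_inside_region(self, personalized_study):
        study, _ = personalized_study
        surf = ims.sweep(study, mode="anisotropic",
                         energy_grid=[np.linspace(0, 0.3, 12)] * 3)
        reg = ims.extract_ropt(surf, alpha=0.4)
        if not reg.empty and reg.center is not None:
            for name in surf.param_names:
                assert reg.robustness_g[name] >= 0
                assert reg.robustness_counts[name] >= 0


class TestObjectiveF:
    @pytest.mark.parametrize(
        "tpr,fpr,p,n,expect",
        [
            (1.0, 0.0, 48, 40, 80.0),  # 2 N
            (1 / 3, 0.0, 48, 40, 0.0),
            (1.0, 0.25, 48, 40, 68.0),
        ],
    )
    def test_direct_substitution(self, tpr, fpr, p, n, expect):
        assert ims.objective_f(tpr, fpr, p, n) == pytest.approx(expect)


class TestComparePersonalization:
    def test_whole_study_combo_recovers_full_auc(self, personalized_study):
        study, _ = personalized_study
        rep = ims.compare_personalization(
            study, n_units_per_combo=8, n_combos=1, seed=0,
            mode="isotropic_energy",
        )
        full = ims.sweep(study, mode="isotropic_energy").auc
        assert rep.mean_auc == pytest.approx(full)

    def test_cloned_units_have_zero_gap(self):
        study = level_study([0.3, 0.35], [0.05, 0.1])
        # clone the same 4 activities into 3 identical units
        acts = []
        for u in range(3):
            for a in study.activities:
                acts.append(ActivityRecord(a.series, a.label,
                                           a.activity_type, f"s{u}", "0"))
        cloned = LabeledStudy(acts)
        rep = ims.compare_personalization(
            cloned, n_units_per_combo=2, n_combos=3, seed=1,
            mode="isotropic_energy", energy_grid=np.linspace(0, 0.4, 32),
        )
        assert rep.gap == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_units_rejected(self):
        study = level_study([0.3], [0.1])
        with pytest.raises(ValueError):
            ims.compare_personalization(study, n_units_per_combo=8, n_combos=1)
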