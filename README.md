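# impactsense

Adaptive, energy-based impact detection for wearable accelerometry.

Falls are the leading physical risk event for older adults, and wearable
fall monitors live or die by two numbers: sensitivity (no missed fall)
and specificity (no alarm fatigue).  `impactsense` implements the
first-layer *impact detector* of such a monitor — a family of threshold
algorithms light enough for an 8-bit sensor node — together with the
unsupervised, per-subject threshold learning that keeps the detector
tuned to its wearer, and the ROC methodology used to show that an
optimal operating region exists, is robust, and is reachable by that
learning rule.

## The method

A trace of 3 (or 4) acceleration axes `a_i(t)`, sampled at
`t_s = 27.5 ms`, is DC-suppressed with a two-tap FIR filter

```
a_AC,i(t) = (a_i(t) − a_i(t − t_s)) / 2
```

and reduced to a windowed energy: the sum of `|a_AC,i|` over the last
`τ = 660 ms` (`N_w = 24` samples), reported on the *E_avg* scale
(divided by `N_w`, so thresholds stay in g).  Three detectors share the
flag-and-hold logic in which each threshold crossing raises a per-axis
binary flag that stays up for `t_h = 1.76 s`:

* **isotropic full** — `h = (OR_i af_i) AND (OR_i ef_i)`: an amplitude
  crossing (`|a_i| > A`) and an energy crossing (`E_AC,i > E`) must
  co-occur within the hold time;
* **isotropic energy-only** — `h = OR_i ef_i` with a scalar `E`
  (amplitude carries no useful information about impacts);
* **anisotropic** — `h = OR_i ef_i` with a per-axis vector
  `(E_1, E_2, E_3)`, the preferred variant.

Thresholds are learned without supervision: each activity bout is
segmented from the energy trace (a factor-*e* level change marks its
edges), characterized by its mean energy `E_m` (an incrementally
maintained running mean over `n` windows), and the per-axis threshold is
the running **maximum of `E_m` over non-impact bouts**.  Because every
subject has a characteristic energy per activity, this places the
detector inside the optimal region

```
R_opt = { thresholds : tpr = 1  and  fpr < α }
```

whose existence, robustness (in ADC counts, 128 counts = 2 g) and
reachability the ROC machinery in `impactsense.roc` quantifies.

The laboratory data behind the original study are not deposited, so
`impactsense.synthetic` generates seeded surrogate studies that follow
the published 11-activity protocol (5 walking/stair tasks, 6 jump/fall
tasks on hard and soft floor) with per-activity energy and duration
statistics matching the published table, in the two layouts of interest:
*personalized* (1 subject × 8 sets = 88 activities) and
*non-personalized* (12 subjects × 1 set = 132 activities).

## Worked example

```python
import impactsense as ims

# a personalized synthetic study: 1 subject x 8 sets x 11 activities
study, _ = ims.generate_study(ims.personalized_spec(seed=1))

# unsupervised threshold learning on the non-impact traces only
learner = ims.ThresholdLearner(strategy="per_axis_max").fit(
    [a.series for a in study if a.label == "non_impact"]
)
print("learned E_vec (g):", learner.e_vec_.round(4))

# the learned operating point
point = ims.evaluate(learner.to_detector(), study)
print(f"tpr = {point.tpr:.3f}, fpr = {point.fpr:.3f}")

# ROC sweep of the anisotropic family and the optimal region
surface = ims.sweep(study, mode="anisotropic")
region = ims.extract_ropt(surface, alpha=0.4)
print(f"AUC = {surface.auc:.4f}, min fpr at tpr = 1: {region.min_fpr_at_tpr1:.3f}")
```

prints

```
learned E_vec (g): [0.0621 0.1242 0.0452]
tpr = 1.000, fpr = 0.375
AUC = 0.9995, min fpr at tpr = 1: 0.025
```

i.e. the learned per-axis threshold misses none of the 48 impact
activities while flagging 15 of the 40 non-impact ones (specificity
62.5%), and the anisotropic family's enveloping ROC curve has area
0.9995 with perfect-sensitivity points available down to fpr = 0.025.

The same workflow is available from the shell:

```
impactsense simulate --preset personalized --seed 1 --out study_dir/
impactsense learn --input study_dir/ --strategy per-axis-max --out thr.yaml
impactsense eval-point --study study_dir/ --threshold-yaml thr.yaml
impactsense roc --study study_dir/ --mode anisotropic --alpha 0.4 --out roc_out/
```

## Layout

| module | contents |
| --- | --- |
| `impactsense.signal` | `AccelSeries`, DC suppression, windowed energy, g↔counts |
| `impactsense.detector` | `ImpactDetector` (the three algorithms, flag/hold logic) |
| `impactsense.learning` | segmentation, `E_m`, running mean, `ThresholdLearner` |
| `impactsense.roc` | evaluate / sweep / envelope+AUC / `R_opt` / personalization |
| `impactsense.synthetic` | activity profiles, subject factors, study generator |
| `impactsense.io`, `impactsense.cli` | CSV/YAML formats and the `impactsense` CLI |

See `docs/methods.md` for the model details, the synthetic-data design
and its limitations, and the numerical choices.
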