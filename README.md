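# thermofusion

Multi-view infrared breast-thermogram classification with late fusion
and a clinical-data decision.

## What this is for

Breast thermography images the skin temperature field of the torso; a
tumour's elevated metabolism raises the local temperature, so lesions
appear as hotspots. A screening study contributes five views per patient
(front, left 45°, left 90°, right 90°, right 45°) as *thermal matrices* —
per-pixel temperature grids in °C — plus a clinical questionnaire
(symptoms, history, lifestyle, age, menarche age).

`thermofusion` implements, as tested and reusable scikit-learn-style
estimators, the late-fusion analysis for this setting:

- a small CNN per view v emitting a probability pair
  [P(H_v), P(S_v)] (conv stride 2, 2×2 max pooling; channel stacks
  32/64/128, or 45/90/135/180 lateral with 50/100/150/200 frontal);
- a clinical MLP whose sigmoid output p is thresholded at 0.5 into the
  **clinical-data decision** d = 1{p ≥ 0.5};
- a fusion network trained on the concatenated tuple
  (P(H_front), P(S_front), …, P(H_left90), P(S_left90) [, d]) —
  10 elements for five views, 11 with the clinical decision;
- the full preprocessing chain: image QC (missing views, blur, injury,
  protocol violations, dynamic-protocol substitution), bilinear resize to
  square, clinical cleaning (age anomalies, "not answered" filling),
  leakage-free one-hot + min–max encoding, and a stratified 80/20 split
  with round-half-up test counts (157 → 126/31, 84 → 67/17);
- evaluation with sick as the positive class: accuracy, sensitivity,
  specificity, precision, F1, ROC and precision–recall curves with
  trapezoidal AUCs and no-skill baselines, and a with/without-clinical
  comparison table.

Because the underlying screening database cannot be redistributed, the
package ships a first-class synthetic cohort generator
(`thermofusion.synthetic`): five correlated views per patient, lateralised
lesion hotspots with controllable contrast ΔT, class-conditional clinical
features with a single effect-size dial, and injectable QC defects so
every preprocessing rule can be exercised. See `docs/methods.md` for the
model, the generator's assumptions and its limits.

Since no deep-learning framework is a dependency, the networks run on a
compact, fully deterministic numpy engine (`thermofusion.nn`) with
explicit backpropagation, verified against finite differences.

## Worked example

```python
from thermofusion import SyntheticConfig, TrainConfig, run_experiment

config = SyntheticConfig(
    n_healthy=50, n_sick=50, image_height=64, image_width=64,
    hotspot_delta_t=3.0, clinical_effect=0.75, pixel_noise_sd=0.3, seed=7,
)
result = run_experiment(config, train_config=TrainConfig(seed=7, max_epochs_per_view=20))
print("per-view test accuracy:",
      {v: round(a, 3) for v, a in result.view_accuracies.items()})
print("fused accuracy, no clinical decision:",
      round(result.report_without_cd.accuracy, 3))
print("fused accuracy, with clinical decision:",
      round(result.report_with_cd.accuracy, 3))
print(result.comparison().round(3).to_string(index=False))
```

Output:

```
per-view test accuracy: {'front': 0.8, 'left90': 0.6, 'right90': 0.7}
fused accuracy, no clinical decision: 0.75
fused accuracy, with clinical decision: 1.0
     metric  without_cd  with_cd  delta
   accuracy       0.750      1.0  0.250
sensitivity       0.800      1.0  0.200
specificity       0.700      1.0  0.300
  precision       0.727      1.0  0.273
         f1       0.762      1.0  0.238
    roc_auc       0.860      1.0  0.140
     pr_auc       0.931      1.0  0.069
```

The 100-patient cohort plants a 3 °C lesion hotspot in the front and two
ipsilateral views of each sick patient and strongly shifts their symptom
rates. Individual views reach 0.6–0.8 test accuracy (lateral views only
see lesions on their own side); fusing the three probability pairs and
appending the clinical decision lifts the 20-patient test set to perfect
classification. On a null cohort (`hotspot_delta_t=0, clinical_effect=0`)
the same pipeline reports chance-level accuracy — see
`tests/test_acceptance.py`.

The same workflow is available from the shell:

```bash
thermofusion run --seed 1 --views 3 --image-side 64 --out results/run1
thermofusion generate --seed 1 --n-healthy 20 --n-sick 20 --image-side 64 --out results/cohort
```

`run` writes `report_without_cd.json`, `report_with_cd.json`,
`comparison.csv`, per-model loss-history CSVs, curve point lists and
checkpoints; reruns with the same seed are byte-identical.

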