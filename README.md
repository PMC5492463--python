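# semg-actmon

Benchmarking surface-EMG feature extraction and classification for
daily-activity monitoring and fall detection.

Wearable surface electromyography (sEMG) records the electrical activity of
muscles through skin electrodes. Because lower-limb muscles fire in
movement-specific patterns — and fire *before* the body actually moves — sEMG
is an attractive signal for recognising activities of daily living (ADLs) and
for detecting falls early enough to react before impact. The practical design
question is which of the many proposed sEMG features and classifiers to put
on a small wearable device, trading recognition accuracy against computation
time.

This package implements that evaluation end to end for a four-channel
lower-limb montage (gastrocnemius, rectus femoris, tibialis anterior,
semitendinosus) sampled at 1024 Hz in 1.5 s epochs (1536 samples), with eight
activity classes: stand-to-squat, squat-to-stand, stand-to-sit, sit-to-stand,
stair-ascending, stair-descending, walking, and trip-fall. It is aimed at
researchers in biomedical signal processing and wearable-system designers who
want a reproducible, fully tested pipeline.

## What is inside

* **`semg_actmon.synth`** — a generator of labeled synthetic sEMG datasets:
  band-limited (20–450 Hz) Gaussian carriers shaped by activity- and
  channel-specific trapezoidal burst envelopes on top of 1.25 μV-rms baseline
  noise, with per-subject envelope jitter and a controllable inter-class
  `separation`. The trip-fall class gets the sharpest, highest burst on all
  channels.
* **`semg_actmon.features`** — the 15 standard myoelectric feature types,
  applied per channel and concatenated:
  time domain IAV, VAR, WAMP, ZC, NT, MA, HIST, AR, ARCU; frequency domain
  MF; wavelet domain EWT, EWP, ZCWT (db8); entropies FE (fuzzy) and PE
  (permutation). For example the Willison amplitude counts threshold
  exceedances of consecutive differences, WAMP = Σᵢ u(|xᵢ₊₁ − xᵢ| − T), and
  permutation entropy is H(n) = −Σ_π p(π) ln p(π) over ordinal patterns of n
  consecutive samples.
* **`semg_actmon.separability`** — Fisher class separability
  J = tr(S_B)/tr(S_W) per feature type, the weighted performance index
  index = (1 − w)·a + w·t that trades normalised separability *a* against
  inverse-normalised extraction time *t*, and Spearman rank agreement of
  per-subject feature rankings.
* **`semg_actmon.classifiers`** — five classifiers behind one train/predict
  contract: linear Fisher discriminant analysis (FDA), the fuzzy min–max
  neural network (FMMNN), Gaussian-kernel Fisher discriminant (GK-FDA),
  Gaussian-kernel SVM (GK-SVM), and fuzzy c-means with majority-label cluster
  mapping (FCM), plus grid search for the kernel width σ (0.5–5, step 0.1)
  and the hyperbox size θ.
* **`semg_actmon.evaluate`** — stratified five-fold cross-validation with
  nested hyperparameter selection, for 8-class activity recognition and for
  binary fall detection with sensitivity (falls identified correctly) and
  specificity (ADLs identified correctly).

## Worked example

```python
from semg_actmon import (GeneratorConfig, generate_dataset, extract,
                         feature_registry, scatter, tradeoff_index)
from semg_actmon.evaluate import (run_recognition, run_fall_detection,
                                  results_to_frame)

cfg = GeneratorConfig(seed=42, n_epochs_per_class=10, n_subjects=1)
ds = generate_dataset(cfg)          # 80 epochs of 1536 samples x 4 channels

reg = feature_registry()
J, t = {}, {}
for fid in ("WAMP", "MA", "ZC"):
    fm = extract(ds, reg[fid])
    J[fid] = scatter(fm.values, ds.labels).J
    t[fid] = fm.extraction_time_s
tab = tradeoff_index(J, t)
print(tab[tab.w == 0.3][["feature_id", "J", "a", "t", "index"]].round(2))

rec = results_to_frame(run_recognition(ds, ["WAMP", "ZC"], ["GK-SVM"], seed=42))
print(rec[["feature_id", "method", "acc_mean", "acc_std"]].round(2))

fall = results_to_frame(run_fall_detection(ds, ["WAMP"], ["GK-FDA"], seed=42))
print(fall[["feature_id", "method", "sensitivity", "specificity"]].round(2))
```

prints

```
feature_id       J      a      t  index
      WAMP 1082.98 100.00  58.51  87.55
        MA  129.09  11.92  55.89  25.11
        ZC    0.29   0.03 100.00  30.02
feature_id method  acc_mean  acc_std
      WAMP GK-SVM    100.00     0.00
        ZC GK-SVM     31.25    15.31
feature_id method  sensitivity  specificity
      WAMP GK-FDA        100.0        100.0
```

Read this as: on synthetic activities that differ in burst amplitude, the
amplitude-sensitive Willison amplitude dominates the separability ranking
(J ≈ 1083, normalised a = 100) and still wins once 30% of the score weights
computation time (index 87.6), while the amplitude-blind zero-crossing count
is fast (t = 100) but nearly unseparable (J ≈ 0.3) and classifies barely
above the 12.5% chance level of the 8-class task. A GK-FDA fall detector on
WAMP features separates the trip-fall from the seven ADLs perfectly on this
easy dataset.

The same stages are available from the shell:

```sh
semg-actmon synth --config cfg.yaml --out data/ --seed 7
semg-actmon features --data data/ --features WAMP,PE --out feats/
semg-actmon separability --data data/ --out sep/
semg-actmon evaluate --data data/ --out results/
semg-actmon run-all --config cfg.yaml --out results/ --seed 7
```

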