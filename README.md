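# grazeclass

Classification of sheep eating behaviour — **grazing**, **ruminating** and
**non-eating** — from wearable inertial sensors (ear tag or neck collar),
for researchers in biologging and precision livestock monitoring.

A tri-axial accelerometer + gyroscope stream sampled at 16 Hz is reduced to
four orientation-invariant channels: the accelerometer magnitude
A̅ = √(Ax² + Ay² + Az²), the gyroscope magnitude G̅ = √(Gx² + Gy² + Gz²),
and their time derivatives AD and GD. The channels are discretised into 7 s
windows with 50 % overlap (112 samples, hop 56); each window takes the
behaviour label of its samples, or the predominant label when a window
straddles a behaviour transition (a *mixed* window). Eleven feature
characteristics per channel — mean, standard deviation, kurtosis, min, max,
interquartile range, signal area, zero crossings, dominant frequency,
spectral entropy and spectral area — give a 44-dimensional feature vector
per window. Features are ranked by multiclass **ReliefF** (k nearest hits
vs. per-class nearest misses, class-prior weighted, Manhattan distance on
range-normalised features), and four learner types (random forest, RBF SVM,
distance-weighted kNN, AdaBoost) are compared under stratified 10-fold
cross-validation, sweeping the number of top-ranked features. Classifier
performance is summarised from the truth-by-prediction confusion matrix as
per-class precision TP/(TP+FP), recall TP/(TP+FN), F-score
2PR/(P+R), specificity TN/(TN+FP) and overall accuracy (trace / total).

Because no public sheep IMU dataset accompanies the published behaviour
study this pipeline mirrors, the package ships a synthetic trial generator
(`grazeclass.synth`) reproducing the qualitative signal structure reported
for grazing sheep — ruminating has the lowest accelerometer magnitude,
non-eating the highest, and each behaviour a distinct movement rhythm — so
the full pipeline is testable end to end. See `docs/methods.md` for the
signal model and its limitations.

## Worked example

```python
import grazeclass as gc

# published collar random-forest confusion matrix (percent units)
report = gc.confusion_to_metrics(gc.load_collar_confusion())
print(gc.format_report(report))

# synthetic end-to-end run
cfg = gc.TrialConfig(duration_s=600.0, seed=1)
stream, track = gc.generate_trial(cfg)
ws = gc.discretise(gc.build_channels(stream), track)
df = gc.extract_feature_matrix(ws)
X, y = df.drop(columns=["label", "is_mixed"]), df["label"]
ranking = gc.rank_features(gc.relieff_weights(X, y, n_neighbors=54))
res = gc.run_cv(X, y, gc.CvConfig(algorithm="random_forest", seed=0,
                                  feature_subset=ranking.top_n(10)))
print("top 5 features:", ", ".join(ranking.top_n(5)))
print(f"10-fold RF accuracy (top 10 features): {res.mean_accuracy:.4f}")
```

prints

```
Behaviour   Precision  Recall  F-score  Specificity
grazing     96%        93%     95%      98%
non-eating  89%        95%     92%      92%
ruminating  92%        87%     89%      97%
Overall accuracy: 92%

top 5 features: GD.dominant_frequency, A.mean, A.signal_area, G.mean, G.signal_area
10-fold RF accuracy (top 10 features): 0.9882
```

The metric table says, e.g., that 96 % of windows predicted *grazing* truly
were grazing (precision) and 93 % of true grazing windows were found
(recall); the 92 % overall accuracy is the fraction of all windows
classified correctly. On the synthetic trial, gyroscope-derived features
(`G.*`, `GD.*`) surface among the top ReliefF ranks, and a random forest on
the ten best features separates the three behaviours almost perfectly —
the synthetic regimes are deliberately clean.

The same pipeline is scriptable from the shell:

```sh
grazeclass simulate --seed 1 --out trial/
grazeclass extract --stream trial/stream.csv --labels trial/labels.csv --out features.csv
grazeclass rank --features features.csv --out ranking.csv
grazeclass evaluate --features features.csv --ranking ranking.csv --algorithms random_forest
grazeclass metrics --confusion collar.csv --unit percent
```

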