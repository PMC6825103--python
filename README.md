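# eegsex

Entropy-based sex recognition from multichannel resting-state EEG.

EEG regularity differs systematically between male and female adults:
epochs recorded from female subjects tend to show higher signal
complexity. This package turns that observation into a reproducible
classification pipeline for researchers in EEG biometrics and
neurophysiological signal analysis:

1. **Signal I/O and preprocessing** — EDF or delimited recordings; 50 Hz
   notch and 0.15–45 Hz Butterworth band-pass (both zero-phase),
   retention of the final 5 minutes, segmentation into non-overlapping
   1-s epochs.
2. **Entropy features** — per epoch per channel: approximate entropy
   (AE), sample entropy (SE), fuzzy entropy (FE) and permutation entropy
   (PE), with embedding dimension m = 2 and tolerance r = 0.25·SD of the
   epoch's series; features min–max scaled to [−1, 1].
3. **Classifiers** — logistic regression (l1, C = 1.0), random forest
   (200 trees, depth ≤ 5), and the **hybrid model**: every sample is
   re-encoded as the one-hot vector of the leaves it reaches in the
   fitted forest, that sparse encoding is concatenated with the original
   features, and a logistic regression is trained on the combination —
   the forest supplies axis-aligned partitions, the linear model weighs
   them.
4. **Evaluation** — nested 10-fold cross-validation (inner 10-fold grid
   search over nt, md, penalty, C), accuracy and ROC/AUC, Welch group
   comparison of entropy between the sexes, and robustness sweeps over
   electrode count, test fraction, and the male:female subject ratio
   (27 cases, 13:1 … 1:15).
5. **Synthetic cohort** — a seeded generator emulating the study
   geometry (13 male / 15 female subjects, 30 channels, 1000 Hz, 300 s
   → 8400 one-second epochs: 4500 female, 3900 male) with a controllable
   sex-linked regularity gap, so the full pipeline runs end to end
   without any external data.

The core statistic, for a series `x` of length N, embedding m and
tolerance r: sample entropy `SampEn = −ln(A/B)` over Chebyshev template
matches; approximate entropy `ApEn = Φ^m − Φ^{m+1}`; fuzzy entropy with
mean-centred templates and membership `exp(−(d/r)^n)`; permutation
entropy as the normalised Shannon entropy of ordinal patterns. See
`docs/methods.md` for the precise conventions.

## Worked example

Simulate a small cohort with a weak effect size, extract fuzzy-entropy
features, and compare the three classifiers under nested CV:

```bash
cat > demo.yaml <<'YAML'
cohort:
  n_male: 4
  n_female: 4
  n_channels: 4
  fs: 128.0
  duration_s: 30.0
  effect: 0.05
normalize: global
YAML
eegsex full --config demo.yaml --out-dir demo_run --seed 42 --measures FE
```

Output:

```
8 recordings -> demo_run/cohort
240 epochs x 4 features -> demo_run/features.csv
classifier  mean_accuracy  mean_auc
        LR         0.7500  0.834028
        RF         0.8500  0.935417
    hybrid         0.8625  0.941667
```

Eight subjects were simulated (4 male, 4 female; male signals more
regular, hence lower entropy), 240 one-second epochs were cut and their
per-channel fuzzy entropy computed, and each classifier was evaluated by
10-fold cross-validation on the 240 × 4 feature matrix. At this
deliberately weak effect size (δ = 0.05) the problem is hard enough to
separate the classifiers: the forest beats plain logistic regression,
and the hybrid leaf-embedding model edges out both in accuracy and AUC —
the ordering the pipeline is designed to exhibit. With the default
effect size (δ = 0.3) all three saturate near accuracy 1.0.

The same stages are available as library calls:

```python
import eegsex as es

cfg = es.CohortConfig(n_channels=6, fs=128.0, duration_s=60.0, seed=1)
recs = es.generate_cohort(cfg)                     # 28 Recording objects
epochs = es.cohort_epochs(recs, retain_s=None)     # filter + epoch
fm = es.extract_features(epochs, measures=("FE",))
print(es.compare_groups(fm)[["female_mean", "male_mean", "p"]].head(1))
```

```
         female_mean  male_mean    p
feature
Fp1:FE      1.309143   0.788625  0.0
```

Female epochs carry significantly higher fuzzy entropy on every channel
— the group-level effect the classifiers exploit.

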