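# radgs — radiomic Gleason-group prediction with ROI inflation

`radgs` implements a radiomics pipeline for predicting prostate-cancer
Gleason grade groups from co-registered quantitative mp-MRI maps, built
around one idea: radiologist-drawn lesion ROIs systematically under-cover
the true tumour extent, so *inflating* the ROI by iterated binary dilation
admits peritumoral texture that carries grade information and can raise
classification accuracy.

It is aimed at researchers in quantitative MRI / radiomics who want a
tested, reproducible implementation of this analysis — including a
synthetic-data module (image phantoms and feature-table generators) so the
whole pipeline is exercisable without patient data.

## The method

Per pixel, three quantitative parameters are fitted:

- **ADC** (μm²/ms) from multi-b DWI: `S = S₀ exp(−b·ADC)`,
  b ∈ {0, 50, 100, 150, 990, 1500} s/mm²;
- **T2** (ms) from multi-echo imaging: `S = S₀ exp(−TE/T2)`,
  TE = 30…270 ms in 30 ms steps;
- **α** (1/s), the DCE uptake rate of the empirical enhancement model
  `PSE(t) = A(1 − e^{−αt}) e^{−βt}` fitted to the percent-signal-enhancement
  curve sampled every 8.3 s.

For each lesion ROI (and each of its inflation levels, applied as 0–4 turns
of binary dilation with a 2×2 square structuring element) a 21-feature
vector is extracted: the ROI mean of each map plus six gray-level
co-occurrence features per map — energy, entropy, contrast, correlation,
homogeneity and inverse difference moment — computed at 32 gray levels for
the four directions 0°/45°/90°/135° and averaged.

Features are then ranked by ReliefF and only positive-weight features kept;
classes are balanced by SMOTE *inside* training folds; and three classifiers
(RBF-kernel SVM with an inner powers-of-two grid search over C and γ, k=5
Euclidean KNN, Gaussian naive Bayes) are scored by stratified 5-fold
cross-validation (8:2 train/test), reporting the accuracy averaged over
folds for three tasks: clinically-significant (Gleason ≥ 3+4) vs
non-significant (3+3), Gleason 3+4 vs ≥ 4+3, and the 3-class grouping.

## Worked example

Simulate the default 50-lesion phantom cohort (13 / 29 / 7 / 1 lesions of
Gleason 3+3 / 3+4 / 4+3 / 4+5) and sweep ROI inflation for the
significant-vs-nonsignificant task:

```python
from radgs.synthetic import default_phantom_config, gen_cohort
from radgs.experiment import run_dilation_sweep
from radgs.classify import ClassifierSpec

cohort = gen_cohort(default_phantom_config(seed=1))
sweep = run_dilation_sweep(
    cohort, "sig_vs_nonsig",
    [ClassifierSpec(kind="svm_rbf"), ClassifierSpec(kind="gaussian_nb")],
    max_turns=3, seed=1,
)
for level in sweep.levels("sig_vs_nonsig"):
    print(f"turns={level}: "
          f"svm={sweep.accuracy('sig_vs_nonsig', 'svm_rbf', level):.3f}  "
          f"bayes={sweep.accuracy('sig_vs_nonsig', 'gaussian_nb', level):.3f}")
print("best cell:", sweep.best["sig_vs_nonsig"])
```

prints

```
turns=0: svm=0.740  bayes=0.740
turns=1: svm=0.840  bayes=0.840
turns=2: svm=0.940  bayes=0.860
turns=3: svm=0.940  bayes=0.680
turns=4: svm=0.880  bayes=0.720
best cell: ('sig_vs_nonsig', 'svm_rbf', 3)
```

Accuracy on the original ROIs (0.74) rises as inflation captures the
heterogeneous tumour rim, peaks, then degrades once the mask grows past the
lesion — the rise-then-fall trend the inflation hypothesis predicts. (The
sweep extended itself to a 4th turn because accuracy was still rising at
turn 3.) These numbers describe synthetic phantoms, not patients.

The same stages are scriptable from the shell:

```bash
radgs simulate --seed 1 --out cohort/        # phantoms as NIfTI + JSON
radgs extract --seed 1 --level 2 --out features.csv
radgs select --table features.csv --task sig_vs_nonsig
radgs classify --table features.csv --task sig_vs_nonsig --clf svm_rbf
radgs full-study --seed 1 --out study_out/   # all tasks, plots, JSON report
```

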