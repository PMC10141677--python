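# osteotex

Texture-based bone age regression from wrist MRI regions of interest.

Skeletal maturity ("bone age") in children is conventionally read from hand
X-rays. MRI offers a radiation-free alternative: the trabecular pattern of
the distal radius and the bright band of the cartilaginous growth plate both
change systematically through adolescence — the growth band narrows and
calcifies, the trabecular texture becomes finer. `osteotex` implements a
radiomics pipeline that quantifies these changes and regresses integer age
(years) from them. It is aimed at researchers in pediatric imaging and
radiomics who want a reproducible, fully tested reference implementation of
the classic texture-feature approach, runnable end to end without access to
patient data.

## Method

For each scan a rectangular region of interest (ROI) is cropped — either a
fixed pixel size or a fixed metric size in millimetres, resolved through the
DICOM pixel spacing. The region is intensity-normalized with the ±3σ rule

    N(x,y) = L · (I(x,y) − (μ − 3σ)) / (6σ),   clamped to [0, L],

with L = 255 (8-bit PNG) or 4095 (12-bit DICOM), which removes scanner gain
and offset. A 307-feature texture descriptor is then computed:

| family                     | count | contents                                          |
|----------------------------|------:|---------------------------------------------------|
| histogram                  |     9 | mean, variance, skewness, kurtosis, percentiles 1/10/50/90/99 |
| co-occurrence (GLCM)       |   220 | 11 Haralick statistics × 4 directions × distances 1–5 |
| run-length (RLM)           |    20 | 5 Galloway statistics × 4 directions              |
| gradient                   |     5 | moments + nonzero fraction of a 3×3 high-pass map |
| autoregressive             |     5 | 4 causal-neighbor weights θ₁..θ₄ + residual σ     |
| Haar wavelet               |    16 | subband energy, 4 scales × {LL, LH, HL, HH}       |
| Gabor                      |    24 | mean magnitude, 4 orientations × 6 envelope sizes |
| HOG                        |     8 | magnitude-weighted 8-bin orientation histogram    |

The regression model (`TextureAgeModel`) is evaluated with leave-one-out
cross-validation. Inside every fold, fitted on the training rows only: the
15 features with the largest |Spearman ρ| against age are kept, standardized
and projected onto the first 3 principal components, and a perceptron with
two hidden layers of 10 rectified-linear units maps the component scores to
age. Pooled held-out predictions yield R², RMSE, MSE and MAE.

Because clinical scans of minors cannot be distributed, the package ships a
synthetic cohort generator (`generate_cohort`) producing 512×512 12-bit
scans (plus 8-bit exports) with a controllable, monotone age→texture effect:
growth-band width/brightness and trabecular correlation length all shrink
with age. Every stage of the pipeline is exercised and property-tested
against brute-force oracles on these cohorts.

## Worked example

```python
import osteotex as ot

# 30 synthetic patients, 55 usable images, full age effect
cohort = ot.generate_cohort(ot.CohortSpec(effect_strength=1.0, seed=1))
table = ot.cohort_to_feature_table(cohort, roi_kind="bone", modality="T1", bit_depth=12)
results = ot.TextureAgeModel.from_dataframe(table).fit(seed=1)
print(results.summary())
```

```
Texture age regression — leave-one-out results
================================================
samples:    55    folds: 55
selected features per fold: 15
principal components:       3
hidden layers:              (10, 10)
seed: 1    config digest: 681d8fa7289501ca
------------------------------------------------
R2   =   0.8982
RMSE =   0.6375  years
MSE  =   0.4064  years^2
MAE  =   0.4704  years
================================================
```

The pooled leave-one-out R² of 0.90 means 90% of the age variance in the
synthetic cohort is explained by texture alone; the mean absolute error of
0.47 years is comfortably below the 1-year resolution of the labels. With
shuffled age labels the same pipeline yields strongly negative R² —
the signal comes from the planted age→texture relationship, not from
overfitting.

The same pipeline is scriptable from a shell:

```bash
osteotex simulate --out cohort/ --n-patients 30 --total-images 55 --seed 1
osteotex extract  --manifest cohort/manifest.csv --roi-config cohort/roi_config.json \
                  --roi-kind bone --modality T1 --bit-depth 12 --out features.csv
osteotex evaluate --features features.csv --out-prefix report --seed 1
```

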