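# gliopipe

Glioma grading from H&E histopathology with integrated molecular data.

Modern CNS tumor classification requires histology *and* genotype: IDH
mutation, 1p/19q codeletion, ATRX mutation and MGMT promoter methylation
stratify diffuse gliomas beyond what morphology alone supports. `gliopipe`
implements that integration as a reusable toolkit for whole-slide H&E
images:

1. **ROI selection** — over-segment a slide thumbnail into superpixels
   (SLIC), rank them by mean intensity, keep the darkest decile (dense
   cellular tissue absorbs most light), and crop fixed-size ROIs at the
   superpixel centroids. The known pen-marker failure mode (ink is darker
   than tissue) is reproduced and mitigated via an exclusion mask.
2. **Stain normalization** — structure-preserving color normalization by
   sparse nonnegative stain separation under Beer–Lambert optics:

   ```
   min_{W≥0, L≥0, ‖wⱼ‖≤1}  ½‖X − WL‖²_F + λ Σⱼ ‖L(j,:)‖₁
   L_norm(j,:) = L_s(j,:) · RM(L_t(j,:)) / RM(L_s(j,:))
   I_norm      = I₀ · exp(−W_t L_norm)
   ```

   where `X = −log(I/I₀)` is optical density, `W` the 3×r color-appearance
   matrix, `L` the per-pixel stain densities, and `RM(·)` the 99% pseudo
   maximum of a density row.
3. **Nuclei segmentation** — a trainable encoder–decoder (cross-entropy,
   Adam, poly learning-rate decay `lr_i = lr₀(1−i/N)^0.9`) and a
   deterministic classical backend (hematoxylin-density thresholding +
   watershed).
4. **Cellularity** — nuclei-area fraction of the ROI, optionally after
   morphological dilation (diameter 11–12 recommended), `0 ≤ c ≤ 1`.
5. **Cascaded grading** — stage 1 (plain CNN) separates HGG from LGG;
   stage 2 (residual network) separates LGG II from III; both fuse image
   features with the binary molecular vector and cellularity. Evaluated by
   case-stratified 5-fold cross-validation, reported as mean% ± std%.

A seed-controlled synthetic-histology module generates H&E-like tiles with
exact nuclei masks, mock slides with pen-mark artifacts, and molecular
cohorts whose grade is encoded by nuclei density — so the entire pipeline
is testable without external data. For whom: image-analysis researchers
who want a transparent, desk-scale reference implementation of this
grading architecture, not a clinical tool.

## Worked example

```python
import numpy as np
from gliopipe import (SyntheticCohortSpec, generate_cohort,
                      ClassifierConfig, evaluate_cv, stratified_summary)

records = generate_cohort(SyntheticCohortSpec(n_cases_per_class=(50, 50, 50),
                                              seed=42))
print(stratified_summary(records).round(4))
rep = evaluate_cv(records, "HGGvsLGG", ClassifierConfig(seed=0))
print("HGG vs LGG:", rep.summary())
```

prints

```
  grade    mean  variance  count
0    II  0.1530    0.0007     50
1   III  0.2879    0.0009     50
2    IV  0.3851    0.0015     50
HGG vs LGG: 94.67% ± 2.98%
```

The cellularity means rise monotonically with grade — the generator
encodes grade as nuclei density, and the summary recovers it — and the
stage-1 classifier recovers the grade split at ~95% case-level accuracy
(five-fold mean ± sample standard deviation).

Command-line equivalents:

```bash
gliopipe synth cohort --n-per-class 50,50,50 --seed 42 --out cohort/
gliopipe grade --cohort cohort/cohort.csv --task HGGvsLGG --seed 0 --out report.json
gliopipe run --config pipeline.yaml      # full resumable pipeline
```

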