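# topoiqa

Topological image-quality assessment (IQA) of eye-fundus photographs.

Automated fundus-image pipelines (diabetic-retinopathy screening,
tele-ophthalmology) must first triage out photographs that are too blurred,
occluded or badly illuminated to read. `topoiqa` implements a
topology-based IQA classifier: instead of learning on raw pixels, each
image is reduced to a 30-element vector of persistent-homology descriptors
and classified good/bad quality by a regularized logistic regression. The
package is aimed at researchers in computational ophthalmology and
topological data analysis who want a compact, interpretable, CPU-friendly
quality gate.

## Method

A grayscale image is a map I : D ⊂ ℤ² → {0, …, 255}. Each pixel becomes a
2-cube (square) of a cubical complex K; every face σ receives the
min-extension

    I′(σ) = min { I(τ) : σ face of τ },

so the sublevel sets K_i = { σ ∈ K : I′(σ) ≤ i } form a filtration indexed
by luminescence level. Persistent homology of this filtration tracks
connected dark components (H₀) and holes — bright regions enclosed by dark
ones (H₁) — as (birth, death) bars. In a readable fundus photograph the
bright retina disc surrounded by the dark camera aperture produces a hole
persisting across most of the 256 levels, and anatomical structures
(macula, vessels, optic disc) produce long H₀/H₁ bars; degraded images
lose these signatures.

Each diagram (per dimension) is vectorized with seven descriptor
families — persistent entropy, bottleneck amplitude, 1- and 2-Wasserstein
amplitudes, persistence landscapes λ₁, λ₂ (L¹/L² norms), Betti curves
(L¹/L²), Gaussian heat surfaces (σ ∈ {1.6, 3.2}, L¹/L²) and point
counts — giving 30 features per image. An L2-penalized logistic regression
(C = 150 000, tol = 10⁻⁸, liblinear, standardized inputs) performs the
binary classification, evaluated with accuracy, per-class
precision/recall/F1, ROC/AUC and the Matthews correlation coefficient.

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

The smallest interesting input is a 3×3 image over four luminescence
levels {1, 2, 3, 4} — a dark ring around a bright center:

```python
import numpy as np
from topoiqa import *

img = toy_ring_image()
print(img.values)
# [[1 2 2]
#  [2 4 2]
#  [2 2 2]]

dg = compute_persistence(build_complex(img))
for bar in dg.bars:
    print(bar)
# Bar(birth=1, death=4, dimension=0, essential=True)
# Bar(birth=2, death=4, dimension=1, essential=False)
```

One component appears at level 1 and survives to the end (the essential
H₀ bar); the ring closes at level 2, creating a hole that is filled when
the center pixel enters at level 4 (the H₁ bar (2, 4)).

End-to-end on synthetic fundus phantoms (no real data needed):

```python
study = generate_study(50, seed=0)            # 50 good + 50 bad, 85/15 split
X = np.vstack([featurize(im).values for im in study.images])
y = encode_labels(study.labels)
model = train_logit(X[study.train_idx], y[study.train_idx], seed=0)
print(evaluate(model, X[study.val_idx], y[study.val_idx]).pretty())
#    label precision  recall     f1  support
#     good     1.000   1.000  1.000        8
#      bad     1.000   1.000  1.000        8
# accuracy: 1.000  MCC: 1.000
# AUC: 1.000
```

At this small validation size the phantom classes separate perfectly;
larger studies (100 per class) give held-out AUC in the 0.95–1.0 range
depending on the seed. Each feature row can also be inspected by name,
e.g. `featurize(img)["bottleneck_h1"]` is half the longest H₁ lifetime.

The same workflow is available from the shell:

```sh
topoiqa synth --n-per-class 50 --seed 0 --out study/
topoiqa featurize study/ --labels study/labels.csv --out features.csv
topoiqa train --features features.csv --out model.json
topoiqa evaluate --features features.csv --model model.json --out report.json
topoiqa predict --features features.csv --model model.json --out preds.csv
```

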