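# eagleseg

Multilevel histogram thresholding for biomedical image segmentation, built
around two components:

1. **Threshold selection.** A bald-eagle-search (BES) metaheuristic — with an
   optional dynamic-opposite-learning enhancement (DOBES) — picks `k` integer
   gray levels `t_1 ≤ … ≤ t_k` on the 256-bin histogram that maximize Kapur's
   entropy

   ```
   F(t) = Σᵢ Hᵢ ,   Hᵢ = − Σ_{j ∈ class i} (Pⱼ/Aᵢ) ln(Pⱼ/Aᵢ)
   ```

   where `Pⱼ` is the probability of gray level `j` and `Aᵢ` the probability
   mass of class `i` (class 0 is `[0..t₁]`, class `i` is `[tᵢ+1..tᵢ₊₁]`).
2. **Region extraction.** The brightest class is binarized and a morphology
   chain (Canny edges → disk dilation → boundary tracing → small-region
   removal → hole filling → largest-component selection) isolates one compact
   bright region — e.g. a contrast-enhanced tumor in a T1 brain MRI slice.

The package is aimed at researchers who need a reproducible, dependency-light
thresholding baseline: every run is fully seeded, a brute-force enumeration
oracle is built in for small `k`, and a synthetic phantom generator makes the
whole pipeline testable without any imaging data.

## Worked example

```python
import eagleseg as es

img, gt = es.make_phantom(es.PhantomSpec(seed=0))   # 256x256 synthetic slice
out = es.segment_image(img, n_thresholds=3, random_state=0)
print("thresholds:", [int(t) for t in out["thresholds"]])
print("fitness:   %.4f" % out["fitness"])
print("dice:      %.4f" % es.dice(gt, out["region"]))
```

prints

```
thresholds: [75, 103, 172]
fitness:   14.1389
dice:      0.9988
```

The three thresholds split the histogram's four intensity modes (background
≈20, two tissue bands ≈90/160, tumor ≈230); the fitness is the Kapur entropy
of that partition, and the Dice value is the overlap between the extracted
region and the phantom's ground-truth tumor disk — 0.999 means near-perfect
recovery.

The estimators compose with scikit-learn:

```python
from sklearn.pipeline import Pipeline
pipe = Pipeline([
    ("thresholds", es.MultilevelThresholder(n_thresholds=3, output="mask")),
    ("region", es.TumorRegionExtractor()),
])
region = pipe.fit(img).transform(img)
```

A CLI mirrors the library: `eagleseg segment`, `benchmark`, `metrics`,
`phantom`, `optimize` (see `eagleseg --help`).

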