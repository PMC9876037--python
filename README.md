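# veinsemble

Single-sample-per-person (SSPP) finger-vein identification with a gated
ensemble of per-feature-map CNN weak classifiers, plus a seeded synthetic
near-infrared vein-image generator so the whole pipeline runs offline.

From each grayscale vein image the pipeline derives six feature maps —
the original, a binary vein segmentation, LBP codes of both, and fused
Gabor-bank responses of both — and trains one small CNN per map on the
single enrollment image of every class. Training runs in `K` steps of `P`
epochs and comes in three regimes:

* **basic** — independent training per map;
* **shared** — after each step a classifier is fine-tuned for a few
  epochs on the other maps, ordered and budgeted by the dataset-level
  FSIM similarity `St` of the map pair (`Ec = max(0, 2⌊P/4·St⌋ − 1)`);
* **full** — shared learning plus loss-driven speed adjustment: the next
  step's own-map epoch count is `⌊sigmoid(L)·P⌋` (minimum 1).

After every step the classifiers' close-test scores and losses become
normalized sigmoid weights `E+`/`E−`; classifiers whose close-test score
exceeds 0.5 vote with weight `∝ |E+ − E−|`, and prediction is the argmax
of the weighted probability mixture.

## Command line

```sh
# generate a two-session synthetic dataset (PNG images + masks + manifest)
veinsemble synth --classes 30 --sessions 2 --samples 6 --seed 0 --out data/

# inspect the six feature maps of one image
veinsemble featmaps data/class_0000/session_1/sample_1.png --out maps/

# FSIM of two images; 6x6 feature-map similarity matrix of a training set
veinsemble fsim A.png B.png
veinsemble simmat --train data/ --out st.csv

# train on the SSPP split (session-1 sample-1 per class) and evaluate
veinsemble train --data data/ --regime full --steps 4 --epochs 8 --seed 0 --out model/
veinsemble eval --model model/ --data data/ --out results.csv

# or the whole pipeline in one go (writes model/, st.csv, run_log.jsonl,
# results.csv and the resolved config.yaml under --out)
veinsemble run --data data/ --out run/ --regime full --seed 0
```

Datasets follow `class_XXXX/session_Y/sample_Z.png` or provide a
`manifest.csv` with columns `class_id,session,sample,path[,mask_path,seed]`.
The SSPP split is fixed: the first sample of session 1 enrolls a class and
all later-session samples are probes.

## Layout

| module | contents |
| --- | --- |
| `veinsemble.synthetic_data` | seeded template/session/sample generator with ground-truth masks |
| `veinsemble.feature_maps` | LBP, Gabor kernels/banks, vein segmentation, the six-map builder |
| `veinsemble.similarity` | phase congruency, gradient magnitude, FSIM, the 6x6 `St` matrix |
| `veinsemble.weak_classifier` | the two CNN architectures, training, close test, persistence |
| `veinsemble._nn` | minimal deterministic numpy CNN engine (im2col + BLAS) |
| `veinsemble.ensemble` | schedulers (Ec, alpha, p), the three regimes, gated weighted voting |
| `veinsemble.io` / `veinsemble.cli` | dataset/manifest loading, run config, pipeline, CLI |
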