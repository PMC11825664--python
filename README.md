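# normeval

Evaluation toolkit for **pseudo-healthy image restoration** in unsupervised
anomaly detection. Generative models trained only on healthy brain MRI learn
what normal anatomy looks like; given a pathological image *x* they produce a
restoration *x̂* that should depict the same subject without the pathology,
and the residual |x − x̂| localizes the anomaly. Evaluating such models only
by detection scores hides how well they actually learned the healthy
distribution. `normeval` scores that normative-learning facet directly, and
also implements the standard detection protocol, for researchers
benchmarking restoration-based anomaly detectors.

## Metrics

Given four image sets — healthy reference `D_H`, unseen healthy `D_UH`,
pathological `D_P`, and restored pathological `D_RP` (paired with `D_P` by
id) — the toolkit computes:

- **RQI** (restoration quality index): perceptual fidelity on unseen healthy
  pairs,
  `RQI = (1/N) Σ 1 − (LPIPS(x, x̂) − min_lp) / (max_lp − min_lp)`,
  with `min_lp = 0`, `max_lp = 25` and per-pair distances capped at
  `max_lp`. Distances use a pluggable perceptual backend (raw deep
  distances × 100 by convention; a deterministic blurred-L1 toy backend is
  bundled and is the default).
- **AHI** (anomaly-to-healthy index): distributional normalization measured
  by Fréchet distances between embedded sets,
  `AHI = max(0, 1 − max(0, FID_RP,H − FID_UH,H) / (FID_P,H − FID_UH,H + ε))`,
  so 1 means the restored set is as close to healthy as real healthy images,
  0 means no improvement over the pathology.
- **CACI** (conservation and correction index): from an SSIM map averaged
  inside (`SSIM_AN`) and outside (`SSIM_H`) the expert lesion mask,
  `CACI = 2 / (1/(SSIM_H + ε) + 1/(max(0, SSIM_H − SSIM_AN) + ε))` per pair,
  averaged over pairs — high only when healthy tissue is preserved *and* the
  lesion is changed.
- **Fused score**: `(2·RQI·CACI/(RQI + CACI) + AHI) / 2`, the harmonic mean
  of RQI and CACI averaged with AHI.
- **Detection protocol**: box-level detection (a box counts as detected when
  ≥ 10% of its pixels are flagged; FP is the ratio of flagged healthy-tissue
  pixels to correctly flagged box pixels; per-case `F1 = 2·P·TP/(P + TP)`
  with `P = TP/(TP + FP)` averaged over cases), and **⌈Dice⌉** — the best
  pooled Dice over a single global residual threshold searched on the test
  set, stratified into small/medium/large lesions by the 25th/75th
  percentiles of lesion pixel count (preset cuts 71/570 px available).

All images are first brought to a canonical form: normalized to the image's
98th intensity percentile, clipped to [0, 1], zero-padded to square, and
bilinearly resized to 128 × 128.

## Worked example

Synthetic phantoms (bright textured ellipse + hyperintense lesion with known
mask/box) make the whole pipeline runnable without any data download:

```python
from normeval import RunConfig, generate_bundle, run_all, stub_restorer

bundle, annotations = generate_bundle(seed=7, n_healthy=64, n_unseen=16, n_path=32)
restored = stub_restorer("oracle", bundle)   # true pseudo-healthy counterfactual
report = run_all(RunConfig(min_fid_set_size=16), bundle=restored,
                 annotations=annotations)
print(report.rqi, report.ahi, report.caci, report.fused)
```

prints (oracle restorer, toy backends):

```
1.0 0.9544021690503665 0.794369719280043 0.9199023354127478
```

RQI = 1 because the oracle restores unseen healthy images exactly; AHI ≈ 0.95
because the restored pathological set is distributionally indistinguishable
from healthy phantoms up to finite-sample noise in the Fréchet distances;
CACI ≈ 0.79 because healthy tissue is untouched while
the lesion region changes strongly (border SSIM windows keep it below 1);
the fused score combines them. An identity "restorer" on the same bundle
scores RQI = 1 but AHI ≈ 0 and CACI ≈ 0 — replicating the input earns
nothing on normative learning.

The same flow works from the shell:

```bash
normeval restore-stub --kind oracle --seed 7 --out run/
normeval run-all --healthy run/healthy --unseen run/unseen_healthy \
    --restored-unseen run/restored_unseen --pathological run/pathological \
    --restored run/restored_pathological --masks run/masks \
    --boxes run/boxes.json --out report.json
```

## Layout

| module | role |
|---|---|
| `normeval.image_io` | PNG/NIfTI reading, canonical preprocessing, masks/boxes/report I/O |
| `normeval.feature_backends` | perceptual-distance and embedding contracts; toy + deep backends |
| `normeval.restoration_metrics` | RQI, masked SSIM, CACI, fused score |
| `normeval.distribution_metrics` | Gaussian moments, Fréchet distance, AHI |
| `normeval.detection_eval` | anomaly maps, box F1 protocol, ⌈Dice⌉, strata |
| `normeval.synthetic_fixtures` | phantom generator, stub restorers, affine augmentation |
| `normeval.pipeline` / `normeval.cli` | RunConfig, validation, `run_all`, `normeval` CLI |

See `docs/methods.md` for the modelling choices, parameter defaults, and
limitations.
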