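# Methods

This note records the model behind each metric, the defaults and why they
were chosen, the numerical conventions, and what the synthetic benchmark
does and does not establish.

## Setting and assumptions

The object under evaluation is a restorer: a map from an image to its
pseudo-healthy counterpart. The toolkit assumes 2-D grayscale images,
evaluated slice-wise, with four sets available — a healthy reference set
`D_H`, a held-out healthy set `D_UH` with its restorations, a pathological
set `D_P` with expert annotations (binary lesion masks and/or labeled
bounding boxes), and the restorations `D_RP` paired with `D_P` by id. It
does not train or run any restorer itself (stub restorers exist only to
exercise the metrics); 3-D volumetric evaluation, DICOM, skull stripping
and registration are out of scope.

### Canonical preprocessing

Every image is normalized by its own 98th intensity percentile (computed
over all pixels, numpy linear interpolation between order statistics),
clipped to [0, 1], zero-padded to a centered square, and bilinearly
resampled to 128 × 128 (no anti-alias prefilter, so the operation is a
deterministic function of the pixels). The interpolation scheme and pad
placement are this package's declared choices — reasonable alternatives
exist, so both are fixed here and echoed in every report. Per-image
percentile normalization means an input and its restoration loaded from
disk are scaled by *different* constants when the lesion shifts the
percentile; pipelines that already have both images in memory on a common
scale should pass them directly rather than round-tripping through files.

## The three indices

**RQI.** Per unseen-healthy pair, a perceptual distance d is mapped through
`1 − (d − min_lp)/(max_lp − min_lp)` and averaged. Defaults `min_lp = 0`
(identity restoration), `max_lp = 25`, and capping of worse-than-max
distances applied per pair, before averaging. Raw deep perceptual distances
are typically below 1, so backends report distance × 100; with that
convention a cap of 25 is attainable by genuinely poor restorers. Both the
×100 convention and `max_lp` are configuration values, because the scale of
a perceptual distance is a property of the backend, not of the index.

**AHI.** Gaussians are fit to backend embeddings of each set (unbiased
covariance, so small hand-computed cases match exactly), and Fréchet
distances to `D_H` anchor the index: `FID_UH,H` is the achievable floor
(what real healthy images score, finite-sample bias included), `FID_P,H`
the no-improvement ceiling. The floor uses the *original* unseen-healthy
images, not their restorations — the floor should represent real healthy
data, independent of the restorer under test; this is configurable for
sensitivity analyses. ε defaults to 1e-8, small enough not to perturb
reported precision. The index is clamped to [0, 1]; the upper clamp only
engages in the degenerate regime `FID_P,H < FID_UH,H`, where the
normalization has no meaning. Fréchet distances between finite samples of
the same distribution are positive and shrink with n; a warning is emitted
below 50 images per set. The matrix square root in the trace term is
computed from the eigendecomposition of the symmetrized congruence
`S_a^{1/2} S_b S_a^{1/2}` (real arithmetic throughout); round-off negative
eigenvalues are clipped at zero, and a clipped mass above 1e-3 of the
spectrum raises a numerical error instead of being silently truncated.

**CACI.** The SSIM map uses the common convention: 11 × 11 Gaussian window,
σ = 1.5, population statistics, stabilizing constants with data range 1.
Region averages are taken over map pixels inside/outside the lesion mask;
windows straddling the lesion border contribute to both regions through
their center pixel, which keeps both averages defined for thin structures
at the cost of slight cross-talk near edges (visible as `SSIM_H`
marginally below 1 even for a perfect restorer). SSIM can be negative, so
`SSIM_H` is clipped below at 0 before entering the harmonic mean, and the
final per-pair value is clipped into [0, 1] (the ε-regularized harmonic
mean exceeds 1 by ~ε at the perfect endpoint). CACI is averaged per pair
rather than over pooled SSIM maps, so large lesions do not dominate small
ones; pairs with empty masks are excluded from the average (the correction
term is undefined) and counted in the report.

**Fusion.** `(2·RQI·CACI/(RQI+CACI) + AHI)/2`. The harmonic mean punishes a
model that is good on only one of RQI/CACI; averaging (rather than a
three-way harmonic mean) keeps near-zero AHI values — common even for
decent restorers, because distribution distances are demanding — from
annihilating the score. The harmonic term is defined as 0 at
RQI + CACI = 0.

## Detection protocol

Anomaly maps default to the absolute residual |x − x̂|; precomputed maps
can be supplied. Image-level scores are the max or mean over pixels.

**Box F1.** The protocol needs flagged pixels, but no binarization rule is
part of the protocol itself; the default derives the threshold from
normative data — the 0.95 quantile of pooled unseen-healthy residual maps —
and the strategy plus the resolved threshold are echoed in the report. A
box is detected when ≥ 10% of its pixels are flagged (boundary inclusive:
exactly 10% counts). FP is the ratio of flagged pixels outside *all* boxes
(inside the brain mask when one is given) to flagged pixels inside the box;
each box is scored independently and contributes one case to the F1
average. The per-case formula `2·P·TP/(P+TP)` with TP ∈ {0, 1} is
implemented as printed in the protocol definition, although treating a 0/1
indicator as a count inside a precision formula is unconventional. An
undetected box has f1 = 0; its FP ratio may be undefined (nothing flagged
inside) and is recorded as not applicable.

**Ceiling Dice.** One global threshold per stratum, searched on the
evaluated test set — a theoretical segmentation upper bound, not an
operating point. The predicate is `score ≥ t` (not strict), so the
select-everything solution is inside the search space (a constant map's
optimum, Dice = 2L/(N+L), is otherwise unreachable); note the F1
binarization keeps strict `>` so that a threshold of 0 on an all-zero map
flags nothing. Candidate thresholds are all unique pooled scores
(exhaustive mode, provably optimal, used on small data and in tests) or 100
evenly spaced values over [min, max] (default; never better than
exhaustive, adequate for smooth residual maps). Ties break toward the
smaller threshold. The headline Dice pools pixels across the stratum's
cases; the mean of per-case Dice at the same threshold is reported
alongside, since both conventions appear in practice and they diverge when
predictions are empty. Constant score maps make the search vacuous and are
flagged degenerate. Strata come from lesion pixel counts: quantile mode
uses the 25th/75th percentiles (`small` strictly below the lower cut,
`large` at or above the upper); the fixed preset (71, 570) px matches the
stroke-lesion benchmark convention. When the two cut points collapse
(all lesions equal), everything is `medium` rather than arbitrarily
`large`.

## Feature backends

The metrics only require two contracts: a symmetric non-negative pairwise
distance with `d(a,a) = 0`, and a deterministic fixed-dimension embedding.
The bundled toy backends satisfy them in closed form:

- blurred-L1 perceptual distance — mean |Gσ(a) − Gσ(b)| × 100 with σ = 1
  px: insensitive to pixel noise, like deep perceptual metrics, while
  remaining exactly recomputable in tests;
- quadrant-statistics embedder — per 2 × 2 quadrant, the mean, variance,
  and gradient energy (dim = 12): separates intensity shifts, texture
  changes, and blur, the failure axes the stub restorers span.

Deep backends (LPIPS; Inception-v3 pooling, dim 2048) are thin lazy-import
wrappers behind the same contracts, available via the `deep` extra; the
grayscale→3-channel/resize adapter they share is pure numpy and covered by
shape tests. No backbone choice is baked into any metric.

## Synthetic benchmark

Phantoms emulate only the statistical skeleton of a mid-axial T1w slice: a
bright ellipse (base 0.55) on a dark background (0.02) with a smooth random
texture (Gaussian-filtered white noise, correlation length size/8,
amplitude 0.08) plus i.i.d. pixel noise (sd 0.02); lesions are hyperintense
discs/ellipses (Δ = +0.35, radius 4–12 px) with exact masks and tight
boxes. The default bundle is 64 healthy / 16 unseen / 32 pathological —
large enough for stable toy-backend Fréchet distances, small enough that
the full evaluation runs in seconds. The texture and noise fields are drawn
before the lesion is applied, so regenerating a phantom without its lesion
(the oracle restorer) yields the exact counterfactual. All generators are
pure functions of their seeds (bitwise reproducibility is promised within a
pinned environment; cross-platform checks should use tolerances).

What passing on phantoms shows: the formulas, their endpoints, and the
expected ordering of restorer archetypes (oracle > blur > identity on the
fused score) are implemented correctly. What it does not show: performance
on real MRI — phantoms have no anatomy, no bias fields, no partial-volume
effects, no inter-subject variability, and their lesions are geometric and
high-contrast; absolute metric values on phantoms do not transfer.

## Known limitations

- Per-case F1 follows the printed protocol exactly (see above); values are
  comparable within the protocol but not to conventional pixel-F1.
- The ceiling-Dice threshold is tuned on the test set by construction;
  never report it as achieved segmentation performance.
- Small-set Fréchet distances are biased; compare AHI values only between
  restorers evaluated on identical sets and backends.
- SSIM region averages mix information across the lesion border within one
  window radius (5 px); CACI on lesions thinner than the window is
  dominated by border windows.
- The affine augmentation helper (rotation ≤ 10°, translation ≤ 0.1,
  scaling 0.9–1.1, horizontal flips at p = 0.5) is provided for training
  pipelines of restorers; it plays no role in evaluation.
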