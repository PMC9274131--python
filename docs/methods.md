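# Methods

This note documents the models, parameter choices and numerical decisions
behind `trapscan`, and what the synthetic benchmark does and does not
demonstrate.

## Problem setting

A trap photograph is a bright, roughly uniform adhesive card against a
darker scene, dotted with insects of ~5–25 px area. Two properties shape
the whole design: the targets are far too small for shape or texture cues
(their segmented contours are ragged at this scale), and the background is
statistically redundant while the insects are "novelty". The pipeline
therefore locates candidates with a prior-free saliency model and
identifies them purely by color.

## RoI extraction

The card is separated from the scene on the Cb (blue-difference) plane of
the full-range BT.601 YCbCr transform: a yellow card has strongly
depressed Cb regardless of brightness. All color conversions are pinned in
one module (`colorspaces`): full-range BT.601 for YCbCr and luma, HSV with
hue in degrees, CIE L\*a\*b\* under D65/2°, intermediate math in float64,
8-bit planes rounded half-up.

Otsu's threshold is computed over the fixed 256-bin histogram with ties
broken toward the lower level. Which side of the threshold is "card" is
decided per image by comparing the largest connected component of each
polarity **before** hole-filling — filling first would let an enclosing
background ring flood to the whole frame and win — and the winner is then
hole-filled (insects punch holes through the chroma threshold) and
recorded on the result. Frames whose largest component covers under 5 %
of the image raise a no-trap error.

## Tiling

Blocks are 64 × 64. The pipeline default stride is 32 (half-block
overlap): with non-overlapping tiles an insect straddling a seam is cut
into fragments that can both fail the minimum-size filter, which measured
at a 4–6 % recall loss on the benchmark. Overlap re-detects each seam
insect whole in a neighbouring block; the resulting duplicates are merged
at detection level (centers closer than 6 px, largest region kept). The
low-level `split_blocks` operation itself defaults to a non-overlapping
stride for callers who want a partition. Remainders are zero-padded —
zeros stay non-salient after the residual's mean removal — and foreground
falling in padding is clipped before any area measurement.

## Spectral-residual saliency

Per block, on the BT.601 luma channel:
amplitude and phase of the 2-D FFT; `L = log(A + 1e-8)` (the epsilon
guards exactly-zero bins of symmetric synthetic inputs); residual
`R = L − h_n ∗ L` with `h_n` a 3 × 3 uniform filter with replicate
borders; `S = g ∗ |F⁻¹[exp(R + iP)]|²` with `g` Gaussian. The map is
min-max normalized to [0, 1]; exactly constant blocks short-circuit to a
zero map, because their off-DC spectrum is FFT rounding noise that the
log/exp pair would amplify into spurious texture.

Two numerical properties worth knowing:

* **σ of the final Gaussian is 0.8 px, deliberately below the target
  radius.** The level set that defines a detected blob includes the blur
  skirt; with σ of the order of the target size the skirt alone is 80–160
  px for an 8–20 px insect — every true object would then fail the 25 px
  bound and recall is literally zero. At σ = 0.8 the half-maximum support
  tracks the object (measured proposal recall 0.994 on planted blobs).
* **Brightness offsets are not exactly invisible.** A constant offset
  changes only the DC bin of the spectrum, but the local-average trend
  filter spreads the DC log-amplitude change into its eight neighbouring
  bins, which re-enters the map as a smooth global component of ~3 %
  relative magnitude. The map's structure (peak locations, normalized
  shape to ~0.05) is stable; bitwise invariance away from the border is
  not, and the tests assert the former.

## Binarization, splitting, sizing

The saliency histogram of a block with real novelty is single-peaked with
the peak near the dark end: almost all pixels are redundant background.
The triangle method exploits exactly this shape — normalize both axes to
[0, 1], draw the line from the peak (ties toward the darker bin) to the
farthest non-empty bin on the bright side, threshold at the bin of maximum
perpendicular distance (ties toward the lower bin). Axis normalization
makes the bin choice invariant to image size and histogram scale.

The dark-peak premise doubles as a novelty gate: a block containing
nothing but sensor noise min-max-normalizes to a **mid**-peaked histogram,
and thresholding it would yield a dozen size-passing false regions per
block. `triangle_threshold` therefore rejects maps whose histogram peak
lies beyond 1/8 of the axis (configurable) as containing no salient
object; the pure histogram-geometry operation `triangle_bin` performs no
such check.

Foreground components are split by a watershed on the inverted saliency
relief, seeded from regional maxima with maxima closer than 4 px merged
(at 3 px, elongated insects — eccentricity up to 2.5, length ~9 px —
produced two maxima and were double-counted). Components without a marker
pass through whole, so the region masks always partition the foreground
exactly.

Because the triangle elbow sits at the *foot* of the background lobe, the
raw binary blob of an object includes its blur skirt and overstates area
several-fold. Each region is therefore refined to the level set at half
its own saliency peak — for a blurred compact object the half-maximum
contour sits at the original boundary — before the size filter keeps areas
in [5, 25] px inclusive. "Size" is read as pixel area of the segmented
component. For color features a stricter core (level 0.7) is used: the
boundary pixels of a 10 px animal are card/insect mixtures, and including
them drags every class's mean toward card color (measured: the whitefly
saturation distribution, truly ~0.12, had median 0.29 with full-mask
averaging).

## Features and color-space choice

A region's feature is the mean of its core pixels' components in one
color space; hue is averaged on the circle (`atan2` of mean sine/cosine),
with the plain arithmetic mean available as a compatibility flag since it
is ill-defined across the 0°/360° wrap.

The color-space diagnostic (`space_separability`) scores the class
clustering by silhouette on the component pairs classically scattered for
this task — (R, G), (H, S), (Cb, Cr), (a\*, b\*) — z-scored per
component. On crops rendered with frame-to-frame exposure variation, RGB
is robustly the worst space (brightness noise is correlated across R and
G, silhouette ~0.23 vs ≥ 0.34 elsewhere) and HSV the best, because
saturation is a within-pixel ratio that exposure cancels. HSV's margin
over L\*a\*b\* is small (~0.005 at the defaults — CIELAB is designed to be
illumination-robust, and on these synthetic color models the two are
statistically tied); HSV is the classifier default, consistent with its
standard choice for this task. Silhouette on full 3-vectors instead of
the pairs ranks CIELAB first, for the same reason.

## Classifier

Soft-margin C-SVC with one-vs-one multiclass reduction (the native scheme
of the libsvm family), RBF kernel, C = 10, gamma = "scale"; features are
standardized on the training set only. All hyperparameters are
configuration, and `cross_validate` (stratified k-fold with per-class
TPR/FPR/accuracy) is the protocol for choosing others. Class weights are
inverse-frequency ("balanced"): the background class is sampled far more
densely than the insect classes (below) and unweighted training biased
predictions toward background, costing whitefly recall.

Training data composition matters more than the kernel here:

* whitefly/thrips samples are 32 × 32 rendered crops, one centered animal
  each, re-segmented by the same saliency pipeline (most-central region,
  feature core); a fraction sit on degraded card (smear wash, stripe) as
  insects in real frames do;
* background samples are **harvested**: insect-free scenes (noise rates
  × 3 so rare artifact types contribute enough samples) are pushed through
  the proposal pipeline and every proposal's feature becomes a background
  sample — the field-data analogue of cropping detected non-target
  objects. Card-colored specks vastly outnumber artifact-colored
  proposals, so only 40 of the former are kept per scene. Training the
  background class on idealized spot crops instead leaves smear-edge and
  stripe fragments (colors between card and insect) unrepresented, and
  they then surface as spurious whitefly/thrips detections that dominate
  the count error.

## Evaluation

Detections are matched one-to-one to ground-truth points greedily by
ascending centroid distance with an 8 px acceptance radius (≈ one target
diameter; IoU is unstable for 5–25 px objects). Per class c: TP = matched
pairs labeled c on both sides; FN = truth c unmatched or matched to
non-c; FP = detections c not matched to truth c; TN = the rest of the
evaluation universe, defined as all matched and unmatched objects of all
classes — a detection task has no natural TN, and this mirrors the
three-class framing where background is itself a category. TPR, FPR and
accuracy follow the standard definitions; zero denominators are reported
as missing, never as 0. Count agreement across images is OLS of automatic
on manual counts with R² = 1 − SS_res/SS_tot.

## Synthetic scenes: what they do and do not show

The generator renders a 640 × 480 frame (full-size is a flag) with a
yellow card (HSV ≈ (55°, 0.92, 0.88)), anti-aliased elliptical insects
(area 8–20 px, eccentricity 1–2.5, no overlap, ≥ 2 px inside the card),
class color models — whitefly pale/low-saturation (60°, 0.12, 0.96),
thrips dark yellow-brown (32°, 0.72, 0.35) — and degradations: glue spots
(pale, S ≈ 0.45, drawn over insects, 0.4 per 10⁴ card px), one stripe and
one bulk smear (drawn under insects), a 10 % illumination gradient, and
sensor noise (σ = 2). Insect layout and noise draw from independent RNG
substreams, so scaling the noise preserves the layout bit-for-bit — the
basis of the robustness sweep. Annotations (center, rendered area, class)
describe the insect layer exactly.

Training crops additionally carry a per-crop exposure gain (σ = 0.10,
clip [0.65, 1.12]) and card-color draw, emulating collection from many
frames across days; a rendered scene is one frame at nominal exposure.
The color models are synthetic stand-ins chosen to reproduce the
qualitative color-space separability ordering, not measured field values.
The glue-spot color is deliberately distinct from the whitefly model;
moving it closer (config) reproduces the classic failure mode where glue
spots are counted as whiteflies.

On this benchmark (18 scenes, 4–24 insects per class per scene, fixed
seeds) the pipeline reaches per-class TPR ≈ 0.93–0.98 and count R² ≥
0.95. That demonstrates the pipeline's mechanics — proposal recall,
segmentation sizing, feature separability, count fidelity — under
conditions matching its assumptions. It does **not** demonstrate field
performance: real traps add wing/body translucency, pose and life-stage
variation, non-target insects, dust, perspective and lens effects, and
color distributions measured from nature, none of which are modeled.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| block size / stride | 64 / 32 px | target scale vs seam-split recovery |
| h_n support | 3 × 3 | local average of the log spectrum |
| Gaussian σ | 0.8 px | keeps half-max support at object scale |
| log ε | 1e-8 | guards log(0) at zero-amplitude bins |
| triangle bins / peak gate | 256 / 1/8 | 8-bit-like axis; dark-peak premise |
| marker merge radius | 4 px | one marker per elongated insect |
| refine / feature-core level | 0.5 / 0.7 | sizing vs color purity |
| size bounds | [5, 25] px incl. | plausible insect area at this scale |
| match radius | 8 px | ≈ target diameter |
| SVM | RBF, C=10, balanced | compact curved clusters, class imbalance |

## Known limitations

* Counts, not tracks: time-lapse association is out of scope.
* Single card per frame; multi-trap frames keep only the largest card.
* The noise gate rejects whole blocks; an insect sharing a block with
  nothing else and contrast below sensor noise is undetectable.
* Color-only identification cannot separate species of similar color;
  adding classes needs only new training crops but also new color
  contrast to exploit.
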