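# Methods

This note records the modelling choices, conventions and parameters behind
`uroslide`, and what the synthetic benchmark does and does not demonstrate.

## Problem and model

Bladder-cancer management hinges on two slide-level judgements from TURBT
material: histologic grade (low vs high) and muscle invasion (whether tumour
infiltrates the muscularis propria). Because all muscle-invasive disease is
treated as high-grade, the slide-level label space is three categories:
HGMI, HGNMI, LGNMI. The pipeline decomposes the judgement into a patch-level
six-class problem (the three diagnostic textures plus illegible areas,
normal interstitium and stain artefacts), dense tile inference, and a fixed
aggregation rule.

The aggregation is deliberately simple and interpretable. For each class,
connected regions of the decision map (8-connectivity on the 1/32 heatmap
grid, minimum area one point) are summarised by area `a_i` and mean class
probability `p_i`; the class score `P_k = Σ a_i p_i / Σ a_i` is the mean
probability over all points decided as class `k` (area-weighting across
contours is equivalent to pooling their points), and slide confidence is the
softmax of `e^{P_k}`. Properties worth knowing:

* `P_k` is bounded by the contour probabilities, and is invariant to how a
  decision region is partitioned into contours (property-tested).
* Because `P_k` is a *mean*, a large confident region and a small equally
  confident region give the same score: the rule compares the classifier's
  conviction where it sees each class, not how much of each class it sees.
* The softmax runs over the three diagnostic categories only; IA/NIA/NA
  contours are computed and reported but carry no diagnostic weight — the
  slide-level task is three-way by definition. A category with no contour
  is *excluded* from the softmax (confidence 0) rather than scored
  `P_k = 0`, which would grant an absent category weight `e^0`. This
  exclusion is configurable in spirit but fixed in code; it follows from
  treating absence of any decided point as absence of evidence.
* Softmax margins are intrinsically soft: scores live in [0,1], so the
  largest possible confidence ratio between two present categories is
  `e ≈ 2.72`. Slide calls therefore hinge on which category's decided
  points are more *confident*, and the number of categories present on a
  slide shifts the confidence scale — a caveat when comparing confidences
  across slides.

## Conventions

* 0-based pixel coordinates, x rightward, y downward; rectangles half-open.
* Channel order everywhere: HGMI, HGNMI, LGNMI, IA, NIA, NA.
* Heatmap point (r, c) corresponds to the patch centred at full-resolution
  position (32c+16, 32r+16), clamped so patches stay inside the image.
  Heatmap dims are `ceil(H/32) × ceil(W/32)`.
* Overlapping annotation polygons resolve in file order, last writer wins.
* Grayscale is Rec.601 luminance, rounded to uint8.
* Argmax ties break to the lowest channel index.

## Background filtering

One global Otsu threshold per slide, from the whole-image histogram
("adaptive" in the sense of per-slide, not per-ROI); pixels at or below the
threshold count as tissue. The tissue-fraction cutoff per ROI defaults to
`min_fraction = 0.1` — permissive, erring toward keeping tissue. The Otsu
tie rule is: among thresholds with nonzero lower-class mass, the smallest
maximizer of between-class variance; restricting candidates this way makes
the degenerate single-level histogram return that level instead of 0.

Otsu always splits a histogram somewhere, including a slide that is nothing
but background noise. `filter_background` therefore declares a slide
tissue-free when the two Otsu classes' means are closer than
`min_contrast = 30` gray levels (stained tissue runs >80 levels darker than
glass; empty-slide noise splits differ by <10).

ROI size defaults to 2048 px, sized for gigapixel clinical slides. On the
2048-px synthetic slides used in the examples and tests a single ROI would
cover the whole slide and make filtering vacuous, so pipeline examples use
512-px ROIs — the same role at the benchmark's scale.

## Patch sampling

Patches are 256 px at full resolution (pairing naturally with the stride-32
heatmap: the pooled patch grid aligns with heatmap points). Sliding-window
sampling keeps a patch only if its whole rectangle lies inside one polygon
of the class — strict purity; every kept patch is one kind of tissue. The
sampling stride defaults to 128 px in the pipeline so that regions a few
hundred pixels across still yield fully contained windows. HGMI patches are
centred on junction points placed every 128 px along shared borders between
high-grade-tumour and muscle polygons, with at least one point (the border
midpoint) per border; border-adjacent patches are clamped inward rather
than discarded because HGMI examples are scarce. Train/validation splits
are stratified *by slide*, never by patch, so no slide contributes to both
sides.

Annotation convention: the muscle compartment of a muscle-invasive slide is
annotated with the HGMI label — muscle adjacent to high-grade tumour is
precisely what defines the category — while tumour regions carry
HGNMI/LGNMI. This lets junction points be recovered from an annotation set
alone (HGNMI–HGMI polygon borders).

## Classifier and training recipe

The classifier is a contract (patch → 6-way probability vector, plus file
serialization); anything honouring it can be dropped in. The reference
implementation is deliberately compact: the 256-px patch is mean-pooled 8×
to 32×32×3 and fed to a small CNN (two 3×3 conv layers of 8 and 16
channels with ReLU and 2×2 max-pooling, a 64-unit hidden layer, 6 logits),
written directly in numpy with a hand-rolled SGD so that training is exactly
reproducible from a seed and a serialized model is nothing but its weight
arrays. It is randomly initialized (He) — no pretraining — and trains to
ceiling on the synthetic benchmark in minutes on one CPU.

Recipe (fixed defaults): cross-entropy; SGD momentum 0.9; weight decay
1e-4; initial LR 0.01 multiplied by 0.1 *at* epochs 18 and 24 (1-based);
30 epochs; batch size 64. Batches draw the six classes uniformly, since
junction-point sampling makes HGMI patches far scarcer than sliding-window
classes. Augmentations are applied per sample on the pooled representation:
circular translation up to size/8, rotation by multiples of 90°, zoom-in
scaling up to 1.2× (crop + nearest resize), horizontal/vertical flips, and
per-channel colour jitter (gain 0.9–1.1, offset ±8 of 255). The final-epoch
model is kept (no best-checkpoint selection), matching the fixed-schedule
recipe; per-epoch learning curves (train loss/accuracy, tuning accuracy)
are logged as CSV.

## Dense inference

The contract is per-point patch prediction at stride 32. The implementation
batches points and, when the patch grid aligns with the pooling factor
(always true for 256-px patches on stride 32 with image dims divisible
by 8), pools the whole image once and slices pooled patches — bitwise
identical to per-patch pooling because the mean runs over the same blocks.
Unaligned geometries fall back to per-patch extraction. Both paths are
tested against a naive per-point loop. No test-time augmentation and no
overlap averaging; points outside retained ROIs stay uncovered (all-zero,
coverage false).

## Synthetic benchmark

The generator renders 8-bit RGB slides with a near-white background
(245 ± 6) and rectangular tissue regions in six procedural textures:

| texture | recipe |
| --- | --- |
| high-grade tumour | saturated violet base (168,110,172), dense dark nuclei (6e-4 /px², r 3–6) |
| low-grade tumour | bright pink base (230,140,170), sparser smaller nuclei (2.5e-4 /px²) |
| muscle | red-pink base (210,112,122), sinusoidal fibre bands (amp 38, period 32 px), scarce nuclei |
| IA | high-grade texture, Gaussian-blurred (σ = 10) — defocus |
| NIA | pale pink base, sparse small nuclei |
| NA | near-white base with large saturated stain blobs, no nuclei |

Each cohort slide carries one diagnostic complex (a large tumour region, or
— for HGMI — a narrow tumour strip abutting a muscle strip) plus NIA, IA
and NA regions, with jittered positions and sizes. Two geometry choices are
load-bearing. First, the muscle-invasion focus is narrow (strips ≈ 0.08 and
0.10 of slide width): nearly every tumour point lies within one patch
radius of the junction, so an HGMI slide produces a dominant HGMI band
rather than a competing pure-HGNMI region — as in a slide whose diagnostic
feature *is* the invasion front. Second, the texture palette keeps each
class away from pairwise *mixtures* of other classes and background that
arise in patches straddling region borders (such patches are never trained,
by the purity rule, so their predictions are extrapolations; the palette
ensures those extrapolations land on low confidences or non-diagnostic
classes rather than on confident wrong diagnoses).

A separability guarantee is part of the generator's contract and is
enforced by test: a 1-nearest-neighbour classifier on mean-RGB plus a local
nucleus count separates the six patch classes (plus the junction texture)
at ≥90% held-out accuracy — the reference CNN's task is learnable by
construction. Determinism is also contractual: a slide is a pure function
of its spec, and cohorts derive per-slide seeds from one master seed.

What the benchmark does **not** emulate: real nuclear morphology and
chromatin texture, staining variation between labs, tissue fragmentation
and cautery artefact of TURBT material, pen marks and folds, non-rectangular
region shapes, or any within-class heterogeneity beyond noise. Passing the
end-to-end test shows the pipeline's plumbing, training recipe and
aggregation rule are correct and that the system recovers planted structure;
it says nothing about accuracy on clinical slides.

## Problem sizes

Unit tests use 256–1024-px slides and small cohorts. The end-to-end study
runs at the benchmark's full design size — 60 training slides (20 per
category, split 4:1 into training and tuning by slide) and 30 evaluation
slides of 2048×2048 px, 30 training epochs — and completes in a few
minutes on one CPU; `scripts/acceptance.py` re-runs it from scratch at the
same size.

## Numerical choices

* Heatmaps are float32; contour means and all aggregation arithmetic are
  float64 (the equation cross-check demands 1e-9 agreement).
* Probability vectors must sum to 1 within 1e-6 (softmax output satisfies
  this exactly up to rounding).
* Clopper–Pearson uses scipy beta quantiles (`ppf`/`isf`), with the exact
  closed forms at k=0 and k=n.
* AUC is Mann–Whitney concordance with half-credit ties
  (`sklearn.roc_auc_score`); "overall AUC" is the macro average of
  one-vs-rest AUCs (micro also reported). AUC intervals, where requested,
  come from a class-stratified bootstrap (2,000 resamples by default)
  because no exact interval exists for AUC.
* Manifest tissue fractions are serialized at six decimals; annotation
  coordinates use shortest-round-trip decimal, so annotation I/O is exact
  and byte-deterministic.

## Known limitations

* The reference CNN sees an 8×-pooled patch; it cannot exploit sub-8-px
  morphology. That is sufficient for the procedural textures and keeps
  CPU training fast, but a clinical deployment would swap in a full-scale
  network behind the same contract.
* Carcinoma in situ is outside the label space.
* The slide-confidence rule inherits the n-dependent softmax scale
  discussed above; confidences are comparable within a slide, only loosely
  across slides.
* Contours are not smoothed and tiny contours are not filtered; a single
  confidently misclassified point can register as a (small, low-weight)
  contour in the report.
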