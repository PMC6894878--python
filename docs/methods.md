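# Methods

## The quantification problem

An H&E-stained section of a retrieved AIS clot is, for our purposes, a
field of three chromatically distinct components — red RBC masses,
blue/purple WBC nuclei, pink fibrin mesh — interrupted by slide background
and by preparation artefacts such as tissue folds. The task is to assign
every pixel to one of {background, artefact, RBC, WBC, fibrin}, report the
composition as percentages of classified tissue, and categorize the clot
(RBC-rich ≥60% RBC, fibrin-rich ≥60% fibrin, otherwise mixed). The
categorization rule is the literal three-way ≥60% scheme; a composition
with a large WBC share but neither RBC nor fibrin at 60% is *mixed*,
because the scheme has no WBC-dominant class.

## Pixel features

Each pixel is described by six scalars per RGB channel computed over the
square window of radius r centered on it (default r = 4, a 9×9 window;
configurable): window minimum, maximum, mean, population variance, edge
factor and the center pixel's own value — 18 features total, channel-major
order. The edge factor is the window mean of the per-pixel gradient
magnitude, where the gradient is the central difference of the
full-resolution channel with reflected borders. Design choices worth
stating explicitly:

* **Per channel, not luminance.** The classes are chromatic (red vs
  purple vs pink); collapsing to intensity would discard exactly the
  separating signal.
* **Population variance** (not sample): the window is a fixed-size
  descriptor, not an estimate of anything.
* **Reflect padding** means `numpy.pad(mode="reflect")` — the edge pixel
  is not repeated. The vectorized implementation (separable rank/uniform
  filters on an explicitly padded array) is contractually identical to the
  per-pixel loop; the test suite enforces agreement to 1e-9 against an
  independent brute-force oracle.
* The window mean and the center value complete the six-feature set
  alongside min/max/variance/edge factor; all six are simple scalars and
  users can reconfigure the window radius.

## The two-stage SVM classifier

Training pixels are sampled uniformly without replacement (seeded),
balanced per class (default 5,000 per class; classes with fewer annotated
pixels contribute all of them, with a warning). Features are standardized
by the training mean/SD; zero-variance features receive SD 1 and are
recorded. The classifier is a C-SVM with RBF kernel, C = 1, kernel width
γ = 1/18 (one over the feature dimension after standardization), one-vs-one
multi-class. These hyperparameters are deliberately plain and all exposed;
on the synthetic data the problem is not hyperparameter-sensitive.

Prediction is computed from the model's own serialized state — support
vectors, dual coefficients, intercepts — with an explicit pairwise vote.
Vote ties break by label order, making prediction a deterministic function
of (model file, image). One consequence worth documenting: scikit-learn
stores the binary-SVM decision with its sign flipped relative to the
one-vs-one convention; the training code undoes that flip so stored state
is uniform across class counts.

The **exclusion model** (background/tissue/artefact) runs first; the
**classification model** (RBC/WBC/fibrin) then relabels only tissue
pixels. No pixel excluded by stage one can ever receive a tissue class,
and the composition denominator is the classified tissue area — this is
the purpose of the exclusion stage, and the reason its accuracy is tested
separately on fold artefacts.

Kernel evaluation is done in single precision with a preallocated chunk
buffer (8,192 pixels per chunk) and in-place updates; the decision is a
vote, so float32 is far beyond sufficient, and the buffering keeps
whole-slide prediction memory-flat. Images longer than 8,192 px on a side
are predicted tile-wise with a margin of real context pixels equal to the
window diameter, which makes the stitched result identical to the untiled
computation (asserted in tests). An optional prediction stride with
nearest-neighbor fill exists for speed; the default stride 1 is the
reference behavior and the only one used in tests.

## Model files

A model file is a magic/version line, one JSON header line (label set,
feature configuration, scaler, training metadata, array manifest, SHA-256
of the payload), then the raw little-endian binary block of classifier
state. Saves are byte-deterministic (sorted keys, fixed layout), so
identical training inputs yield identical files; the checksum turns any
payload corruption into a load error rather than silent misprediction.
The combined main-model file embeds both stage files verbatim.

## Synthetic slides

The generator emulates the visual vocabulary the classifier must cope
with, not stain physics (no optical-density mixing model):

* a connected tissue blob (noisy radial field thresholded at the requested
  area quantile) on near-white background, default 70% tissue;
* fibrin as the tissue matrix with smooth strand-like brightness
  modulation; RBCs as densely packed, overlap-permitted discs of radius
  3–5 px; WBCs as sparse non-merging discs of radius 5–7 px with a darker
  rim; composition is controlled over tissue pixels and discs are added
  until the requested share is reached (an unreachable share — e.g. WBC
  beyond the non-overlapping packing limit — raises an error stating the
  achievable maximum);
* fold artefacts as dark, partially transparent curved bands whose pixels
  become ground-truth artefact, mirroring how folds are excluded from
  quantification in practice;
* per-pixel class-mean color (RBC (190,55,65), WBC (85,60,140), fibrin
  (230,165,180), background (247,246,245), artefact (45,40,45)) plus
  Gaussian noise (default SD 8) and a 0.5 px blur, which creates enough
  within-class variance that the SVM is non-trivially exercised.

Ground truth is exact by construction; realized fractions are measured on
the label map and always sum to 100% of tissue. Auto-annotation samples
pure single-class patches (5×5, falling back to 3×3 and single pixels for
thin classes like folds) disjointly from the truth, emulating a user
annotating unambiguous regions.

What passing tests on these slides shows: the pipeline recovers known
compositions through the full feature→SVM→exclusion→quantify path under
realistic within-class variance and artefact occlusion. What it does not
show: robustness to staining-batch variation, out-of-focus regions,
compression artefacts, or morphologies the generator lacks (e.g.
platelet-rich regions); real deployments should validate on scanned
slides with expert annotations.

## Color-threshold comparator

The reference method is reproduced with its documented character: one
representative region per class defines per-channel inclusive RGB bounds
(min/max ± tolerance), artefact regions are cropped out first, and a pixel
matches a class iff all three channels fall in range. Pixels matching
several classes go to the nearest bound-midpoint centroid in RGB (so
percentages can sum to 100); pixels matching none are "unmatched". Both
denominators are supported: whole un-cropped image (the manual method's
own convention, reported with the unmatched fraction) and matched tissue
(for apples-to-apples comparison with the ML pipeline).

## Statistics

* Bland–Altman: bias = mean of differences (ML − reference), SD with n−1
  denominator, limits of agreement bias ± 1.96·SD; the (average,
  difference) point list is emitted for plotting.
* Spearman ρ: mid-rank ties, two-sided p from t = ρ√((n−2)/(1−ρ²)) on n−2
  df (the standard large-sample practice at the n = 50–150 of method
  comparisons; an exact permutation p is available for n ≤ 10); ρ = ±1
  reports p = 0.
* Pearson χ²: expected = margin product / total, no continuity correction
  by default (Yates available as a flag), df = (r−1)(c−1). The HAS
  association uses the 3×2 composition × HAS table and the collapsed 2×2
  (RBC-rich vs other); the collapsed test is reported at its true df = 1.
* HAS rule: mean clot attenuation ≥ 50 HU is HAS-positive.
* `agreement_report` joins two per-clot composition tables and a clinical
  table on clot id (row order irrelevant) and emits pooled per-component
  Spearman (n = clots × 3), Bland–Altman on the pooled pairs, per-method
  %RBC vs mean-HU Spearman, and per-method HAS χ² tests. Tables import
  from CSV or XLSX through a column-mapping layer, so spreadsheets with
  arbitrary headers can be analyzed without editing.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at 160×160 px
slides, 2,000 training pixels per class, 1,500 annotated pixels per class
per slide, 5 training + 5 validation slides and 10 held-out test slides
spanning (80,5,15) to (15,5,80) — sizes at which the recovery error is
stable (per-component MAE well under 1 percentage point) and the full run
completes in seconds on one core. The library default of 5,000 pixels per
class is intended for real slides with more annotation area. Degenerate
inputs are errors, not guesses: zero tissue pixels, single-class training
sets, constant inputs to correlation, zero-margin contingency tables and
empty regions all raise with a named cause.

## Known limitations

* The SVM is uncalibrated (no class probabilities); outputs are hard
  labels by design.
* The generator's classes are color-separable by construction; it cannot
  measure the benefit of texture features over color alone.
* The comparator's "manual" artefact crop is emulated from ground truth in
  tests, which is more generous than a human would be.
* No support for vendor-proprietary whole-slide formats; pyramidal
  OME-TIFF is read at a stated level, everything else as flat PNG/TIFF.
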