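# Methods

This note documents the models and procedures the package implements, the
synthetic data they are exercised on, the numerical choices made where the
design was genuinely open, and what the tests do and do not establish.

## The analysis model

Each video frame of a talking face is represented as the pair (shape change,
shape-free texture): a dense backward warp field `d` registering the frame to
a common reference plus the RGB texture warped through `d` onto the reference
geometry. Stacking `(dx, dy, R, G, B)` per pixel and flattening yields one
sample per frame (81,920 dimensions at 128 px; 20,480 at the 64 px used in
the shipped study conditions). This is an active appearance model: shape and
texture jointly describe the face, and both are linear in the sample vector,
which is what makes PCA, LDA and the back-projection chain well-posed.

PCA retains the minimal number of components explaining 90% of the variance
(1/(n−1) normalisation, mean-centred features). LDA separates positive from
negative valence; the discriminant dimension is the normalised weight vector
(orthogonal to the decision boundary by construction), anchored at the
boundary point midway between the projected class centroids, with distances
in SD units of the pooled projections of *all* samples (1/(n−1)). Images are
generated from axis points by inverting each step: z-scoring, PCA, then the
warp (a fixed-point inversion of the backward field, applied to the texture).

Two geometric facts drive two design choices here. First, a line through the
class centroids is orthogonal to the LDA boundary only under spherical pooled
covariance, so the weight vector — not the centroid line — defines the axis
(the centroid variant is available via `extract_axis(...,
use_centroid_direction=True)`). Second, back-projected warp fields at far
extrapolations (±3 SD) need not satisfy the fold-over precondition
(displacement gradient < 1); the inverter pre-smooths such fields with an
escalating Gaussian (σ = 1.5, 3, 6 px) before failing. Smoothing affects
only these visualisation outputs, never a quantitative path.

## Registration engine

The two-frame registration is a gradient-constraint estimator run
coarse-to-fine: at each pyramid level (factor-2 Gaussian pyramid down to a
16-px floor) it iterates a locally aggregated normal-equation solve — a
Gaussian window (σ = 3 px) over products of image derivatives, a small
Tikhonov term (1e−4), per-iteration displacement steps capped at 2 px and
smoothed with σ = 0.8 px — with early exit when the mean step falls below
0.01 px. Derivatives are averaged between the warped source and the
reference for symmetry. These defaults were chosen to pass the sub-pixel
recovery oracle (median error < 0.25 px on integer translations) and the
smooth-deformation oracle (≥ 80% residual reduction) on rendered faces, and
are exposed in `WarpConfig` so an alternative engine could be slotted in
behind the same contract.

Conventions: backward mapping (the field stores where to *sample from*),
0-based pixel-centre coordinates, bilinear interpolation, edge clamping for
out-of-bounds samples (faces are centred, borders are uniform background).
The estimator enforces its monotone contract — warping never increases the
residual — by falling back to the identity field in the degenerate case.

Two further numerical choices matter on video input. Frames of a clip are
registered with a *warm start* — each frame's field is initialised from the
preceding frame's solution (injected at the coarsest pyramid level), so the
refinement only tracks the frame-to-frame change. And because the data term
says nothing about uniform regions, each final field undergoes a
confidence-weighted diffusion (normalized convolution, σ = 8 px, confidence
= windowed gradient energy of the reference): textured regions keep their
own estimate, while background and flat-shaded areas take the diffused
estimate of confident neighbours. Without this, warm-started fields can
carry stale displacements in regions nothing constrains.

The reference is initialised with the temporally middle frame of the first
clip (deterministic and overridable) and updated three times with the mean
warped texture of **all frames of all clips of the subject**; the
per-iteration change norms are recorded and are non-increasing on all test
fixtures.

## Synthetic data generator

No public corpus of good-news/bad-news deliveries exists, so the generator
defines the study conditions. It renders schematic faces — smoothly shaded
geometric primitives with a fixed procedural skin texture — parameterised by
seven latents: vertical head offset (px), head pitch/yaw/roll (deg),
lip-corner curvature, inner-brow elevation, and a texture-jitter scale. All
geometry is drawn in head-local coordinates, so a pure head offset translates
the image exactly (the basis of the shift-recovery oracles). Rendering is
quantised to the 8-bit grid, making PNG round trips bit-exact.

Per-clip latent trajectories are

```
latent(t) = baseline + class_sign · effect/2 · ramp(t)
          + phrase_offset(class, phrase) + repeat_noise(t)
```

with `ramp` a raised cosine from 0.3 to 1. The non-zero floor reflects that a
speaker already knows the valence at phrase onset: natural deliveries carry
expression information from the first frame and deepen over the clip, rather
than starting from a perfectly neutral face. Phrase offsets are drawn once
per (class, phrase) from the dataset seed — so leave-one-phrase-out
cross-validation genuinely tests generalisation over phrase idiosyncrasies —
and repeat noise is i.i.d. per frame. Default design: 3 subjects, 10 phrases
per class, 15/15/16 repeats, 36-frame prefix clips, suffix clips drawn
uniformly from 20–48 frames. The default class effect raises the head (3 px,
4° pitch), curves the mouth (+0.5) and lifts the brows (+0.25) for positive
valence; phrase and repeat variability (0.5 and 0.25 of each parameter's
natural scale) are calibration choices of this package — the magnitude of
within-class variability in real deliveries is not documented anywhere — and
are deliberately large enough that single frames are not trivially
classifiable.

The feature-table generator emits the 23-column action-unit/head-pose dialect
(OpenFace 2.x names) with the valence effect injected into vertical position,
pitch, AU01 (inner-brow raiser), AU12 (lip-corner puller) and AU17 (chin
raiser), matching the directions the image generator uses; AU intensities are
clipped at zero. Simulated raters respond with
`clip(gain · position/3 + noise, −1, +1)` — monotone-plus-noise.

What the generator does **not** emulate: photorealistic appearance, lighting
and background variation, speech-driven mouth articulation, occlusions, or
rigid 3-D rotation (pitch/yaw act as smooth feature displacements). Passing
tests therefore demonstrate that the pipeline recovers a known signal under
controlled, smooth, low-noise imaging — not that it would survive real-world
video nuisances.

## Cross-validation schemes

*Within-subject*: 10-fold leave-one-phrase-out; each fold holds out every
repeat and frame of one phrase in both classes. The PCA is refitted per fold
on training frames only. Train and test sets are z-scored **independently**
(each with its own means and SDs) — unusual but leakage-free; the
conventional train-fitted scaler is available (`zscore_mode="train"`).
Samples are individual frames and accuracy is frame-level proportion
correct; a clip-level majority-vote summary is reported alongside as an
auxiliary view. Confusion matrices are row-normalised with accuracy the mean
of the diagonal.

*Cross-subject*: subjects are first equalised — clips beyond the common
count are dropped from the end of a repeat-major clip ordering (the only
drop order that preserves (class, phrase, repeat) correspondence), and all
clips are truncated to the globally shortest length. Row correspondence
across subjects is then by (class, phrase, repeat, frame); this is asserted,
not assumed. Per outer fold (5-fold leave-two-phrases-out, phrases paired in
sorted order by default, seeded random pairing optional), per-subject
embeddings with a **shared** component count (maximum over subjects of each
minimal k) and the two-stage Procrustes alignment are fitted on outer-train
phrases and applied to outer-test phrases; alignment is fitted on unscaled
embedded data, z-scoring happens per inner split. The inner loop (subjects ×
2 phrase assignments) fits the LDA on one phrase per class in all-but-one
subject and tests the other phrase on the held-out subject — 30 folds with 3
subjects.

The Procrustes fit is the similarity-transform least-squares solution via
SVD of the cross-covariance, reflections allowed (no determinant
correction), scale = trace(Σ)/‖X_c‖². Stage 1 grows an unweighted running
average of aligned datasets in subject order; stage 2 refits every subject
to the stage-1 average; no further iteration is used.

## Statistics

LDA is solved directly on the pooled within-class covariance (Cholesky;
optional ridge, with a clear error advising it when the covariance is
singular). Ties in decision scores break toward the first sorted class
label. One-sample t-tests are two-sided (sidedness conservative by choice);
zero-variance inputs yield flagged degenerate results rather than silent
infinities. Holm-Bonferroni uses the standard step-down with monotonicity.

The repeated-measures ANOVA computes the one-way within-subject
decomposition with the fold as the unit; the Greenhouse-Geisser epsilon uses
the sample covariance of the model levels (clipped to [1/(k−1), 1]) and
scales both degrees of freedom. Eta-squared is reported in the partial form
SS_effect/(SS_effect+SS_error) and generalised eta-squared in the
observed-effect form SS_effect/(SS_effect+SS_subject+SS_error). The
implementation is cross-checked against an explicit sums-of-squares oracle
and against pingouin in the tests.

Dunnett many-to-one adjusted p-values are computed by seeded Monte-Carlo
integration of the correlated multivariate t of the paired contrasts
(estimated contrast correlation, n−1 df; 2,000–20,000 draws depending on
context) rather than by table lookup — dependency-free and validated by the
family-wise-error calibration below. Tukey pairwise comparisons use the
studentised-range distribution on √2·|paired t| with k groups and n−1 df.
Undefined correlations (constant responses) are flagged, never dropped.

All three adjusted procedures are calibrated by 1000-replicate null
simulations: their family-wise error at nominal α = 0.05 must land in
[0.03, 0.07].

## Study conditions for the shipped evaluation

The acceptance script (`scripts/acceptance.py`) runs the full image pipeline
at 1 subject × 10 phrases per class × 6 repeats × 36-frame prefix clips,
rendered at 64 px, with a strong (4× default, clipped to parameter bounds)
valence effect, and again with zero effect; PCA inside the CV uses the
randomized solver capped at 60 components (the exact total variance is still
used for the 90% criterion, so the retained count is unaffected while the
fit stays tractable on one CPU). The null run's chance band treats the fold
as the unit of independence: frames and repeats within a held-out phrase
share that phrase's offset, and under the null the two phrase cells of a
fold are classified coherently — whether the discriminant's projection onto
the held-out phrase-offset difference happens to point the right way decides
both cells at once — so each of the 10 folds contributes one effective
Bernoulli draw and fold accuracies are strongly bimodal rather than
binomial in the frame count. Cross-subject evaluation uses three subjects sharing a
common 23-dimensional feature signal under per-subject random orthogonal
transforms, scalings and shifts — the exact invariance class the Procrustes
alignment is designed to remove.

## Known limitations

- The registration engine is a generic gradient-constraint estimator; the
  published multi-channel gradient filter family is not reproduced, only the
  registration contract it serves.
- Back-projection fidelity is quantified for samples inside the retained PCA
  span; far extrapolations are visualisations whose warp fields may require
  pre-smoothing (documented above).
- Frame-level accuracy depends on the expression ramp: frames early in a
  clip carry weaker signal by design, so fold accuracies are bounded away
  from 1 in a way controlled by `ramp_floor`.
- The nested cross-subject scheme generalises the 3-subject design to N
  subjects × 2 assignments but is not intended for large cohorts or
  piecewise (searchlight-style) alignment.
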