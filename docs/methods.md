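# Methods

`infantpose` detects the 14 body joints of a supine infant in overhead
video frames with a tree-structured deformable part-based model, and
encodes movement as joint-angle time series. This note documents the
model, the training procedure, the synthetic study that validates the
implementation, the numerical choices, and the known limitations.

## Model

A body configuration is an assignment `z = {(l_a, s_a)}` of a cell
location `l_a` and an appearance state `s_a` to each part `a` of a
kinematic tree (head-rooted: head → neck → shoulders/hips → elbows/knees
→ hands/feet). Its score on a frame is

```
S(I, z) =  Σ_a  f_a^{s_a} · Φ(I, l_a)                 (template responses)
         − Σ_(a,b)∈E  ζ_ab^{s_a s_b} · ψ(l_b − l_a − r_ab)   (springs)
         + Σ_a R_a^{s_a} + Σ_(a,b)∈E R_ab^{s_a s_b}   (co-occurrence)
         + bias
```

* `Φ(I, l)` is a 5×5-cell patch of HOG features (unsigned orientations,
  9 bins, magnitude-weighted hard assignment, per-cell normalization by
  the four surrounding 2×2 blocks; per-cell L2 and unnormalized variants
  are configurable). Multi-scale detection uses a pyramid with scales
  `2^(−k/interval)`.
* `ψ(v) = [dx, dy, dx², dy²]` and `ζ ≥ 0` in the quadratic entries, so
  each edge is a spring penalizing the child's deviation from its rest
  offset `r_ab`. Rest offsets are the k-means centroids of the child's
  displacement relative to its parent over the training set; each
  centroid is one *state* of the child, giving a mixture of templates
  per part.
* The co-occurrence tables score state assignments and state pairs,
  letting the model prefer anatomically coherent mixtures.

All learnable weights concatenate into a single vector `β` with a fixed
slot order, and `S(I, z) = β · φ(I, z)` for a sparse feature vector
`φ`; this linearity is what makes max-margin training applicable, and is
verified directly by the tests (dual-path score equality).

## Inference

Because the graph is a tree, the global maximum of `S` over all
`(location × state)` assignments is found exactly by one leaf-to-root
message pass with argmax backpointers. The inner "best child location
per parent location" maximization separates per axis (the spring cost is
a sum of per-axis linear+quadratic terms) and is computed as two
vectorized per-axis max-reductions — exact for any sign of the linear
terms, with a brute-force non-separable version kept as the test oracle.
Ties in every argmax break toward the smallest `(level, y, x, state)`,
so detections are deterministic. On grids small enough to enumerate, DP
equals dense enumeration exactly (acceptance check).

Detection post-processing:

* **NMS** — greedy intersection-over-union suppression of root boxes;
  single-subject mode (default) keeps the top survivor, since the
  recordings contain one infant.
* **Occlusion threshold** — each part's appearance score is compared to
  a per-part threshold Ω_score stored in the model (the 10th percentile
  of that part's appearance scores over training positives). Parts
  below threshold keep their location but are flagged occluded and are
  excluded from angle computation and from the evaluation metrics.
* **Temporal restriction** — after the first (exhaustive) frame, the
  search space is the previous pose's bounding box dilated by Ω_dist
  (default 30 px; infants do not move fast between frames). Restricting
  the search never increases the best score, and when motion stays below
  Ω_dist it provably returns the full-search result; tracking falls
  back to a full search if a restricted frame yields nothing.

## Movement encoding and metrics

At each articulated joint `j` with endpoint child `i` and parent `k`,
`θ = arccos(V1·V2 / |V1||V2|)` with `V1 = l_i − l_j`, `V2 = l_k − l_j`,
clamped into [−1, 1] before the arccos; angles are unsigned in
[0°, 180°]. Joint estimates are the centers of the predicted 5×5-cell
patches. No temporal smoothing is applied by default; an optional
moving-median flag exists. Metrics: AJPE (mean per-part Euclidean
error, ×`mm_per_px`), WCA (percent of frames with *every* visible joint
within a threshold), MAE (mean absolute angle difference, gaps excluded
pairwise).

## Training

1. **Augmentation** (default): horizontal flip (with left/right label
   swap) and rotations −15°…15° in 5° steps — 14 variants per image,
   joints mapped by the same affine transform, padding instead of
   cropping when a rotation would push joints off canvas.
2. **Scale normalization**: per frame, each limb length is divided by
   the training-set median for that limb; the 75% quantile (linear
   interpolation) of these ratios times the base patch size gives the
   frame's patch size, and the frame is resized so that patch equals
   the 5×5-cell template footprint.
3. **States**: per part, k-means (10 restarts, seeded) on parent-
   relative displacements; cluster count fixed per part or selected by
   `BIC = n·ln(R/n) + S(d+1)·ln(n)` with `d = 2` and `R` the k-means
   residual sum of squares. Note the penalty grows as `ln n` while the
   gain from splitting a true cluster grows linearly in `n`, so BIC
   recovers the generating count reliably only at modest sample sizes
   (19/20 seeds at 10 points per blob in the acceptance check) and
   over-segments at large `n` — consistent with the tendency of
   BIC-selected mixture sizes to exceed empirically tuned ones.
4. **Margin learning**: maximum-margin constraints — annotated
   positives score ≥ +1, mined negative configurations ≤ −1, with all
   negatives from one image sharing one slack variable — optimized with
   the regularizer centered at the spring initialization `β₀`
   (`ζ = [0, 0, 0.01, 0.01]` per edge and state pair, everything else
   zero), which keeps the springs sensible before hard negatives exist.

The optimizer is dual coordinate descent over a growing working set,
organized in mining rounds:

* Hard negatives are mined each round as the top root configurations in
  every negative image; only margin violators are added (deduplicated
  by placement). Mining stops when a round finds no unseen violator
  *and* every cached constraint is satisfied within 1e−3.
* Two round modes. In the default **proximal** mode each round
  re-centers the regularizer at the current weights and restarts the
  dual variables: round `t` solves
  `min ½‖β − β^(t)‖² + C·Σ slacks` from `β^(t)`, a proximal-point
  sequence whose fixed point satisfies the margin constraints exactly
  (it approaches the hard-margin solution as rounds accumulate — the
  mined-negative margins converge to −1). In **persistent** mode the
  dual variables live across rounds, giving the single global
  soft-margin SVM with the per-image shared-slack cap
  `Σ_{i∈image} αᵢ ≤ C`. Proximal is the default because whole-image
  margin separation is easy here while *localization* quality depends
  on strongly discriminative weights; the soft-margin optimum at
  practical `C` leaves the part templates too weak.
* In both modes the invariant `β = center + Σ αᵢ φᵢ` holds throughout,
  so every α update is an exact dual coordinate step. Exact dual
  ascent does not make the primal monotone pass by pass, so each round
  retains the best (lowest-primal) iterate seen and logs its objective;
  exploration continues from the raw iterate. The logged trace is
  therefore non-increasing within a round, and the returned model is
  the retained iterate.
* The positivity floor on the quadratic spring weights (`ε = 1e−4`) is
  enforced by projection once per round, after the passes; the
  projection delta is absorbed into the center so the α-correspondence
  survives. Projecting inside the pass loop fights the positives'
  preference for soft springs and oscillates. Inference is exact for
  any spring sign, so transiently unclamped springs during mining are
  safe.

Cross-validation for `C` is two-stage (coarse log grid, then a narrow
geometric refinement around the winner), scored by mean held-out WCA at
half the patch size; ties break toward the smaller `C`.

## Synthetic study

The hospital recordings behind the original system are private, so the
package bundles a generator that emulates the recording scenario: a
single supine figure on a plain background under a fixed overhead
camera. The figure is a 2-D articulated stick figure — 14 joints,
limbs drawn as textured strips (width 10 px), head as a disc, additive
Gaussian noise — with forward kinematics driven by interior joint
angles, so ground-truth joints *and* angles are exact by construction.
Left and right limbs carry different texture stripe periods (7 px vs
11.2 px): orientation features cannot see texture phase, so a
frequency cue is what keeps mirrored limbs separable. Negative frames
contain scattered strips with the same width/texture statistics
(clutter, like blankets or equipment edges); with plain-noise negatives
alone the margin problem is solvable by the bias and the learned
templates stay uninformative.

Study conditions (used by the tests and `scripts/acceptance.py`):
120×160 px frames, 200 independently sampled training poses, 20
negative images, 4 px cells (20 px patches, twice the limb width), 2
states for axial parts / 4 for distal parts, `C = 10`, no rotation/flip
augmentation (the generator samples dense pose variation directly, and
flipping would relabel the side-specific textures), 30 mining rounds of
up to 200 passes. Training takes a few minutes on one core.
Evaluation: 50 held-out poses for AJPE/WCA, a 100-frame smooth motion
sequence (sinusoidal angle programs, per-frame displacement ≤ 4 px)
tracked with Ω_dist = 30 px for MAE. The margin-feasibility audit uses
a separable 80×80 set (50 positives, 20 plain-noise negatives, one
state per part, `C = 50`) trained to tight convergence.

What passing these tests shows: the scoring, inference, learning and
evaluation machinery are correct and the pipeline recovers poses it was
never shown, under appearance statistics (oriented texture on smooth
background) far cleaner than real video. It does not demonstrate
robustness to real nuisance factors — cloth, lighting, skin tone,
camera motion, partial views — and reported pixel metrics translate to
millimetres only through a camera calibration the user must supply
(`mm_per_px`).

### Angle-error floor from patch-center quantization

Joint estimates are centers of predicted patches, hence quantized to
the cell lattice (4 px here). For the study figure (limb segments
14–26 px), feeding *perfectly detected but lattice-quantized* joints
through the angle encoder already yields an MAE of ≈ 6.3° on the study
sequence; the trained detector reaches ≈ 6.6°, i.e. within half a
degree of that floor. Sub-5° MAE at this resolution would require either finer
cells — which shrinks the 5×5-cell patch below twice the limb width and
collapses detection (verified at 3 px cells and at 1.5×/2× upsampling) —
or larger subjects in pixels, which is how the original system's ~3°
(640×480, ≈ 80 px limbs) is consistent with this analysis. The
acceptance test asserting MAE < 5° therefore fails by design of the
study resolution; the companion test asserts the honest property, that
detection stays within 1.5° of the quantization floor.

## Numerical choices and degenerate inputs

* Gradients: `numpy.gradient` stencil (central differences, one-sided
  borders); color frames to luminance with BT.601 weights.
* Quantile definition: linear interpolation between order statistics.
* Zero-length limbs are excluded from the patch-size quantile (logged);
  coincident joints make an angle undefined and propagate as a gap.
* Disallowed placements in a restricted search use a large finite
  penalty (−1e15) rather than −inf to keep arithmetic NaN-free; an
  empty search region returns no detections and tracking falls back to
  a full search.
* `k`-means uses 10 seeded restarts; all randomness flows from a single
  integer seed per entry point, and training is bit-reproducible for a
  fixed seed, config and data.
* Model files are JSON with base64 little-endian float64 weight blocks
  and a format/version tag; foreign or truncated files are rejected
  without returning a partial model.

## Limitations

* 2-D only: out-of-plane foreshortening is modelled only through the
  mixture states; no depth, no 3-D angles.
* Single subject per frame (NMS single-subject mode by default).
* The structured-SVM formulation constrains whole configurations, not
  individual parts, so per-part localization sharpness depends on the
  negative set containing part-like distractors (hence the clutter in
  the synthetic negatives).
* BIC-based state selection over-segments at large sample sizes (see
  above); fixed per-part counts are the default.
* Millimetre-scale metrics require an external `mm_per_px` calibration;
  the default 1.0 reports pixels and logs a warning.
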