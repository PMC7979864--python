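# Methods

`combtrack` implements a markerless pipeline for honey-bee colonies filmed on
a natural comb background: dense detection of bees and capped brood by
segmentation networks, appearance-based re-identification with a triplet
objective, greedy trajectory assembly, and colony-level sociometric and
per-trajectory motion analytics. A synthetic-colony simulator with full
ground truth closes the loop so every stage is testable end to end on a
desktop CPU.

## Detection by segmentation

Bees are annotated as point tuples `(x, y, b, alpha)`: the body center in
image coordinates (x = column, y = row, origin top-left), the class
(`b = 1` fully visible "full-bee", `b = 2` "cell-bee" with only the abdomen
showing inside a comb cell), and the body orientation `alpha` in degrees
measured clockwise from vertical-up (`alpha = 0` for cell-bees, which have no
orientation). From these the `targets` module renders three maps:

* **class map** — each full-bee becomes an oriented ellipse with semi-axes a
  third of the half body dimensions (default body 80 x 30 px, so ~13.3 x 5 px);
  each cell-bee a disk of the same major diameter. The 1/3 fraction keeps
  blobs of neighbouring bees from merging in dense configurations. Where
  blobs overlap nonetheless, the later annotation wins per pixel
  (deterministic; overlap is avoided by construction).
* **angle map** — the bee's `alpha` on its blob, −1 on background. The
  invariant `angle_map == −1 ⇔ class_map == 0` holds by construction.
* **weight map** — `1 + ratio · G` per bee, where `G` is a unit-peak
  Gaussian with sigmas equal to the blob semi-axes, oriented along the body,
  and `ratio` is the training set's background-to-foreground pixel ratio,
  computed once per dataset. The additive unit baseline (rather than a
  replacement) is a choice; it guarantees strictly positive weights.

Rendered targets persist as NPZ archives with arrays ``class_map``,
``angle_map`` and ``weight_map`` (`combtrack.io.write_targets`); annotations
travel as CSV with columns ``frame,x,y,b,alpha`` for bees and ``frame,x,y``
for brood cells.

The detection network is a U-Net-style encoder–decoder with two convolutions
per level, max-pooling, nearest-neighbour upsampling followed by a 3x3
convolution, and skip concatenations. Two 1x1 heads produce 3-class logits
and an angle map. The **recurrent variant** keeps the penultimate feature map
of the previous video frame and concatenates it with the current penultimate
features before the heads (an all-zero prior starts a sequence; in tiled
inference each tile keeps its own prior). The temporal prior carries enough
context that every encoder/decoder width can drop to a quarter of the
original (16/32/64/128/256 instead of 64/128/256/512/1024), removing ~94% of
the trainable parameters (93.75% counted layer by layer for this exact
architecture). The raw angle-head output is multiplied by 180 so that O(1)
activations span the degree circle; the circular loss is unaffected by the
reparameterization and small-budget optimization becomes feasible.

Losses: per-pixel 3-way cross-entropy weighted by the weight map and averaged
over all pixels, plus the circular regression loss `sin^2((α̂ − α)/2)`
(difference taken in radians) averaged over foreground pixels, zero on empty
foreground. The angle loss is symmetric and 360°-periodic in both arguments.

Output maps become detections by 8-connected component analysis: components
with area outside [10, 1000] px are discarded; the position is the mean
member-pixel coordinate; the class is the member majority; for full-bees the
orientation is the first principal component of the member coordinates
(defined mod 180°), flipped to the half-turn closer — in the angle-loss
sense — to the circular (resultant-vector) mean of the member pixels'
predicted angles. Degenerate blobs without a principal axis use the circular
mean directly. Frames larger than one tile are processed in 512-px windows
overlapping so that each tile contributes only its interior (50-px margins
cropped except at frame borders); stitching the interior maps attributes
every blob to exactly one tile and makes tiled inference equal whole-frame
inference on single-tile frames.

Because no GPU deep-learning framework is part of the dependency set, the
package ships a compact numpy NN core (`combtrack.nn`): convolution, pooling,
upsampling and dense layers with hand-written backward passes and an Adam
optimizer. Every backward pass is verified against central finite
differences in the test suite. The networks exercised in tests are small
(widths 8/16 on 256-px frames); the default and original widths exist for
parameter accounting and can be trained with the same code given time.

**Brood detection** reuses the same machinery without recurrence: a
background image is extracted from a 12-h frame window as the per-pixel
median over "static" samples (frame-to-frame difference below a robust
threshold of median + 3 x 1.4826 MAD of all differences, with a plain-median
fallback for never-static pixels — a simple deterministic background
extractor). Brood cells are annotated as center points, rendered as
radius-10 disks (317 lattice pixels) with a `1 + 10·G` weight, segmented
with a binary-head network, and read out as component centroids with a
minimum area of half a brood disk.

## Appearance embeddings

A convolutional backbone maps a square crop centered on a detection
(default 128 px, zero-padded at borders) to a 64-d vector `f`. Training
minimizes the triplet hinge
`max(‖f(i1) − f(i2)‖² − ‖f(i1) − f(i3)‖² + margin, 0)` with margin 0.5,
where `i1` is an anchor detection, `i2` the same bee in a later frame and
`i3` a *different* bee in that same frame. Two devices keep the otherwise
astronomically large triplet space tractable:

* **matcher-constrained sampling** — negatives are drawn only inside the
  tracker's distance cutoff of the anchor, i.e., exactly the configurations
  where identity swaps can occur;
* **hard-example feedback** — triplets with positive loss re-enter the next
  batch; the rest of the batch is freshly sampled.

The batch objective is the sum of triplet losses divided by
`max(1, #zero-loss triplets)` (the reading of an ambiguous convention; a
plain mean over violating triplets is available via `batch_rule`).
Optional augmentation draws one transform (k·90° rotation, mirror flips) per
triplet and applies it to all three crops, preserving their orientation
relationship. Optional background masking zeroes pixels outside the
full-body ellipse (abdomen disk for cell-bees). A "rotated" variant embeds
crops rotated so the body axis points up, removing orientation cues.
The default backbone is deliberately small (two conv/pool stages, adaptive
4x4 pooling, a dense head) and swappable; the contracts are
architecture-independent.

## Trajectory assembly

All detections start as length-one trajectories. At each frame, candidate
(trajectory, detection) pairs must satisfy a class-dependent distance cutoff

* `c_d = a·sqrt(Δt)` when more than half of the trajectory's last (up to) 10
  detections are full-bees, with `a = 40 px` (half a body length) and `Δt`
  counted in frames at 10 FPS (configurable to seconds);
* `c_d = a/3` otherwise (cell-bees barely move),

and, in embedding modes, an appearance cutoff `V < c_v = 1.75` where `V` is
the minimum squared embedding distance to the trajectory's last (up to) 10
detections. Admissible pairs are sorted by the cost

    D = B·E + V + l         (embedding modes, B = 0.033)
    D = E + l               (position-only mode)

with `E` the Euclidean distance and `l = A·(1 − |T_j| / max|T_i|)`,
`A = 30`, the length factor that prioritizes extending long trajectories
over short, possibly spurious ones. The orientation variants add
`0.25·sin²(Δα/2)`. Matching is greedy in increasing `D` with deterministic
ties (trajectory id, then detection index); one pass per frame; unmatched
detections seed new trajectories after all matches commit.

Unmatched trajectories stay open until their gap exceeds 10 s (cell-bee
majority), 1 s (last detection inside the entrance region, where dense
traffic makes long gaps unsafe) or 3 s (otherwise); closed trajectories are
retained only if they span at least one minute. Long recordings can be
processed per one-minute segment (`track_parallel`): each segment is tracked
with a warm-up of the preceding second of detections (trimmed afterwards) so
the appearance window is populated from the segment's first frame, and
segment boundaries are stitched with the same `c_d`/`c_v`/`D` criteria,
iterated to a fixed point so chains of short pieces merge. On the simulator
scenes the parallel output is identical to the serial one.

A trajectory is scored **correct** against ground truth when a single
identity accounts for ≥ 80% of its detections and those detections cover
≥ 80% of that identity's detectable presence; each identity is credited at
most once, and the reported proportion is relative to the mean number of
detections per frame.

## Analytics

* **Periodogram** of a mean-subtracted count series (scipy), with the
  dominant period taken over 2–48 h; total power equals the series variance
  (Parseval).
* **Rayleigh test** of hour-of-day uniformity using `z = n·R̄²` and the
  standard finite-n corrected approximation
  `p = exp(sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n))` with `R = n·R̄`; it matches
  pingouin's implementation to numerical precision and its type-I error at
  `α = 1e-4` is verified ≤ 5e-4 over 10^5 uniform simulations.
* **Nightly cell-bee excess**: per calendar day (days with < 50% coverage
  excluded) samples strictly above the daily median are binned into 24 1-h
  bins; the circular mean hour summarizes the peak.
* **Windowed correlation**: both series are averaged in common 12-h windows,
  mean-subtracted, and correlated (Pearson, two-sided p).
* **Brood distances**: nearest-brood-cell distance per detection (KD-tree),
  compared between classes with a two-sided Wilcoxon rank-sum test
  (≥ 2 detections per class required).
* **Motion metrics** per trajectory: mean speed from successive
  displacements; mean angular speed from successive displacement headings
  wrapped to (−π, π] (body-angle-based headings are available but
  displacement headings are the default since they exist for cell-bees too);
  path length; motion span (diagonal of the axis-aligned bounding box);
  diffusion coefficient as slope/4 of a straight-line fit (with intercept) to
  the MSD over lags ≤ 10 s; comb-cell visits as class transitions 1→2.
* **Entrance enrichment**: the in-region fraction of the selected (top-k)
  trajectories' positions divided by its mean under random reselection, with
  `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, n_perm ≥ 999.

## The simulator

The simulator generates the study conditions, not a photorealistic hive:

* **Motion** — a run-and-turn correlated random walk (Gamma-distributed
  per-frame speeds, mean 40 px/s; Gaussian heading jitter) with reflecting
  walls; Poisson-initiated comb-cell episodes freeze the bee and set
  `b = 2`; entries/exits happen only through a configurable entrance region.
  Bodies exclude each other anisotropically: a pair is pushed apart along
  the line joining the centers until it exceeds the sum of the two body
  ellipses' radii in that direction, so bees touch flank-to-flank at one
  body width but head-to-head only at a full body length (a frozen cell-bee
  stays put and the walker yields). In the tracking scene 15% of encounters
  become "climb-overs" — for a bounded episode (exponential, mean 1.5 s) the
  pair may interpenetrate, emulating one bee walking over the other, the
  occlusion events a real detector faces. A detection (and its annotation)
  is dropped whenever the bee's center is painted over by a later-drawn
  bee's body — its target region is then covered and neither a detector nor
  a human labeler could mark it. A center-distance radius is available as a
  simpler alternative criterion. The detection scene disables climb-overs:
  it probes rendering, training and blob extraction on touching but
  non-interpenetrating bees, while occlusion robustness is the tracking
  scene's concern.
* **Rendering** — textured oriented ellipses (per-identity brightness,
  stripe frequency/phase, and a head-to-tail gradient that makes the
  half-turn learnable) over a hexagonal-interference comb background with
  frozen speckle and per-frame Gaussian sensor noise; painter's order by
  identity id.
* **Appearance oracle** — per-identity 64-d centers (orthogonal, norm
  `s/√2`, so between-identity squared distances equal `s²` exactly for up to
  64 identities) plus isotropic per-frame noise; with the defaults
  (`s = 2`, `σ = 0.1`) the right-identity windowed similarity stays under
  `c_v` and the wrong-identity one above it in > 99% of frames. This stands
  in for a trained re-identification network in tracker tests.
* **Count series** — visible bees as a 24-h cosine (peak 14:00, baseline
  1000, amplitude 150 — colony-scale numbers) plus noise; brood as a
  baseline minus the 12-h-windowed bee excess (the anticorrelation
  structure); cell-bees with a von-Mises-shaped nightly bump peaking at
  02:00.

Everything is a pure function of `(config, seed)`; per-purpose seed streams
are split off a `SeedSequence`. What the simulator does **not** emulate —
photorealistic texture, lighting drift, wing/leg articulation, comb
construction, brood development — means that passing tests demonstrate the
correctness and internal consistency of the algorithms at realistic
densities and noise levels, not field performance on video.

## Problem sizes and numerical choices

The test suite and the acceptance script run three desk-scale studies chosen
to fit a single CPU: a detection scene of 30 frames at 256x256 px with 15
bees (44 x 16 px bodies; 24 training frames, 6 held out; widths 8/16, up to
45 epochs at Adam lr 1e-3 with the angle loss weighted 0.2 and checkpoint
selection on training-frame detection rates — several CPU-minutes) reaching
held-out TPR ≥ 0.95 at FPR ≤ 0.10 on the reference scene (hard scene draws
with heavy cell-bee camouflage can measure a few points lower); a tracking
scene of 50 identities at hive-like density (1024x1024 px, 120 s at 10 FPS)
where embedding-mode tracking recovers ≥ 95% of identities and position-only
mode strictly fewer; and a two-week sociometric series at 2-min sampling. TPR counts ground-truth bees matched
within a quarter body length; FPR is the fraction of detections matching no
bee. Network weights are float32 (float64 in gradient-check tests);
losses and statistics are float64. All randomness flows from explicit seeds.

## Known limitations

* The numpy NN core is single-threaded BLAS-bound; paper-scale training
  (full-width networks, thousands of epochs) is out of its intended range.
* Re-identification across hive exits/entries is not attempted; a bee that
  leaves and returns receives a new identity.
* The brood pipeline detects capped brood only; eggs, larvae and storage
  cells are out of scope.
* `score_against_truth` needs per-detection ground-truth identities and is
  therefore simulator-only; real recordings require manual validation.
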