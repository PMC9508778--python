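# Methods

This note documents the models and procedures implemented in `gazepheno`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohort does and does not emulate.

## Coordinate conventions and geometry

All positions are in screen pixels, origin top-left, y downward, screen
bounds half-open `[0, W) × [0, H)` (default 1920 × 1080). Visual angle
converts at 41 linear pixels per degree — a 23″ 1080p monitor viewed at
~65 cm. A pixel belongs to a region iff its integer coordinate lies inside
the (half-open) region; a pixel belongs to the gaze disk iff its centre
lies within the disk radius (20.5 px at the 1° default). All area
computations are rasterized at 1-px resolution, so box and mask inputs
behave identically, and the fast patch-based assignment is *exactly* equal
to brute-force pixel enumeration (tested on 1,000 random frames).

## AOI construction

Eyes and mouth regions derive from five facial keypoints: (i) the smallest
box enclosing the keypoints; (ii) a medium box whose corners are the
midpoints between corresponding corners of the small box and the detector's
face box; (iii) the medium box split at the nose's y into eyes (upper) and
mouth (lower). The split row itself belongs to the mouth (half-open
convention, tie-free). A nose outside the medium box is a degenerate split:
the face is kept with empty eyes/mouth regions and the event logged.

Overlap precedence where regions collide: eyes/mouth carve out of the face;
face beats hands beats other-body (the socially informative, typically
smaller region wins); non-social content is the complement of all person
regions. These choices make the coarse labels an exact partition of the
screen (pixel-count tested). Precedence between persons follows the same
label order; co-present faces are kept disjoint by the generator (see
below) because face-on-face occlusion has no principled labelling.

Body-part detections arrive either already grouped (face / hands /
other-body) or in the 24-part dense-pose taxonomy, mapped by a fixed
lookup (head → face, hand parts → hands, the remaining 20 → other-body).

## Gaze coding

Raw gaze is averaged within each frame span `[f/fps, (f+1)/fps)` (boundary
samples belong to the later frame); the mean of the valid samples is the
frame's gaze point. No valid samples → missing; mean outside the screen →
off-screen; both count as "not on-screen". Because only the within-frame
mean is used, 300 Hz and 120 Hz recordings are processed identically
(tested to 1e-9 px). On-screen percentage is over all frames; every AOI
percentage is over on-screen frames only, which controls for individual
differences in on-screen time. Eyes/mouth are coded hierarchically: the
coarse argmax first, then the fine argmax within the face, so the eyes
share can never exceed the face share. Participants missing more than half
of either episode are excluded (strictly more: exactly 50% is kept).

## Heatmaps

A bin's heatmap is the sum of isotropic Gaussians (σ = 0.5° = 20.5 px,
truncated at 4σ, which discards < 3·10⁻⁴ of kernel mass and makes the cost
linear in points) stamped at the frame-rate gaze points of the bin; 1-s
bins by default. The reference heatmap pools the reference group's points,
always leaving the compared participant out when they belong to the group.
Correlations are Pearson on the flattened grids; empty or constant grids
are undefined and skipped, never zero-filled. Mean reference correlation
per participant feeds the feature vector; participants beyond 4 SD of the
other participants' mean (leave-one-out, so an outlier cannot mask itself)
are excluded. Grids may be computed on an integer-downsampled grid
(default 4× in the analysis configuration); per-bin correlations are
stable to the factor within ±0.02, and factor 1 reproduces the full
resolution.

## Resampling statistics

* **Cohen's d** uses the pooled SD with the `n₁+n₂−2` denominator,
  oriented TD − ASD. The bootstrap resamples within groups (default
  10,000), reports the mean d, the 2.5th/97.5th percentile CI, and a
  two-sided sign-crossing p with add-one smoothing,
  `p = min(1, 2(1+k)/(B+1))` where k counts bootstrap draws on the far
  side of zero. Degenerate draws (zero pooled SD) are redrawn and logged.
* **Epoch sampling** draws contiguous epochs with uniform starts; pairs
  are uniform over the feasible non-overlapping set (by rejection; the
  exact-tiling case `T = 2d` falls back to the only feasible placement).
  Epoch features come from cumulative per-frame label counts, so any
  epoch's feature matrix is an O(participants) lookup.
* **Reliability** is the Spearman correlation across participants of a
  feature computed in two non-overlapping epochs, averaged over
  iterations; group comparison uses the same epoch pair for both groups
  and the sign-crossing p of the ρ_ASD − ρ_TD distribution.
* **Partial rank correlation** rank-transforms all four variables,
  regresses rank(x) on rank(z) and rank(y) on rank(w), and Pearson-
  correlates the residuals (the data are already ranks).
* **FDR** is Benjamini–Hochberg, applied within each analysis table (per
  epoch duration).
* Demographics: unpaired equal-variance t (df = n₁+n₂−2) and the
  Yates-corrected χ² for 2×2 tables. Familiarity splits use ratings > 5 vs
  < 5 (missing and exactly 5 excluded); severity correlations are Spearman,
  uncorrected, ASD only.

## Fingerprinting

Feature vectors are standardized to zero mean and unit variance across
participants within each epoch (population SD). Identification goes
epoch-A → epoch-B by minimum L2 distance with the participant themselves
among the candidates; ties break to the lowest row index (logged). The
permutation null shuffles the identities of the epoch-B vectors; since the
nearest-neighbour map is fixed under the shuffle, chance matches behave as
the fixed points of a random permutation (≈ Poisson(1); verified against
the exact rencontres distribution), putting the null's 95th percentile at
3/n — 6.2% at n = 48, 2.9% at n = 105. With bootstrap-duplicated
participants an identification succeeds iff the nearest neighbour is any
copy of the same original, which keeps the chance level at ~1/n distinct.
In the epoch-sampled variant the null collects one shuffled accuracy per
iteration and the p-value compares the mean observed accuracy against that
distribution.

## Classification and clustering

The diagnosis classifier is Gaussian Naive Bayes (per-class per-feature
Gaussians with a relative variance floor of 1e-9, priors from training
frequencies, posterior ties to the majority class) on the four-feature
vector (% on-screen, faces, eyes, heatmap correlation). Cross-validation
samples an epoch and holds out one third of each group per iteration; the
chance level is the 95th percentile of an identical procedure with
diagnosis labels permuted once per iteration — a null that preserves class
imbalance and CV structure. Our implementation agrees with the standard
library classifier on random problems and is kept in-package because the
tie and variance-floor behaviour are part of the contract.

Clustering fits a variational Bayesian Gaussian mixture (5 components by
default; a Dirichlet-process weight-concentration prior of 1e-3 lets
unneeded components empty, so 10- or 20-component initializations give the
same populated clusters — tested) to the per-window standardized feature
matrix. Numerical choices that matter at cohort-scale n (~100 points,
4 features): **tied covariance** — per-component full covariances make
splitting a cluster almost free and systematically over-fragment planted
structure, while a shared covariance still absorbs the strong
between-feature correlations; and **restart selection by the variational
lower bound** over random initializations plus a deterministic ladder of
k-means partitions with 2…k clusters (padded with empty components). On
planted data the lower-bound optimum is the true solution by a wide
margin; the ladder merely guarantees its basin is visited.

Clusters smaller than 4 members dissolve into the nearest large-cluster
mean (means computed before reassignment; ties to the lowest index).
Across the moving windows (10-min window, 1-min step at full scale; 4-min
window, 30-s step at the desk scale used here), cluster identities are
matched by nearest cluster-mean vectors onto a reference window chosen to
have the modal cluster count; the mapping is deliberately many-to-one, so
a window that transiently splits a cluster still contributes its members
to the same identity instead of minting phantom clusters.

## The synthetic cohort

The generator defines the statistical structure the analyses assume; the
real study has no generative model, so this one is designed to make every
downstream quantity identifiable and plantable.

* **Scenes**: lognormal shot durations (median 4 s, σ_log 0.6), 0–3
  persons per shot (≥1 person in ~96% of frames), persons static within a
  shot. Faces are 120–210 px boxes with deterministic keypoints (eyes at
  40% of box height, nose at 55%, mouth corners at 72%); bodies extend
  below the face, with 0–2 hand boxes. Co-present faces are
  rejection-sampled to be disjoint.
* **Traits**: probability traits (on-screen; face given on-screen; eyes
  and mouth given face) live on the logit scale. A participant's latent
  trait is drawn once from their group distribution — optionally a mixture
  of components, which is how heterogeneous groups are built — and
  perturbed per episode by session jitter. Group shift, heterogeneity and
  session noise are therefore independent knobs.
* **Gaze**: a dwell process. Each dwell draws a target from the
  trait-weighted categorical over the AOI categories present in the shot;
  the face keeps exactly its trait probability whenever a face is present
  (absent categories redistribute within the non-face pool). The anchor is
  the target region's interior point (eyes/mouth centroids; the chin strip
  for other-face) plus Gaussian scatter (0.4° default), held for an
  exponential dwell (mean 0.5 s; 0.3 s in the heterogeneous cohort,
  matching typical fixation durations in dynamic scenes) snapped to frame
  boundaries, and emitted at 300 Hz with 0.05° per-sample noise. With
  probability 1 − p_onscreen a dwell is tracker-lost.
* **Calibration**: trait means are set to the observed group statistics of
  the cohort the pipeline models — TD face-looking ~80.7% of on-screen
  time (SD ~4%), ASD ~77.4%, eye shares ~60% vs ~52% — and the generator
  is *honest*: with small scatter and faces always present, coded
  fractions converge to the trait probabilities within ±2% on a 10-minute
  episode (tested end to end).

The heterogeneous ("hypothesis-2") cohort used by the analysis scripts
gives both groups the same atypical-gaze component — markedly fewer eye
fixations (eyes share logit 0.42 ≈ 32% vs 75% typical···calibrated against
the reported group gap), less on-screen time, mildly less face-looking —
at 50% prevalence in the ASD group and 25% in controls, mirroring the
reported composition of the data-driven atypical cluster (~22.5/48
autistic and ~27/105 control members). The ASD near-typical component is
mildly shifted so the group-level d stays in the reported 0.5–0.8 range.
Session jitter (0.07 on the logit scale) is calibrated so desk-scale
reliability sits at the reported ρ ≈ 0.7–0.9. Because the atypical cluster
crosses diagnostic lines with a ~1:1 density ratio, strengthening its
separation stabilizes clustering *without* helping diagnosis
classification — which is precisely the phenomenon under study.

What the generator does **not** emulate: episode-level content effects
(both episodes are exchangeable draws, whereas real episodes differ in
face time), semantic saliency and scanpath dynamics, smooth pursuit,
blinks as a distinct process, and detector noise in the annotations
(boxes are exact). Passing tests therefore validate the analysis chain and
its statistical behaviour, not claims about real gaze data.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: cohorts of
20–90 participants, two 5-minute episodes, windows of 2.5–4 minutes,
300–2,000 resampling iterations (10,000 where the quantity is cheap, e.g.
permutation nulls). Full-scale settings (48/105 participants, 22+21-minute
episodes, 10,000 iterations everywhere) are plain configuration:
`synthetic.paper_scale_cohort()` and the `PipelineConfig` defaults.

## Known limitations

* Heatmap stamping centres kernels on the nearest grid pixel; sub-pixel
  placement error is ≪ σ and irrelevant after correlation.
* The epoch-sampled fingerprint p-value compares a mean against
  per-iteration null draws; it is conservative for strong effects and
  should not be read as an exact test.
* The reliability group-comparison p is a sign-crossing bootstrap on the
  ρ difference; the original analysis reported such comparisons without
  specifying a construction.
* With very small groups (< ~10) the GNB holdout and the mixture fits
  become unstable; the implementations guard and log, but results at that
  scale are not meaningful.
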