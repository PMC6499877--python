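# Methods

`prfdecode` implements a retinotopy-based pipeline for reconstructing and
decoding imagined letter shapes (H, T, S, C) from voxel activation
patterns in early visual cortex, together with a synthetic-cortex
generator that provides ground-truth data to exercise it. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic results do and do not show.

## Stimulus model

The visual field is a square pixel raster (default 150 x 150) calibrated
in degrees of visual angle. The raster's full extent defaults to 10 deg:
the letters live in an 8 x 8 deg guide box and a 1 deg margin on each
side leaves room for reconstruction spill-over. Pixel centers are
symmetric about fixation; x points rightward, y upward; images are
vectorized row-major (p = 22500 pixels at the default raster).

Letters are binary glyphs built from axis-aligned bars and annulus
sectors filling the guide box with a configurable stroke width (default
1.2 deg). The glyph geometry is the package's own choice (no font is
canonical here); it preserves the coarse-to-fine ordering that matters
scientifically — 'T' and 'H' are wide straight strokes, 'C' a single open
ring, 'S' two stacked thin arcs — so that coarse letters reconstruct more
easily than fine ones.

Bar-aperture mapping stimuli are 1.33 deg wide bars at 4 orientations
(0/45/90/135 deg), each sweeping the raster in 12 steps of 3 s (one per
volume), each orientation repeated 6 times: 288 frames. Step positions
tile the raster's projection onto the bar normal, so diagonal sweeps
cover the corners; step order is randomized per orientation-repetition
block under an explicit seed. Bars at the screen edge are clipped by the
raster, so the nominal band width holds for interior steps.

## Synthetic cortex

Each voxel has an isotropic Gaussian pRF with center (x0, y0) and width
sigma = max(slope * eccentricity, 0.1 deg), plus optional Gaussian width
jitter. Populations are sampled uniformly over a disk large enough to
cover the raster corners. Default area slopes: V1 0.15, V2 0.25, V3 0.35
(within the 0.1-1 range the fitting grid explores, increasing across
areas as receptive-field sizes do).

The forward model is linear: neural drive per volume is the pixel sum of
the (unit-sum) pRF profile times the stimulus frame, convolved with a
canonical double-gamma HRF (gamma modes at 6 s and 16 s, undershoot ratio
1/6, sampled at TR = 3 s). With a 6 s peak, the +2..+3 volume window used
for pattern extraction (6-9 s after onset) straddles the response peak.

Sessions follow the study design: one perception run (8 trials per
letter, 6 s stimulation) and four imagery runs (32 trials each, 8 per
letter, 6 s imagery phase), with rests alternating pseudo-randomly
between 9 and 12 s. Imagery trials drive voxels with
`imagery_gain` x the perceptual drive (default 0.5) and carry more noise
(default 2 x the perceptual noise SD), emulating attenuated, noisier
topographic signal during imagery.

Noise is additive white Gaussian per voxel and volume, with SD expressed
**relative to the peak full-gain evoked amplitude** of the session. This
calibration makes `noise_sd` an interpretable SNR dial (1.0 = noise as
large as the largest single-voxel response) and keeps the imagery gain a
genuine SNR reduction; absolute noise in raw drive units would depend on
arbitrary pRF scaling. Each simulated run is z-normalized per voxel over
time, as the preprocessing contract requires.

Not emulated: physiological or temporally autocorrelated noise, motion,
distortion, surface geometry, and between-subject vividness differences
beyond the gain/noise settings. Passing tests therefore show that the
*analysis* behaves correctly under its stated assumptions, not that those
assumptions hold in scanner data.

One deliberate consequence of per-voxel temporal z-normalization: in
noiseless data it equalizes response amplitudes across voxels, so
extracted patterns are not proportional to the drive (they remain
monotonically related and letter-identifying). Tests assert ranking and
positive correlation rather than proportionality for such cases.

## pRF fitting

Grid search over 100 polar angles x 100 eccentricities x 10 slopes
(0.1..1.0). Eccentricity levels follow
e_k = ecc_max * (exp(decay*k/100) - 1) / (exp(decay) - 1) with decay 3 —
the named property is exponentially decaying density with eccentricity;
this is the simplest map with that property, and decay -> 0 recovers
uniform spacing. Candidate width is sigma = max(slope*ecc, 0.1); the
floor keeps the Gaussian well-defined at fixation.

Goodness of fit is the Pearson correlation between predicted and observed
time courses (amplitude-free, so the arbitrary gain between drive and
z-units cancels). The HRF is applied to the frame matrix once before the
candidate sweep (convolution and the pixel sum commute), making the
search a single matrix product per candidate block. Ties resolve to the
smallest eccentricity, then smallest slope, then smallest angle —
deterministic and conservative. Constant observed series are flagged
invalid. Voxel selection keeps fits with score >= 0.2 by default (the
retained count is itself a quantity of interest downstream).

The encoding matrix W_pRF (v x p) stacks each selected voxel's Gaussian
evaluated at pixel centers, scaled to unit row sum; any global gain is
absorbed by pattern z-scoring.

## Pattern extraction

Runs are high-pass filtered by regressing out an intercept, a linear
trend, and sine/cosine pairs at 1, 2, 3 cycles per run, then z-normalized
per voxel over time. Single-trial patterns average the volumes at
onset+2 and onset+3 (inclusive two-volume reading of the "+2 until +3"
window) and are z-scored **across voxels**; the two distinct
z-normalizations (temporal for runs, spatial for patterns) are named
explicitly throughout. Per-letter averages are the mean of single-trial
patterns, re-z-scored. Full design bookkeeping: 8 perceptual and 32
imagery single-trial patterns per letter.

## Encoding analysis

Predicted patterns are W_pRF @ vec(letter), z-scored. For each imagined
letter the observed average imagery pattern is regressed (OLS with
intercept, via statsmodels) on the four predicted patterns; collinear
predictor sets are rejected on condition number (> 1e8). The per-subject
contrast places +3 on the matching letter's beta and -1 on each other
beta, and a one-sample t test across subjects (one-sided, matching the
directional hypothesis) evaluates it at the Bonferroni-corrected alpha
0.05/12 = 0.0042 for the 4-letter x 3-ROI family. A full random-effects
mixed model is out of scope; with a fixed within-subject design the
per-subject OLS + across-subject t test is the estimable core.

## Reconstruction

The reconstruction x of a voxel pattern y minimizes
(y - Wx)^T (y - Wx) + x^T D x, where D is diagonal with the *outdegree*
of each pixel — defined here as the column mass of W_pRF (the total
encoding weight the pixel projects to cortex, a cortical-magnification
proxy; a binary count mode is also provided). The penalty term is read as
the quadratic form x^T D x, the only reading consistent with the closed
form x = (W^T W + D)^(-1) W^T y.

Numerics: every outdegree is floored at 1e-6 x max(D) (all columns, not
only exactly-zero ones — near-zero positive masses would otherwise blow
up the inverse), which keeps W^T W + D positive definite and shrinks
uncovered pixels to zero. For p larger than a few thousand the p x p
system is never formed; the projection is applied through the
algebraically identical form D^(-1) W^T (I_v + W D^(-1) W^T)^(-1) with a
v x v Cholesky factorization, computed once per ROI and reused for every
pattern. Non-SPD systems are rejected with a smallest-eigenvalue
estimate. Both routes are cross-checked against each other and against an
LSQR solve of the augmented least-squares system.

Quality metrics: first-level r is the Pearson correlation between a
reconstruction and the binary letter over all pixels; second-level r
correlates the 6 pairwise letter-letter correlations with the 6 pairwise
reconstruction-reconstruction correlations; Fisher z (arctanh) is
available for aggregation. Pearson r is scale-invariant, so whether
reconstructions are rescaled first is immaterial.

## Denoising autoencoder and classifier

Tied single-hidden-layer autoencoder: k = floor(0.1 v) hidden units,
decoder weights structurally equal to the encoder transpose (never stored
separately, so the tie cannot drift), linear output, ReLU hidden units by
default with the logistic activation available by configuration (both are
defensible readings of the architecture; both are tested). Training set:
the four average perceptual patterns plus four zero patterns (so inputs
without signal restore toward zero), each corrupted afresh at every step
with N(0, sd^2) noise, sd = 12 z-units by default and robust across
[8, 14]. Loss is MSE between restoration and the clean target; optimizer
is Adam (0.9/0.999/1e-8), batch 100 drawn with replacement from the
8-item set, 2000 steps.

Learning rate: Adam's per-parameter step is bounded by the learning rate,
so total weight movement over training is at most lr x iterations.
Reaching the weight scale the attractor solution requires on
unit-variance patterns within a 2000-step budget needs lr of order 1e-4
or larger; the package defaults to 1e-3, which trains to attractor
behavior (restoration-to-attractor correlation > 0.95, pure noise mapped
toward zero) across pattern sizes from a few hundred to a few thousand
voxels. Rates much smaller than this leave the weights essentially at
their random initialization. The rate is configurable.

The classifier replaces the decoder with a 4-unit softmax head on the
frozen hidden layer (multinomial logistic regression on pretrained
hidden representations; encoder weights and biases are untouched, which
tests verify bitwise). Head training: cross-entropy, Adam lr 1e-4, batch
96, 250 steps, zero initialization (the problem is convex, so zero init
plus full-batch gradients make training deterministic).

Evaluation is leave-one-run-out over the four imagery runs: train on 96
single-trial patterns, test on 32, report the mean over the four folds.
Significance comes from 1000 permutations in which the 96 training labels
are scrambled jointly (test labels intact — the standard decoding null;
within-run-stratified scrambling would also be defensible) and the full
LORO procedure is repeated; observed accuracy is significant when it
exceeds the nearest-rank 95th percentile of the null. Because the head is
full-batch, zero-init, and convex, the permutation nulls are trained with
a vectorized trainer that fits all permutations simultaneously; tests
assert it is bit-identical to the sequential trainer, so the batching is
an implementation detail, not an approximation.

## Pipeline and problem sizes

The pipeline simulates each subject's three areas as one combined
population recorded in a single session, analyzes V1, V2, V3 by slicing
and the combined V1V2V3 ROI as their union, and derives every stage seed
from one master seed (bit-identical reruns). The configuration is a
strict schema: unknown keys are rejected, and the full configuration is
serialized into every results directory.

Default problem sizes were chosen so the full study runs on a laptop
core: analysis scripts use 6 subjects x 370 voxels on a 100 x 100 raster
with a 40 x 40 x 10 search grid and 300 permutations; the test suite
exercises the headline sizes where the design pins them (150 x 150 raster and
2000 voxels for closed-loop fidelity; the full 100 x 100 x 10 search grid
for recovery at 500 voxels; 1000 permutations for the null) and smaller
sizes elsewhere. Noiseless closed-loop reconstruction fidelity is
measured at slope 0.1 (V1-like foveal precision, the smallest slope the
search grid covers); at larger slopes pRF blur lowers the attainable
first-level r below 0.8 even without noise, though reconstructions still
rank their own letter first.

## Known limitations

- The generator's white-noise assumption makes pattern extraction's
  two-volume averaging mildly optimistic relative to autocorrelated
  scanner noise.
- Overlapping HRF responses from neighboring trials (rest 9-12 s, HRF
  tail ~30 s) contaminate extracted patterns; this is faithful to the
  design but means even noiseless patterns are not pure letter drives.
- The encoding contrast analysis simplifies a random-effects mixed model to
  per-subject OLS plus an across-subject t test.
- With six desk-scale synthetic subjects, only a minority of the 12
  letter x ROI contrasts clear the Bonferroni cutoff (all are positive);
  the full-strength result requires real high-field data.
- The autoencoder ceiling: denoised imagery can at best reach the quality
  of the perceptual patterns the autoencoder was trained on, and trials
  that fall in the wrong attractor basin are actively mapped to the wrong
  letter.
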