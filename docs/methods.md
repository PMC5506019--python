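# Methods

This note documents the algorithms implemented in `brainheart` and the
design of the synthetic validation. Quantitative statements here are either
analytic or computed by the shipped tests (`tests/`) and the acceptance
script (`scripts/acceptance.py`).

## Synthetic cohort generator (`synth`)

**Atlas.** A 3-D voxel grid is partitioned into 5 disjoint network blocks
(dmn, temporolimbic, salience, fp_left, fp_right), a white-matter block and
a CSF block; remaining voxels are noise-only background. The analysis mask
is everything outside WM/CSF. Background voxels are retained deliberately:
they keep the network indicator maps linearly independent of the spatial
constant after voxel centering, and they supply true-null voxels for
calibrating voxelwise inference.

**Latent time courses.** For each session a target correlation matrix is
assembled from the session's FC effects (base correlation on the designated
sync edge, condition-specific edge shifts, behaviour-linked shifts),
projected to the nearest correlation matrix, and sampled through a Cholesky
factor. Background FC between unrelated networks is zero by default:
sliding-window FC estimates of two edges that share a node co-fluctuate in
proportion to the correlation of the non-shared nodes, so a nonzero uniform
background would mechanically propagate FC–HR coupling from the designated
edge onto its neighbours.

**Heart rate.** Each subject draws a baseline HR (70 ± 7 bpm) and a
condition delta (−3 ± 6 bpm applied during gratitude). Within the gratitude
session, per-window target HR is built as
`mean + 3·(ρ·z_fc + √(1−ρ²)·AR(0.8) noise)` where `z_fc` is the
standardized windowed FC of the sync edge. Beat times are back-solved from
these window means with a smoothness-penalized least-squares system and a
damped fixed-point loop whose correction is decomposed into two orthogonal
parts — the demeaned window-shape error and a scalar session-mean bias
(the mean of 60/IBI exceeds the target mean by a factor `1 + cv²`) — so
windowed correlations and the session mean converge independently. A PPG
waveform is then rendered from the beat train.

**Images.** Voxel time series are network indicator loadings on the
latents plus white noise and a leakage of WM/CSF confound signals; motion
parameters are simulated per session.

## Physiology (`physio`)

PPG beats are detected by local-maximum peak picking with refractory and
amplitude constraints; implausible inter-beat intervals are rejected as
artifacts. Instantaneous HR is `60 / IBI`; windowed HR averages beats per
sliding window (windows with fewer than a minimum number of beats are
flagged NaN).

## Preprocessing (`preprocess`)

Per session: discard the first 5 volumes, regress out motion and tissue
(WM/CSF) mean confounds via ordinary least squares, band-pass 0.009–0.08 Hz
with a zero-phase FIR filter, optional Gaussian smoothing. Unit tests check
the nuisance step against the explicit projection matrix
`(I − X(X'X)⁻¹X')y` and the filter's pass/stop-band gains.

## Seed-based FC (`seedfc`)

Sphere ROIs in mm space; FC maps are voxelwise Pearson correlations to the
ROI mean time course, Fisher-z transformed. Verified against per-voxel
brute-force loops at 1e-10.

## Group ICA (`gica`)

Temporal-concatenation group ICA: per-subject temporal PCA (30
components over the concatenated 5 sessions), subject-wise concatenation,
group PCA whitening to 20 dimensions, extended infomax ICA (tanh
nonlinearity, kurtosis-sign switching, natural gradient). The learning rate
adapts to the angle between successive updates, and a monotone cap anneals
on plateaus (cap ×0.8 when the best update norm has not improved for 100
iterations) to break limit-cycle orbits near convergence. Components are
matched to network templates by Hungarian assignment on absolute spatial
correlation with sign alignment. Subject/session maps and time courses come
from dual regression (spatial then temporal least squares); inter-network
FC is the Fisher-z correlation matrix of the matched network time courses.

## FC–HR coupling (`coupling`)

Sliding windows of 60 s advanced by 10 s over the retained 150 volumes
(25 windows). Per window, edge FC is the Pearson correlation of the two
network time courses; per subject, the synchronization statistic is the
correlation across windows between the windowed-FC series and the windowed
HR (pairwise NaN deletion, ≥ 3 windows required). Group inference is a
one-sample t-test on per-subject sync values, BH-FDR across edges, or
cluster inference for voxelwise maps.

## Statistics (`stats`)

One-sample and paired t-tests, one-way repeated-measures ANOVA, post-hoc
pairwise tests, covariate regression, Benjamini–Hochberg FDR, and
permutation cluster-FWE inference: cluster-defining threshold on the voxel
statistic, clusters labelled at 6/18/26-connectivity, null distribution of
the maximum cluster size over sign flips, condition swaps, or score
permutations, `p_fwe = (1 + #{null ≥ observed}) / (n_perm + 1)`. All of
these are tested against independent oracles (scipy, statsmodels, explicit
sums of squares, BFS flood fill).

## Validation design and known-marginal assertion

The acceptance tests plant effects with the generator and require recovery
and calibration at stated tolerances (`tests/test_acceptance.py`). One
assertion is marginal by construction: with coupling 0.6 on one edge and 0
on the other 9, FDR at q = 0.05 must flag *only* the designated edge in
≥ 18 of 20 replicate cohorts (n = 29 each). Because the designated edge's
p-value is ≈ 1e-10, the BH step-up threshold for a second discovery is
2q/m = 0.01; with 9 independent uniform null p-values, at least one extra
edge is co-flagged with probability 1 − 0.99⁹ ≈ 8.6 % per cohort. The
per-replicate exact-specificity probability therefore has a hard analytic
ceiling of ≈ 0.914 for any correct implementation, and P(≥ 18 of 20) ≤
0.757. At the fixed a-priori seeds the observed count is 16/20, so this
assertion fails; the extra flags carry no structure (null-edge p-values are
uniform and the co-flagged edges are not concentrated on neighbours of the
designated edge). The test is retained as written — neither the seeds nor
the threshold were adjusted after observing the outcome. The companion
clauses (mean designated-edge sync 0.61 vs injected 0.6; 0 of 20 null
cohorts flag any edge) pass.
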