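# Methods

## Data model

A focus is a peak coordinate in mm in a Talairach-like reference space.
An experiment is the unit of meta-analysis: one contrast of one study,
with a subject count and ≥ 1 focus. Contrasts computed on the same group
of subjects are merged (foci concatenated, duplicates kept) before any
kernel modelling, so each subject group contributes one observation; in
the Sleuth text dialect the group identity is the study id ("Author,
Year"). All voxel-wise work happens on a regular isotropic grid with a
NIfTI affine and a boolean brain mask; mm space is authoritative and
foci are assigned to their nearest voxel centre (half-up rounding).
Out-of-grid foci are dropped with a logged count; in-grid but
out-of-mask foci are kept in the dataset but excluded from density
counts and null construction.

The default analysis grid is 40×48×40 at 4 mm with an inscribed-ellipsoid
brain mask (≈ 40,000 in-mask voxels): large enough for realistic cluster
geometry, small enough that the full Monte-Carlo machinery runs on one
CPU in seconds. A 2 mm grid is available through the same constructor
when finer sampling is wanted; no external template is required.

## Paradigm–ROI association

With N in-brain foci of one paradigm and an ROI covering p = |ROI|/|brain|
of the mask, the in-ROI count k is Binomial(N, p) under the null that the
paradigm's activations are spatially uniform. The reported statistic is
the one-sided normal approximation

    z = (k − Np) / sqrt(Np(1 − p)),

with no continuity correction by default, so k = Np gives exactly z = 0
(a correction is available as an option but shifts the mean of the null z
to ≈ −0.5/sd). Significance uses a configurable threshold defaulting to
z* = 3.3 (a Bonferroni-style family cutoff taken as given rather than
recomputed, since the family size depends on the database taxonomy).
Foci of merged experiments count individually. Note the discreteness of
k: for N = 200 and p ≈ 0.1 the attainable test sizes at z* = 1.645
oscillate between ≈ 0.043 and ≈ 0.067 as p varies, so empirical tail
rates can sit a percentage point away from the nominal level without any
defect in the statistic.

The multi-mask consensus keeps paradigms flagged in ≥ k (default 2) of
the supplied profiles, ordered by the maximum z attained across masks.

## ALE

Kernel: each focus is modelled as an isotropic 3-D Gaussian probability
kernel whose sd combines template and subject uncertainty,

    sd(n) = sqrt(σ_t² + σ_s²/n),  FWHM(n) = sqrt(8 ln 2) · sd(n).

Defaults σ_t = 3.5 mm, σ_s = 8 mm put FWHM between ≈ 9 mm (n = 30) and
≈ 12 mm (n = 5), the range of published ALE kernel models; both are
configuration values, never hard-coded. Kernels are sampled at voxel
centres, truncated below 10⁻⁶ of peak, and normalised to unit mass over
the lattice, so the value at a voxel is the probability that the
experiment's true activation lies there; the per-experiment modelled
activation (MA) map is the voxel-wise maximum over that experiment's
kernels (non-additive: a cluster of reported peaks cannot count more than
once). Because kernels are evaluated from the focus's voxel centre, they
are translation-invariant and cached per (sd, voxel size) — the
quantization this introduces is at most half a voxel, negligible against
kernel widths. Experiments combine by probabilistic union,
ALE = 1 − Π(1 − MA), which stays strictly below 1.

Voxel-wise null: the in-brain MA values of each experiment are
histogrammed at resolution 10⁻⁵ (configurable) and combined pairwise
under the union formula, weighting each bin by its in-brain frequency.
This is the distribution of the ALE value at one voxel when every
experiment's activation is independently relocated uniformly within the
brain, *given* the observed per-experiment MA value histograms. The
Monte-Carlo check used in the tests resamples in-brain voxels of the
observed MA maps — an exact simulation of that model (agreement within
≈ 0.004 at 2000 redraws). Literal redrawing of foci additionally
resamples the histograms themselves; on very small grids the
realization-to-realization fluctuation of a histogram reaches several
percentage points (overlap and mask-edge effects), a modelling
approximation shared by the standard analytic ALE null rather than an
implementation property.

Cluster-level FWE: the cluster-forming threshold is the smallest ALE
value with null exceedance ≤ cfp (default 0.001); supra-threshold voxels
(ties included) form 6-connected components. The null of the maximum
cluster size is built from n_perm datasets in which every experiment's
foci are redrawn uniformly in-brain (same focus and subject counts); the
size threshold is the smallest integer size whose null exceedance
fraction is ≤ alpha — the attainable-integer version of the ceiling of
the (1 − alpha) quantile, with the correct alpha = 1 limit (every formed
cluster survives). Measured family-wise error over 100 null analyses:
≈ 0.05–0.08 at alpha = 0.05.

Fail-safe: round(proportion · n_experiments) noise experiments are
appended, their (n_foci, n_subjects) pairs resampled jointly with
replacement from the observed experiments and their foci uniform
in-brain; the analysis is re-run and an original cluster counts as
retained when its peak voxel (or a face neighbour) lies inside the
augmented surviving clusters. With proportion 0, the call reduces
exactly to the plain analysis under the same seed.

## Decomposition

The thresholded ALE maps (ALE value inside surviving clusters, 0
elsewhere) are vectorized over the brain mask into a maps × voxels
matrix. Dissimilarity is d = 1 − Pearson r. The embedding is metric MDS
by stress majorization (SMACOF) with tolerance 10⁻⁹ and up to 3000
iterations, initialised from the classical (Torgerson) coordinates of
the distance matrix — a deterministic initialisation whose first two
columns at dims = 3 equal the dims = 2 initialisation, which is why the
standardized stress S(3D) ≤ S(2D) ordering holds in practice (verified
over random instances). Goodness of fit is Kruskal's standardized
stress with raw dissimilarities in the denominator,
S = sqrt(Σ(D − d̂)² / ΣD²).

PCA treats maps as variables and voxels as observations: each map is
mean-centred over voxels, with no variance scaling (the maps share one
statistic scale); loadings are map coefficients, scores are voxel
projections rendered back into volumes, and explained-variance ratios
are reported. ICA whitens to k dimensions and maximises non-Gaussianity
of the voxel scores (FastICA, log-cosh contrast, tolerance 10⁻⁶),
deterministic given its seed; non-convergence raises (it is expected on
structureless Gaussian data, where the contrast has no optimum).
Component order and sign are indeterminate, so the aligned decomposition
greedily matches ICs to PCs by |Pearson r| of voxel scores (highest
first, ties to the lower PC index — k ≤ 9 makes greedy equal to optimal
in practice) and flips signs so matched correlations are positive.

Sampling adequacy: Bartlett's sphericity chi-square
−(n − 1 − (2p + 5)/6)·ln det R with p(p−1)/2 df, and the KMO index
Σr²/(Σr² + Σa²) over off-diagonal zero-order (r) and partial (a)
correlations. n is the in-mask voxel count; voxels are spatially
dependent, so the effective n is much smaller and the Bartlett p-value
is anti-conservative — reported with that caveat.

## Atlas and gradient comparison

Positive voxels are those strictly > 0 (maps are compared after
thresholding; gradient volumes on their native signed scale). RSN
proportions are fractions of a map's positive voxels per parcellation
label (label 0 reported as unassigned); Jaccard is intersection over
union. Gradient affinity uses Pearson r over in-mask voxels; the
positive-part test is a Welch (unequal-variance) two-sample t of
gradient values inside versus outside the map's positive support, one
tailed for "inside > outside" — Welch because the two groups differ
enormously in size and spread. Overlap is the percentage of the map's
positive voxels where the gradient is positive, invariant to monotone
rescaling of the map. The axis correlation relates maps' coordinates on
a chosen MDS axis to their per-map gradient correlations, with the
p-value from t = r·sqrt((n−2)/(1−r²)) and a configurable tail. None of
the voxel-wise tests corrects for spatial autocorrelation; their
p-values are descriptive.

## Synthetic data

The generator emulates the structure of a curated foci database.
Experiments per paradigm is a fixed count (default 30); foci per
experiment follow a shifted negative binomial, 1 + NB, with mean 10 and
dispersion 2 — heavy-tailed counts consistent with per-paradigm totals
of roughly ten foci per experiment in published database summaries;
subject counts are a discretised log-normal with median 15 and log-sd
0.4. Signal paradigms draw each focus from a planted centre plus
isotropic Gaussian jitter (default sd 8 mm, resampled into the mask)
with probability 1 − background, otherwise uniformly over mask voxel
centres; background paradigms are entirely uniform. Default planted
centres lie on voxel centres of the default grid inside the ROI
neighbourhood, which keeps recovery distances well defined (a centre
equidistant between voxels has no unique "own voxel") and makes the
designated network-associated paradigms geometrically recoverable.

ROI masks are three equal-volume balls (a configurable fraction of the
brain, default 0.1) at offset centres — three imperfectly agreeing
definitions of one network; the parcellation labels every in-brain voxel
by nearest seed (Voronoi) among K random seeds. Gradient volumes are
mixtures of low-order polynomial basis fields (linear and quadratic in
normalised coordinates), zero-mean over the mask.

What the generator does not emulate: anatomical geometry (the brain is
an ellipsoid, ROIs are balls), spatially varying base rates of
activation, inter-experiment heterogeneity of jitter, correlated noise
between paradigms, or the database's behavioural taxonomy. Passing
recovery tests therefore demonstrates statistical correctness of the
machinery under the stated model, not performance on real data.

## Localisation accuracy of ALE peaks

Under a dense planted signal (≈ 10 foci/experiment, jitter sd 8 mm,
kernel FWHM ≈ 10 mm) the max-over-foci MA saturates near the centre:
nearly every experiment has some focus within a kernel width of every
voxel in the jitter ball, so the union ALE forms a plateau of roughly
the jitter radius and the argmax wanders within it. Measured over 100
replicates at 4 mm voxels, the surviving cluster's peak lands within one
voxel of the planted centre in ≈ 88–93 % of runs and within two voxels
otherwise; detection (some surviving cluster covering the centre) and
fail-safe retention at 6 % injected noise are at or near 100 %. Cluster
membership, not peak position, is the reliable localisation readout at
this signal geometry.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed (generation, FWE
permutations, fail-safe noise, ICA); the pipeline writes all
intermediates plus a manifest and is byte-reproducible given one
configuration. The test suite and the acceptance script size their
simulations for a single CPU: calibration of the density statistic uses
2000 simulated paradigms; the analytic-null check 2000 relocation
redraws on a 12³ grid; FWE calibration 100 (tests) / 40 (script) null
analyses at 200 permutations; recovery 100 / 30 replicates at 100
permutations.
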