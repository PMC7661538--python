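# Methods

`voxbag` compares six ways of reducing voxel-wise radiomics feature maps
over a tumor region of interest (ROI) to a per-patient descriptor, and
measures what each way is worth for overall-survival prediction. This note
documents the models, the defaults and why they were chosen, what the
synthetic cohorts emulate, and the numerical corner cases.

## Image model and preprocessing

Inputs are pairs of co-registered 3D scalar volumes per patient (a CT-like
and a PET-like modality, already in physical units) plus a binary tumor
mask on the same grid. Preprocessing is:

1. trilinear resampling of images (nearest-neighbour for masks) to an
   isotropic grid, 1 mm by default, so texture offsets measured in voxels
   are physical lengths;
2. ROI construction by dilating the tumor mask with a 5 mm Euclidean
   margin (computed on the distance transform in mm, so it is correct for
   anisotropic inputs as well). The margin gives border windows context;
   all per-voxel features are computed at every ROI voxel;
3. gray-level quantization to Λ = 64 equal-width bins over the intensity
   range observed *inside the dilated ROI* (level = min(Λ, ⌊Λ(v−min)/(max−min)⌋+1);
   voxels outside the ROI carry a sentinel and never enter any count). A
   constant ROI degenerates to level 1 with a warning. Fixed absolute
   bounds per modality are available (`FeatureConfig.intensity_bounds`)
   for analyses that need bins comparable across patients; the
   mean-matched-pair demonstration uses them (below).

Quantization bounds come from the dilated ROI rather than the tumor alone
because that is the region the features are computed on; per-window
binning would make window features incomparable across the ROI.

## Feature maps (21 per modality)

*Filters.* Laplacian of Gaussian (σ = 2 mm, kernel truncated to a 4 mm
ball and DC-corrected to sum exactly to zero), a slice-wise 2D Gabor bank
(σ = 11/3, frequency 0.4 cycles/mm, 4 mm support, four in-plane
orientations whose rectified responses are averaged), and a 3×3×3 Sobel
gradient magnitude. Zero-mean kernels are rectified with the absolute
value, so filter maps are non-negative. Convolution uses mirror padding.
The Gabor operator has no canonical 3D form at these parameters; the
slice-wise orientation-averaged variant is the common volumetric practice
and is recorded here as a modelling choice.

*Sliding-window gray-level matrices.* At every ROI voxel a 5×5×5 window is
scanned. Co-occurrences are counted for 26 offsets (the 13 unique 3D
lattice directions up to sign × displacements of 1 and 2 voxels), with
both endpoints required inside window ∩ volume ∩ ROI, accumulated
symmetrically into a single 64×64 matrix per window ("merged" offset
aggregation; per-offset averaging is available but merging maximizes
counts in a 125-voxel window and keeps the matrix well populated). Eight
Haralick-type statistics are computed: energy, inverse difference moment,
entropy (bits, 0·log 0 ≡ 0), Haralick correlation, cluster shade, cluster
prominence, inertia, correlation. Correlation-type features are defined as
0 when the marginal variance vanishes; a window with no valid pair falls
back to the point-mass conventions (energy = IDM = 1, the rest 0) and is
counted as degenerate. For a symmetric direction-merged matrix the
Haralick-correlation and correlation formulas coincide analytically; both
columns are kept because the catalogue treats them as distinct features,
and the penalized survival models are unaffected by the collinearity.

Run-length matrices count maximal runs of equal level along the 13
directions within the same window (runs are broken by the window border,
the volume border, or an out-of-ROI voxel, and truncated runs count with
their in-window length, so the matrix has exactly five length columns).
The ten standard run-length statistics are computed; a window with no run
yields all zeros and a degeneracy flag.

The windowed path is compiled (numba); the package also exposes pure
single-window reference operations (`glcm_window`, `glrlm_window`,
`glcm_features`, `glrlm_features`) that define the semantics, and the test
suite checks the compiled path against naive per-voxel enumeration
exactly.

A patient's *feature stack* is the |ROI| × 42 matrix of all feature maps
(21 per modality) sampled at ROI voxels in raster order. An optional
seeded, order-preserving voxel subsample caps the stack size; the phantom
studies below use 1 500 voxels/patient so a 120-patient study runs in
minutes on one CPU, with the subsample seed derived per patient from the
master seed.

## Aggregation strategies

- **classical** — no sliding windows: ROI mean of each rectified filter
  map, plus one co-occurrence / run-length matrix accumulated over the
  whole ROI before the 8 + 10 scalars are computed (42 values).
- **mean**, **var**, **mean_var** — per-column mean and/or population
  variance of the windowed feature maps over the ROI (42/42/84 values).
- **volume** — the ROI voxel count (1 value).
- **bovw** — bag of visual words. Training-fold stacks are pooled (seeded
  per-patient subsample, ≤ 2 000 voxels each), columns standardized (the
  scaler is stored in the dictionary and reused at encode time; nothing is
  learned from validation folds), and a Gaussian mixture with k components
  fit by EM. Diagonal covariances are the default for stability in 42
  dimensions; full covariance, soft assignment, number of EM
  re-initializations and the initialization scheme are configurable. Each
  voxel is hard-assigned to its maximum-posterior component and the k-bin
  count histogram is normalized to relative frequencies, so descriptors
  are comparable across tumors of different size (raw counts would
  re-encode volume, which is deliberately a separate model). Refitting
  with the same seed and data reproduces the dictionary to ~1e-8.

The number of words is chosen with Tibshirani's gap statistic:
Gap(k) = E[log W*] − log W with W the within-cluster sum of squared
distances to centroids and the reference datasets drawn uniformly over the
per-column bounding box of the standardized pooled stack (B = 20 draws by
default); the smallest k passing the standard-error rule is selected
(grid argmax is available).

## Survival validation

The cohort is split `n_splits` = 5 times into training and validation
parts with a stratified shuffle on the event indicator. Per split and per
strategy: z-scoring is fit on the training part only (zero-variance
columns pass through as zeros); the bag-of-visual-words dictionary is
refit on the training part only; an L1-penalized Cox model (scikit-
survival's Coxnet path) predicts the hazard score HS = xᵀβ. The penalty is
the path value maximizing the held-out Breslow partial likelihood summed
over 5 inner stratified folds of the training part; an all-zero
coefficient vector is a valid (constant-score) model and is flagged. On
each validation part, 1 000 bootstrap resamples are drawn with
replacement, every model is evaluated on the *same* resamples (paired
comparison), and Harrell's C-index is computed per resample: over all
comparable pairs (strictly ordered times, shorter-time patient an event),
the fraction where the shorter-time patient has the higher score, ties
counting ½ — Harrell's original convention; equal event times are
incomparable. Resamples with no comparable pair are redrawn (counted,
capped). 5 × 1 000 = 5 000 estimates per model are summarized by their
mean and percentile (2.5, 97.5) interval, and pairwise differences by the
paired bootstrap difference distribution (mean, percentile CI, two-sided
tail fraction as a p-value).

Kaplan–Meier stratification splits validation patients at the median
hazard score (ties to the low-risk group, so groups have ⌈n/2⌉ and ⌊n/2⌋
members), fits per-group Kaplan–Meier curves, and reports the two-sample
log-rank test.

## Synthetic cohorts

The phantom module generates the study conditions every test runs under:
48³ volumes at 1 mm, a lumpy spherical tumor (radius 6–9 mm) on a
textured background, two modalities sharing a correlated Gaussian texture
field (correlation length 1.5 mm; CT-like: base 40, amplitude 8, noise 2;
PET-like: base 5, amplitude 0.8, noise 0.2; background at 0 ± 10 and
1 ± 0.5 respectively).

*Composition model.* Every tumor is split 50/50 into hyper- and
hypo-intense tissue in each modality separately (CT offsets ± 20 HU, PET
± 2 SUV, transitions smoothed with a 1 mm Gaussian so compartment edges do
not dominate the filter responses). The per-patient heterogeneity fraction
f is the *discordant* volume fraction — the part of the tumor where the
PET deviation opposes the CT deviation (class B; the concordant remainder
is class A). Construction is exact: the tumor is halved along a random
direction for CT, and the discordant region takes the top f-cap of each
CT half along an orthogonal direction, which keeps both modality marginals
exactly 50/50 for every f. Consequences that the validation tests rely
on:

- every single-modality feature distribution is identical across
  compositions, so mean, variance and classical (whole-ROI) descriptors
  are blind to f *by construction*, not by noise;
- the joint two-modality voxel distribution shifts mass between the four
  (CT, PET) hot/cold combinations in direct proportion to f, which is
  precisely what a visual-word histogram over the 42-dimensional feature
  space reads off.

*Survival.* Times are exponential with log-hazard = β_h·f + β_v·(volume /
volume of the largest radius), β_h = 5.0, β_v = 0.4, baseline median 30
months; censoring is administrative-uniform with the horizon solved in
closed form so the expected censoring fraction matches the 20% target.
The effect sizes were fixed by a power argument: percentile CIs of paired
bootstrap C-index differences on ~36-patient validation parts only
exclude zero for true C-index gaps around 0.2, which requires the
histogram model to operate near its PH ceiling (C ≈ 0.78 for the true
log-hazard at β_h = 5) while composition-blind models sit near chance
plus the small volume effect.

*Phantom study protocol.* `run_phantom_study` uses 70/30 stratified
splits (36-patient validation parts at n = 120); 80/20 validation parts
of 24 patients make bootstrap C-index distributions too wide for any
model comparison at this cohort size. `run_validation` itself defaults to
the conventional 80/20. The study dictionary uses 32 words (k-means++
initialization, two EM restarts, ≤ 600 pooled voxels per training
patient): with a 5 mm context margin roughly three quarters of ROI voxels
are background, and the dictionary needs enough components to cover the
background structure *and* the four joint tumor states — at 16 words the
tumor typically receives too few components and most of the composition
signal is lost, while 24–32 words recover it fully.

*The mean-matched pair.* A controlled two-patient construction for the
information-loss demonstration: two exactly mirror-symmetric disjoint
tumor lobes (far enough apart that no 5×5×5 window spans both), shared
texture-field and noise realizations, and quantization with fixed bounds
whose bin widths divide the compartment offsets exactly (± 9 HU = 3 bins
of 3 HU; ± 0.9 SUV = 3 bins of 0.3 SUV; texture amplitude 4 HU / 0.4 SUV).
Patient 1 is homogeneous at the base intensity; patient 2 has one lobe at
+offset and one at −offset. Zero-mean filters are exactly offset-blind,
and a uniform gray-level shift leaves all eight co-occurrence statistics
exactly invariant, so the two patients agree in every mean-aggregated
descriptor up to (i) the O((s/λ)²) convexity of the level-weighted
run-length features and (ii) sampling effects — measured well under the
2% contract. The demonstration runs at margin 0 mm (tumor-only stacks):
with a 5 mm context ring ~75% of the ROI is background, which would both
dominate a two-patient dictionary and cap any histogram difference at
~0.35. A three-word dictionary (full covariance, k-means++ with 10
restarts) resolves the low/mid/high structure; the homogeneous patient
concentrates on the middle word and the mixed patient on the outer two.
A two-word dictionary cannot show the effect on an *exactly* mean-matched
pair: the homogeneous patient's voxels sit at the midpoint of the two
compartment clusters, so every two-component split is symmetric with
respect to both patients and their histograms coincide.

What the phantoms do *not* emulate: scanner-specific noise physics,
partial-volume effects, inter-center calibration differences, realistic
anatomy, or registration error. Passing tests therefore show that the
pipeline and the aggregation comparison behave as designed under the
stated statistical structure, not that any particular clinical effect
size is reproduced.

## Numerical choices and degenerate inputs

- Offsets are stored one per ± pair; symmetry is realized by accumulating
  each pair in both orders, so matrices are exactly symmetric.
- The LoG kernel is DC-corrected on its truncated support (|Σk| < 1e-6·‖k‖₁
  holds by construction); Gabor kernels are likewise mean-corrected.
- C-index: ties in score count ½; equal times are incomparable; zero
  comparable pairs raise an error (bootstrap resamples are redrawn
  instead).
- EM non-convergence triggers re-initialization with fresh seeds (3
  attempts by default, 500 iterations each) before erroring.
- All randomness flows from explicit seeds through `numpy.random.
  SeedSequence` spawns (per-patient subsampling, dictionary fitting,
  splits, bootstraps), so every result in the test suite and the
  acceptance script is bit-reproducible for a given seed.

## Known limitations

- The Gabor operator is slice-wise 2D; a true 3D Gabor with orientation
  sampling over the sphere would differ.
- Held-out-partial-likelihood penalty selection is conservative on weak
  signals (it happily selects the null model when no feature carries
  reliable signal — visible as C ≈ 0.5 for composition-blind strategies on
  phantoms).
- The gap statistic uses the simplest uniform-box reference; PCA-aligned
  references would be more conservative for elongated clouds.
- Phantom effect sizes are set for statistical power at n = 120 and are
  larger than typical clinical effects; the comparison is qualitative
  (ordering), not a quantitative reproduction of any cohort.
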