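# voxbag

Voxel-level radiomics feature maps, feature aggregation — including
bag-of-visual-words (BoVW) encoding — and survival-analysis validation for
3D tumor regions of interest in co-registered two-modality imaging
(CT-like and PET-like volumes).

## The problem

Standard radiomics reduces each feature of a tumor ROI **M** to one number,
usually by averaging a voxel-wise response map h[k] over the ROI:
η = (1/|M|) Σ_{k∈M} h[k]. When the tumor is heterogeneous — composed of
distinct tissue sub-regions — the average lands *between* the sub-region
signatures and describes none of them; downstream survival models then see
a washed-out descriptor. This package implements and compares six
aggregation strategies over the same per-voxel feature maps:

| strategy    | descriptor η                                                | dim |
|-------------|-------------------------------------------------------------|-----|
| `classical` | whole-ROI filter means + whole-ROI GLCM/GLRLM scalars       | 42  |
| `mean`      | ROI mean of each windowed feature map                       | 42  |
| `var`       | ROI variance of each windowed feature map                   | 42  |
| `mean_var`  | both                                                        | 84  |
| `volume`    | ROI voxel count                                             | 1   |
| `bovw`      | visual-word histogram over the voxel feature space          | k   |

The per-voxel feature space has 42 dimensions: for each modality, 3
convolutional filters (Laplacian of Gaussian σ=2 mm, a slice-wise Gabor
bank σ=11/3 / f=0.4, 3×3×3 Sobel magnitude) and 18 sliding-window
gray-level statistics (8 Haralick features from a 5×5×5-window
co-occurrence matrix over 26 offsets — 13 unique 3D directions ×
displacements {1, 2} mm at 64 gray levels — and 10 run-length features
over the 13 directions). The BoVW dictionary is a Gaussian mixture fit on
pooled training-fold voxels; each voxel is hard-assigned to its
maximum-posterior word c_i and the normalized word histogram is the
patient descriptor, preserving piece-wise homogeneous sub-regions that
averaging destroys. The number of words is selected with the gap
statistic.

Validation follows a survival protocol: per stratified train/validation
split, z-scoring, dictionary fitting and an L1-penalized Cox model (hazard
score HS = xᵀβ, penalty by inner cross-validated partial likelihood) are
learned on the training part only; Harrell's C-index is computed on 1 000
bootstrap resamples of the validation part, with all strategies evaluated
on the same resamples (paired comparison), plus Kaplan–Meier curves from a
median-HS split with a log-rank test.

Because real multi-center cohorts cannot ship with a package, `voxbag`
includes a first-class synthetic-cohort generator: 3D two-modality texture
phantoms whose tumors have a controlled heterogeneous composition and
whose survival times follow a proportional-hazards model driven by that
composition and by tumor volume. The phantom is constructed so that every
*single-modality* feature distribution is independent of composition —
mean/variance/classical aggregation is blind to it by construction — while
the joint two-modality voxel distribution carries it, which is exactly
what the visual-word histogram reads off. See `docs/methods.md` for the
full design.

## Worked example

Generate a small cohort, extract features, and run the six-model
validation from the shell:

```bash
voxbag phantom --out cohort --n-patients 60 --grid-size 48 --seed 7
cat > config.yaml <<EOF
cohort_dir: cohort
output_dir: out
num_levels: 32
max_voxels: 1500
bovw_words: 32
n_splits: 5
test_fraction: 0.3
n_boot: 200
seed: 7
EOF
voxbag extract --config config.yaml
voxbag validate --config config.yaml
```

or equivalently in Python, at study scale:

```python
from voxbag import PhantomSpec, PipelineConfig, FeatureConfig, run_phantom_study

cfg = PipelineConfig(features=FeatureConfig(num_levels=32, max_voxels=1500))
patients, tables, result = run_phantom_study(PhantomSpec(n_patients=120), cfg, seed=1)
print(result.summary().round(3))
print(result.compare("bovw", "volume"))
```

which prints (seed 1):

```
           mean_c_index  ci_low  ci_high  n_estimates
model
classical         0.474   0.314    0.559         5000
mean              0.452   0.287    0.561         5000
var               0.476   0.324    0.614         5000
mean_var          0.452   0.291    0.615         5000
volume            0.521   0.375    0.675         5000
bovw              0.782   0.673    0.874         5000
{'mean_diff': 0.2609447678153825, 'ci_low': 0.07046705324196098, 'ci_high': 0.43381991382737867, 'p_value': 0.008}
```

Reading: each row is one aggregation strategy's mean Harrell's C-index
over 5 stratified 70/30 splits × 1 000 paired bootstrap resamples of the
validation patients (percentile 95% interval alongside). On this phantom
cohort the hazard depends on tumor composition, which is invisible to
every per-feature aggregate (the first four rows sit at chance) and only
weakly related to volume; the visual-word histogram recovers it, and the
paired bootstrap difference against the volume model excludes zero. This
is the qualitative signature the method predicts for heterogeneous
tumors: histogram aggregation > volume > first-order aggregation.

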