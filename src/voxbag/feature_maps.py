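"""Voxel-wise feature maps: convolutional filters and sliding-window
gray-level texture matrices.

Per modality, 21 feature maps are computed:

- 3 filter responses — Laplacian of Gaussian (sigma 2 mm, support radius
  4 mm), a slice-wise Gabor bank (sigma 11/3, frequency 0.4 cycles/mm,
  support radius 4 mm, 4 in-plane orientations averaged) and a 3x3x3 Sobel
  gradient magnitude. Zero-mean kernels are rectified with the absolute
  value, so filter maps are non-negative.
- 8 GLCM (Haralick) statistics from a 5x5x5 sliding-window co-occurrence
  matrix accumulated symmetrically over 26 offsets (13 unique 3D directions
  x displacements of 1 and 2 voxels on the 1 mm grid).
- 10 GLRLM statistics from the same window, with maximal runs counted along
  the 13 directions and truncated at the window border.

All 26/13 offset matrices are merged into a single matrix per window before
scalars are computed (direction-merged aggregation); per-offset averaging is
available via ``offset_aggregation="average"`` on the public single-window
operations but the merged scheme is the default everywhere.

For a two-modality study the per-voxel feature matrix therefore has
F = 2 x 21 = 42 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _texture
from .image_core import QuantizedImage, RoiMask, VolumetricImage, quantize

__all__ = [
    "DIRECTIONS_13",
    "OffsetSet",
    "make_offsets",
    "FilterBank",
    "FeatureMap",
    "FeatureStack",
    "FeatureConfig",
    "apply_filter",
    "glcm_window",
    "glcm_features",
    "glrlm_window",
    "glrlm_features",
    "compute_feature_stack",
    "FILTER_NAMES",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "FEATURE_NAMES",
]

# The 13 unique 3D lattice directions up to sign (one representative per
# +/- pair): 3 axis, 6 face-diagonal, 4 space-diagonal.
DIRECTIONS_13 = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)

FILTER_NAMES = ("log", "gabor", "sobel")
GLCM_FEATURE_NAMES = (
    "glcm_energy",
    "glcm_inverse_difference_moment",
    "glcm_entropy",
    "glcm_haralick_correlation",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_inertia",
    "glcm_correlation",
)
GLRLM_FEATURE_NAMES = (
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_grey_level_nonuniformity",
    "glrlm_run_length_nonuniformity",
    "glrlm_low_grey_level_run_emphasis",
    "glrlm_high_grey_level_run_emphasis",
    "glrlm_short_run_low_grey_level_emphasis",
    "glrlm_short_run_high_grey_level_emphasis",
    "glrlm_long_run_low_grey_level_emphasis",
    "glrlm_long_run_high_grey_level_emphasis",
)
FEATURE_NAMES = FILTER_NAMES + GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES


@dataclass(frozen=True)
class OffsetSet:
    """Direction vectors and voxel displacements used for GLCM/GLRLM.

    ``offsets`` scales each of the 13 canonical directions by every
    displacement; symmetric (+/-) counting is handled by the accumulation
    step, so only one representative per sign pair is stored.
    """

    directions: np.ndarray  # (13, 3) int
    displacements: tuple[int, ...]

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate(
            [self.directions * d for d in self.displacements], axis=0
        )

    def __len__(self) -> int:
        return len(self.directions) * len(self.displacements)


def make_offsets(displacements_mm=(1, 2)) -> OffsetSet:
    """13 canonical directions x displacement lengths (voxels on a 1 mm grid)."""
    disp = tuple(sorted(int(d) for d in set(displacements_mm)))
    if not disp:
        raise ValueError("displacement set must be non-empty")
    if any(d < 1 for d in disp):
        raise ValueError("displacements must be positive integers")
    return OffsetSet(directions=DIRECTIONS_13.copy(), displacements=disp)


# ---------------------------------------------------------------------------
# Convolutional filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterBank:
    """Parameters of the three convolutional operators.

    LoG: isotropic 3D Laplacian of Gaussian, sigma in mm, kernel truncated to
    a ball of ``log_radius_mm`` and DC-corrected so it sums to zero exactly.
    Gabor: 2D kernels applied slice-wise in the axial plane at
    ``gabor_orientations`` evenly spaced in-plane angles; per-voxel response
    is the mean rectified response over orientations.
    Sobel: three orthogonal 3x3x3 kernels combined as gradient magnitude.
    """

    log_sigma_mm: float = 2.0
    log_radius_mm: float = 4.0
    gabor_sigma: float = 11.0 / 3.0
    gabor_freq: float = 0.4
    gabor_radius_mm: float = 4.0
    gabor_orientations: int = 4


@lru_cache(maxsize=8)
def _log_kernel(sigma: float, radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1, dtype=np.float64)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = x * x + y * y + z * z
    support = r2 <= radius * radius + 1e-9
    k = (r2 - 3.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2.0 * sigma**2))
    k[~support] = 0.0
    # Enforce a zero-sum (DC-free) kernel on the truncated support.
    k[support] -= k[support].mean()
    return k


@lru_cache(maxsize=8)
def _gabor_kernels(
    sigma: float, freq: float, radius: float, n_orient: int
) -> tuple[np.ndarray, ...]:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1, dtype=np.float64)
    x, y = np.meshgrid(ax, ax, indexing="ij")
    r2 = x * x + y * y
    support = r2 <= radius * radius + 1e-9
    env = np.exp(-r2 / (2.0 * sigma**2))
    kernels = []
    for i in range(n_orient):
        theta = np.pi * i / n_orient
        carrier = np.cos(2.0 * np.pi * freq * (x * np.cos(theta) + y * np.sin(theta)))
        k = env * carrier
        k[~support] = 0.0
        k[support] -= k[support].mean()
        kernels.append(k)
    return tuple(kernels)


def _sobel_magnitude(values: np.ndarray) -> np.ndarray:
    g2 = np.zeros_like(values)
    for axis in range(3):
        d = ndimage.sobel(values, axis=axis, mode="mirror")
        g2 += d * d
    return np.sqrt(g2)


@dataclass
class FeatureMap:
    """A voxel-wise feature response map over the full grid."""

    values: np.ndarray
    name: str
    modality: str
    valid_mask: np.ndarray | None = None


def apply_filter(
    img: VolumetricImage, filter_name: str, bank: FilterBank = FilterBank()
) -> FeatureMap:
    """Convolve with one of the three filters and rectify (absolute value)."""
    if not img.is_isotropic:
        raise ValueError("filters require an isotropically resampled image")
    name = filter_name.lower()
    if name == "log":
        k = _log_kernel(bank.log_sigma_mm, bank.log_radius_mm)
        resp = np.abs(ndimage.convolve(img.values, k, mode="mirror"))
    elif name == "gabor":
        kernels = _gabor_kernels(
            bank.gabor_sigma, bank.gabor_freq, bank.gabor_radius_mm,
            bank.gabor_orientations,
        )
        resp = np.zeros_like(img.values)
        for k2 in kernels:
            resp += np.abs(ndimage.convolve(img.values, k2[:, :, None], mode="mirror"))
        resp /= len(kernels)
    elif name == "sobel":
        resp = _sobel_magnitude(img.values)
    else:
        raise ValueError(f"unknown filter {filter_name!r}; expected one of {FILTER_NAMES}")
    return FeatureMap(values=resp, name=name, modality=img.modality)


# ---------------------------------------------------------------------------
# Single-window gray-level matrices (reference semantics)
# ---------------------------------------------------------------------------


def _window_bounds(shape, center, window):
    half = window // 2
    return tuple(
        (max(0, c - half), min(n, c + half + 1)) for c, n in zip(center, shape)
    )


def glcm_window(
    q: QuantizedImage,
    center: tuple[int, int, int],
    offsets: OffsetSet,
    window: int = 5,
    offset_aggregation: str = "merged",
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix for one sliding window.

    Pairs (k, k+offset) require both endpoints inside window, volume and ROI
    (level > 0); each pair is counted in both orders, so the matrix is
    symmetric. With ``offset_aggregation="merged"`` (default) all offsets
    accumulate into one matrix; ``"average"`` returns the mean of per-offset
    normalized matrices. Returns a zero matrix if the window has no valid
    pair.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    shape = q.values.shape
    if not all(0 <= c < n for c, n in zip(center, shape)):
        raise ValueError(f"center {center} outside image {shape}")
    L = q.num_levels
    bounds = _window_bounds(shape, center, window)
    (l0, h0), (l1, h1), (l2, h2) = bounds
    sub = q.values[l0:h0, l1:h1, l2:h2]
    per_offset = []
    merged = np.zeros((L, L))
    for off in offsets.offsets:
        C = np.zeros((L, L))
        # shifted views of the window along the offset: dst = src + off
        src = [slice(max(0, -o), sub.shape[i] - max(0, o)) for i, o in enumerate(off)]
        dst = [slice(max(0, o), sub.shape[i] - max(0, -o)) for i, o in enumerate(off)]
        la = sub[tuple(src)].ravel()
        lb = sub[tuple(dst)].ravel()
        ok = (la > 0) & (lb > 0)
        if ok.any():
            np.add.at(C, (la[ok] - 1, lb[ok] - 1), 1.0)
            np.add.at(C, (lb[ok] - 1, la[ok] - 1), 1.0)
        merged += C
        per_offset.append(C)
    if offset_aggregation == "merged":
        total = merged.sum()
        return merged / total if total > 0 else merged
    if offset_aggregation == "average":
        mats = [c / c.sum() for c in per_offset if c.sum() > 0]
        return np.mean(mats, axis=0) if mats else merged
    raise ValueError(f"unknown offset_aggregation {offset_aggregation!r}")


def glcm_features(C: np.ndarray) -> dict[str, float]:
    """The 8 Haralick-type statistics of a normalized symmetric GLCM.

    Entropy is in bits; 0*log 0 is 0; correlation-type features are 0 when
    the marginal variance vanishes. A zero matrix (degenerate window) maps to
    the point-mass conventions energy = IDM = 1, all others 0.
    """
    C = np.asarray(C, dtype=np.float64)
    L = C.shape[0]
    total = C.sum()
    if total <= 0:
        return dict(zip(GLCM_FEATURE_NAMES, (1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)))
    P = C / total
    i = np.arange(1, L + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_i = P.sum(axis=1)
    mu = float(np.dot(i, p_i))
    var = float(np.dot((i - mu) ** 2, p_i))
    nz = P > 0
    energy = float(np.sum(P * P))
    idm = float(np.sum(P / (1.0 + (ii - jj) ** 2)))
    entropy = float(-np.sum(P[nz] * np.log2(P[nz])))
    inertia = float(np.sum((ii - jj) ** 2 * P))
    t = (ii - mu) + (jj - mu)
    shade = float(np.sum(t**3 * P))
    prom = float(np.sum(t**4 * P))
    if var > 1e-12:
        hcorr = float((np.sum(ii * jj * P) - mu * mu) / var)
        corr = float(np.sum((ii - mu) * (jj - mu) * P) / var)
    else:
        hcorr = corr = 0.0
    return dict(
        zip(
            GLCM_FEATURE_NAMES,
            (energy, idm, entropy, hcorr, shade, prom, inertia, corr),
        )
    )


def glrlm_window(
    q: QuantizedImage,
    center: tuple[int, int, int],
    directions: np.ndarray | None = None,
    window: int = 5,
) -> np.ndarray:
    """Run-length count matrix (levels x window lengths) for one window.

    Maximal runs of identical level along each of the 13 directions; a run
    is broken by the window border, the volume border or a sentinel (out of
    ROI) voxel, and truncated runs count with their in-window length.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if directions is None:
        directions = DIRECTIONS_13
    shape = q.values.shape
    if not all(0 <= c < n for c, n in zip(center, shape)):
        raise ValueError(f"center {center} outside image {shape}")
    bounds = _window_bounds(shape, center, window)
    R = np.zeros((q.num_levels, window))
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]

    def inside(p):
        return all(lo[i] <= p[i] < hi[i] for i in range(3))

    for v in np.asarray(directions, dtype=int):
        for s0 in range(lo[0], hi[0]):
            for s1 in range(lo[1], hi[1]):
                for s2 in range(lo[2], hi[2]):
                    lv = q.values[s0, s1, s2]
                    if lv == 0:
                        continue
                    prev = (s0 - v[0], s1 - v[1], s2 - v[2])
                    if inside(prev) and q.values[prev] == lv:
                        continue
                    ln = 1
                    cur = (s0 + v[0], s1 + v[1], s2 + v[2])
                    while inside(cur) and q.values[cur] == lv:
                        ln += 1
                        cur = (cur[0] + v[0], cur[1] + v[1], cur[2] + v[2])
                    R[lv - 1, min(ln, window) - 1] += 1
    return R


def glrlm_features(R: np.ndarray) -> dict[str, float]:
    """The 10 run-length statistics of a run count matrix (levels x lengths)."""
    R = np.asarray(R, dtype=np.float64)
    nr = R.sum()
    if nr <= 0:
        return dict(zip(GLRLM_FEATURE_NAMES, (0.0,) * 10))
    L, W = R.shape
    lvl = np.arange(1, L + 1, dtype=np.float64)[:, None]
    ln = np.arange(1, W + 1, dtype=np.float64)[None, :]
    row = R.sum(axis=1)
    col = R.sum(axis=0)
    vals = (
        float(np.sum(R / ln**2) / nr),
        float(np.sum(R * ln**2) / nr),
        float(np.sum(row**2) / nr),
        float(np.sum(col**2) / nr),
        float(np.sum(R / lvl**2) / nr),
        float(np.sum(R * lvl**2) / nr),
        float(np.sum(R / (lvl**2 * ln**2)) / nr),
        float(np.sum(R * lvl**2 / ln**2) / nr),
        float(np.sum(R * ln**2 / lvl**2) / nr),
        float(np.sum(R * ln**2 * lvl**2) / nr),
    )
    return dict(zip(GLRLM_FEATURE_NAMES, vals))


# ---------------------------------------------------------------------------
# Per-patient feature stack
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings shared across patients."""

    window_size: int = 5
    num_levels: int = 64
    displacements_mm: tuple[int, ...] = (1, 2)
    bank: FilterBank = field(default_factory=FilterBank)
    offset_aggregation: str = "merged"
    #: optional fixed quantization bounds per modality, e.g.
    #: (("CT", (-100.0, 200.0)), ("PET", (0.0, 20.0))); None = per-patient
    #: bounds from the ROI intensity range.
    intensity_bounds: tuple[tuple[str, tuple[float, float]], ...] | None = None
    #: optional cap on ROI voxels per stack (seeded raster-preserving subsample);
    #: None computes the windowed features at every ROI voxel.
    max_voxels: int | None = None
    subsample_seed: int = 0

    def bounds_for(self, modality: str) -> tuple[float, float] | None:
        if self.intensity_bounds is None:
            return None
        return dict(self.intensity_bounds).get(modality)


@dataclass
class FeatureStack:
    """Per-voxel feature matrix for one patient (|M| rows x F columns)."""

    matrix: np.ndarray
    voxel_index: np.ndarray  # (N, 3) voxel coordinates, raster order
    feature_names: list[str]
    patient_id: str = ""
    n_degenerate_windows: int = 0

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        for a, name in enumerate("xyz"):
            df.insert(a, f"voxel_{name}", self.voxel_index[:, a])
        return df


def roi_voxel_indices(roi: RoiMask, config: FeatureConfig) -> np.ndarray:
    """Deterministic raster-scan coordinates of ROI voxels, optionally
    subsampled (seeded, order-preserving)."""
    idx = np.argwhere(roi.values)
    if config.max_voxels is not None and idx.shape[0] > config.max_voxels:
        rng = np.random.default_rng(config.subsample_seed)
        keep = np.sort(
            rng.choice(idx.shape[0], size=config.max_voxels, replace=False)
        )
        idx = idx[keep]
    return np.ascontiguousarray(idx, dtype=np.int64)


def compute_feature_stack(
    images: list[VolumetricImage],
    roi: RoiMask,
    config: FeatureConfig = FeatureConfig(),
    patient_id: str = "",
) -> FeatureStack:
    """Assemble the per-voxel feature matrix over the ROI.

    For each modality: 3 filter responses sampled at ROI voxels, then the
    windowed GLCM (8) and GLRLM (10) statistics from the compiled sliding
    window path. Rows follow a deterministic raster scan of the ROI; columns
    are modality-qualified feature names.
    """
    if not images:
        raise ValueError("at least one modality image is required")
    if roi.voxel_count == 0:
        raise ValueError("ROI is empty")
    for img in images:
        roi.check_companion(img)
        if not img.is_isotropic:
            raise ValueError("images must be resampled to an isotropic grid first")
    idx = roi_voxel_indices(roi, config)
    offsets = make_offsets(config.displacements_mm)
    cols: list[np.ndarray] = []
    names: list[str] = []
    n_degenerate = 0
    for img in images:
        for fname in FILTER_NAMES:
            fmap = apply_filter(img, fname, config.bank)
            cols.append(fmap.values[idx[:, 0], idx[:, 1], idx[:, 2]])
            names.append(f"{img.modality}:{fname}")
        q = quantize(img, roi, config.num_levels, config.bounds_for(img.modality))
        feats, ndeg = _texture.texture_feature_maps(
            q.values.astype(np.int64),
            idx,
            np.ascontiguousarray(offsets.offsets, dtype=np.int64),
            np.ascontiguousarray(offsets.directions, dtype=np.int64),
            config.num_levels,
            config.window_size,
        )
        n_degenerate += int(ndeg)
        for m, fname in enumerate(GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES):
            cols.append(feats[:, m])
            names.append(f"{img.modality}:{fname}")
    matrix = np.column_stack(cols)
    if not np.all(np.isfinite(matrix)):
        raise FloatingPointError("feature stack contains non-finite values")
    return FeatureStack(
        matrix=matrix,
        voxel_index=idx,
        feature_names=names,
        patient_id=patient_id,
        n_degenerate_windows=n_degenerate,
    )
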