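"""Aggregation of voxel-wise feature maps into per-patient descriptors.

Six competing strategies reduce a tumor's feature maps to the scalar
collection used by the survival models:

- ``classical``  — whole-ROI aggregation: ROI average of each rectified
  filter map, plus one co-occurrence / run-length matrix accumulated over
  the entire ROI before the 8+10 scalars are computed (no sliding windows).
- ``mean`` / ``var`` / ``mean_var`` — first-order moments of the windowed
  feature maps over the ROI.
- ``volume`` — the ROI voxel count alone.
- ``bovw`` — a bag-of-visual-words histogram: voxels are standardized with a
  scaler learned on training patients, hard-assigned to the component of
  maximal posterior probability under a Gaussian-mixture visual dictionary,
  and the per-word counts are normalized to relative frequencies.

The dictionary (``BagOfVisualWords``) follows the scikit-learn estimator
protocol (fit on a list of training-fold stacks, transform any stack into a
k-dimensional histogram) and doubles as the serializable visual dictionary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from . import _texture
from .feature_maps import (
    FILTER_NAMES,
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    FeatureConfig,
    FeatureStack,
    apply_filter,
    glcm_features,
    glrlm_features,
    make_offsets,
)
from .image_core import RoiMask, VolumetricImage, quantize

__all__ = [
    "PatientDescriptor",
    "aggregate_moments",
    "aggregate_classical",
    "aggregate_volume",
    "BagOfVisualWords",
    "fit_dictionary",
    "encode_bovw",
    "GapResult",
    "gap_statistic",
]

STRATEGIES = ("classical", "mean", "var", "mean_var", "volume", "bovw")


@dataclass
class PatientDescriptor:
    """The aggregated scalar collection for one patient and one strategy."""

    patient_id: str
    strategy: str
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names length mismatch")


def aggregate_moments(
    stack: FeatureStack, which: tuple[str, ...] = ("mean", "variance")
) -> PatientDescriptor:
    """Per-column sample mean and/or population variance over ROI voxels."""
    if stack.n_voxels == 0:
        raise ValueError("empty feature stack")
    which = tuple(which)
    if not which or any(w not in ("mean", "variance") for w in which):
        raise ValueError(f"which must be a non-empty subset of mean/variance, got {which}")
    blocks, names = [], []
    if "mean" in which:
        blocks.append(stack.matrix.mean(axis=0))
        names += [f"mean:{n}" for n in stack.feature_names]
    if "variance" in which:
        blocks.append(stack.matrix.var(axis=0))
        names += [f"var:{n}" for n in stack.feature_names]
    strategy = {("mean",): "mean", ("variance",): "var"}.get(which, "mean_var")
    return PatientDescriptor(
        patient_id=stack.patient_id,
        strategy=strategy,
        values=np.concatenate(blocks),
        feature_names=names,
    )


def _glcm_volume_counts(levels: np.ndarray, offsets: np.ndarray, num_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts over the whole volume (ROI-valid voxels)."""
    C = np.zeros((num_levels, num_levels))
    for off in offsets:
        src = [slice(max(0, -o), levels.shape[i] - max(0, o)) for i, o in enumerate(off)]
        dst = [slice(max(0, o), levels.shape[i] - max(0, -o)) for i, o in enumerate(off)]
        la = levels[tuple(src)].ravel()
        lb = levels[tuple(dst)].ravel()
        ok = (la > 0) & (lb > 0)
        if ok.any():
            np.add.at(C, (la[ok] - 1, lb[ok] - 1), 1.0)
            np.add.at(C, (lb[ok] - 1, la[ok] - 1), 1.0)
    return C


def aggregate_classical(
    images: list[VolumetricImage],
    roi: RoiMask,
    config: FeatureConfig = FeatureConfig(),
    patient_id: str = "",
) -> PatientDescriptor:
    """Classical radiomics aggregation (no sliding windows).

    Filters are averaged over the ROI; gray-level matrices are accumulated
    once over the whole ROI (all offsets/directions merged, symmetric) and
    summarized by the usual scalars — 21 values per modality.
    """
    if roi.voxel_count == 0:
        raise ValueError("ROI is empty")
    offsets = make_offsets(config.displacements_mm)
    values, names = [], []
    fg = roi.values
    for img in images:
        roi.check_companion(img)
        for fname in FILTER_NAMES:
            fmap = apply_filter(img, fname, config.bank)
            values.append(float(fmap.values[fg].mean()))
            names.append(f"{img.modality}:{fname}")
        q = quantize(img, roi, config.num_levels, config.bounds_for(img.modality))
        levels = q.values.astype(np.int64)
        C = _glcm_volume_counts(levels, offsets.offsets, config.num_levels)
        total = C.sum()
        gf = glcm_features(C / total if total > 0 else C)
        values += list(gf.values())
        names += [f"{img.modality}:{n}" for n in GLCM_FEATURE_NAMES]
        R = _texture.glrlm_volume_counts(
            levels,
            np.ascontiguousarray(offsets.directions, dtype=np.int64),
            config.num_levels,
            int(max(levels.shape)),
        )
        rf = glrlm_features(R)
        values += list(rf.values())
        names += [f"{img.modality}:{n}" for n in GLRLM_FEATURE_NAMES]
    return PatientDescriptor(
        patient_id=patient_id,
        strategy="classical",
        values=np.array(values),
        feature_names=names,
    )


def aggregate_volume(roi: RoiMask, patient_id: str = "") -> PatientDescriptor:
    """The most basic aggregation: the foreground voxel count of the ROI."""
    if roi.voxel_count == 0:
        raise ValueError("ROI is empty")
    return PatientDescriptor(
        patient_id=patient_id,
        strategy="volume",
        values=np.array([float(roi.voxel_count)]),
        feature_names=["voxel_count"],
    )


# ---------------------------------------------------------------------------
# Bag of visual words
# ---------------------------------------------------------------------------


def _as_matrix(stack) -> np.ndarray:
    return stack.matrix if isinstance(stack, FeatureStack) else np.asarray(stack)


class BagOfVisualWords(BaseEstimator):
    """Gaussian-mixture visual dictionary + histogram encoder.

    fit() pools a seeded per-patient subsample of training-fold voxels,
    standardizes the columns (the scaler is stored and reused at encode
    time — no test-fold leakage) and fits a Gaussian mixture whose component
    means are the visual words. transform() hard-assigns every voxel of a
    stack to its maximum-posterior word and returns the k-bin histogram of
    relative frequencies.

    Parameters
    ----------
    n_words : number of visual words (mixture components), k.
    covariance_type : GMM covariance structure; "diag" by default for
        stability in ~42 dimensions with modest voxel counts.
    max_voxels_per_patient : subsampling cap when pooling training voxels.
    assignment : "hard" (max posterior, default) or "soft" (mean
        responsibilities).
    max_retries : re-initializations attempted if EM fails to converge.
    """

    def __init__(
        self,
        n_words: int = 50,
        covariance_type: str = "diag",
        max_voxels_per_patient: int = 2000,
        assignment: str = "hard",
        max_retries: int = 3,
        reg_covar: float = 1e-6,
        init_params: str = "kmeans",
        n_init: int = 1,
        max_iter: int = 500,
        random_state: int | None = 0,
    ):
        self.n_words = n_words
        self.covariance_type = covariance_type
        self.max_voxels_per_patient = max_voxels_per_patient
        self.assignment = assignment
        self.max_retries = max_retries
        self.reg_covar = reg_covar
        self.init_params = init_params
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    # -- dictionary views ---------------------------------------------------
    @property
    def k(self) -> int:
        return self.n_words

    @property
    def weights(self) -> np.ndarray:
        return self.gmm_.weights_

    @property
    def means(self) -> np.ndarray:
        return self.gmm_.means_

    @property
    def covariances(self) -> np.ndarray:
        return self.gmm_.covariances_

    def fit(self, stacks, y=None):
        if self.n_words < 1:
            raise ValueError("n_words must be >= 1")
        ss = np.random.SeedSequence(self.random_state)
        per_patient = ss.spawn(len(stacks) + 1)
        pooled = []
        for child, stack in zip(per_patient[:-1], stacks):
            X = _as_matrix(stack)
            if X.shape[0] > self.max_voxels_per_patient:
                rng = np.random.default_rng(child)
                keep = np.sort(
                    rng.choice(X.shape[0], self.max_voxels_per_patient, replace=False)
                )
                X = X[keep]
            pooled.append(X)
        X = np.vstack(pooled)
        if X.shape[0] < self.n_words:
            raise ValueError(
                f"pooled voxel count {X.shape[0]} < n_words {self.n_words}"
            )
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        gmm_seed_rng = np.random.default_rng(per_patient[-1])
        last_err = None
        for _ in range(max(1, self.max_retries)):
            seed = int(gmm_seed_rng.integers(0, 2**31 - 1))
            gmm = GaussianMixture(
                n_components=self.n_words,
                covariance_type=self.covariance_type,
                reg_covar=self.reg_covar,
                random_state=seed,
                init_params=self.init_params,
                n_init=self.n_init,
                max_iter=self.max_iter,
            ).fit(Xs)
            if gmm.converged_ or self.n_words == 1:
                self.gmm_ = gmm
                self.feature_names_ = (
                    list(stacks[0].feature_names)
                    if isinstance(stacks[0], FeatureStack)
                    else [f"f{i}" for i in range(X.shape[1])]
                )
                self.n_features_in_ = X.shape[1]
                self.n_pooled_voxels_ = X.shape[0]
                return self
            last_err = RuntimeError("EM did not converge")
        raise last_err

    def encode(self, stack) -> np.ndarray:
        """Histogram of visual-word assignments for one patient (sums to 1)."""
        X = _as_matrix(stack)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"stack width {X.shape[1]} != dictionary width {self.n_features_in_}"
            )
        Xs = self.scaler_.transform(X)
        if self.assignment == "hard":
            labels = self.gmm_.predict(Xs)
            counts = np.bincount(labels, minlength=self.n_words).astype(np.float64)
            return counts / counts.sum()
        if self.assignment == "soft":
            return self.gmm_.predict_proba(Xs).mean(axis=0)
        raise ValueError(f"unknown assignment {self.assignment!r}")

    def transform(self, stacks) -> np.ndarray:
        return np.vstack([self.encode(s) for s in stacks])

    def fit_transform(self, stacks, y=None) -> np.ndarray:
        return self.fit(stacks).transform(stacks)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.get_params(),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "weights": self.gmm_.weights_.tolist(),
            "means": self.gmm_.means_.tolist(),
            "covariances": self.gmm_.covariances_.tolist(),
            "feature_names": self.feature_names_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BagOfVisualWords":
        payload = json.loads(Path(path).read_text())
        obj = cls(**payload["params"])
        means = np.asarray(payload["means"])
        obj.scaler_ = StandardScaler()
        obj.scaler_.mean_ = np.asarray(payload["scaler_mean"])
        obj.scaler_.scale_ = np.asarray(payload["scaler_scale"])
        obj.scaler_.var_ = obj.scaler_.scale_ ** 2
        obj.scaler_.n_features_in_ = means.shape[1]
        gmm = GaussianMixture(
            n_components=obj.n_words, covariance_type=obj.covariance_type
        )
        gmm.weights_ = np.asarray(payload["weights"])
        gmm.means_ = means
        gmm.covariances_ = np.asarray(payload["covariances"])
        from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky

        gmm.precisions_cholesky_ = _compute_precision_cholesky(
            gmm.covariances_, obj.covariance_type
        )
        obj.gmm_ = gmm
        obj.feature_names_ = payload["feature_names"]
        obj.n_features_in_ = means.shape[1]
        return obj


def fit_dictionary(
    stacks,
    k: int = 50,
    seed: int | None = 0,
    max_voxels_per_patient: int = 2000,
    **kwargs,
) -> BagOfVisualWords:
    """Fit a k-word Gaussian-mixture visual dictionary on training stacks."""
    return BagOfVisualWords(
        n_words=k,
        max_voxels_per_patient=max_voxels_per_patient,
        random_state=seed,
        **kwargs,
    ).fit(stacks)


def encode_bovw(stack, dictionary: BagOfVisualWords) -> PatientDescriptor:
    """Encode one patient's stack as a visual-word frequency histogram."""
    hist = dictionary.encode(stack)
    pid = stack.patient_id if isinstance(stack, FeatureStack) else ""
    return PatientDescriptor(
        patient_id=pid,
        strategy="bovw",
        values=hist,
        feature_names=[f"word_{i}" for i in range(dictionary.n_words)],
    )


# ---------------------------------------------------------------------------
# Gap statistic
# ---------------------------------------------------------------------------


@dataclass
class GapResult:
    k_grid: list[int]
    gap: np.ndarray
    sk: np.ndarray
    log_w: np.ndarray
    selected_k: int


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        if len(pts) > 1:
            w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return max(w, 1e-300)


def _cluster_labels(X, k, seed, clusterer, covariance_type="diag"):
    if clusterer == "gmm":
        model = GaussianMixture(
            n_components=k, covariance_type=covariance_type, random_state=seed,
            reg_covar=1e-6,
        ).fit(X)
        return model.predict(X)
    if clusterer == "kmeans":
        from sklearn.cluster import KMeans

        return KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(X)
    raise ValueError(f"unknown clusterer {clusterer!r}")


def gap_statistic(
    X: np.ndarray,
    k_grid,
    B: int = 20,
    seed: int | None = 0,
    clusterer: str = "gmm",
    rule: str = "se",
    covariance_type: str = "diag",
) -> GapResult:
    """Tibshirani's gap statistic for choosing the number of visual words.

    Gap(k) = mean_b log W*_kb - log W_k, with W the within-cluster sum of
    squared distances to centroids and W* from B reference datasets drawn
    uniformly over the per-column bounding box of X. ``rule="se"`` selects
    the smallest k with Gap(k) >= Gap(k+1) - s_{k+1} (standard-error rule);
    ``rule="max"`` takes the grid argmax.
    """
    X = np.asarray(X, dtype=np.float64)
    k_grid = [int(k) for k in k_grid]
    if not k_grid or B < 1:
        raise ValueError("k_grid must be non-empty and B >= 1")
    ss = np.random.SeedSequence(seed)
    ref_rng = np.random.default_rng(ss.spawn(1)[0])
    seed_rng = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = [ref_rng.uniform(lo, hi, size=X.shape) for _ in range(B)]
    gaps, sks, log_ws, used_k = [], [], [], []
    for k in k_grid:
        if k > X.shape[0]:
            continue
        base_seed = int(seed_rng.integers(0, 2**31 - 1))
        labels = _cluster_labels(X, k, base_seed, clusterer, covariance_type)
        log_w = np.log(_within_dispersion(X, labels))
        log_wref = np.array(
            [
                np.log(
                    _within_dispersion(
                        ref, _cluster_labels(ref, k, base_seed + b + 1, clusterer, covariance_type)
                    )
                )
                for b, ref in enumerate(refs)
            ]
        )
        gaps.append(log_wref.mean() - log_w)
        sks.append(log_wref.std() * np.sqrt(1.0 + 1.0 / B))
        log_ws.append(log_w)
        used_k.append(k)
    gaps = np.array(gaps)
    sks = np.array(sks)
    selected = used_k[int(np.argmax(gaps))]
    if rule == "se":
        for i in range(len(used_k) - 1):
            if gaps[i] >= gaps[i + 1] - sks[i + 1]:
                selected = used_k[i]
                break
    elif rule != "max":
        raise ValueError(f"unknown rule {rule!r}")
    return GapResult(
        k_grid=used_k, gap=gaps, sk=sks, log_w=np.array(log_ws), selected_k=selected
    )
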