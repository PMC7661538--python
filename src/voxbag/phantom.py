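"""Seeded synthetic cohorts: 3D two-modality texture phantoms with
proportional-hazards survival outcomes.

Each patient is a lumpy spherical tumor on a textured background, imaged in
two co-registered modalities ("CT"-like and "PET"-like, 1 mm grid). The
tumor interior is partitioned into two texture-class compartments at a
per-patient heterogeneity fraction f (volume fraction of class B), and the
survival time is drawn from an exponential proportional-hazards model with

    log-hazard = beta_h * f + beta_v * (normalized volume),

with independent administrative (uniform) censoring calibrated to a target
censoring rate.

Texture design. Every tumor splits 50/50 into hyper- and hypo-intense
tissue in *each* modality, so the single-modality image statistics are the
same for every patient regardless of composition. Heterogeneity f is the
*discordant* volume fraction — the part of the tumor where the PET
deviation opposes the CT deviation (class B; the concordant remainder is
class A). Any aggregate of a single feature map (mean, variance, whole-ROI
matrices, and the per-modality texture features built on them) is blind to
f by construction; only the joint two-modality voxel distribution carries
it, as the relative mass of the four (CT, PET) hot/cold combinations —
exactly what a visual-word histogram over the 42-dimensional feature space
reads off.

The mean-matched pair generator uses the same mechanism under exact
control: two mirror-symmetric disjoint lobes, offsets that are exact
multiples of the fixed quantization bin width, and shared field/noise
realizations, making the homogeneous and the fully-deviant patient agree
in every mean-aggregated descriptor while their histograms differ.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .image_core import RoiMask, VolumetricImage, save_volume

__all__ = [
    "TextureClass",
    "PhantomSpec",
    "PhantomPatient",
    "GroundTruth",
    "generate_patient",
    "generate_mean_matched_pair",
    "generate_cohort",
]


@dataclass(frozen=True)
class TextureClass:
    """Texture parameters of one tissue class, per modality.

    ``ct_offset``/``pet_offset`` are the hot/cold deviation amplitudes: the
    generator applies them with sign +1 in the hyper-intense half of the
    tumor and -1 in the hypo-intense half (per modality, exactly balanced).
    """

    ct_base: float = 40.0
    ct_amplitude: float = 8.0
    ct_offset: float = 0.0
    pet_base: float = 5.0
    pet_amplitude: float = 0.8
    pet_offset: float = 0.0
    #: +1: PET deviation field aligned with CT's; -1: anti-aligned;
    #: 0: independent field.
    pet_alignment: float = 1.0
    correlation_length: float = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 120
    grid_size: int = 48
    spacing: float = 1.0
    class_a: TextureClass = field(default_factory=TextureClass)
    class_b: TextureClass = field(
        default_factory=lambda: TextureClass(ct_offset=20.0, pet_offset=2.0)
    )
    tumor_radius_mm: tuple[float, float] = (6.0, 9.0)
    heterogeneity_range: tuple[float, float] = (0.0, 1.0)
    beta_heterogeneity: float = 5.0
    beta_volume: float = 0.4
    baseline_median_months: float = 30.0
    censoring_rate: float = 0.2
    ct_noise: float = 2.0
    pet_noise: float = 0.2
    ct_bg_base: float = 0.0
    ct_bg_amplitude: float = 10.0
    pet_bg_base: float = 1.0
    pet_bg_amplitude: float = 0.5
    bg_correlation_length: float = 2.0
    #: Gaussian smoothing (mm) of the hot/cold offset transitions; softens
    #: the compartment edges so zero-mean filters respond to texture, not to
    #: the compartment geometry. 0 = hard plateaus (used by the exact pair).
    offset_transition_mm: float = 1.0
    #: compartment base-intensity offsets used by the mean-matched pair design
    #: (multiples of the pair quantization bin widths, 3.0 HU / 0.3 SUV)
    pair_ct_offset: float = 9.0
    pair_pet_offset: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.heterogeneity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("heterogeneity_range must lie in [0, 1]")
        if self.tumor_radius_mm[0] <= 0:
            raise ValueError("tumor radii must be positive")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        max_r = self.tumor_radius_mm[1] + 3.0  # lumpy boundary + jitter slack
        if max_r >= self.grid_size * self.spacing / 2.0:
            raise ValueError("tumor does not fit inside the grid")


@dataclass
class GroundTruth:
    fraction: float
    log_hazard: float
    radius_mm: float
    compartment_b: np.ndarray  # deviant (heterogeneous) tissue mask
    compartment_hot: np.ndarray  # its hyper-intense half
    true_event_time: float


@dataclass
class PhantomPatient:
    patient_id: str
    images: list[VolumetricImage]
    mask: RoiMask
    time: float
    event: int
    truth: GroundTruth


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    g = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(g, sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _admin_censoring_time(spec: PhantomSpec) -> float:
    """Administrative-censoring horizon matching the target censoring rate.

    For T ~ Exp(rate) and C ~ U(0, c), P(C < T) = (1 - exp(-rate*c))/(rate*c);
    the rate is evaluated at the cohort-typical log-hazard.
    """
    if spec.censoring_rate <= 0:
        return np.inf
    lam0 = np.log(2.0) / spec.baseline_median_months
    f_mid = float(np.mean(spec.heterogeneity_range))
    rate = lam0 * np.exp(spec.beta_heterogeneity * f_mid + spec.beta_volume * 0.5)

    def g(c):
        return (1.0 - np.exp(-rate * c)) / (rate * c) - spec.censoring_rate

    return float(brentq(g, 1e-9, 1e9))


def _physical_coords(spec: PhantomSpec):
    n = spec.grid_size
    ax = (np.arange(n) - (n - 1) / 2.0) * spec.spacing
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _build_volumes(
    spec: PhantomSpec,
    rng: np.random.Generator,
    classes: tuple[TextureClass, TextureClass],
    fraction: float,
    geometry: str = "sphere",
    cut_axis: np.ndarray | None = None,
) -> tuple[list[VolumetricImage], RoiMask, np.ndarray, float]:
    """Deterministically build (images, tumor mask, deviant mask, hot mask,
    radius) from one generator stream.

    ``geometry="twolobe"`` builds two disjoint mirror-symmetric lobes along
    axis 0 (used by the mean-matched pair); ``cut_axis`` overrides the
    random compartment-cut direction.
    """
    cls_a, cls_b = classes
    shape = (spec.grid_size,) * 3
    r = float(rng.uniform(*spec.tumor_radius_mm))
    jitter = rng.uniform(-1.5, 1.5, size=3)
    x, y, z = _physical_coords(spec)
    lump = _smooth_field(rng, shape, sigma=3.0)
    if geometry == "sphere":
        dist = np.sqrt(
            (x - jitter[0]) ** 2 + (y - jitter[1]) ** 2 + (z - jitter[2]) ** 2
        )
    elif geometry == "twolobe":
        # two disjoint, exactly mirror-symmetric lobes along axis 0, far
        # enough apart that no 5x5x5 window can span both; each lobe is one
        # compartment. No jitter/lumpiness: the lobes then contain exactly
        # the same number of voxels, so 50/50 statements are exact.
        sep = 1.35 * r
        d1 = np.sqrt((x - sep) ** 2 + y**2 + z**2)
        d2 = np.sqrt((x + sep) ** 2 + y**2 + z**2)
        dist = np.minimum(d1, d2)
        tumor = dist <= r
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if geometry == "sphere":
        tumor = dist <= r + 1.0 * lump
        tumor |= dist <= r * 0.5  # guarantee a solid core
    t_idx = np.argwhere(tumor)
    n_t = len(t_idx)
    comp_b = np.zeros(shape, dtype=bool)  # discordant tissue (class B)
    hot = np.zeros(shape, dtype=bool)  # CT-hyper-intense half
    # the direction draws are unconditional so that patients generated from
    # the same stream share all subsequent field/noise realizations
    # regardless of f
    u1 = rng.standard_normal(3)
    u1 /= np.linalg.norm(u1)
    u2 = rng.standard_normal(3)
    if cut_axis is not None:
        u1 = np.asarray(cut_axis, dtype=float)
        u1 /= np.linalg.norm(u1)
    u2 = u2 - (u2 @ u1) * u1
    if np.linalg.norm(u2) < 1e-6:
        u2 = np.array([u1[1], -u1[0], 0.0])
    u2 /= np.linalg.norm(u2)
    if geometry == "twolobe":
        if fraction > 0:
            # deviant tissue occupies the whole two-lobe tumor; hot/cold are
            # the two (exactly equal) lobes, concordant across modalities
            comp_b = tumor.copy()
            hot = tumor & (d1 <= d2)
        ct_sgn_pos = hot
        pet_sgn_pos = hot
        deviant = comp_b
    else:
        # Every tumor is split 50/50 into CT-hyper and CT-hypo halves along
        # u1, and 50/50 into PET-hyper/PET-hypo; each single-modality image
        # therefore has the same composition for every patient.
        # Heterogeneity f is the *discordant* volume fraction: in the
        # discordant region (top f-cap of each CT half along u2, keeping the
        # PET marginal exactly 50/50) the PET sign opposes the CT sign.
        proj1 = t_idx @ u1
        order1 = np.argsort(proj1, kind="stable")
        half = n_t // 2
        ct_hot_idx = t_idx[order1[n_t - half:]]
        ct_cold_idx = t_idx[order1[: n_t - half]]
        hot[ct_hot_idx[:, 0], ct_hot_idx[:, 1], ct_hot_idx[:, 2]] = True
        for part in (ct_hot_idx, ct_cold_idx):
            n_d = int(round(fraction * len(part)))
            if n_d > 0:
                proj2 = part @ u2
                order2 = np.argsort(proj2, kind="stable")
                sel = part[order2[len(part) - n_d:]]
                comp_b[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        ct_sgn_pos = hot
        pet_sgn_pos = hot ^ comp_b  # discordant voxels flip the PET sign
        deviant = tumor
    comp_a = tumor & ~comp_b

    u_a = _smooth_field(rng, shape, cls_a.correlation_length)
    u_b = (
        u_a
        if cls_b.correlation_length == cls_a.correlation_length
        else _smooth_field(rng, shape, cls_b.correlation_length)
    )
    indep = {}  # independent PET fields, generated only if a class asks
    for tag, cls in (("a", cls_a), ("b", cls_b)):
        if cls.pet_alignment == 0.0:
            indep[tag] = _smooth_field(rng, shape, cls.correlation_length)

    ct = spec.ct_bg_base + spec.ct_bg_amplitude * _smooth_field(
        rng, shape, spec.bg_correlation_length
    )
    pet = spec.pet_bg_base + spec.pet_bg_amplitude * _smooth_field(
        rng, shape, spec.bg_correlation_length
    )
    # per-modality hot/cold sign fields (exactly balanced 50/50 over the
    # deviant tissue, so every single-modality statistic is composition
    # blind); transitions optionally smoothed so the compartment edges do
    # not dominate the filter responses
    ct_sgn = np.zeros(shape)
    ct_sgn[deviant & ct_sgn_pos] = 1.0
    ct_sgn[deviant & ~ct_sgn_pos] = -1.0
    pet_sgn = np.zeros(shape)
    pet_sgn[deviant & pet_sgn_pos] = 1.0
    pet_sgn[deviant & ~pet_sgn_pos] = -1.0
    if spec.offset_transition_mm > 0:
        sig = spec.offset_transition_mm / spec.spacing
        ct_sgn = ndimage.gaussian_filter(ct_sgn, sig, mode="reflect")
        pet_sgn = ndimage.gaussian_filter(pet_sgn, sig, mode="reflect")
    for cls, mask, u_f, tag in (
        (cls_a, comp_a, u_a, "a"),
        (cls_b, comp_b, u_b, "b"),
    ):
        if not mask.any():
            continue
        ct[mask] = cls.ct_base + cls.ct_amplitude * u_f[mask]
        if cls.pet_alignment == 0.0:
            dev = cls.pet_amplitude * indep[tag][mask]
        else:
            dev = cls.pet_alignment * cls.pet_amplitude * u_f[mask]
        pet[mask] = cls.pet_base + dev
    # the offset fields are continuous across compartment borders (signs
    # decay smoothly to 0 outside the deviant tissue); the deviation
    # amplitude is a property of the deviant structure (class_b)
    ct += cls_b.ct_offset * ct_sgn
    pet += cls_b.pet_offset * pet_sgn
    ct = ct + spec.ct_noise * rng.standard_normal(shape)
    pet = pet + spec.pet_noise * rng.standard_normal(shape)
    images = [
        VolumetricImage(ct, (spec.spacing,) * 3, modality="CT"),
        VolumetricImage(pet, (spec.spacing,) * 3, modality="PET"),
    ]
    mask = RoiMask(tumor, (spec.spacing,) * 3)
    return images, mask, comp_b, hot, r


def _draw_survival(
    spec: PhantomSpec, rng: np.random.Generator, fraction: float, voxel_count: int
) -> tuple[float, int, float, float]:
    """(observed time, event, log-hazard, true event time)."""
    lam0 = np.log(2.0) / spec.baseline_median_months
    vmax = 4.0 / 3.0 * np.pi * spec.tumor_radius_mm[1] ** 3
    vnorm = voxel_count * spec.spacing**3 / vmax
    logh = spec.beta_heterogeneity * fraction + spec.beta_volume * vnorm
    rate = lam0 * np.exp(logh)
    t_event = float(rng.exponential(1.0 / rate))
    c_admin = _admin_censoring_time(spec)
    c = float(rng.uniform(0.0, c_admin)) if np.isfinite(c_admin) else np.inf
    if t_event <= c:
        return max(t_event, 1e-2), 1, logh, t_event
    return max(c, 1e-2), 0, logh, t_event


def generate_patient(
    spec: PhantomSpec, index: int, fraction: float | None = None
) -> PhantomPatient:
    """Generate one patient; fully determined by (spec, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))
    if fraction is None:
        fraction = float(rng.uniform(*spec.heterogeneity_range))
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    images, mask, comp_b, hot, r = _build_volumes(
        spec, rng, (spec.class_a, spec.class_b), fraction
    )
    time, event, logh, t_true = _draw_survival(spec, rng, fraction, mask.voxel_count)
    return PhantomPatient(
        patient_id=f"P{index:04d}",
        images=images,
        mask=mask,
        time=time,
        event=event,
        truth=GroundTruth(
            fraction=fraction,
            log_hazard=logh,
            radius_mm=r,
            compartment_b=comp_b,
            compartment_hot=hot,
            true_event_time=t_true,
        ),
    )


def pair_intensity_bounds(
    spec: PhantomSpec, num_levels: int = 64
) -> tuple[tuple[str, tuple[float, float]], ...]:
    """Fixed quantization bounds for the mean-matched pair, chosen so the
    pair offsets are exact multiples of the bin width (the offset then shifts
    quantized levels uniformly and the co-occurrence statistics of interior
    windows are exactly invariant)."""
    ct_half = 96.0  # bin width 2*96/num_levels = 3.0 HU at 64 levels
    pet_half = 9.6  # bin width 0.3 SUV at 64 levels
    a = spec.class_a
    return (
        ("CT", (a.ct_base - ct_half, a.ct_base + ct_half)),
        ("PET", (a.pet_base - pet_half, a.pet_base + pet_half)),
    )


def generate_mean_matched_pair(spec: PhantomSpec) -> tuple[PhantomPatient, PhantomPatient]:
    """Two patients with matched ROI means but different composition.

    Patient 1: homogeneous two-lobe tumor at the reference base intensity.
    Patient 2: same geometry, with the two (exactly equal) lobes at base
    +/- the pair offsets — a 50/50 hot/cold split. Both share the texture
    field and noise realizations, so the only difference is the compartment
    offsets — invisible to first-order aggregation (zero-mean filters are
    offset-blind and, with the bin-exact bounds of
    :func:`pair_intensity_bounds`, the co-occurrence statistics are
    shift-invariant) but plainly visible to a voxel-level histogram. The
    disjoint lobes mean no sliding window ever mixes the two classes.
    """
    # hard offset plateaus: the lobes are disjoint, so no smoothing is needed
    # and exact bin-shift invariance is preserved
    spec = replace(spec, offset_transition_mm=0.0)
    mid = replace(spec.class_a, ct_offset=0.0, pet_offset=0.0, pet_alignment=1.0)
    deviant = replace(
        mid, ct_offset=spec.pair_ct_offset, pet_offset=spec.pair_pet_offset
    )

    def build(fraction, pid):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10_000]))
        images, mask, comp_b, hot, r = _build_volumes(
            spec, rng, (mid, deviant), fraction, geometry="twolobe"
        )
        time, event, logh, t_true = _draw_survival(
            spec, rng, fraction, mask.voxel_count
        )
        return PhantomPatient(
            patient_id=pid,
            images=images,
            mask=mask,
            time=time,
            event=event,
            truth=GroundTruth(fraction, logh, r, comp_b, hot, t_true),
        )

    homogeneous = build(0.0, "PAIR_HOMOG")
    mixed = build(1.0, "PAIR_MIXED")
    return homogeneous, mixed


def generate_cohort(
    spec: PhantomSpec, out_dir: str | Path | None = None
) -> tuple[list[PhantomPatient], pd.DataFrame]:
    """Generate the full cohort; optionally write NIfTI/CSV/JSON to disk."""
    patients = [generate_patient(spec, i) for i in range(spec.n_patients)]
    survival = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "time": [p.time for p in patients],
            "event": [p.event for p in patients],
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        for p in patients:
            for img in p.images:
                save_volume(
                    img, out / "images" / f"{p.patient_id}_{img.modality}.nii.gz"
                )
            save_volume(p.mask, out / "images" / f"{p.patient_id}_mask.nii.gz")
        survival.to_csv(out / "survival.csv", index=False)
        truth = {
            p.patient_id: {
                "fraction": p.truth.fraction,
                "log_hazard": p.truth.log_hazard,
                "radius_mm": p.truth.radius_mm,
                "true_event_time": p.truth.true_event_time,
            }
            for p in patients
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        import yaml

        def _spec_dict(s):
            d = asdict(s)
            return d

        (out / "phantom_spec.yaml").write_text(yaml.safe_dump(_spec_dict(spec)))
    return patients, survival
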