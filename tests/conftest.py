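import numpy as np
import pytest

from voxbag.image_core import QuantizedImage, RoiMask, VolumetricImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(values, spacing=(1.0, 1.0, 1.0), modality="CT"):
    return VolumetricImage(values=np.asarray(values, dtype=float), spacing=spacing,
                           modality=modality)


def make_mask(values, spacing=(1.0, 1.0, 1.0)):
    return RoiMask(values=np.asarray(values, dtype=bool), spacing=spacing)


@pytest.fixture
def small_quantized(rng):
    """Random 8^3 quantized volume (5 levels) with a random in-ROI region."""
    levels = rng.integers(1, 6, size=(8, 8, 8)).astype(np.int16)
    roi = rng.random((8, 8, 8)) < 0.8
    levels[~roi] = 0
    return QuantizedImage(values=levels, num_levels=5, source_range=(0.0, 1.0))


@pytest.fixture(scope="session")
def tiny_patient():
    """One small phantom patient, shared across tests (session-scoped for speed)."""
    from voxbag.phantom import PhantomSpec, generate_patient

    spec = PhantomSpec(grid_size=32, tumor_radius_mm=(5.0, 6.0), seed=7)
    return generate_patient(spec, 0, fraction=0.4)


@pytest.fixture(scope="session")
def tiny_features(tiny_patient):
    from voxbag.feature_maps import FeatureConfig
    from voxbag.workflow import PipelineConfig, extract_patient

    cfg = PipelineConfig(
        features=FeatureConfig(num_levels=16, max_voxels=800)
    )
    return extract_patient(
        tiny_patient.images, tiny_patient.mask, cfg, patient_id="T0"
    )
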