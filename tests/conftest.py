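import numpy as np
import pytest

from octflush import (
    AcquisitionMeta,
    GuidewireSpec,
    LumenModel,
    PhantomSpec,
    StentSpec,
    generate_pullback,
)
from octflush.segmentation import default_strut_classifier


@pytest.fixture(scope="session")
def small_meta():
    """Compact acquisition geometry: 240 A-lines, 1.8 mm imaged depth."""
    return AcquisitionMeta(
        n_alines=240, n_depth=360, axial_pitch_um=5.0, pullback_length_mm=2.0
    )


@pytest.fixture(scope="session")
def stented_spec():
    return PhantomSpec(
        lumen=LumenModel(base_radius_mm=1.3, center_offset_mm=0.2, ovality=0.04),
        stent=StentSpec(n_struts=8, start_angle_deg=12.0),
        guidewire=GuidewireSpec(center_deg=200.0, width_deg=30.0),
        residual_blood_density=0.04,
        seed=71,
    )


@pytest.fixture(scope="session")
def stented_pullback(stented_spec, small_meta):
    return generate_pullback(stented_spec, small_meta, n_frames=3)


@pytest.fixture(scope="session")
def clean_spec():
    """Unstented, guidewire-free, blood-free vessel."""
    return PhantomSpec(
        lumen=LumenModel(base_radius_mm=1.3, center_offset_mm=0.25), seed=5
    )


@pytest.fixture(scope="session")
def clean_pullback(clean_spec, small_meta):
    return generate_pullback(clean_spec, small_meta, n_frames=2)


@pytest.fixture(scope="session")
def strut_classifier():
    return default_strut_classifier()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
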