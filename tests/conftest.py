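import numpy as np
import pytest

from contourpro import ContourImage, GroupSpec, PeakSpec, generate_two_group_study
from contourpro.synthetic import render_contour


@pytest.fixture(scope="session")
def peak_group():
    """A small structured peak field used as a generic test subject."""
    return GroupSpec(
        label="g",
        base_peaks=[
            PeakSpec(0.3, 0.3, 0.9, 0.04, 0.04),
            PeakSpec(0.7, 0.5, 0.7, 0.03, 0.05),
            PeakSpec(0.5, 0.7, 0.5, 0.05, 0.03),
        ],
        bleed_level=0.3,
    )


@pytest.fixture(scope="session")
def peak_image(peak_group):
    return render_contour(peak_group, size=(96, 96), jitter=0.0, noise_sd=0.02, seed=3)


@pytest.fixture(scope="session")
def study_fixture():
    """Two-group study with 3 planted marker windows (session-cached)."""
    return generate_two_group_study(
        n_per_group=15, k_markers=3, size=(256, 256), seed=7, marker_amplitude=0.8
    )


@pytest.fixture
def const_image():
    return ContourImage(np.full((64, 64, 3), 0.3, dtype=np.float32))
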