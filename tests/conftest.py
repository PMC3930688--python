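import numpy as np
import pytest

from clusteridif import phantom, svca
from clusteridif.core_io import DynamicImage, FrameSchedule, MaskVolume


@pytest.fixture(scope="session")
def fine_grid():
    """A 1-second grid over 90 minutes."""
    return np.linspace(0.0, 90.0, 90 * 60 + 1)


@pytest.fixture(scope="session")
def default_input(fine_grid):
    return phantom.input_model(phantom.InputCurveParams(), fine_grid)


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec.small(noise=0.0, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """Noiseless, PSF-blurred small phantom (shared across tests)."""
    return phantom.build_phantom(small_spec)


@pytest.fixture(scope="session")
def small_phantom_sharp():
    """Noiseless, unblurred small phantom."""
    spec = phantom.PhantomSpec.small(noise=0.0, psf_fwhm_mm=0.0, seed=11)
    return phantom.build_phantom(spec)


def make_schedule(durations_min):
    durations = np.asarray(durations_min, dtype=float) * 60.0
    starts = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
    return FrameSchedule(starts, durations)


@pytest.fixture
def tiny_image():
    """A deterministic 4x3x2 image with 5 frames for unit tests."""
    rng = np.random.default_rng(3)
    sched = make_schedule([0.5, 0.5, 1.0, 2.0, 2.0])
    vox = rng.gamma(2.0, 1.0, size=(4, 3, 2, 5))
    return DynamicImage(vox, (2.0, 2.0, 4.0), sched)


@pytest.fixture(scope="session")
def small_templates(small_phantom):
    """Templates built from the small phantom's own truth masks."""
    img, truth = small_phantom
    std = svca.standardize_frames(img)
    cohort = [(std, truth.gray_mask, truth.white_mask, truth.carotid_mask)]
    return svca.build_template_tacs(cohort)


@pytest.fixture(scope="session")
def small_weights(small_phantom, small_templates):
    img, truth = small_phantom
    std = svca.standardize_frames(img)
    analysis = MaskVolume(
        std.stats_mask.indicator
        | truth.carotid_mask.indicator
        | truth.head_mask.indicator
    )
    return svca.solve_weights(std, small_templates, analysis)
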