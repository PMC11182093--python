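import numpy as np
import pytest

from retmap.synthetic import PhantomSpec, gen_mosaic, render_channels


@pytest.fixture(scope="session")
def cone_phantom():
    """Standard jittered-hex cone mosaic rendered at SNR 10."""
    spec = PhantomSpec(
        seed=42, density=15000.0, field_um=150.0, microns_per_pixel=0.6,
        jitter_fraction=0.10, snr=10.0,
    )
    truth = gen_mosaic(spec)
    channels = render_channels(truth["centers"], truth["dark"], spec)
    return spec, truth, channels


@pytest.fixture(scope="session")
def textured_image(cone_phantom):
    """A structured grayscale image for registration tests."""
    return cone_phantom[2]["confocal"]


def match_rates(detected: np.ndarray, truth: np.ndarray, tol: float):
    """(precision, recall) of detected centers vs ground truth."""
    from scipy.spatial import cKDTree

    if len(detected) == 0:
        return 0.0, 0.0
    d, _ = cKDTree(truth).query(detected)
    precision = float((d < tol).mean())
    dd, _ = cKDTree(detected).query(truth)
    recall = float((dd < tol).mean())
    return precision, recall
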