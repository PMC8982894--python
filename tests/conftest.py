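import numpy as np
import pytest

import pecowaco as pw

# Scenario used by both the PIV-route recovery test and the
# cross-engine comparison: an 8-cell-stage-like cell (15 um radius)
# carrying a 2-wavelength traveling wave with an 80 s period, imaged
# every 5 s so that 8 full periods fit the velocity record exactly.
EIGHT_CELL_SPEC = pw.WaveCellSpec(
    radius=15.0, amplitude=1.0, period=80.0, wave_number=2,
    frame_interval=5.0, duration=645.0, seed=101)


@pytest.fixture(scope="session")
def eight_cell_scenario():
    contours, truth = pw.make_wave_cell(EIGHT_CELL_SPEC)
    movie = pw.render_movie(contours, pixel_size=0.5, seed=101)
    return contours, truth, movie


@pytest.fixture(scope="session")
def eight_cell_piv_traces(eight_cell_scenario):
    _, _, movie = eight_cell_scenario
    return pw.movie_velocity_traces(movie)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def speckle_frame(shape=(96, 96), sigma=1.5, seed=0):
    """A smooth random texture suitable for window correlation."""
    from scipy.ndimage import gaussian_filter

    r = np.random.default_rng(seed)
    return gaussian_filter(r.normal(0.0, 1.0, shape), sigma)
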