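import numpy as np
import pytest

from uripage import calibration, densitometry, synthetic

LADDER_11 = (250.0, 150.0, 100.0, 80.0, 60.0, 50.0, 40.0, 30.0, 25.0, 15.0, 10.0)


@pytest.fixture(scope="session")
def model():
    return synthetic.GelModel()


@pytest.fixture(scope="session")
def true_curve(model):
    """Calibration curve fitted on noise-free pairs from the true migration law."""
    pairs = [(mw, model.migration_rf(mw)) for mw in LADDER_11]
    return calibration.fit_mw_curve(pairs, degree=3)


@pytest.fixture(scope="session")
def analyze(true_curve):
    """Profile array -> calibrated bands, using default detection settings."""

    def _analyze(profile, lane_id="lane", curve=true_curve, **detect_kwargs):
        sub = densitometry.subtract_background(
            densitometry.LaneProfile(profile, lane_id=lane_id)
        )
        bands = densitometry.detect_bands(sub, **detect_kwargs)
        return calibration.annotate_mw(bands, curve)

    return _analyze


def gaussian(n, center, sigma, area=1.0):
    x = np.arange(n, dtype=float)
    return area * np.exp(-0.5 * ((x - center) / sigma) ** 2) / (
        sigma * np.sqrt(2 * np.pi)
    )
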