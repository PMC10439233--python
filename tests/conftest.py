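import numpy as np
import pytest

from stenella.contours import WhistleContour
from stenella.simulate import make_two_ecotype_dataset


def make_contour(freqs_khz, duration_ms=500.0, whistle_id="w", amps=None, **meta):
    """Contour from a kHz trace on a uniform grid."""
    freqs_khz = np.asarray(freqs_khz, float)
    times = np.linspace(0.0, duration_ms, len(freqs_khz))
    return WhistleContour(
        whistle_id, times, freqs_khz * 1000.0, None if amps is None else np.asarray(amps), dict(meta)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Forty whistles (20 per ecotype) with group structure, fixed seed."""
    return make_two_ecotype_dataset(20, seed=7)


@pytest.fixture
def linear_sweep():
    return make_contour(np.linspace(5, 10, 50), duration_ms=500.0, whistle_id="sweep")


@pytest.fixture
def flat_contour():
    return make_contour(np.full(40, 5.0), duration_ms=1000.0, whistle_id="flat")
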