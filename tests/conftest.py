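import numpy as np
import pytest

import cardiomap as cm


def run_pipeline(spec: cm.WaveSpec):
    """Full analysis chain for one synthetic spec.

    Returns (truth, movie, activation map, velocity field).
    """
    truth, movie = cm.simulate(spec)
    normalized = cm.normalize_pixels(movie)
    amap = cm.activation_map(normalized)
    field = cm.velocity_field(amap)
    return truth, movie, amap, field


@pytest.fixture(scope="session")
def pipeline():
    return run_pipeline


@pytest.fixture(scope="session")
def planar_spec():
    """Noiseless planar wave, 10 μm/ms along +x, linear-ramp upstroke."""
    return cm.WaveSpec(scenario="planar", direction_deg=0.0, speed_um_per_ms=10.0,
                       grid_shape=(32, 32))


@pytest.fixture(scope="session")
def planar_run(planar_spec):
    return run_pipeline(planar_spec)


@pytest.fixture(scope="session")
def radial_run():
    spec = cm.WaveSpec(scenario="radial", speed_um_per_ms=8.0, grid_shape=(33, 33))
    return run_pipeline(spec)


@pytest.fixture(scope="session")
def study_run():
    """Fixed two-region study conditions (8 vs 2 μm/ms, SNR 10)."""
    spec = cm.two_region_study_spec(seed=7)
    return spec, run_pipeline(spec)


def interior(mask: np.ndarray, margin: int) -> np.ndarray:
    """Restrict a validity mask to pixels at least `margin` from the edge."""
    out = np.zeros_like(mask)
    out[margin:-margin, margin:-margin] = mask[margin:-margin, margin:-margin]
    return out
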