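import numpy as np
import pytest

from dwlra.lra import run_lra
from dwlra.phantom import PhantomSpec, simulate_acquisition
from dwlra.pipeline import (PipelineConfig, default_roi, matching_roi,
                            run_pipeline)

CENTER = 6


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(noise_sigma=0.0)
    series, truth = simulate_acquisition(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study conditions: Rician channel sigma 5 (SNR ~ 18 at b=100)."""
    spec = PhantomSpec(seed=0)
    series, truth = simulate_acquisition(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def snr10_phantom():
    """Channel sigma 9: SNR ~ 10 on the b=100 liver signal."""
    spec = PhantomSpec(noise_sigma=9.0, seed=0)
    series, truth = simulate_acquisition(spec)
    return spec, series, truth


def _lra(series, truth):
    roi = matching_roi(truth.adc_map, CENTER)
    return run_lra(series, roi.mask, CENTER), roi


@pytest.fixture(scope="session")
def noiseless_lra(noiseless_phantom):
    spec, series, truth = noiseless_phantom
    result, roi = _lra(series, truth)
    return spec, series, truth, result


@pytest.fixture(scope="session")
def snr10_lra(snr10_phantom):
    spec, series, truth = snr10_phantom
    result, roi = _lra(series, truth)
    return spec, series, truth, result


@pytest.fixture(scope="session")
def pipeline_result():
    cfg = PipelineConfig(phantom=PhantomSpec(seed=0))
    return cfg, run_pipeline(cfg)


def reference_relative_shifts(series, truth, center=CENTER):
    """True shifts relative to the parity group the reference slice
    belongs to (lowest b, first direction, repeat 1)."""
    parity = "odd" if center % 2 else "even"
    key = (min(series.b_values), series.directions[0], 1, parity)
    return truth.relative_shifts(key)


def angle_deg(a, b):
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    return np.degrees(np.arccos(min(1.0, abs(float(a @ b)))))
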