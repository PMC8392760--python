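"""Shared fixtures: analytic boluses and phantom scans.

Heavier phantom artefacts are session-scoped so the rendering cost is
paid once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from mlifpet.curves import TimeActivityCurve, default_frame_schedule, window_0_to_6min
from mlifpet.io_cli import RunConfig, process_scan, simulate_scan_records
from mlifpet.phantom import (
    PhantomGeometry,
    generate_aif,
    generate_wrist_measurement,
    render_dynamic_image,
    sample_subject,
)


def gamma_bolus(
    t: np.ndarray, amplitude: float = 50.0, t0: float = 15.0, tp: float = 10.0, alpha: float = 3.0
) -> np.ndarray:
    """Smooth gamma-variate bolus used as a known analytic test curve."""
    tt = np.maximum(np.asarray(t, dtype=float) - t0, 0.0)
    return amplitude * (tt / tp) ** alpha * np.exp(alpha * (1.0 - tt / tp))


@pytest.fixture
def bolus_curve() -> TimeActivityCurve:
    t = np.arange(0.0, 361.0)
    return TimeActivityCurve(t, gamma_bolus(t), grid_kind="uniform-1s")


@pytest.fixture
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def subject():
    return sample_subject(7, "baseline")


@pytest.fixture(scope="session")
def clean_scan(subject):
    """Noise-free, PSF-free rendering: the exact-recovery reference."""
    geom = PhantomGeometry(psf_fwhm_mm=0.0)
    img, gm = render_dynamic_image(subject, geom, noise_scale=0.0, rng_seed=0)
    return img, gm


@pytest.fixture(scope="session")
def noisy_scan(subject):
    """Default-noise, default-PSF rendering of the same subject."""
    img, gm = render_dynamic_image(subject, noise_scale=1.0, rng_seed=3)
    return img, gm


@pytest.fixture(scope="session")
def local_aif_360(subject):
    return window_0_to_6min(generate_aif(subject))


@pytest.fixture(scope="session")
def noisy_record(noisy_scan, subject):
    img, gm = noisy_scan
    meas = generate_wrist_measurement(subject, noise_scale=1.0, rng_seed=4)
    return process_scan(img, gm, meas, RunConfig())


@pytest.fixture(scope="session")
def phantom_cohort():
    """20-subject paired phantom cohort run through the full pipeline."""
    baseline, acz, truth = simulate_scan_records(20, seed=42)
    return baseline, acz, truth
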